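"""Single line-level of depression (SL-LD) outliers and their randomization test.

A probe whose detected outlier sublines all belong to one inbred line AND one
depression level is an SL-LD outlier — the signature expected of a fixed,
line-specific genetic alteration that both depresses fitness and perturbs
expression.  Significance of the number of SL-LD probes is assessed by a
Westfall-Young-style randomization: the (line, level) identification codes of
the 24 inbred sublines are shuffled as a unit across ALL probes, so each
probe's outlier identities — and hence the between-probe correlation
structure — are conserved, and only the coincidence of codes is broken.
Outlier calls are never recomputed inside a replicate; only the codes move.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import SampleSheet
from .grubbs import sequential_outlier_scan

SLLD_COLUMNS = ("probe_id", "line", "level", "direction", "n_outliers",
                "alpha", "outlier_samples")

LADDER_COLUMNS = ("alpha", "direction", "n_outliers", "n_candidate_probes",
                  "observed_total", "observed_most", "observed_least",
                  "expected_mean", "p_total", "p_most_only")


def _check_single_family(calls: pd.DataFrame) -> tuple[float, str]:
    """Calls must come from one scan: a single alpha and a single direction."""
    alphas = calls["alpha"].unique()
    directions = calls["direction"].unique()
    if len(alphas) > 1 or len(directions) > 1:
        raise ValueError(
            "classify/randomize expect calls from a single scan "
            f"(alphas={alphas!r}, directions={directions!r})"
        )
    return (float(alphas[0]) if len(alphas) else np.nan,
            str(directions[0]) if len(directions) else "")


def _top_outlier_tuples(calls: pd.DataFrame, sheet: SampleSheet,
                        n_outliers: int, mode: str) -> pd.DataFrame:
    """Per-probe tuple of the top-``n_outliers`` outlier samples.

    ``mode="at_least"`` keeps probes with n or more sequential calls (using
    the first n by order); ``mode="exact"`` requires exactly n.  Probes whose
    top calls include a control sample are dropped: controls carry no
    (line, level) code, so they can never contribute to an SL-LD coincidence,
    observed or randomized.
    """
    if mode not in ("at_least", "exact"):
        raise ValueError(f"mode must be 'at_least' or 'exact', got {mode!r}")
    known = set(sheet.sample_ids)
    bad = set(calls["sample_id"]) - known
    if bad:
        raise KeyError(f"outlier calls reference unknown samples: "
                       f"{sorted(bad)[:5]}")
    rows = []
    for probe, grp in calls.groupby("probe_id", sort=False):
        if mode == "exact" and len(grp) != n_outliers:
            continue
        if len(grp) < n_outliers:
            continue
        top = grp.sort_values("order", kind="stable").head(n_outliers)
        samples = tuple(top["sample_id"])
        cells = [sheet.cell_of(s) for s in samples]
        if any(c is None for c in cells):
            continue
        rows.append({"probe_id": probe, "samples": samples, "cells": cells})
    return pd.DataFrame(rows, columns=["probe_id", "samples", "cells"])


def classify_slld(calls: pd.DataFrame, sheet: SampleSheet,
                  n_outliers: int = 2, mode: str = "at_least") -> pd.DataFrame:
    """Probes whose top-``n_outliers`` outlier sublines share one (line, level).

    ``calls`` must come from a single scan (one alpha, one direction).
    Returns one row per SL-LD probe with the shared cell and the contributing
    samples.
    """
    alpha, direction = _check_single_family(calls)
    tuples = _top_outlier_tuples(calls, sheet, n_outliers, mode)
    rows = []
    for _, row in tuples.iterrows():
        cells = set(row["cells"])
        if len(cells) == 1:
            line, level = next(iter(cells))
            rows.append({
                "probe_id": row["probe_id"],
                "line": line,
                "level": level,
                "direction": direction,
                "n_outliers": n_outliers,
                "alpha": alpha,
                "outlier_samples": ";".join(row["samples"]),
            })
    return pd.DataFrame(rows, columns=list(SLLD_COLUMNS))


@dataclass
class RandomizationResult:
    """Observed vs randomized SL-LD counts for one scan family."""

    direction: str
    n_outliers: int
    alpha: float
    observed_total: int
    observed_most: int
    observed_least: int
    expected_mean: float
    expected_most_mean: float
    expected_least_mean: float
    replicate_sd: float
    p_total: float
    p_most_only: float
    n_candidate_probes: int
    n_replicates: int
    seed: int | None
    most_comparison: str
    add_one: bool

    def to_dict(self) -> dict:
        return asdict(self)


def randomization_test(calls: pd.DataFrame, sheet: SampleSheet,
                       n_outliers: int = 2, n_replicates: int = 10_000,
                       seed=0, mode: str = "at_least",
                       most_comparison: str = "total",
                       add_one: bool = False) -> RandomizationResult:
    """Code-relabeling significance test for the observed SL-LD count.

    Each replicate draws a uniform random permutation of the (line, level)
    codes over the inbred sublines (controls are never randomized), keeps
    every probe's outlier sample identities fixed, and recounts SL-LD
    coincidences.  ``p_total`` is the proportion of replicates whose count
    reaches the observed total; ``p_most_only`` compares the observed count in
    most-depressed cells against the replicate distribution of TOTAL counts
    (``most_comparison="total"``, deliberately conservative) or against half
    the replicate total (``"half"``, since the two levels have equal expected
    shares under the null).  ``add_one`` applies the (b+1)/(R+1) small-sample
    correction.
    """
    if most_comparison not in ("total", "half"):
        raise ValueError("most_comparison must be 'total' or 'half'")
    alpha, direction = _check_single_family(calls)

    inbred = sheet.inbred_ids
    pos = {s: i for i, s in enumerate(inbred)}
    cells = [sheet.cell_of(s) for s in inbred]
    cell_ids, uniq = pd.factorize(pd.Series(cells))
    counts_per_cell = np.bincount(cell_ids)
    if (counts_per_cell < 2).any():
        raise ValueError("every (line, level) cell needs >= 2 sublines for "
                         "the randomization test")
    codes = np.asarray(cell_ids)
    is_most_cell = np.array([lv == "most_depressed" for _, lv in uniq])

    tuples = _top_outlier_tuples(calls, sheet, n_outliers, mode)
    n_candidates = len(tuples)

    rng = np.random.default_rng(seed)
    seed_out = int(seed) if isinstance(seed, (int, np.integer)) else None

    if n_candidates:
        T = np.array([[pos[s] for s in samples]
                      for samples in tuples["samples"]], dtype=np.intp)
        obs_cells = codes[T]
        obs_same = np.all(obs_cells == obs_cells[:, :1], axis=1)
        observed_total = int(obs_same.sum())
        observed_most = int((obs_same & is_most_cell[obs_cells[:, 0]]).sum())

        perms = np.argsort(rng.random((n_replicates, len(inbred))), axis=1)
        cp = codes[perms]                              # (R, n_inbred)
        first = cp[:, T[:, 0]]                         # (R, P)
        same = np.ones_like(first, dtype=bool)
        for k in range(1, n_outliers):
            same &= cp[:, T[:, k]] == first
        rep_total = same.sum(axis=1)
        rep_most = (same & is_most_cell[first]).sum(axis=1)
    else:
        observed_total = observed_most = 0
        rep_total = np.zeros(n_replicates, dtype=int)
        rep_most = np.zeros(n_replicates, dtype=int)

    def _p(tail_count: int) -> float:
        if add_one:
            return (tail_count + 1) / (n_replicates + 1)
        return tail_count / n_replicates

    p_total = _p(int((rep_total >= observed_total).sum()))
    if most_comparison == "total":
        p_most = _p(int((rep_total >= observed_most).sum()))
    else:
        p_most = _p(int((rep_total / 2.0 >= observed_most).sum()))

    return RandomizationResult(
        direction=direction,
        n_outliers=n_outliers,
        alpha=alpha,
        observed_total=observed_total,
        observed_most=observed_most,
        observed_least=observed_total - observed_most,
        expected_mean=float(rep_total.mean()),
        expected_most_mean=float(rep_most.mean()),
        expected_least_mean=float((rep_total - rep_most).mean()),
        replicate_sd=float(rep_total.std(ddof=0)),
        p_total=float(p_total),
        p_most_only=float(p_most),
        n_candidate_probes=n_candidates,
        n_replicates=int(n_replicates),
        seed=seed_out,
        most_comparison=most_comparison,
        add_one=add_one,
    )


def alpha_ladder(matrix, sheet: SampleSheet,
                 alphas: Sequence[float] = (0.10, 0.05, 0.025, 0.01),
                 n_outliers: int = 2,
                 directions: Sequence[str] = ("up", "down"),
                 n_replicates: int = 10_000, seed: int = 0,
                 max_outliers: int = 3, mode: str = "at_least",
                 sidedness: str = "one", include_controls: bool = False,
                 most_comparison: str = "total") -> pd.DataFrame:
    """Observed vs expected SL-LD counts across a ladder of Grubbs alphas.

    For every (alpha, direction): run the sequential scan, classify SL-LD
    probes, and attach the randomization test.  Returns a tidy table (one row
    per alpha x direction), the machine-readable analogue of the per-alpha
    bar chart of observed and expected SL-LD counts.
    """
    if any(not 0 < a < 1 for a in alphas):
        raise ValueError("alphas must lie in (0, 1)")
    children = np.random.SeedSequence(seed).spawn(len(alphas) * len(directions))
    rows = []
    k = 0
    for direction in directions:
        for alpha in alphas:
            calls = sequential_outlier_scan(
                matrix, sheet=sheet, alpha=alpha, max_outliers=max_outliers,
                direction=direction, sidedness=sidedness,
                include_controls=include_controls)
            res = randomization_test(
                calls, sheet, n_outliers=n_outliers,
                n_replicates=n_replicates, seed=children[k], mode=mode,
                most_comparison=most_comparison)
            k += 1
            rows.append({
                "alpha": alpha,
                "direction": direction,
                "n_outliers": n_outliers,
                "n_candidate_probes": res.n_candidate_probes,
                "observed_total": res.observed_total,
                "observed_most": res.observed_most,
                "observed_least": res.observed_least,
                "expected_mean": res.expected_mean,
                "p_total": res.p_total,
                "p_most_only": res.p_most_only,
            })
    return pd.DataFrame(rows, columns=list(LADDER_COLUMNS))
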