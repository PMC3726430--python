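"""Grubbs (extreme studentized deviate) tests and the sequential outlier scan.

A Grubbs test asks whether the most extreme value of a sample is too far from
the mean, in units of the sample standard deviation, to be plausible under a
Gaussian model.  The scan applies the test per probe to the expression of the
eligible samples (by default the 24 inbred sublines), removes a detected
outlier, and re-tests the remainder — up to ``max_outliers`` calls per probe
and direction.  Up- and down-regulation are scanned separately with one-sided
tests by default, so "order 1" is the most extreme expression in that
direction, "order 2" the next after removal, and so on.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, SampleSheet

CALL_COLUMNS = ("probe_id", "sample_id", "direction", "order", "G", "G_crit",
                "alpha", "n_at_test")


class DegenerateDataError(ValueError):
    """The input has zero variance, so the studentized deviate is undefined."""


def grubbs_statistic(values: Sequence[float],
                     side: str = "two_sided") -> tuple[float, int]:
    """Studentized deviation of the extreme value from the sample mean.

    Parameters
    ----------
    values
        1-D numeric sample, ``n >= 3``, with positive variance.
    side
        ``"min"`` tests the smallest value, ``"max"`` the largest,
        ``"two_sided"`` whichever deviates most from the mean.

    Returns
    -------
    (G, index)
        The statistic ``|x_extreme - mean| / sd`` (sd with the n-1
        denominator) and the position of the extreme value.  Ties at the
        extreme resolve to the first occurrence.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-D")
    if x.size < 3:
        raise ValueError(f"Grubbs test requires n >= 3, got n={x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance: Grubbs statistic undefined")
    if side == "max":
        idx = int(np.argmax(x))
        g = (x[idx] - mean) / sd
    elif side == "min":
        idx = int(np.argmin(x))
        g = (mean - x[idx]) / sd
    elif side == "two_sided":
        dev = np.abs(x - mean)
        idx = int(np.argmax(dev))
        g = dev[idx] / sd
    else:
        raise ValueError(f"unknown side {side!r}")
    return float(g), idx


def grubbs_critical(n: int, alpha: float, sidedness: str = "one") -> float:
    """Critical value of the Grubbs statistic at level ``alpha``.

    Uses the exact Student-t construction
    ``G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2))`` with ``t`` the
    upper-tail quantile at ``alpha/n`` (one-sided) or ``alpha/(2n)``
    (two-sided), ``n-2`` degrees of freedom.  The result is always strictly
    below the attainable maximum ``(n-1)/sqrt(n)``.
    """
    n = int(n)
    if n < 3:
        raise ValueError(f"Grubbs critical value requires n >= 3, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if sidedness not in ("one", "two"):
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    k = 1 if sidedness == "one" else 2
    t = stats.t.isf(alpha / (k * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def sequential_outlier_scan(matrix: ExpressionMatrix,
                            sheet: SampleSheet | None = None,
                            eligible_samples: Sequence[str] | None = None,
                            alpha: float = 0.05,
                            max_outliers: int = 3,
                            direction: str = "down",
                            sidedness: str = "one",
                            include_controls: bool = False) -> pd.DataFrame:
    """Sequential per-probe Grubbs scan in one direction.

    For every probe: test the extreme expression among the currently remaining
    eligible samples at level ``alpha``; if significant, emit a call, drop that
    sample, and repeat (recomputing mean and sd) until the test fails or
    ``max_outliers`` calls have been made.  Eligible samples default to the
    inbred sublines of ``sheet`` (``include_controls=True`` adds controls); if
    no sheet is given, all samples are eligible.

    Returns a call table with columns ``probe_id, sample_id, direction, order,
    G, G_crit, alpha, n_at_test``; constant (zero-variance) probes yield no
    calls.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if max_outliers < 1:
        raise ValueError("max_outliers must be >= 1")
    if eligible_samples is None:
        if sheet is not None:
            eligible_samples = (sheet.sample_ids if include_controls
                                else sheet.inbred_ids)
        else:
            eligible_samples = matrix.sample_ids
    eligible = list(eligible_samples)
    missing = [s for s in eligible if s not in matrix.values.columns]
    if missing:
        raise KeyError(f"eligible samples not in matrix: {missing[:5]}")
    n0 = len(eligible)
    if n0 < 3 + max_outliers - 1:
        raise ValueError(
            f"need >= {3 + max_outliers - 1} eligible samples for "
            f"max_outliers={max_outliers}, got {n0}"
        )

    work = matrix.values[eligible].to_numpy(dtype=float, copy=True)
    probe_ids = np.asarray(matrix.probe_ids, dtype=object)
    n_probes = work.shape[0]
    active = np.ones(n_probes, dtype=bool)
    side = "min" if direction == "down" else "max"

    records: list[pd.DataFrame] = []
    for order in range(1, max_outliers + 1):
        n = n0 - (order - 1)
        if n < 3 or not active.any():
            break
        crit = grubbs_critical(n, alpha, sidedness)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(work, axis=1)
            sd = np.nanstd(work, axis=1, ddof=1)
            if side == "min":
                ext = np.nanmin(work, axis=1)
                idx = _nan_arg(work, np.nanargmin)
                g = np.where(sd > 0, (mean - ext) / np.where(sd > 0, sd, 1.0),
                             -np.inf)
            else:
                ext = np.nanmax(work, axis=1)
                idx = _nan_arg(work, np.nanargmax)
                g = np.where(sd > 0, (ext - mean) / np.where(sd > 0, sd, 1.0),
                             -np.inf)
        sig = active & (g > crit)
        hit = np.nonzero(sig)[0]
        if hit.size:
            records.append(pd.DataFrame({
                "probe_id": probe_ids[hit],
                "sample_id": [eligible[i] for i in idx[hit]],
                "direction": direction,
                "order": order,
                "G": g[hit],
                "G_crit": crit,
                "alpha": alpha,
                "n_at_test": n,
            }))
            work[hit, idx[hit]] = np.nan
        active = sig

    if not records:
        return pd.DataFrame(columns=list(CALL_COLUMNS))
    calls = pd.concat(records, ignore_index=True)
    return calls.sort_values(["probe_id", "order"],
                             kind="stable").reset_index(drop=True)


def _nan_arg(a: np.ndarray, fn) -> np.ndarray:
    """Row-wise nan-aware argmin/argmax; first occurrence breaks ties."""
    return fn(a, axis=1)
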