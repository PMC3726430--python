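"""Productivity summaries, inbreeding depression rates, and F-coefficient utilities.

The inbreeding depression rate (IDR) expresses the proportional loss of a
fitness trait per unit increase of the inbreeding coefficient F:
``IDR = (W_O - W_I) / (F * W_O)`` with ``W_O`` the outbred control mean and
``W_I`` the inbred mean.  On this scale 1.0 reads as "1% fitness loss per 1%
increase in inbreeding".  The study's mating scheme (8 generations of sib
mating) yields F ~= 0.7, which is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_model import ProductivityTable


def idr(w_o: float, w_i: float, f: float = 0.7) -> float:
    """Inbreeding depression rate per unit F: ``(w_o - w_i) / (f * w_o)``.

    Scale-invariant in productivity units.  Multiply by 1 to read as % per
    1% increase in F.
    """
    if w_o <= 0:
        raise ValueError(f"control mean productivity must be > 0, got {w_o}")
    if not 0 < f <= 1:
        raise ValueError(f"inbreeding coefficient must be in (0, 1], got {f}")
    return (w_o - w_i) / (f * w_o)


@dataclass
class DepressionSummary:
    """Overall and per-subline depression rates from a productivity table."""

    w_o: float
    w_i: float
    f: float
    overall_idr: float
    per_subline: pd.DataFrame  # line, subline_id, mean_productivity, idr

    def to_dict(self) -> dict:
        return {
            "w_o": self.w_o,
            "w_i": self.w_i,
            "f": self.f,
            "overall_idr": self.overall_idr,
            "per_subline": self.per_subline.to_dict(orient="records"),
        }


def summarize_depression(productivity: ProductivityTable,
                         f: float = 0.7) -> DepressionSummary:
    """Compute W_O, W_I, the overall IDR, and per-subline IDRs.

    ``W_O`` is the mean over control vials (rows with ``line == "control"``),
    ``W_I`` the mean of per-subline means across all inbred sublines; each
    subline's own rate uses its mean in place of ``W_I``.
    """
    t = productivity.table
    control = t.loc[t["line"] == "control", "pupae_per_female"]
    if control.empty:
        raise ValueError("productivity table has no control rows")
    w_o = float(control.mean())
    means = productivity.subline_means()
    if means.empty:
        raise ValueError("productivity table has no inbred rows")
    w_i = float(means["mean_productivity"].mean())
    per = means.copy()
    per["idr"] = [idr(w_o, m, f) for m in per["mean_productivity"]]
    return DepressionSummary(w_o=w_o, w_i=w_i, f=f,
                             overall_idr=idr(w_o, w_i, f), per_subline=per)


def select_extreme_sublines(productivity: ProductivityTable, k: int = 3,
                            min_viable: float | None = None) -> pd.DataFrame:
    """Pick the k most- and k least-depressed sublines per line.

    Sublines are ranked by mean productivity across replicate vials; the
    most-depressed set is the k lowest means, the least-depressed set the k
    highest.  ``min_viable`` excludes sublines whose mean falls below the
    threshold from the most-depressed set (the "enough individuals to be
    further analysed" filter); by default no filter is applied.  Ties are
    broken by subline id, ascending.  Returns a tidy frame with columns
    ``line, subline_id, mean_productivity, group``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    means = productivity.subline_means()
    rows = []
    for line, grp in means.groupby("line", sort=True):
        grp = grp.sort_values(["mean_productivity", "subline_id"],
                              kind="stable")
        eligible_most = grp if min_viable is None else grp[
            grp["mean_productivity"] >= min_viable]
        if len(eligible_most) < k or len(grp) < 2 * k:
            raise ValueError(
                f"line {line!r}: need >= {k} viable and >= {2 * k} total "
                f"sublines, got {len(eligible_most)} viable of {len(grp)}"
            )
        most = eligible_most.head(k).assign(group="most_depressed")
        least = (grp.sort_values(["mean_productivity", "subline_id"],
                                 ascending=[False, True], kind="stable")
                 .head(k).assign(group="least_depressed"))
        overlap = set(most["subline_id"]) & set(least["subline_id"])
        if overlap:
            raise ValueError(
                f"line {line!r}: most/least selections overlap ({overlap}); "
                f"not enough distinct sublines"
            )
        rows.append(most)
        rows.append(least)
    return pd.concat(rows, ignore_index=True)


def sib_mating_F(t: int, g_switch: int | None = None,
                 n_e: float | None = None) -> float:
    """Inbreeding coefficient after ``t`` generations of full-sib mating.

    Uses the recurrence ``F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4``.  If
    ``g_switch`` is given, generations after it instead accumulate
    ``dF = 1 / (2 n_e)`` per generation (``F_t = F_{t-1} + (1-F_{t-1})/(2 n_e)``),
    modelling a switch from single-pair to small-group mating (e.g. 2 males x
    2 females, ``n_e = 4``).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if (g_switch is None) != (n_e is None):
        raise ValueError("g_switch and n_e must be given together")
    f_prev2, f_prev1 = 0.0, 0.0
    f = 0.0
    for gen in range(1, t + 1):
        if g_switch is not None and gen > g_switch:
            f = f_prev1 + (1.0 - f_prev1) / (2.0 * n_e)
        else:
            f = (1.0 + 2.0 * f_prev1 + f_prev2) / 4.0
        f_prev2, f_prev1 = f_prev1, f
    return f
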