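"""Reference constants describing the inbreeding-depression microarray study.

The experiment this package analyses took four inbred *Drosophila melanogaster*
lines (``a``-``d``), each founded from a single outbred couple and sib-mated for
eight generations into many sublines.  Pupa productivity was scored for every
surviving subline; from each line the three most- and three least-depressed
sublines were profiled on expression arrays alongside three outbred controls,
giving 27 arrays in total (24 inbred + 3 controls).

Everything here is printed study metadata — design dimensions, published
productivity means, the cluster-1 correlation table, and the headline
candidate counts.  Nothing in this module is computed by the package; the
pipeline's synthetic-data generator takes these values as its defaults so that
simulations emulate the study's conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Design dimensions
# ---------------------------------------------------------------------------

LINES = ("a", "b", "c", "d")
LEVELS = ("most_depressed", "least_depressed")
SUBLINES_PER_CELL = 3
N_CONTROLS = 3
N_INBRED_SAMPLES = len(LINES) * len(LEVELS) * SUBLINES_PER_CELL  # 24
N_SAMPLES = N_INBRED_SAMPLES + N_CONTROLS  # 27

#: Probe sets retained after present-call filtering in the original analysis.
N_PROBES_ANALYSED = 9133

#: Average variance of expression between sublines within a line, by group.
WITHIN_LINE_VARIANCES = {
    "control": 0.028,
    "least_depressed": 0.044,
    "most_depressed": 0.086,
}

# ---------------------------------------------------------------------------
# Productivity and inbreeding
# ---------------------------------------------------------------------------

#: Mean pupae per female of the outbred control (70 replicated vials).
W_O = 101.97
#: Mean pupae per female across all inbred sublines.
W_I = 34.28
#: Average inbreeding coefficient after the 8-generation sib-mating scheme.
F_STUDY = 0.7
#: Printed span of per-subline inbreeding depression rates (% per 1% F).
IDR_RANGE = (0.64, 1.4)

#: GEO accession of the deposited expression data (requires download + RMA).
GEO_ACCESSION = "GSE47176"

# ---------------------------------------------------------------------------
# Headline real-data results — reference only, NOT desk-scale reproducible
# ---------------------------------------------------------------------------

#: Published candidate counts from the real arrays.  Reproducing them needs the
#: GEO series plus RMA normalisation and present-call filtering, which this
#: package deliberately does not perform; they are kept as flagged reference
#: values and are never computed or asserted by the desk-scale pipeline.
HEADLINE_RESULTS = {
    "n_slld_candidates_alpha_05": 14,
    "n_three_outlier_up_alpha_05": 9,
    "n_three_outlier_down_alpha_05": 24,
    "candidate_cluster_sizes": (6, 3, 2, 3),
    "candidate_cluster_lines": ("b", "c", "d", "a"),
    "desk_scale": False,
    "requires": f"GEO {GEO_ACCESSION} + RMA normalisation + present-call filter",
}

# ---------------------------------------------------------------------------
# Cluster-1 correlation table (6 genes)
# ---------------------------------------------------------------------------

CLUSTER1_GENES = ("CG3610", "CG3121", "CG11598", "CG5509", "CG32396", "CG11414")

# Pairwise Pearson correlations between the six cluster-1 genes, all 27 samples.
_R_FULL_UPPER = [
    # CG3121 CG11598 CG5509 CG32396 CG11414   (row gene vs later genes)
    [0.921, 0.872, 0.901, 0.886, 0.842],  # CG3610
    [0.815, 0.846, 0.832, 0.769],         # CG3121
    [0.906, 0.935, 0.891],                # CG11598
    [0.923, 0.933],                       # CG5509
    [0.943],                              # CG32396
]

# Same pairs after removing the two outlier sublines (25 samples).
_R_REDUCED_LOWER = [
    [0.770],                              # CG3121 vs CG3610
    [0.445, 0.418],                       # CG11598 vs CG3610, CG3121
    [0.690, 0.661, 0.432],                # CG5509
    [0.565, 0.548, 0.616, 0.409],         # CG32396
    [0.313, 0.297, 0.164, 0.226, 0.462],  # CG11414
]

#: Pairs printed in bold in the reduced half (significant after BH at 0.05).
CLUSTER1_REDUCED_BOLD = [
    [True],
    [True, False],
    [True, True, False],
    [True, True, True, False],
    [False, False, False, False, True],
]


def _symmetric(genes, upper=None, lower=None) -> pd.DataFrame:
    m = len(genes)
    a = np.eye(m)
    if upper is not None:
        for i, row in enumerate(upper):
            for k, v in enumerate(row):
                j = i + 1 + k
                a[i, j] = a[j, i] = v
    if lower is not None:
        for r, row in enumerate(lower):
            i = r + 1
            for j, v in enumerate(row):
                a[i, j] = a[j, i] = v
    return pd.DataFrame(a, index=list(genes), columns=list(genes))


def cluster1_r_full() -> pd.DataFrame:
    """Symmetric correlation matrix of the 6 cluster-1 genes, all 27 samples."""
    return _symmetric(CLUSTER1_GENES, upper=_R_FULL_UPPER)


def cluster1_r_reduced() -> pd.DataFrame:
    """Symmetric correlation matrix after removal of the two outlier sublines."""
    return _symmetric(CLUSTER1_GENES, lower=_R_REDUCED_LOWER)


def cluster1_bold_flags() -> pd.DataFrame:
    """Boolean matrix of the reduced half's bold (BH-significant) pairs."""
    df = _symmetric(CLUSTER1_GENES, lower=CLUSTER1_REDUCED_BOLD).astype(bool)
    for g in CLUSTER1_GENES:
        df.loc[g, g] = False
    return df
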