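"""Characterization of candidate genes: correlations, BH tests, clustering.

Candidates that share a regulatory cause should stay correlated even after
the outlier sublines that revealed them are removed.  This module computes
pairwise Pearson correlations with and without specified samples, tests each
pair with the two-sided t statistic ``t = r * sqrt((n-2)/(1-r^2))`` (df =
n-2) under Benjamini-Hochberg FDR control, and groups candidates by
complete-linkage hierarchical clustering on the distance ``1 - |r|`` with
plain bootstrap proportions (resampling samples with replacement) as cluster
support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix


def mean_pairwise(r: pd.DataFrame | np.ndarray) -> float:
    """Mean of the off-diagonal upper half of a symmetric pair matrix."""
    a = np.asarray(r, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("expected a square matrix")
    iu = np.triu_indices(a.shape[0], k=1)
    return float(a[iu].mean())


def _pearson_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Gene-by-gene Pearson correlation of the rows of ``df``."""
    sd = df.std(axis=1, ddof=1)
    zero = sd[sd == 0]
    if not zero.empty:
        raise ValueError(f"zero-variance gene(s): {list(zero.index)[:5]}")
    r = np.corrcoef(df.to_numpy())
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=df.index,
                        columns=df.index)


def correlation_significance(r_matrix: pd.DataFrame, n: int,
                             alpha: float = 0.05
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided t tests on a correlation matrix with BH step-up control.

    Each unordered pair is tested with ``t = r sqrt((n-2)/(1-r^2))`` against
    Student t with ``n - 2`` degrees of freedom; ``|r| = 1`` maps to p = 0.
    Returns symmetric DataFrames of raw p-values and of BH significance flags
    at level ``alpha`` (diagonals: p = 0, flag = False).
    """
    if n < 3:
        raise ValueError(f"correlation test needs n >= 3, got {n}")
    genes = list(r_matrix.index)
    r = np.asarray(r_matrix, dtype=float)
    m = len(genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(m, k=1)
    flags_flat = multipletests(p[iu], alpha=alpha, method="fdr_bh")[0]
    flags = np.zeros((m, m), dtype=bool)
    flags[iu] = flags_flat
    flags |= flags.T
    return (pd.DataFrame(p, index=genes, columns=genes),
            pd.DataFrame(flags, index=genes, columns=genes))


@dataclass
class CorrelationReport:
    """Pairwise correlations before/after removing outlier sublines."""

    genes: list[str]
    removed_samples: list[str]
    n_full: int
    n_reduced: int
    r_full: pd.DataFrame
    r_reduced: pd.DataFrame
    p_full: pd.DataFrame
    p_reduced: pd.DataFrame
    sig_full: pd.DataFrame
    sig_reduced: pd.DataFrame
    mean_r_full: float
    mean_r_reduced: float
    alpha: float

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "removed_samples": self.removed_samples,
            "n_full": self.n_full,
            "n_reduced": self.n_reduced,
            "alpha": self.alpha,
            "mean_r_full": self.mean_r_full,
            "mean_r_reduced": self.mean_r_reduced,
            "r_full": self.r_full.round(6).to_dict(),
            "r_reduced": self.r_reduced.round(6).to_dict(),
            "p_full": self.p_full.to_dict(),
            "p_reduced": self.p_reduced.to_dict(),
            "sig_full": self.sig_full.astype(bool).to_dict(),
            "sig_reduced": self.sig_reduced.astype(bool).to_dict(),
        }


def correlation_with_without(matrix: ExpressionMatrix, genes: Sequence[str],
                             removed_samples: Sequence[str] = (),
                             alpha: float = 0.05) -> CorrelationReport:
    """Pairwise gene correlations over all samples and after sample removal.

    ``removed_samples`` may have any size (e.g. two outlier sublines, or
    three where the outliers span three sublines); at least 3 samples must
    remain.  Mean correlations are exact averages over the unordered pairs.
    """
    genes = list(genes)
    sub = matrix.subset(probes=genes).values
    removed = list(removed_samples)
    unknown = [s for s in removed if s not in sub.columns]
    if unknown:
        raise KeyError(f"removed samples not in matrix: {unknown[:5]}")
    kept = [s for s in sub.columns if s not in set(removed)]
    if len(kept) < 3:
        raise ValueError(f"need >= 3 retained samples, got {len(kept)}")

    r_full = _pearson_rows(sub)
    r_reduced = _pearson_rows(sub[kept])
    n_full, n_reduced = sub.shape[1], len(kept)
    p_full, sig_full = correlation_significance(r_full, n_full, alpha)
    p_red, sig_red = correlation_significance(r_reduced, n_reduced, alpha)
    return CorrelationReport(
        genes=genes, removed_samples=removed,
        n_full=n_full, n_reduced=n_reduced,
        r_full=r_full, r_reduced=r_reduced,
        p_full=p_full, p_reduced=p_red,
        sig_full=sig_full, sig_reduced=sig_red,
        mean_r_full=mean_pairwise(r_full),
        mean_r_reduced=mean_pairwise(r_reduced),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Complete-linkage tree on the distance ``1 - |r|`` between genes.

    ``linkage`` is a scipy linkage matrix over ``genes`` (which are sorted
    lexicographically so that distance ties resolve deterministically).
    ``bp`` holds one bootstrap proportion per internal node, aligned with the
    linkage rows; single-gene leaves have support 1 by convention and are not
    listed.
    """

    genes: list[str]
    linkage: np.ndarray
    labels: pd.Series | None = None
    newick: str = ""
    bp: np.ndarray | None = None
    n_boot: int = 0
    seed: int | None = None

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def node_gene_sets(self) -> list[frozenset[str]]:
        """Leaf-gene set of every internal node, in linkage order."""
        return _node_leafsets(self.linkage, self.genes)

    def merge_table(self) -> pd.DataFrame:
        sets = self.node_gene_sets()
        rows = []
        for i, s in enumerate(sets):
            rows.append({
                "node": i,
                "height": float(self.linkage[i, 2]),
                "n_genes": len(s),
                "genes": ";".join(sorted(s)),
                "bp": float(self.bp[i]) if self.bp is not None else np.nan,
            })
        return pd.DataFrame(rows)


def _abs_corr_distance(df: pd.DataFrame) -> np.ndarray:
    r = _pearson_rows(df).to_numpy()
    d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return squareform(d, checks=False)


def _node_leafsets(Z: np.ndarray, genes: Sequence[str]) -> list[frozenset]:
    n = len(genes)
    sets: list[frozenset] = []
    for i in range(Z.shape[0]):
        members: set[str] = set()
        for child in (int(Z[i, 0]), int(Z[i, 1])):
            if child < n:
                members.add(genes[child])
            else:
                members |= sets[child - n]
        sets.append(frozenset(members))
    return sets


def _to_newick(Z: np.ndarray, genes: Sequence[str]) -> str:
    n = len(genes)

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height(node)
        if node < n:
            return f"{genes[node]}:{bl:.6g}"
        i = node - n
        left = render(int(Z[i, 0]), height(node))
        right = render(int(Z[i, 1]), height(node))
        return f"({left},{right}):{bl:.6g}"

    root = n + Z.shape[0] - 1
    i = root - n
    left = render(int(Z[i, 0]), height(root))
    right = render(int(Z[i, 1]), height(root))
    return f"({left},{right});"


def hierarchical_cluster(matrix: ExpressionMatrix, genes: Sequence[str],
                         cut_height: float | None = None,
                         n_clusters: int | None = None) -> ClusterResult:
    """Complete-linkage clustering of genes on the distance ``1 - |r|``.

    Correlations use all samples of the matrix.  Gene order is sorted
    lexicographically before linkage so ties break deterministically.  If
    ``cut_height`` or ``n_clusters`` is given, flat cluster memberships are
    attached.
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("clustering needs >= 2 genes")
    sub = matrix.subset(probes=genes).values
    Z = hierarchy.linkage(_abs_corr_distance(sub), method="complete")
    labels = None
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    elif cut_height is not None:
        labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    if labels is not None:
        labels = pd.Series(labels, index=genes, name="cluster")
    return ClusterResult(genes=genes, linkage=Z, labels=labels,
                         newick=_to_newick(Z, genes))


def bootstrap_support(matrix: ExpressionMatrix, genes: Sequence[str],
                      n_boot: int = 1000, seed: int = 0,
                      cut_height: float | None = None,
                      n_clusters: int | None = None) -> ClusterResult:
    """Bootstrap proportions (BP) for every internal node of the gene tree.

    Samples (matrix columns) are resampled with replacement ``n_boot`` times;
    a node's BP is the fraction of replicate trees containing that node's
    exact gene set as a cluster.  A gene that is constant in a replicate gets
    correlation 0 with every other gene there (the replicate still yields a
    tree).  Deterministic given ``seed``.
    """
    result = hierarchical_cluster(matrix, genes, cut_height=cut_height,
                                  n_clusters=n_clusters)
    targets = result.node_gene_sets()
    sub = matrix.subset(probes=result.genes).values.to_numpy()
    n_samples = sub.shape[1]
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(targets))
    for _ in range(n_boot):
        cols = rng.integers(0, n_samples, size=n_samples)
        xb = sub[:, cols]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.corrcoef(xb)
        r = np.nan_to_num(r, nan=0.0)
        d = 1.0 - np.abs(np.clip(r, -1.0, 1.0))
        np.fill_diagonal(d, 0.0)
        Z = hierarchy.linkage(squareform(d, checks=False), method="complete")
        found = set(_node_leafsets(Z, result.genes))
        for i, t in enumerate(targets):
            if t in found:
                counts[i] += 1
    result.bp = counts / n_boot
    result.n_boot = int(n_boot)
    result.seed = int(seed)
    return result
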