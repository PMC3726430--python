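"""Correlation reports, BH significance, clustering, and bootstrap support."""

import numpy as np
import pandas as pd
import pytest

import inbredscan as ib
from inbredscan import study
from inbredscan.postanalysis import mean_pairwise


def _factor_block_matrix(block_sizes, n_samples=27, within=0.95, seed=0):
    """Genes in blocks sharing a latent factor: high |r| within, low between."""
    rng = np.random.default_rng(seed)
    rows, names, labels = [], [], []
    for b, size in enumerate(block_sizes):
        f = rng.standard_normal(n_samples)
        for k in range(size):
            e = rng.standard_normal(n_samples)
            rows.append(np.sqrt(within) * f + np.sqrt(1 - within) * e)
            names.append(f"blk{b}_g{k}")
            labels.append(b)
    m = ib.ExpressionMatrix(pd.DataFrame(
        rows, index=names, columns=[f"s{j}" for j in range(n_samples)]))
    return m, pd.Series(labels, index=names)


class TestMeanPairwise:
    def test_exact_average_of_printed_triangles(self):
        """Off-diagonal mean equals a direct hand summation of the 15 pairs."""
        upper_vals = [v for row in study._R_FULL_UPPER for v in row]
        assert len(upper_vals) == 15
        assert mean_pairwise(study.cluster1_r_full()) == pytest.approx(
            sum(upper_vals) / 15, abs=1e-12)
        lower_vals = [v for row in study._R_REDUCED_LOWER for v in row]
        assert mean_pairwise(study.cluster1_r_reduced()) == pytest.approx(
            sum(lower_vals) / 15, abs=1e-12)

    def test_requires_square_matrix(self):
        with pytest.raises(ValueError):
            mean_pairwise(np.ones((2, 3)))


class TestCorrelationSignificance:
    def test_single_pair_t_and_p(self):
        r = pd.DataFrame([[1.0, 0.445], [0.445, 1.0]],
                         index=["a", "b"], columns=["a", "b"])
        p, _ = ib.correlation_significance(r, n=25)
        # t = 0.445*sqrt(23/(1-0.445^2)) ~= 2.383 -> two-sided p ~= 0.026
        assert p.loc["a", "b"] == pytest.approx(0.0258, abs=5e-4)

    def test_zero_correlation_not_significant(self):
        r = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        p, flags = ib.correlation_significance(r, n=25)
        assert p.loc["a", "b"] == 1.0
        assert not flags.to_numpy().any()

    def test_perfect_correlation_maps_to_zero_p(self):
        r = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]],
                         index=["a", "b"], columns=["a", "b"])
        p, flags = ib.correlation_significance(r, n=10)
        assert p.loc["a", "b"] == 0.0
        assert flags.loc["a", "b"]

    def test_bh_flags_monotone_in_r(self):
        """For fixed n no larger |r| may be non-significant while a smaller
        one is significant."""
        _, flags = ib.correlation_significance(study.cluster1_r_reduced(),
                                               n=25)
        r = study.cluster1_r_reduced().to_numpy()
        f = flags.to_numpy()
        iu = np.triu_indices(6, 1)
        sig_r = np.abs(r[iu])[f[iu]]
        nonsig_r = np.abs(r[iu])[~f[iu]]
        assert sig_r.min() > nonsig_r.max()


class TestCorrelationWithWithout:
    def test_identical_genes_fully_correlated(self, matrix_factory):
        base = np.arange(6.0)
        m = matrix_factory([base, base.copy(), -base])
        rep = ib.correlation_with_without(m, ["g0", "g1", "g2"],
                                          removed_samples=["s0"])
        assert rep.r_full.loc["g0", "g1"] == pytest.approx(1.0)
        assert rep.r_reduced.loc["g0", "g1"] == pytest.approx(1.0)
        assert rep.r_full.loc["g0", "g2"] == pytest.approx(-1.0)

    def test_empty_removal_reduces_to_full(self, planted_sim):
        _, matrix, _, truth = planted_sim
        genes = list(truth["probe_id"])[:5]
        rep = ib.correlation_with_without(matrix, genes, removed_samples=())
        pd.testing.assert_frame_equal(rep.r_full, rep.r_reduced)
        assert rep.mean_r_full == rep.mean_r_reduced
        assert rep.n_full == rep.n_reduced == 27

    def test_removing_outliers_lowers_planted_correlation(self, planted_sim):
        """Planted same-cell effects inflate pairwise r; removing the two
        affected sublines deflates it."""
        _, matrix, _, truth = planted_sim
        block_b = truth[truth["line"] == "b"]
        genes = list(block_b["probe_id"])
        removed = block_b["affected_samples"].iloc[0].split(";")
        rep = ib.correlation_with_without(matrix, genes,
                                          removed_samples=removed)
        assert rep.mean_r_full > rep.mean_r_reduced
        assert rep.n_reduced == 25

    def test_zero_variance_gene_rejected(self, matrix_factory):
        m = matrix_factory([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            ib.correlation_with_without(m, ["g0", "g1"])

    def test_too_few_retained_samples(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(0).normal(size=(2, 4)))
        with pytest.raises(ValueError, match=">= 3"):
            ib.correlation_with_without(m, ["g0", "g1"],
                                        removed_samples=["s0", "s1"])


class TestHierarchicalCluster:
    def test_two_genes_merge_at_one_minus_abs_r(self, matrix_factory):
        # exact r = 0.5 via orthogonal design vectors
        z1 = np.array([1.0, -1.0, 1.0, -1.0])
        z2 = np.array([1.0, 1.0, -1.0, -1.0])
        m = matrix_factory([z1, 0.5 * z1 + np.sqrt(0.75) * z2])
        res = ib.hierarchical_cluster(m, ["g0", "g1"])
        assert res.heights[0] == pytest.approx(0.5, abs=1e-12)

    def test_anticorrelated_genes_merge_at_zero(self, matrix_factory):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = matrix_factory([x, -x])
        res = ib.hierarchical_cluster(m, ["g0", "g1"])
        assert res.heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_four_blocks_recovered_at_cut(self):
        m, labels = _factor_block_matrix([6, 3, 2, 3], seed=4)
        res = ib.hierarchical_cluster(m, list(labels.index), n_clusters=4)
        got = res.labels
        # same partition: every true block maps to exactly one found cluster
        mapping = {}
        for gene, blk in labels.items():
            mapping.setdefault(blk, set()).add(got[gene])
        assert all(len(v) == 1 for v in mapping.values())
        assert len({next(iter(v)) for v in mapping.values()}) == 4

    def test_heights_non_decreasing(self, planted_sim):
        _, matrix, _, truth = planted_sim
        res = ib.hierarchical_cluster(matrix, list(truth["probe_id"]))
        assert np.all(np.diff(res.heights) >= -1e-12)
        assert res.newick.endswith(";")
        assert res.newick.count("(") == len(res.genes) - 1

    def test_single_gene_rejected(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(0).normal(size=(2, 5)))
        with pytest.raises(ValueError, match=">= 2 genes"):
            ib.hierarchical_cluster(m, ["g0"])


class TestBootstrapSupport:
    def test_separated_blocks_have_full_support(self):
        m, labels = _factor_block_matrix([4, 4], within=0.97, seed=6)
        res = ib.bootstrap_support(m, list(labels.index), n_boot=300, seed=1)
        sets = res.node_gene_sets()
        for blk in (0, 1):
            members = frozenset(labels.index[labels == blk])
            i = sets.index(members)
            assert res.bp[i] >= 0.95

    def test_seed_determinism(self):
        m, labels = _factor_block_matrix([3, 3], seed=7)
        a = ib.bootstrap_support(m, list(labels.index), n_boot=100, seed=5)
        b = ib.bootstrap_support(m, list(labels.index), n_boot=100, seed=5)
        assert np.array_equal(a.bp, b.bp)

    def test_merge_table_shape(self):
        m, labels = _factor_block_matrix([3, 2], seed=8)
        res = ib.bootstrap_support(m, list(labels.index), n_boot=50, seed=0)
        tab = res.merge_table()
        assert len(tab) == len(labels) - 1
        assert tab["bp"].between(0, 1).all()
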