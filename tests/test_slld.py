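"""SL-LD classification and the code-relabeling randomization test."""

import numpy as np
import pandas as pd
import pytest

import inbredscan as ib


def _calls(rows, alpha=0.05, direction="down"):
    """Hand-built outlier-call table: rows of (probe, sample, order)."""
    return pd.DataFrame([{
        "probe_id": p, "sample_id": s, "direction": direction, "order": o,
        "G": 5.0, "G_crit": 3.0, "alpha": alpha, "n_at_test": 24 - o + 1,
    } for p, s, o in rows])


class TestClassify:
    def test_pair_in_one_cell_is_slld(self, canonical_sheet):
        calls = _calls([("p1", "b_most_1", 1), ("p1", "b_most_2", 2)])
        out = ib.classify_slld(calls, canonical_sheet, n_outliers=2)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["line"], row["level"]) == ("b", "most_depressed")
        assert row["n_outliers"] == 2
        assert row["outlier_samples"] == "b_most_1;b_most_2"

    @pytest.mark.parametrize("samples", [
        ("a_most_1", "b_most_1"),      # different lines
        ("a_most_1", "a_least_1"),     # same line, different levels
    ])
    def test_split_pairs_are_not_slld(self, canonical_sheet, samples):
        calls = _calls([("p1", samples[0], 1), ("p1", samples[1], 2)])
        assert ib.classify_slld(calls, canonical_sheet).empty

    def test_at_least_vs_exact_mode(self, canonical_sheet):
        calls = _calls([("p1", "b_most_1", 1), ("p1", "b_most_2", 2),
                        ("p1", "b_most_3", 3)])
        assert len(ib.classify_slld(calls, canonical_sheet, n_outliers=2,
                                    mode="at_least")) == 1
        assert ib.classify_slld(calls, canonical_sheet, n_outliers=2,
                                mode="exact").empty
        assert len(ib.classify_slld(calls, canonical_sheet, n_outliers=3,
                                    mode="exact")) == 1

    def test_mixed_alpha_families_rejected(self, canonical_sheet):
        calls = pd.concat([_calls([("p1", "b_most_1", 1)], alpha=0.05),
                           _calls([("p2", "b_most_1", 1)], alpha=0.1)])
        with pytest.raises(ValueError, match="single scan"):
            ib.classify_slld(calls, canonical_sheet)

    def test_unknown_sample_rejected(self, canonical_sheet):
        calls = _calls([("p1", "nope", 1), ("p1", "b_most_2", 2)])
        with pytest.raises(KeyError, match="nope"):
            ib.classify_slld(calls, canonical_sheet)


class TestRandomization:
    def test_no_candidates_gives_p_one(self, canonical_sheet):
        calls = _calls([("p1", "b_most_1", 1)])  # only one call: no pair
        res = ib.randomization_test(calls, canonical_sheet, n_outliers=2,
                                    n_replicates=100, seed=0)
        assert res.observed_total == 0
        assert res.p_total == 1.0
        assert res.expected_mean == 0.0

    def test_observed_count_matches_classification(self, planted_sim,
                                                   planted_down_calls):
        _, _, sheet, _ = planted_sim
        slld = ib.classify_slld(planted_down_calls, sheet, n_outliers=2)
        res = ib.randomization_test(planted_down_calls, sheet, n_outliers=2,
                                    n_replicates=50, seed=0)
        assert res.observed_total == len(slld)
        assert res.observed_most == (slld["level"] == "most_depressed").sum()

    def test_seeded_reproducibility(self, planted_sim, planted_down_calls):
        _, _, sheet, _ = planted_sim
        a = ib.randomization_test(planted_down_calls, sheet,
                                  n_replicates=500, seed=42)
        b = ib.randomization_test(planted_down_calls, sheet,
                                  n_replicates=500, seed=42)
        c = ib.randomization_test(planted_down_calls, sheet,
                                  n_replicates=500, seed=43)
        assert a == b
        assert (a.p_total, a.expected_mean) != (c.p_total, c.expected_mean)

    def test_level_symmetry_of_expected_counts(self, planted_sim,
                                               planted_down_calls):
        """Randomized codes are level-blind: expected most == least counts,
        with the gap shrinking as replicates grow."""
        _, _, sheet, _ = planted_sim
        small = ib.randomization_test(planted_down_calls, sheet,
                                      n_replicates=200, seed=8)
        big = ib.randomization_test(planted_down_calls, sheet,
                                    n_replicates=50_000, seed=8)
        gap_small = abs(small.expected_most_mean - small.expected_least_mean)
        gap_big = abs(big.expected_most_mean - big.expected_least_mean)
        assert gap_big < 0.05 * big.expected_mean
        assert gap_big <= gap_small

    def test_null_observed_matches_expectation(self):
        """Exchangeable-null data: observed SL-LD count sits within 3
        replicate SDs of the randomization expectation."""
        cfg = ib.null_calibration_config(seed=17, n_probes=6000)
        m, sheet, _ = ib.simulate_expression(cfg)
        calls = ib.sequential_outlier_scan(m, sheet=sheet, alpha=0.05,
                                           direction="down")
        res = ib.randomization_test(calls, sheet, n_replicates=4000, seed=17)
        assert abs(res.observed_total - res.expected_mean) <= (
            3 * res.replicate_sd + 1e-9)

    def test_small_cells_rejected(self):
        rows = [(f"l{i}_m", "inbred", f"l{i}", "most_depressed", 1)
                for i in range(3)]
        rows += [(f"l{i}_l", "inbred", f"l{i}", "least_depressed", 1)
                 for i in range(3)]
        sheet = ib.SampleSheet(pd.DataFrame(
            rows, columns=["sample_id", "role", "line", "level",
                           "subline_index"]))
        calls = _calls([("p1", "l0_m", 1), ("p1", "l1_m", 2)])
        with pytest.raises(ValueError, match=">= 2 sublines"):
            ib.randomization_test(calls, sheet, n_replicates=10, seed=0)


@pytest.fixture(scope="module")
def ladder(planted_sim):
    _, matrix, sheet, _ = planted_sim
    return ib.alpha_ladder(matrix, sheet, alphas=(0.1, 0.05, 0.01),
                           n_replicates=500, seed=4)


class TestAlphaLadder:
    def test_counts_weakly_decrease_with_alpha(self, ladder):
        for _, grp in ladder.groupby("direction"):
            grp = grp.sort_values("alpha", ascending=False)
            assert grp["n_candidate_probes"].is_monotonic_decreasing
            assert grp["observed_total"].is_monotonic_decreasing

    def test_observed_bounded_by_candidates(self, ladder):
        assert (ladder["observed_total"]
                <= ladder["n_candidate_probes"]).all()
        assert (ladder["observed_most"] + ladder["observed_least"]
                == ladder["observed_total"]).all()

    def test_planted_signal_in_down_most_cell(self, ladder):
        row = ladder[(ladder["direction"] == "down")
                     & (ladder["alpha"] == 0.05)].iloc[0]
        assert row["observed_most"] >= 14 * 0.8
        assert row["p_total"] < 0.05
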