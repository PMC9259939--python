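"""Statistical layer: histograms, rank-sum test, percent positive, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import ishquant as iq
from ishquant.config import CountModel, PositivityOptions, SimConfig
from ishquant.errors import ConfigError, EmptyPopulationError

from oracles import rank_sum_p_bruteforce


class TestFrequencyDistribution:
    def test_worked_example(self):
        h = iq.frequency_distribution([0, 1, 1, 2], bin_width=1.0)
        np.testing.assert_allclose(h.relative_frequency, [0.25, 0.5, 0.25])
        np.testing.assert_allclose(h.bin_edges, [0, 1, 2, 3])

    def test_single_value_occupies_one_bin(self):
        h = iq.frequency_distribution([5.0] * 7, bin_width=1.0)
        assert h.relative_frequency[-1] == 1.0
        assert h.bin_edges[-2] == 5.0  # value sits in [5, 6)

    def test_errors(self):
        with pytest.raises(EmptyPopulationError):
            iq.frequency_distribution([])
        with pytest.raises(ConfigError):
            iq.frequency_distribution([1.0], bin_width=0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=50, allow_nan=False),
                    min_size=1, max_size=60),
           st.sampled_from([0.5, 1.0, 2.0]))
    def test_normalised_and_order_invariant(self, scores, width):
        h1 = iq.frequency_distribution(scores, width)
        h2 = iq.frequency_distribution(list(reversed(scores)), width)
        assert h1.relative_frequency.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_array_equal(h1.counts, h2.counts)


class TestRankSum:
    def test_separated_samples_exact_p(self):
        r = iq.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(0.10, abs=1e-12)

    def test_identical_samples_p_one(self):
        r = iq.rank_sum_test([1, 2], [1, 2])
        assert r.p_two_sided == 1.0

    def test_interleaved_example(self):
        r = iq.rank_sum_test([1, 3, 5, 7], [2, 4, 6, 8])
        assert r.statistic_U == 6.0
        assert r.p_two_sided == pytest.approx(48 / 70, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptyPopulationError):
            iq.rank_sum_test([], [1.0])

    def test_exact_matches_bruteforce_all_small_sizes(self):
        """Every tie-free (n1, n2) with n1+n2 <= 10 agrees with enumeration
        and with scipy's exact Mann-Whitney."""
        rng = np.random.default_rng(12)
        for n1 in range(1, 9):
            for n2 in range(1, 11 - n1):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                mine = iq.rank_sum_test(x, y)
                assert mine.method == "exact"
                assert mine.p_two_sided == pytest.approx(
                    rank_sum_p_bruteforce(x, y), abs=1e-12)
                ref = sps.mannwhitneyu(x, y, method="exact",
                                       alternative="two-sided").pvalue
                assert mine.p_two_sided == pytest.approx(ref, abs=1e-9)

    def test_exact_with_ties_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(0, 4, size=4).astype(float)
            y = rng.integers(0, 4, size=5).astype(float)
            mine = iq.rank_sum_test(x, y)
            assert mine.p_two_sided == pytest.approx(
                rank_sum_p_bruteforce(x, y), abs=1e-12)

    def test_normal_approx_tracks_exact_montecarlo(self):
        """n1=n2=50 tie-free: normal approximation within 0.01 of scipy's
        exact distribution p-value across random datasets."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            x = rng.normal(size=50)
            y = rng.normal(0.2, 1.0, size=50)
            mine = iq.rank_sum_test(x, y)
            assert mine.method == "normal_approx"
            ref = sps.mannwhitneyu(x, y, method="exact",
                                   alternative="two-sided").pvalue
            assert abs(mine.p_two_sided - ref) <= 0.01

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False),
                    min_size=1, max_size=6),
           st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False),
                    min_size=1, max_size=6))
    def test_symmetry_and_range(self, x, y):
        a = iq.rank_sum_test(x, y)
        b = iq.rank_sum_test(y, x)
        assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)
        assert 0.0 <= a.p_two_sided <= 1.0
        assert 0 <= a.statistic_U <= a.n1 * a.n2


def typed_table(rows):
    return pd.DataFrame(rows)


class TestPercentPositive:
    def test_single_section(self):
        df = typed_table([
            {"type_label": "g", "positive": i < 7, "section_id": "S1"} for i in range(10)
        ])
        pp = iq.percent_positive(df, "g", "positive")
        assert pp.mean == pytest.approx(70.0)
        assert pp.sem == 0.0
        assert pp.pooled == pytest.approx(70.0)

    def test_two_sections_mean_and_sem(self):
        rows = [{"type_label": "g", "positive": i < 6, "section_id": "S1"} for i in range(10)]
        rows += [{"type_label": "g", "positive": i < 8, "section_id": "S2"} for i in range(10)]
        pp = iq.percent_positive(typed_table(rows), "g", "positive")
        assert pp.mean == pytest.approx(70.0)
        assert pp.sem == pytest.approx(10.0)  # two-point SEM = half range

    def test_all_negative_is_zero(self):
        df = typed_table([{"type_label": "g", "positive": False, "section_id": "S1"}] * 5)
        assert iq.percent_positive(df, "g", "positive").mean == 0.0

    def test_empty_population_rejected(self):
        df = typed_table([{"type_label": "g", "positive": True, "section_id": "S1"}])
        with pytest.raises(EmptyPopulationError):
            iq.percent_positive(df, "other", "positive")


def scored_table(scores_a, scores_b, area_um2=50.0):
    rows = []
    for i, s in enumerate(scores_a):
        rows.append({"type_label": "A", "section_id": f"S{i % 2}",
                     "Gprc5b_dot_count": int(s), "Gprc5b_dot_density": s,
                     "mask_area_um2": area_um2})
    for i, s in enumerate(scores_b):
        rows.append({"type_label": "B", "section_id": f"S{i % 2}",
                     "Gprc5b_dot_count": int(s), "Gprc5b_dot_density": s,
                     "mask_area_um2": area_um2})
    return pd.DataFrame(rows)


class TestComparePopulations:
    def test_identical_populations_p_one(self):
        scores = [1.0, 2.0, 3.0, 4.0] * 4
        df = scored_table(scores, scores)
        s = iq.compare_populations(df, "region", "A", "B")
        assert s.rank_sum.p_two_sided == 1.0
        np.testing.assert_array_equal(
            s.populations["A"].histogram.counts, s.populations["B"].histogram.counts)

    def test_shifted_populations_detected(self):
        """NB-mean-8 vs NB-mean-3 scores at n=300: correct direction, p < 1e-4."""
        rng = np.random.default_rng(5)
        a = rng.negative_binomial(2, 2 / 10, size=300).astype(float)
        b = rng.negative_binomial(2, 2 / 5, size=300).astype(float)
        s = iq.compare_populations(scored_table(a, b), "region", "A", "B")
        assert s.populations["A"].median_score > s.populations["B"].median_score
        assert s.rank_sum.p_two_sided < 1e-4

    def test_empty_population_named_in_error(self):
        df = scored_table([1.0], [2.0])
        with pytest.raises(EmptyPopulationError, match="C"):
            iq.compare_populations(df, "region", "A", "C")

    def test_type_i_error_calibrated(self):
        """Null rejection rate at alpha=0.05 within [0.035, 0.065] (400 sims)."""
        rng = np.random.default_rng(11)
        rej = sum(
            iq.rank_sum_test(rng.normal(size=50), rng.normal(size=50)).p_two_sided < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08  # wide gate at 400; full gate in acceptance


class TestEvaluateRecovery:
    def test_poisson_closed_form(self):
        cm = {"A": {"Gprc5b": CountModel(distribution="poisson", mean=3.0)},
              "B": {"Gprc5b": CountModel(distribution="poisson", mean=0.0)}}
        cfg = SimConfig(type_proportions={"A": 0.5, "B": 0.5}, count_model=cm)
        assert iq.true_percent_positive(cfg, "A", "Gprc5b", 1) == pytest.approx(
            100 * (1 - np.exp(-3)), abs=1e-9)
        assert iq.true_percent_positive(cfg, "B", "Gprc5b", 1) == 0.0

    def test_nb_zero_probability_vs_montecarlo(self):
        cm = CountModel(distribution="negative_binomial", mean=8.0, dispersion=2.0)
        closed = cm.prob_at_least(1)
        draws = sps.nbinom(2.0, 2 / 10).rvs(size=10 ** 6,
                                            random_state=np.random.RandomState(4))
        assert closed == pytest.approx((draws >= 1).mean(), abs=2e-3)
        assert closed == pytest.approx(1 - (2 / 10) ** 2, abs=1e-12)

    def test_recovery_report_direction(self):
        rng = np.random.default_rng(9)
        a = rng.negative_binomial(2, 2 / 10, size=200).astype(float)
        b = rng.negative_binomial(2, 2 / 5, size=200).astype(float)
        df = scored_table(a, b).replace({"type_label": {"A": "GABAergic",
                                                        "B": "glutamatergic"}})
        s = iq.compare_populations(df, "region", "GABAergic", "glutamatergic")
        rep = iq.evaluate_recovery(s, SimConfig(), PositivityOptions())
        assert rep.direction_correct
        assert rep.p_two_sided < 1e-4
        est = rep.per_population["GABAergic"].estimated_percent_positive
        true = rep.per_population["GABAergic"].true_percent_positive
        assert true == pytest.approx(96.0, abs=1e-9)
        assert abs(est - true) < 5.0


class TestAdjustPvalues:
    def test_bonferroni_and_bh_small_example(self):
        p = [0.01, 0.04, 0.03, 0.005]
        bonf = iq.adjust_pvalues(p, "bonferroni")
        np.testing.assert_allclose(bonf, [0.04, 0.16, 0.12, 0.02])
        bh = iq.adjust_pvalues(p, "bh")
        # BH: sorted p (0.005,0.01,0.03,0.04) -> q = p*m/rank, monotonised
        np.testing.assert_allclose(sorted(bh), [0.02, 0.02, 0.04, 0.04])

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            iq.adjust_pvalues([0.1], "holmes")
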