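import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from conftest import brute_force_pairs, random_table
from doorstat import (
    DoorTable,
    PairCounts,
    component_door,
    convert_metrics,
    count_pairs,
    cumulative_door,
    door_probability,
    forest_table,
    halperin_ci,
    variance_u,
    wmw_test,
)
from doorstat.rank import EstimationError, tie_corrected_null_variance


class TestCountPairs:
    def test_dori05_tallies(self, dori05):
        pc = count_pairs(dori05)
        assert (pc.wins, pc.ties, pc.losses) == (32769, 77007, 30100)
        assert pc.total == 374 * 374

    def test_all_tied(self):
        pc = count_pairs(DoorTable(np.array([[5, 0], [7, 0]])))
        assert (pc.wins, pc.ties, pc.losses) == (0, 35, 0)

    def test_complete_separation(self):
        pc = count_pairs(DoorTable(np.array([[4, 0, 0], [0, 0, 6]])))
        assert (pc.wins, pc.ties, pc.losses) == (24, 0, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        table = random_table(np.random.default_rng(seed))
        pc = count_pairs(table)
        assert (pc.wins, pc.ties, pc.losses) == brute_force_pairs(table)


class TestDoorProbability:
    def test_dori05(self, dori05):
        assert door_probability(dori05) == pytest.approx(0.50954, abs=5e-6)

    def test_identical_arms_half(self):
        assert door_probability(DoorTable(np.array([[3, 2, 1], [3, 2, 1]]))) == 0.5

    def test_direct_arithmetic(self):
        assert door_probability(PairCounts(3, 2, 5)) == pytest.approx(0.4)

    def test_zero_pairs_error(self):
        with pytest.raises(EstimationError):
            door_probability(PairCounts(0, 0, 0))


class TestComponentCumulative:
    def test_clinical_response_component(self, dori05_components):
        est = component_door(dori05_components["Absence of clinical success"])
        assert est.estimate == pytest.approx(0.5428, abs=5e-5)

    def test_infectious_complications_component(self, dori05_components):
        est = component_door(dori05_components["Infectious complications"])
        assert est.estimate == pytest.approx((1755 + 129634 / 2) / 139876)
        assert est.estimate == pytest.approx(0.4760, abs=5e-4)

    def test_death_component(self, dori05_components):
        est = component_door(dori05_components["Death"])
        assert est.estimate == pytest.approx((0 + 139502 / 2) / 139876)

    def test_cumulative_cut1(self, dori05):
        est = cumulative_door(dori05, 1)
        assert est.estimate == pytest.approx((31823 + 79970 / 2) / 139876)
        assert est.estimate == pytest.approx(0.51337, abs=5e-6)

    def test_last_cut_equals_death_component(self):
        # a table whose only between-arm difference is deaths
        table = DoorTable(np.array([[300, 73, 1], [300, 74, 0]]))
        est_cut = cumulative_door(table, 2)
        est_comp = component_door(table.dichotomized(2))
        assert est_cut.estimate == est_comp.estimate
        assert (est_cut.ci_low, est_cut.ci_high) == (est_comp.ci_low, est_comp.ci_high)

    def test_identical_distributions_any_cut(self):
        table = DoorTable(np.array([[10, 20, 5], [10, 20, 5]]))
        for cut in (1, 2):
            assert cumulative_door(table, cut).estimate == 0.5

    def test_cut_out_of_range(self, dori05):
        with pytest.raises(ValueError):
            cumulative_door(dori05, 0)
        with pytest.raises(ValueError):
            cumulative_door(dori05, 5)


class TestVariance:
    def test_all_tied_zero(self):
        assert variance_u(DoorTable(np.array([[9, 0], [11, 0]]))) == 0.0

    def test_bootstrap_agreement(self, dori05):
        # within-arm multinomial bootstrap of the estimator, 10,000 replicates
        rng = np.random.default_rng(42)
        B = 10_000
        a = dori05.counts[0]
        b = dori05.counts[1]
        A = rng.multinomial(a.sum(), a / a.sum(), size=B).astype(float)
        Bc = rng.multinomial(b.sum(), b / b.sum(), size=B).astype(float)
        tail = np.concatenate(
            [np.cumsum(Bc[:, ::-1], axis=1)[:, ::-1][:, 1:], np.zeros((B, 1))], axis=1
        )
        p = ((A * tail).sum(1) + (A * Bc).sum(1) / 2) / (a.sum() * b.sum())
        assert variance_u(dori05) == pytest.approx(p.var(), rel=0.10)

    def test_inverse_n_scaling(self, dori05):
        doubled = DoorTable(dori05.counts * 2)
        assert variance_u(doubled) == pytest.approx(variance_u(dori05) / 2, rel=0.05)


class TestHalperinCI:
    def test_dori05_bounds_to_one_decimal(self, dori05):
        est = halperin_ci(dori05)
        assert round(100 * est.ci_low, 1) == 47.6
        assert round(100 * est.ci_high, 1) == 54.3

    def test_component_bounds(self, dori05_components):
        est = component_door(dori05_components["Infectious complications"])
        assert abs(100 * est.ci_low - 46.2) <= 0.05
        assert abs(100 * est.ci_high - 49.0) <= 0.05

    def test_null_coverage(self):
        # identical multinomial arms, n=100/arm: 95% CI covers 0.5 at ~95%
        rng = np.random.default_rng(2024)
        probs = (0.6, 0.25, 0.1, 0.05)
        covered = 0
        n_rep = 2000
        for _ in range(n_rep):
            counts = rng.multinomial(100, probs, size=2)
            est = halperin_ci(DoorTable(counts))
            covered += est.ci_low <= 0.5 <= est.ci_high
        assert 0.93 <= covered / n_rep <= 0.97

    def test_degenerate_collapses_with_warning(self):
        with pytest.warns(UserWarning):
            est = halperin_ci(DoorTable(np.array([[5, 0], [6, 0]])))
        assert est.ci_low == est.estimate == est.ci_high == 0.5

    def test_fallback_method_is_labeled(self, dori05):
        est = halperin_ci(dori05, method="logit-wald")
        assert est.method == "logit-wald"
        assert est.ci_low < door_probability(dori05) < est.ci_high

    def test_bad_level(self, dori05):
        with pytest.raises(ValueError):
            halperin_ci(dori05, level=1.2)


class TestWMWTest:
    def test_dori05_p_value(self, dori05):
        assert wmw_test(dori05) == pytest.approx(0.58, abs=0.005)

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            table = random_table(rng)
            x = np.repeat(np.arange(1, table.K + 1), table.counts[0])
            y = np.repeat(np.arange(1, table.K + 1), table.counts[1])
            if len(np.unique(np.concatenate([x, y]))) == 1:
                continue
            expected = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
            assert wmw_test(table) == pytest.approx(expected, rel=1e-10)

    def test_identical_large_arms_p_near_one(self):
        table = DoorTable(np.array([[400, 300, 200], [400, 300, 200]]))
        assert wmw_test(table) > 0.99

    def test_complete_separation_tiny_p(self):
        table = DoorTable(np.array([[50, 0], [0, 50]]))
        assert wmw_test(table) < 1e-10

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert wmw_test(DoorTable(np.array([[5, 0], [5, 0]]))) == 1.0

    def test_one_sided_direction(self, dori05):
        greater = wmw_test(dori05, alternative="greater")
        less = wmw_test(dori05, alternative="less")
        assert greater < less  # experimental arm slightly favored
        assert greater + less == pytest.approx(1.0)


class TestConvertMetrics:
    def test_dori05_conversions(self, dori05):
        m = convert_metrics(count_pairs(dori05))
        assert m["win_ratio"] == pytest.approx(1.0887, abs=5e-5)
        assert m["win_odds"] == pytest.approx(1.0389, abs=5e-5)
        assert m["ntb"] == pytest.approx(0.01908, abs=5e-6)

    def test_null_values(self):
        m = convert_metrics(PairCounts(10, 5, 10))
        assert m["ntb"] == 0 and m["win_odds"] == 1

    def test_no_ties_ratio_equals_odds(self):
        m = convert_metrics(PairCounts(12, 0, 6))
        assert m["win_ratio"] == m["win_odds"] == 2.0

    def test_zero_losses_infinite_ratio(self):
        m = convert_metrics(PairCounts(12, 3, 0))
        assert np.isinf(m["win_ratio"]) and np.isfinite(m["win_odds"])


class TestForestTable:
    def test_rows_and_overall(self, dori05, dori05_components):
        frame = forest_table(dori05, dori05_components)
        # overall + K-1 cumulative cuts + 4 components
        assert len(frame) == 1 + 4 + 4
        assert frame.iloc[0]["estimate"] == pytest.approx(0.50954, abs=5e-6)
        assert set(frame.columns) >= {"label", "estimate", "ci_low", "ci_high", "n1", "n2"}
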