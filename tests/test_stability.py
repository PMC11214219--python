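import numpy as np
import pytest

from symptomnet.simulate import make_truth_network, simulate_scores
from symptomnet.stability import (
    CaseDropCurve,
    bootstrap_edges,
    case_drop_bootstrap,
    cs_coefficient,
)


def crafted_curve(pass_up_to, grid=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7), B=200):
    """Correlations equal 1.0 up to (and including) `pass_up_to`, 0.0 after."""
    props = np.array(grid)
    corr = {}
    for idx in ("strength", "closeness", "betweenness", "expected_influence"):
        c = np.where(props[:, None] <= pass_up_to + 1e-12, 1.0, 0.0)
        corr[idx] = np.broadcast_to(c, (props.size, B)).copy()
    return CaseDropCurve(props, corr, B, n=200, seed=0)


class TestCsCoefficient:
    def test_pass_up_to_half_gives_cs_half(self):
        # exactly 96% of correlations >= 0.7 through drop 0.5, all fail at 0.6
        curve = crafted_curve(0.5, B=200)
        row = np.array([1.0] * 192 + [0.0] * 8)
        curve.correlations["strength"][:5] = row
        cs = cs_coefficient(curve, 0.7, 0.95)
        assert cs["strength"] == pytest.approx(0.5)

    def test_all_pass_gives_grid_maximum(self):
        cs = cs_coefficient(crafted_curve(0.7))
        assert cs["strength"] == pytest.approx(0.7)

    def test_all_fail_gives_zero(self):
        cs = cs_coefficient(crafted_curve(0.0))
        assert cs["strength"] == 0.0

    def test_cumulative_rule_blocks_non_monotone_inflation(self):
        curve = crafted_curve(0.7)
        curve.correlations["strength"][2, :] = 0.0  # dip at 0.3
        cs = cs_coefficient(curve)
        assert cs["strength"] == pytest.approx(0.2)

    def test_nonincreasing_in_threshold_and_confidence(self):
        rng = np.random.default_rng(8)
        props = np.array([0.1, 0.3, 0.5, 0.7])
        corr = {
            idx: np.clip(0.95 - props[:, None] + rng.normal(0, 0.15, (4, 300)), -1, 1)
            for idx in ("strength", "closeness", "betweenness", "expected_influence")
        }
        curve = CaseDropCurve(props, corr, 300, n=200, seed=0)
        for idx in curve.indices:
            cs_lo = cs_coefficient(curve, 0.5, 0.8)[idx]
            cs_mid = cs_coefficient(curve, 0.7, 0.8)[idx]
            cs_hi = cs_coefficient(curve, 0.9, 0.8)[idx]
            assert cs_lo >= cs_mid >= cs_hi
            assert cs_coefficient(curve, 0.7, 0.6)[idx] >= cs_coefficient(curve, 0.7, 0.95)[idx]

    def test_nan_correlations_count_as_failures(self):
        curve = crafted_curve(0.7)
        curve.correlations["betweenness"][:] = np.nan
        assert cs_coefficient(curve)["betweenness"] == 0.0

    def test_empty_curve_rejected(self):
        empty = CaseDropCurve(np.array([]), {i: np.empty((0, 0)) for i in crafted_curve(0.1).indices}, 100, 0, None)
        with pytest.raises(ValueError):
            cs_coefficient(empty)


@pytest.fixture(scope="module")
def scores():
    truth = make_truth_network(5, "chain", 0.3)
    return simulate_scores(truth, n=400, seed=33)


class TestBootstrapEdges:
    def test_bookkeeping_counts_resamples(self, scores):
        res = bootstrap_edges(scores, B=100, seed=1)
        assert res.boot_weights.shape[0] + res.n_failures == 100
        assert res.B == 100

    def test_fixed_seed_is_bit_reproducible(self, scores):
        a = bootstrap_edges(scores, B=100, seed=7)
        b = bootstrap_edges(scores, B=100, seed=7)
        np.testing.assert_array_equal(a.boot_weights, b.boot_weights)

    def test_ci_bounds_are_ordered_and_level_recorded(self, scores):
        res = bootstrap_edges(scores, B=120, level=0.9, seed=2)
        assert np.all(res.ci_lower <= res.ci_upper)
        assert res.level == 0.9

    def test_ci_width_shrinks_with_sample_size(self):
        truth = make_truth_network(5, "chain", 0.3)
        widths = {}
        for n in (200, 2000):
            scores = simulate_scores(truth, n=n, seed=17)
            res = bootstrap_edges(scores, B=150, seed=3)
            widths[n] = np.median(res.ci_upper - res.ci_lower)
        assert widths[2000] < widths[200]

    def test_null_edges_cis_cover_zero(self):
        truth = make_truth_network(5, "chain", 0.0)
        scores = simulate_scores(truth, n=1000, seed=29)
        res = bootstrap_edges(scores, B=150, seed=4)
        covered = (res.ci_lower <= 0) & (0 <= res.ci_upper)
        assert covered.mean() >= 0.9

    def test_too_small_B_rejected(self, scores):
        with pytest.raises(ValueError):
            bootstrap_edges(scores, B=50)


class TestCaseDropBootstrap:
    def test_strong_signal_survives_halving(self):
        truth = make_truth_network(5, "chain", 0.4)
        scores = simulate_scores(truth, n=5000, seed=41)
        curve = case_drop_bootstrap(scores, drop_grid=(0.1, 0.5), B=100, seed=5)
        at_half = curve.correlations["strength"][1]
        assert np.nanmedian(at_half) > 0.9

    def test_weak_signal_degrades_monotonically_in_the_median(self):
        truth = make_truth_network(5, "chain", 0.3)
        scores = simulate_scores(truth, n=207, seed=43)
        curve = case_drop_bootstrap(scores, drop_grid=(0.1, 0.7), B=150, seed=6)
        s = curve.correlations["strength"]
        assert np.nanmedian(s[1]) < np.nanmedian(s[0])

    def test_fixed_seed_is_bit_reproducible(self):
        truth = make_truth_network(5, "chain", 0.3)
        scores = simulate_scores(truth, n=300, seed=47)
        a = case_drop_bootstrap(scores, drop_grid=(0.2, 0.4), B=100, seed=9)
        b = case_drop_bootstrap(scores, drop_grid=(0.2, 0.4), B=100, seed=9)
        for idx in a.indices:
            np.testing.assert_array_equal(a.correlations[idx], b.correlations[idx])

    def test_subsample_below_p_plus_one_warns_and_skips(self):
        truth = make_truth_network(5, "chain", 0.3)
        scores = simulate_scores(truth, n=12, seed=51)
        with pytest.warns(UserWarning, match="skipped"):
            curve = case_drop_bootstrap(scores, drop_grid=(0.1, 0.7), B=100, seed=10)
        assert np.isnan(curve.correlations["strength"][1]).all()

    def test_invalid_grid_rejected(self):
        truth = make_truth_network(5, "chain", 0.3)
        scores = simulate_scores(truth, n=300, seed=53)
        with pytest.raises(ValueError):
            case_drop_bootstrap(scores, drop_grid=(0.0, 0.5), B=100)
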