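import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri
from scipy.stats import multivariate_normal

from symptomnet.polychoric import (
    CorrelationMatrix,
    CorrelationPolicy,
    DegenerateVariableError,
    build_correlation_matrix,
    bvn_cdf,
    estimate_thresholds,
    polychoric_pair,
)

EQUIPROBABLE_5 = ndtri(np.arange(1, 5) / 5)


def discretize(z, cuts=EQUIPROBABLE_5):
    return np.digitize(z, cuts) + 1.0


class TestBvnCdf:
    @pytest.mark.parametrize("rho", [-0.9, -0.3, 0.0, 0.5, 0.95])
    def test_matches_scipy_bivariate_normal(self, rho, rng):
        pts = rng.normal(0, 1.5, size=(20, 2))
        mvn = multivariate_normal(cov=[[1, rho], [rho, 1]])
        expected = np.array([mvn.cdf(p) for p in pts])
        got = bvn_cdf(pts[:, 0], pts[:, 1], rho)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_infinite_bounds_reduce_to_margins(self):
        from scipy.special import ndtr

        assert bvn_cdf(np.inf, 0.7, 0.4) == pytest.approx(float(ndtr(0.7)))
        assert bvn_cdf(-np.inf, 0.7, 0.4) == 0.0
        assert bvn_cdf(np.inf, np.inf, 0.4) == 1.0


class TestThresholds:
    def test_balanced_binary_gives_zero(self):
        np.testing.assert_allclose(estimate_thresholds([1, 1, 2, 2]), [0.0], atol=1e-12)

    def test_three_categories_inverse_normal(self):
        # proportions (0.5, 0.3, 0.2) -> thresholds (0, Phi^-1(0.8))
        x = np.repeat([1, 2, 3], [50, 30, 20])
        np.testing.assert_allclose(
            estimate_thresholds(x), [0.0, 0.8416212335], atol=1e-8
        )

    def test_single_category_is_degenerate(self):
        with pytest.raises(DegenerateVariableError):
            estimate_thresholds(np.ones(30))

    def test_thresholds_strictly_increasing(self, rng):
        x = rng.integers(1, 6, size=500)
        tau = estimate_thresholds(x)
        assert np.all(np.diff(tau) > 0)


class TestPolychoricPair:
    def test_perfect_concordance(self, rng):
        x = rng.integers(1, 6, size=400).astype(float)
        assert polychoric_pair(x, x) > 0.99

    def test_independent_samples_near_zero(self, rng):
        x = rng.integers(1, 6, size=4000).astype(float)
        y = rng.integers(1, 6, size=4000).astype(float)
        assert abs(polychoric_pair(x, y)) < 0.1

    def test_recovers_latent_correlation(self):
        rng = np.random.default_rng(42)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 5000, method="cholesky")
        rho = polychoric_pair(discretize(z[:, 0]), discretize(z[:, 1]))
        assert rho == pytest.approx(0.5, abs=0.05)

    def test_symmetry(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], 800, method="cholesky")
        x, y = discretize(z[:, 0]), discretize(z[:, 1])
        assert polychoric_pair(x, y) == pytest.approx(polychoric_pair(y, x), abs=1e-6)

    def test_invariant_to_monotone_relabeling(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], 800, method="cholesky")
        x, y = discretize(z[:, 0]), discretize(z[:, 1])
        assert polychoric_pair(x - 1, 10 * y) == pytest.approx(
            polychoric_pair(x, y), abs=1e-6
        )

    def test_many_categories_approach_latent_pearson(self):
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 5000, method="cholesky")
        cuts10 = ndtri(np.arange(1, 10) / 10)
        rho = polychoric_pair(discretize(z[:, 0], cuts10), discretize(z[:, 1], cuts10))
        latent_r = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
        assert rho == pytest.approx(latent_r, abs=0.05)

    def test_matches_tetrachoric_grid_scan_on_2x2(self):
        from _oracles import tetrachoric_grid_scan

        table = np.array([[55, 20], [15, 60]])
        x = np.repeat([1, 1, 2, 2], table.ravel())
        y = np.repeat([1, 2, 1, 2], table.ravel())
        assert polychoric_pair(x, y) == pytest.approx(
            tetrachoric_grid_scan(table), abs=1e-3
        )


class TestCorrelationMatrix:
    def test_independent_variables_near_identity(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.integers(1, 6, size=(2000, 5)).astype(float))
        cm = build_correlation_matrix(df)
        off = cm.values[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 0.08)
        assert np.allclose(np.diag(cm.values), 1.0)

    def test_method_policy_polychoric_vs_spearman(self, rng):
        df = pd.DataFrame(
            {
                "a": rng.integers(1, 5, 300).astype(float),
                "b": rng.integers(1, 5, 300).astype(float),
                "c": rng.integers(1, 60, 300).astype(float),  # many categories
            }
        )
        cm = build_correlation_matrix(df)
        assert cm.method_per_pair[("a", "b")] == "polychoric"
        assert cm.method_per_pair[("a", "c")] == "spearman"

    def test_continuous_variables_use_pearson(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=["x", "y", "z"])
        cm = build_correlation_matrix(df)
        assert set(cm.method_per_pair.values()) == {"pearson"}

    def test_n_not_exceeding_p_is_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 5)))
        with pytest.raises(ValueError, match="too few"):
            build_correlation_matrix(df)

    def test_indefinite_matrix_is_repaired_psd(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(bad)[0] < 0
        from statsmodels.stats.correlation_tools import corr_nearest

        repaired = np.asarray(corr_nearest(bad, threshold=1e-8))
        cm = CorrelationMatrix(
            (repaired + repaired.T) / 2, ["a", "b", "c"], psd_repaired=True
        )
        assert cm.min_eigenvalue() >= -1e-10

    def test_construction_rejects_asymmetry_and_bad_diagonal(self):
        with pytest.raises(ValueError):
            CorrelationMatrix(np.array([[1.0, 0.2], [0.3, 1.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            CorrelationMatrix(np.array([[0.9, 0.2], [0.2, 1.0]]), ["a", "b"])

    def test_decile_binning_enables_polychoric_throughout(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 800, method="cholesky")
        df = pd.DataFrame({"x": z[:, 0] * 10 + 50, "y": z[:, 1] * 8 + 40})
        cm = build_correlation_matrix(df, CorrelationPolicy(bin_deciles=True))
        assert set(cm.method_per_pair.values()) == {"polychoric"}
        assert cm.values[0, 1] == pytest.approx(0.5, abs=0.12)
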