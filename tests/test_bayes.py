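import numpy as np
import pytest

from envgp import SimConfig, ValidationError, simulate
from envgp.bayes import (
    FitResult,
    MCMCConfig,
    ModelSpec,
    fit,
    heritability,
    predict_missing,
    variance_report,
)
from envgp.kernels import (
    KernelMatrix,
    build_designs,
    env_kernel_noec,
    ge_kernel,
    genomic_relationship,
    genotype_kernel,
)


def random_kernel(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, n))
    return KernelMatrix(list(range(n)), A @ A.T / n, "Kg")


class TestFit:
    def test_fixed_variance_posterior_matches_ridge_solution(self):
        """With variances pinned, u-posterior mean equals the BLUP closed form."""
        rng = np.random.default_rng(21)
        n, s2u, s2e = 30, 1.0, 0.5
        K = random_kernel(n, 22)
        L = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))
        y = 1.5 + L @ rng.normal(size=n) + rng.normal(0, np.sqrt(s2e), n)
        fr = fit(
            ModelSpec("E+G", "NoEC", {"g": K}), y,
            MCMCConfig(n_iter=8000, burn_in=1000, thin=2, seed=5,
                       fixed_variances={"g": s2u, "resid": s2e}),
        )
        # closed form with the intercept profiled out by GLS (flat prior on mu)
        V = s2u * K.values + s2e * np.eye(n)
        Vi = np.linalg.inv(V)
        one = np.ones(n)
        mu_gls = (one @ Vi @ y) / (one @ Vi @ one)
        u_blup = s2u * K.values @ (Vi @ (y - mu_gls))
        assert np.max(np.abs(fr.effects["g"] - u_blup)) < 0.03 * np.std(y, ddof=1)

    def test_seed_determinism(self):
        K = random_kernel(15, 2)
        y = np.arange(15, dtype=float)
        cfg = MCMCConfig(n_iter=300, burn_in=50, thin=2, seed=9)
        fr1 = fit(ModelSpec("E+G", "NoEC", {"g": K}), y, cfg)
        fr2 = fit(ModelSpec("E+G", "NoEC", {"g": K}), y, cfg)
        np.testing.assert_array_equal(fr1.y_hat, fr2.y_hat)
        assert fr1.var_components == fr2.var_components

    def test_constant_response_degenerates_gracefully(self):
        K = random_kernel(12, 3)
        y = np.full(12, 4.2)
        fr = fit(ModelSpec("E+G", "NoEC", {"g": K}), y,
                 MCMCConfig(n_iter=600, burn_in=100, thin=2, seed=1))
        assert fr.mu_hat == pytest.approx(4.2, abs=0.05)
        np.testing.assert_allclose(fr.y_hat, 4.2, atol=0.1)

    def test_missing_rows_get_finite_predictions(self):
        K = random_kernel(20, 4)
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        y[[3, 7, 11]] = np.nan
        fr = fit(ModelSpec("E+G", "NoEC", {"g": K}), y,
                 MCMCConfig(n_iter=400, burn_in=100, thin=2, seed=2))
        assert fr.n_missing == 3
        assert np.isfinite(fr.y_hat).all()
        assert all(v > 0 for v in fr.var_components.values())

    def test_observation_exchangeability(self):
        """Permuting observations permutes posterior-mean predictions."""
        n = 25
        K = random_kernel(n, 6)
        rng = np.random.default_rng(8)
        y = np.linalg.cholesky(K.values + 0.5 * np.eye(n)) @ rng.normal(size=n)
        cfg = MCMCConfig(n_iter=6000, burn_in=1000, thin=2, seed=3)
        fr = fit(ModelSpec("E+G", "NoEC", {"g": K}), y, cfg)
        perm = np.random.default_rng(1).permutation(n)
        Kp = KernelMatrix([K.labels[i] for i in perm], K.values[np.ix_(perm, perm)], "Kg")
        frp = fit(ModelSpec("E+G", "NoEC", {"g": Kp}), y[perm], cfg)
        np.testing.assert_allclose(frp.y_hat, fr.y_hat[perm],
                                   atol=0.05 * np.std(y, ddof=1))

    def test_invalid_chain_settings_rejected(self):
        with pytest.raises(ValidationError):
            MCMCConfig(n_iter=100, burn_in=100)

    def test_ge_kernel_reduces_training_residuals_when_ge_present(self):
        """On data with real GE, the GE term absorbs signal: training RSS
        under E+G+GE is smaller than under E+G in most replicates."""
        wins = 0
        n_rep = 8
        for seed in range(n_rep):
            phen, markers, covs, _ = simulate(
                SimConfig(n_geno=30, n_env=4, n_markers=60, n_cov=3,
                          var_ge=1.5, seed=seed)
            )
            d = build_designs(phen, "Y", markers, covs)
            G = genomic_relationship(markers)
            kg = genotype_kernel(G, d)
            ke = env_kernel_noec(d)
            cfg = MCMCConfig(n_iter=500, burn_in=150, thin=2, seed=seed + 50)
            f1 = fit(ModelSpec("E+G", "NoEC", {"E": ke, "g": kg}), d.y, cfg)
            f2 = fit(ModelSpec("E+G+GE", "NoEC",
                               {"E": ke, "g": kg, "gE": ge_kernel(kg, ke)}), d.y, cfg)
            rss1 = np.sum((d.y - f1.y_hat) ** 2)
            rss2 = np.sum((d.y - f2.y_hat) ** 2)
            wins += rss2 < rss1
        assert wins >= 0.75 * n_rep


class TestPredictMissing:
    @pytest.fixture(scope="class")
    def fitted(self):
        K = random_kernel(10, 5)
        y = np.arange(10, dtype=float)
        y[[2, 5]] = np.nan
        return fit(ModelSpec("E+G", "NoEC", {"g": K}), y,
                   MCMCConfig(n_iter=300, burn_in=50, thin=2, seed=4))

    def test_missing_rows(self, fitted):
        out = predict_missing(fitted, [2, 5])
        assert out.shape == (2,) and np.isfinite(out).all()

    def test_training_row_returns_fitted_value(self, fitted):
        out = predict_missing(fitted, [0])
        assert out[0] == fitted.y_hat[0]

    def test_empty_and_unknown(self, fitted):
        assert predict_missing(fitted, []).shape == (0,)
        with pytest.raises(ValidationError, match="unknown"):
            predict_missing(fitted, [99])


class TestVarianceReport:
    def _fit_result(self, vc):
        return FitResult(
            mu_hat=5.0, var_components=vc, effects={}, y_hat=np.zeros(2),
            samples_kept=10, obs_keys=[0, 1], predictor="E+G+GE",
            strategy="NoEC", n_missing=0, y_obs_mean=5.0,
        )

    def test_noiseless_limit_heritability_one(self):
        assert heritability(1.0, 0.0, 0.0, 3.0) == pytest.approx(1.0)

    def test_formula_half(self):
        assert heritability(1.0, 1.0, 1.0, 2.0) == pytest.approx(0.5)

    def test_report_layout(self):
        fits = {"GY": self._fit_result({"E": 2.0, "g": 1.0, "gE": 1.0, "resid": 1.0})}
        tab = variance_report(fits, n_env_mean=2.0)
        assert list(tab["Component"]) == ["Env:Line", "Line", "Env", "Residual"]
        assert tab["Heritability"].iloc[0] == pytest.approx(0.5)
        assert tab["CV"].iloc[0] == pytest.approx(1.0 / 5.0)

    def test_requires_complete_ge_fit(self):
        fr = self._fit_result({"E": 1.0, "g": 1.0, "gE": 1.0, "resid": 1.0})
        fr.n_missing = 2
        with pytest.raises(ValidationError, match="complete data"):
            variance_report({"GY": fr}, 2.0)
        fr2 = self._fit_result({"E": 1.0, "g": 1.0, "resid": 1.0})
        fr2.predictor = "E+G"
        with pytest.raises(ValidationError, match="E\\+G\\+GE"):
            variance_report({"GY": fr2}, 2.0)
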