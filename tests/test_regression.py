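import numpy as np
import pandas as pd
import pytest
from scipy import stats

from predinf.regression import (
    CIRC_COEF_NAMES,
    RegressionFit,
    circular_log_posterior,
    fit_action_confidence,
    fit_circular_update_model,
    fit_confidence_model,
    group_level_test,
    zscore,
)

DEG = np.pi / 180.0


def _design(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "pe": rng.uniform(-90, 90, n),
            "cpp": rng.beta(1, 6, n),
            "ru": rng.beta(2, 5, n),
            "hit": rng.integers(0, 2, n).astype(float),
        }
    )


def _simulate_updates(d, beta, kappa, seed=0):
    rng = np.random.default_rng(seed)
    pe = d["pe"].to_numpy()
    X = np.column_stack(
        [
            pe,
            pe * (d["cpp"] - d["cpp"].mean()),
            pe * (d["ru"] - d["ru"].mean()),
            pe * (d["hit"] - d["hit"].mean()),
        ]
    )
    mu = X @ np.asarray(beta)
    noise = rng.vonmises(0.0, kappa, len(d)) / DEG  # radians -> degrees
    return mu + noise, X


class TestCircularObjective:
    def test_matches_brute_force_density_summation(self):
        """The analytic objective equals a direct scipy.stats.vonmises +
        Gaussian-prior evaluation at random parameter points."""
        d = _design(150, seed=3)
        y, X = _simulate_updates(d, [0.6, 0.3, 0.1, -0.2], kappa=8.0, seed=3)
        rng = np.random.default_rng(7)
        for _ in range(50):
            beta = rng.normal(0, 1, 4)
            kappa = rng.uniform(0.2, 50)
            ours = circular_log_posterior(beta, kappa, X, y, prior_width=5.0)
            mu = X @ beta
            brute = float(
                np.sum(stats.vonmises.logpdf(y * DEG, kappa, loc=mu * DEG))
                + np.sum(stats.norm.logpdf(beta, 0, 5.0))
            )
            assert ours == pytest.approx(brute, abs=1e-8)

    def test_prior_drops_when_width_is_none(self):
        d = _design(50, seed=1)
        y, X = _simulate_updates(d, [0.5, 0, 0, 0], kappa=10.0, seed=1)
        beta = np.array([0.4, 0.1, -0.1, 0.2])
        with_prior = circular_log_posterior(beta, 5.0, X, y, prior_width=5.0)
        without = circular_log_posterior(beta, 5.0, X, y, prior_width=None)
        assert without - with_prior == pytest.approx(
            -float(np.sum(stats.norm.logpdf(beta, 0, 5.0))), abs=1e-10
        )


class TestCircularFit:
    def test_parameter_recovery_pe_only(self):
        """beta_PE = 0.6 with high concentration is recovered within 0.05
        and the inactive interactions stay near zero."""
        d = _design(200, seed=11)
        y, _ = _simulate_updates(d, [0.6, 0.0, 0.0, 0.0], kappa=400.0, seed=11)
        d["update"] = y
        fit = fit_circular_update_model(d, seed=0)
        assert fit.converged
        assert fit.coefficients["PE"] == pytest.approx(0.6, abs=0.05)
        for name in ("PExCPP", "PExRU", "PExHit"):
            assert abs(fit.coefficients[name]) < 0.05

    def test_noiseless_data_dominates_prior(self):
        """With exact updates (kappa -> inf) the MAP sits at the generating
        coefficients; prior shrinkage vanishes."""
        d = _design(200, seed=5)
        beta = [0.7, 0.25, 0.15, -0.2]
        y, X = _simulate_updates(d, beta, kappa=60.0, seed=5)
        d["update"] = X @ np.asarray(beta)  # no noise at all
        fit = fit_circular_update_model(d, seed=1)
        for name, b in zip(CIRC_COEF_NAMES, beta):
            assert fit.coefficients[name] == pytest.approx(b, abs=1e-3)
        assert fit.kappa > 1e3

    def test_map_approaches_mle_for_wide_prior(self):
        d = _design(200, seed=9)
        y, _ = _simulate_updates(d, [0.55, 0.2, 0.0, -0.15], kappa=15.0, seed=9)
        d["update"] = y
        map_fit = fit_circular_update_model(d, prior_width=1e6, seed=2)
        mle_fit = fit_circular_update_model(d, prior_width=None, seed=2)
        for name in CIRC_COEF_NAMES:
            assert map_fit.coefficients[name] == pytest.approx(
                mle_fit.coefficients[name], abs=1e-4
            )

    def test_too_few_trials_rejected(self):
        d = _design(4, seed=0)
        d["update"] = 0.5 * d["pe"]
        with pytest.raises(ValueError, match="trials"):
            fit_circular_update_model(d)


class TestConfidenceModel:
    def _data(self, n=300, slope=-0.5, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        d = _design(n, seed=seed)
        abs_pe = np.abs(d["pe"])
        conf = np.empty(n)
        conf[0] = 0.0
        conf[1:] = slope * abs_pe.to_numpy()[:-1] + noise * rng.normal(0, 1, n - 1)
        d["abs_pe"] = abs_pe
        d["confidence"] = conf
        return d

    def test_slope_recovery_with_noise(self):
        d = self._data(n=2000, slope=-0.5, noise=1.0, seed=4)
        fit = fit_confidence_model(d, variant="pe_model")
        # z-scored scale: slope_z = slope * sd(|PE|) / sd(conf)
        sd_x = np.std(np.abs(d["pe"]))
        sd_y = np.std(d["confidence"][1:])
        expected = -0.5 * sd_x / sd_y
        assert fit.coefficients["|PE|"] == pytest.approx(expected, abs=0.07)

    def test_noiseless_generation_gives_unit_r2(self):
        d = self._data(n=300, slope=-0.5, noise=0.0, seed=8)
        fit = fit_confidence_model(d, variant="pe_model")
        assert fit.extra["r2"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["|PE|"] == pytest.approx(-1.0, abs=1e-8)

    def test_zero_variance_regressor_dropped(self):
        d = self._data(n=100, seed=2)
        d["hit"] = 1.0
        with pytest.warns(UserWarning, match="hit"):
            fit = fit_confidence_model(d, variant="pe_model")
        assert "Hit" not in fit.coefficients
        assert "hit" in fit.extra["dropped"]

    def test_combined_variant_reports_condition_number(self):
        d = self._data(n=200, seed=3)
        fit = fit_confidence_model(d, variant="combined")
        assert fit.extra["condition_number"] > 0
        assert set(fit.coefficients) == {"intercept", "|PE|", "CPP", "RU", "Hit"}

    @pytest.mark.parametrize(
        "variant,signs",
        [
            ("pe_model", {"|PE|": -1, "RU": -1, "Hit": +1}),
            ("cpp_model", {"CPP": -1, "RU": -1, "Hit": +1}),
            ("combined", {"CPP": -1, "Hit": +1}),
        ],
    )
    def test_cohort_sign_pattern(self, normative, variant, signs):
        """Simulated cohorts reproduce the canonical signs: the uncertainty
        regressors (|PE|, CPP, RU) predict confidence negatively, accuracy
        (Hit) positively. |PE| and CPP are tested in their separate models
        because their collinearity makes shared coefficients unstable."""
        fits = []
        for _, g in normative[normative["session"] == 1].groupby("participant_id"):
            fits.append(fit_confidence_model(g, variant=variant))
        for name, sign in signs.items():
            res = group_level_test(fits, name)
            assert np.sign(res.mean) == sign, name
            assert res.p < 0.01, name


class TestActionConfidence:
    def test_exact_linear_coupling(self):
        n = 100
        rng = np.random.default_rng(0)
        upd = rng.uniform(0, 80, n)
        conf = np.empty(n)
        conf[1:] = 100 - upd[:-1]
        conf[0] = 50
        d = pd.DataFrame(
            {"trial": np.arange(1, n + 1), "update": upd, "confidence": conf}
        )
        fit = fit_action_confidence(d)
        assert fit.coefficients["abs_update_raw"] == pytest.approx(-1.0, abs=1e-9)
        assert fit.extra["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_shuffled_confidence_uncoupled(self):
        n = 2000
        rng = np.random.default_rng(1)
        d = pd.DataFrame(
            {
                "trial": np.arange(1, n + 1),
                "update": rng.uniform(-80, 80, n),
                "confidence": rng.integers(1, 101, n).astype(float),
            }
        )
        fit = fit_action_confidence(d)
        assert abs(fit.coefficients["abs_update_zz"]) < 0.05

    def test_constant_confidence_rejected(self):
        d = pd.DataFrame({"trial": [1, 2, 3], "update": [1.0, 2.0, 3.0], "confidence": 50.0})
        with pytest.raises(ValueError, match="confidence"):
            fit_action_confidence(d)

    def test_cohort_coupling_negative(self, normative):
        fits = []
        for _, g in normative[normative["session"] == 1].groupby("participant_id"):
            fits.append(fit_action_confidence(g))
        res = group_level_test(fits, "abs_update")
        assert res.mean < 0
        assert res.p < 0.001


class TestGroupLevelTest:
    def _fits(self, values):
        return [
            RegressionFit(
                model="m", coefficients={"b": v}, se={}, kappa=None, resid_sd=None,
                log_posterior=0.0, converged=True, n_trials_used=10,
            )
            for v in values
        ]

    def test_all_zero_coefficients(self):
        res = group_level_test(self._fits([0.0] * 6), "b")
        assert res.t == 0.0 and res.p == 1.0

    def test_tiny_jitter_still_significant(self):
        rng = np.random.default_rng(0)
        res = group_level_test(self._fits(1.0 + rng.normal(0, 1e-6, 8)), "b")
        assert res.p < 1e-6

    def test_constant_nonzero_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            group_level_test(self._fits([1.0, 1.0, 1.0]), "b")

    def test_zscore_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 2, 50)
        assert np.allclose(zscore(zscore(x)), zscore(x), atol=1e-12)

    def test_zscore_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore(np.ones(10))
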