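"""Tests of the random-intercept logistic regression and its harnesses.

Validation routes: reduction to ordinary logistic regression (against
statsmodels and the 2x2 closed form), agreement with lme4::glmer at matched
quadrature on a shared fixture, and Monte-Carlo calibration properties.
"""

import shutil
import subprocess
import sys
import warnings

import numpy as np
import pandas as pd
import pytest

from kamrisk.config import GeneratorConfig
from kamrisk.risk_models import (
    GlmmFit,
    NonIdentifiableError,
    bonferroni,
    build_feature_regressions,
    fit_glmm_logistic,
    loo_cross_validation,
    lrt_pvalue,
    marginal_r2,
    observed_power,
)
from kamrisk.synthetic import sample_cohort_features
from tests.conftest import small_config


def _truth_table(cfg: GeneratorConfig) -> pd.DataFrame:
    trials, _ = sample_cohort_features(cfg)
    tab = trials[["athlete_id", "true_early_peak", "leg_injured"]].copy()
    tab["early_peak"] = tab["true_early_peak"].astype(int)
    tab["injured"] = tab["leg_injured"].astype(int)
    return tab


def _dummy_fit(loglik, beta1=None, sigma=0.0, converged=True):
    return GlmmFit(
        fixed="x" if beta1 is not None else None,
        beta0=0.0,
        beta1=beta1,
        sigma_u=sigma,
        loglik=loglik,
        se_beta1=0.5 if beta1 is not None else None,
        converged=converged,
        separation=False,
        n_obs=10,
        n_groups=5,
        n_quad=25,
    )


class TestGlmmReductions:
    def test_sigma_zero_matches_statsmodels_logit(self, rng):
        import statsmodels.api as sm

        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-(-1.0 + 0.8 * x)))).astype(int)
        tab = pd.DataFrame({"athlete_id": [f"a{i}" for i in range(n)], "x": x, "injured": y})
        ours = fit_glmm_logistic(tab, "x", fix_sigma=0.0)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert ours.beta0 == pytest.approx(ref.params[0], abs=1e-6)
        assert ours.beta1 == pytest.approx(ref.params[1], abs=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_two_by_two_closed_form(self):
        # textbook odds ratio (a*d)/(b*c) = (10*20)/(10*5) = 4, one trial per
        # athlete and the random-intercept variance constrained to zero
        rows = (
            [(1, 1)] * 10 + [(1, 0)] * 10 + [(0, 1)] * 5 + [(0, 0)] * 20
        )
        tab = pd.DataFrame(
            {
                "athlete_id": [f"a{i}" for i in range(len(rows))],
                "x": [r[0] for r in rows],
                "injured": [r[1] for r in rows],
            }
        )
        fit = fit_glmm_logistic(tab, "x", fix_sigma=0.0)
        assert fit.or_hat == pytest.approx(4.0, rel=1e-6)

    def test_parameter_recovery_from_true_glmm(self, rng):
        # simulate from the model itself (within-group outcome variation,
        # known parameters) and recover them by maximum likelihood
        b0, b1, sigma = -1.0, 0.8, 1.0
        m, n_per = 150, 25
        u = rng.normal(0.0, sigma, m)
        g = np.repeat(np.arange(m), n_per)
        x = rng.normal(size=m * n_per)
        eta = b0 + b1 * x + u[g]
        y = (rng.random(m * n_per) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        tab = pd.DataFrame({"athlete_id": g, "x": x, "injured": y})
        fit = fit_glmm_logistic(tab, "x")
        assert fit.beta0 == pytest.approx(b0, abs=0.25)
        assert fit.beta1 == pytest.approx(b1, abs=0.15)
        assert fit.sigma_u == pytest.approx(sigma, abs=0.25)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestAgainstLme4:
    def test_matches_glmer_at_matched_quadrature(self, tmp_path):
        cfg = GeneratorConfig(
            seed=7, n_athletes=30, n_injured=4, trials_per_athlete=10, female_fraction=1.0
        )
        tab = _truth_table(cfg)
        csv = tmp_path / "fixture.csv"
        tab[["athlete_id", "early_peak", "injured"]].to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lme4))
        tab <- read.csv("{csv}")
        m <- glmer(injured ~ early_peak + (1|athlete_id), data=tab, family=binomial, nAGQ=25)
        cat(fixef(m)[1], fixef(m)[2], sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0_r, b1_r, sig_r, ll_r = (float(v) for v in out.stdout.strip().splitlines()[-4:])
        fit = fit_glmm_logistic(tab, "early_peak")
        assert fit.beta1 == pytest.approx(b1_r, abs=1e-3)
        assert fit.beta0 == pytest.approx(b0_r, abs=2e-3)
        assert fit.sigma_u == pytest.approx(sig_r, rel=1e-3)
        assert fit.loglik == pytest.approx(ll_r, abs=1e-4)


class TestLrtAndAdjustment:
    def test_equal_logliks_give_p_one(self):
        assert lrt_pvalue(_dummy_fit(-10.0, beta1=0.1), _dummy_fit(-10.0)) == 1.0

    def test_chisq_critical_value(self):
        # deviance 3.841 is the 5% critical value of chi-square(1)
        p = lrt_pvalue(_dummy_fit(-10.0, beta1=1.0), _dummy_fit(-10.0 - 3.841 / 2))
        assert p == pytest.approx(0.050, abs=5e-4)

    def test_negative_deviance_clamped(self):
        assert lrt_pvalue(_dummy_fit(-11.0, beta1=0.1), _dummy_fit(-10.0)) == 1.0

    def test_nonconverged_raises(self):
        with pytest.raises(ValueError):
            lrt_pvalue(_dummy_fit(-9.0, beta1=1.0, converged=False), _dummy_fit(-10.0))

    @pytest.mark.parametrize(
        "p,fam,expected", [(0.01, 3, 0.03), (0.5, 3, 1.0), (0.2, 1, 0.2), (1.0, 3, 1.0)]
    )
    def test_bonferroni_examples(self, p, fam, expected):
        assert bonferroni(p, fam) == pytest.approx(expected)

    def test_bonferroni_bounds_and_validation(self):
        for p in np.linspace(0, 1, 21):
            adj = bonferroni(float(p), 3)
            assert p <= adj <= 1.0
        with pytest.raises(ValueError):
            bonferroni(1.5)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestMarginalR2:
    def test_zero_slope_gives_zero(self):
        fit = _dummy_fit(-5.0, beta1=0.0)
        assert marginal_r2(fit, np.random.default_rng(0).normal(size=50)) == 0.0

    def test_forced_half(self):
        # sigma_u = 0 and var(beta1 * x) = pi^2/3 make the ratio exactly 1/2
        a = np.pi / np.sqrt(3.0)
        fit = _dummy_fit(-5.0, beta1=1.0, sigma=0.0)
        assert marginal_r2(fit, np.array([-a, a])) == pytest.approx(0.5, abs=1e-12)

    def test_matches_formula_recomputation(self):
        tab = _truth_table(small_config(seed=3, n_athletes=20, trials_per_athlete=8))
        fit = fit_glmm_logistic(tab, "early_peak")
        x = tab["early_peak"].to_numpy()
        expect = (fit.beta1**2 * np.var(x)) / (
            fit.beta1**2 * np.var(x) + fit.sigma_u**2 + np.pi**2 / 3
        )
        assert marginal_r2(fit, x) == pytest.approx(expect, abs=1e-12)


class TestLoo:
    def test_eight_injured_gives_eight_refits(self, default_table):
        res = loo_cross_validation(default_table, "early_peak")
        assert res.n_refits == 8
        assert res.or_range[0] <= res.or_range[1]
        assert 0.0 <= res.p_range[0] <= res.p_range[1] <= 1.0

    def test_two_injured_gives_two_refits(self):
        tab = _truth_table(small_config(seed=4, n_athletes=16, trials_per_athlete=8))
        res = loo_cross_validation(tab, "early_peak")
        assert res.n_refits == 2

    def test_fewer_than_two_injured_raises(self):
        tab = _truth_table(small_config(seed=4, n_athletes=16, trials_per_athlete=8, n_injured=1))
        with pytest.raises(ValueError):
            loo_cross_validation(tab, "early_peak")

    def test_bounded_influence_of_low_exposure_athlete(self, default_table):
        # force one injured athlete to contribute no early-peak trials; its
        # exclusion must not move the estimate by more than a modest factor
        tab = default_table.copy()
        aid = tab.loc[tab["injured"] == 1, "athlete_id"].iloc[0]
        tab.loc[tab["athlete_id"] == aid, "early_peak"] = 0
        full = fit_glmm_logistic(tab, "early_peak")
        res = loo_cross_validation(tab, "early_peak")
        loo_or = res.entries.set_index("athlete_id").loc[aid, "or_hat"]
        assert abs(np.log(loo_or) - np.log(full.or_hat)) < np.log(2.5)


class TestDegenerateInputs:
    def test_constant_fixed_column_raises(self):
        tab = pd.DataFrame(
            {"athlete_id": list("aabb"), "x": [1, 1, 1, 1], "injured": [1, 1, 0, 0]}
        )
        with pytest.raises(NonIdentifiableError):
            fit_glmm_logistic(tab, "x")

    def test_single_athlete_raises(self):
        tab = pd.DataFrame({"athlete_id": ["a"] * 4, "x": [0, 1, 0, 1], "injured": [0, 1, 0, 1]})
        with pytest.raises(NonIdentifiableError):
            fit_glmm_logistic(tab, "x")

    def test_nonbinary_outcome_raises(self):
        tab = pd.DataFrame({"athlete_id": list("abcd"), "x": [0, 1, 0, 1], "injured": [0, 2, 0, 1]})
        with pytest.raises(ValueError):
            fit_glmm_logistic(tab, "x")

    def test_separation_flagged_with_capped_estimate(self):
        rows = []
        for a in range(8):
            y = int(a < 4)
            rows += [{"athlete_id": f"a{a}", "x": y, "injured": y}] * 5
        tab = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_glmm_logistic(tab, "x")
        assert fit.separation
        assert abs(fit.beta1) <= 15.0


class TestObservedPower:
    def test_null_model_power_matches_level(self):
        cfg = GeneratorConfig(target_trial_or=1.0)
        est = observed_power(cfg, n_sims=150, alpha=0.05, seed=99)
        assert 0.005 <= est.power <= 0.11
        assert est.ci95[0] <= est.power <= est.ci95[1]

    def test_enormous_effect_power_near_one(self):
        cfg = GeneratorConfig(target_trial_or=30.0)
        est = observed_power(cfg, n_sims=60, alpha=0.05, seed=7)
        assert est.power >= 0.9

    def test_monotone_in_effect_size(self):
        powers = [
            observed_power(GeneratorConfig(target_trial_or=orr), n_sims=100, seed=5).power
            for orr in (1.5, 6.0, 25.0)
        ]
        assert powers[0] <= powers[1] + 0.05
        assert powers[1] <= powers[2] + 0.05

    def test_monotone_in_trials_per_athlete(self):
        powers = [
            observed_power(
                GeneratorConfig(target_trial_or=3.0, trials_per_athlete=m), n_sims=100, seed=6
            ).power
            for m in (6, 21, 48)
        ]
        assert powers[0] <= powers[1] + 0.05
        assert powers[1] <= powers[2] + 0.05

    def test_small_n_sims_warns(self):
        cfg = small_config(seed=1, n_athletes=16, trials_per_athlete=6)
        with pytest.warns(UserWarning, match="n_sims"):
            observed_power(cfg, n_sims=20, seed=3)

    def test_fitted_model_route(self):
        tab = _truth_table(small_config(seed=8, n_athletes=20, trials_per_athlete=8))
        fit = fit_glmm_logistic(tab, "early_peak")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = observed_power(fit, n_sims=40, seed=11, table=tab)
        assert 0.0 <= est.power <= 1.0
        assert est.n_sims == 40

    def test_rejects_unknown_model(self):
        with pytest.raises(TypeError):
            observed_power(object(), n_sims=10)


class TestFeatureRegressions:
    def test_report_mirrors_variable_list(self, default_table):
        rep = build_feature_regressions(default_table)
        assert len(rep) == 6
        assert rep["family"].value_counts().to_dict() == {"kinematics": 3, "kinetics": 3}
        assert ((rep["p_adjusted"] >= rep["p_lrt"] - 1e-12) & (rep["p_adjusted"] <= 1.0)).all()
        assert np.isfinite(rep["or_hat"]).all()

    def test_abduction_angle_is_the_risk_covariate(self, default_table):
        rep = build_feature_regressions(default_table).set_index("variable")
        assert rep.loc["knee_abd_angle_ic", "or_hat"] > 1.1
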