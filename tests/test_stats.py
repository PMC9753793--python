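"""Paired-eye models, LRT, multiplicity adjustment, concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from scleramech.exceptions import (
    EstimabilityError,
    InvalidInputError,
    NestingError,
)
from scleramech.stats import (
    adjust_multivariate_t,
    concordance_correlation,
    emm_percent_iod,
    fit_paired_log_model,
    likelihood_ratio_test,
    paired_gaussian_iod,
)


def simulate_paired(rng, n_animals=30, eye_effect=0.0, animal_sd=0.3,
                    eye_sd=0.15, strain_slope=0.0, n_steps=1):
    rows = []
    for a in range(n_animals):
        base = rng.normal(0.0, animal_sd)
        for role in ("treated", "contralateral"):
            mu = base + (eye_effect if role == "treated" else 0.0)
            for step in range(1, n_steps + 1):
                dev = rng.uniform(-0.015, 0.015)
                rows.append({
                    "animal_id": f"a{a}", "eye_id": f"a{a}_{role}",
                    "eye": role, "step": step, "strain_deviation": dev,
                    "value": float(np.exp(mu + strain_slope * dev
                                          + rng.normal(0.0, eye_sd))),
                })
    return pd.DataFrame(rows)


class TestPairedLogModel:
    def test_consistency_at_large_n(self):
        """With a true multiplicative eye effect exp(b)=0.7 the coefficient
        converges to log 0.7 at n=200 animals."""
        rng = np.random.default_rng(1)
        df = simulate_paired(rng, n_animals=200, eye_effect=np.log(0.7))
        fit = fit_paired_log_model(df)
        est = emm_percent_iod(fit, contrast="eye")
        assert est.estimate_log == pytest.approx(np.log(0.7), abs=3 * est.se_log)
        assert abs(est.estimate_log - np.log(0.7)) < 0.05

    def test_null_coefficient_near_zero(self):
        """Under a zero eye effect the coefficient stays within 3 SE of 0 in
        the vast majority of replicates."""
        rng = np.random.default_rng(2)
        inside = 0
        n_rep = 40  # the 200-replicate sweep runs in the acceptance suite
        for _ in range(n_rep):
            df = simulate_paired(rng, n_animals=12)
            est = emm_percent_iod(fit_paired_log_model(df), contrast="eye")
            inside += abs(est.estimate_log) < 3 * est.se_log
        assert inside >= int(0.9 * n_rep)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(3)
        df = simulate_paired(rng, n_animals=15, eye_effect=-0.2)
        dup = pd.concat([df, df.assign(
            animal_id=df["animal_id"] + "_dup",
            eye_id=df["eye_id"] + "_dup")], ignore_index=True)
        b1 = emm_percent_iod(fit_paired_log_model(df), "eye").estimate_log
        b2 = emm_percent_iod(fit_paired_log_model(dup), "eye").estimate_log
        assert b2 == pytest.approx(b1, abs=1e-5)

    def test_strain_deviation_corrected(self):
        """A log-linear dependence on strain deviation is removed by the
        covariate: the EMM at zero deviation recovers the configured effect."""
        rng = np.random.default_rng(4)
        df = simulate_paired(rng, n_animals=150, eye_effect=np.log(0.75),
                             strain_slope=-8.0, n_steps=3)
        fit = fit_paired_log_model(df)
        est = emm_percent_iod(fit, contrast="eye")
        assert est.estimate_log == pytest.approx(np.log(0.75), abs=0.05)
        slope = fit.params["strain_deviation"]
        assert slope == pytest.approx(-8.0, abs=2.0)

    def test_positive_outcomes_required(self):
        df = simulate_paired(np.random.default_rng(0), n_animals=5)
        df.loc[0, "value"] = -1.0
        with pytest.raises(InvalidInputError):
            fit_paired_log_model(df)

    def test_gamma_glm_cross_check_agrees(self):
        """The Gamma/log GLM with animal blocks reproduces the mixed-model
        eye effect on the same data."""
        rng = np.random.default_rng(5)
        df = simulate_paired(rng, n_animals=40, eye_effect=np.log(0.8))
        lmm = emm_percent_iod(fit_paired_log_model(df), "eye")
        glm = emm_percent_iod(fit_paired_log_model(df, method="gamma_glm"),
                              "eye")
        assert glm.estimate_log == pytest.approx(lmm.estimate_log, abs=0.02)

    def test_unknown_contrast_raises(self):
        df = simulate_paired(np.random.default_rng(6), n_animals=8)
        with pytest.raises(EstimabilityError):
            emm_percent_iod(fit_paired_log_model(df), "nonexistent_term")


class TestEmmTransform:
    def test_percent_transform_examples(self):
        df = simulate_paired(np.random.default_rng(7), n_animals=10)
        fit = fit_paired_log_model(df)
        est = emm_percent_iod(fit, "eye")
        assert est.percent_change == pytest.approx(
            100 * (np.exp(est.estimate_log) - 1))
        assert est.ci_low <= est.percent_change <= est.ci_high
        # exp(0) - 1 = 0%, exp(log 2) - 1 = +100%
        assert 100 * (np.exp(0.0) - 1) == 0.0
        assert 100 * (np.exp(np.log(2.0)) - 1) == pytest.approx(100.0)


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self):
        df = simulate_paired(np.random.default_rng(8), n_animals=12)
        fit = fit_paired_log_model(df)
        stat, df_, p = likelihood_ratio_test(fit, fit)
        assert stat == 0.0 and df_ == 0 and p == 1.0

    def test_rescaling_invariance(self):
        """Multiplying the outcome by a positive constant shifts the log-mean
        only; the LRT statistic for the eye effect is unchanged."""
        rng = np.random.default_rng(9)
        df = simulate_paired(rng, n_animals=20, eye_effect=-0.3)
        stats_ = []
        for scale in (1.0, 137.0):
            scaled = df.assign(value=df["value"] * scale)
            full = fit_paired_log_model(scaled)
            null = fit_paired_log_model(scaled, formula="_log_y ~ 1")
            stats_.append(likelihood_ratio_test(full, null)[0])
        assert stats_[0] == pytest.approx(stats_[1], abs=1e-5)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(10)
        df = simulate_paired(rng, n_animals=10, n_steps=2)
        eye_only = fit_paired_log_model(
            df, formula="_log_y ~ C(eye, Treatment(reference='contralateral'))")
        step_only = fit_paired_log_model(df, formula="_log_y ~ C(step)")
        with pytest.raises(NestingError):
            likelihood_ratio_test(eye_only, step_only)

    def test_type_i_error_calibrated(self):
        """Null-true LRT rejection rate at alpha=0.05 is near nominal (the
        1000-replicate calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 120
        for _ in range(n_rep):
            df = simulate_paired(rng, n_animals=25)
            full = fit_paired_log_model(df)
            null = fit_paired_log_model(df, formula="_log_y ~ 1")
            _, _, p = likelihood_ratio_test(full, null)
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.01 <= rate <= 0.11


class TestMultivariateT:
    def test_single_contrast_equals_raw(self):
        p_raw, p_adj = adjust_multivariate_t([1.5], [[0.25]], df=20)
        np.testing.assert_allclose(p_adj, p_raw)

    def test_two_independent_contrasts_match_sidak(self):
        est = np.array([1.2, -0.4])
        cov = np.diag([0.25, 0.16])
        p_raw, p_adj = adjust_multivariate_t(est, cov, df=np.inf,
                                             n_draws=200_000, seed=1)
        sidak = 1.0 - (1.0 - p_raw) ** 2
        np.testing.assert_allclose(p_adj, sidak, atol=5e-3)

    def test_perfectly_correlated_equals_raw(self):
        cov = np.array([[0.2, 0.2], [0.2, 0.2]])
        p_raw, p_adj = adjust_multivariate_t([0.9, 0.9], cov, df=15)
        np.testing.assert_allclose(p_adj, p_raw)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(3, 3))
        cov = a @ a.T + 0.5 * np.eye(3)
        p_raw, p_adj = adjust_multivariate_t(rng.normal(size=3), cov, df=10,
                                             n_draws=20_000, seed=2)
        assert np.all(p_adj >= p_raw - 1e-12)

    def test_non_psd_rejected(self):
        with pytest.raises(InvalidInputError):
            adjust_multivariate_t([1.0, 1.0], [[1.0, 2.0], [2.0, 1.0]], df=10)


class TestConcordance:
    def test_worked_examples(self):
        assert concordance_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert concordance_correlation([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)
        x = np.array([-1.0, 0.0, 1.0])
        assert concordance_correlation(x, -x) == pytest.approx(-1.0)

    def test_bounded_and_below_pearson(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            x = rng.normal(size=12)
            y = 0.5 * x + rng.normal(size=12) + rng.uniform(-1, 1)
            rho_c = concordance_correlation(x, y)
            r = sps.pearsonr(x, y).statistic
            assert -1.0 <= rho_c <= 1.0
            assert abs(rho_c) <= abs(r) + 1e-12

    def test_degenerate_rejected(self):
        with pytest.raises(InvalidInputError):
            concordance_correlation([2.0, 2.0], [2.0, 2.0])


def test_paired_gaussian_iod_recovers_mean():
    rng = np.random.default_rng(14)
    d = rng.normal(-2.35, 1.11, size=400)
    res = paired_gaussian_iod(d)
    assert res["mean_iod"] == pytest.approx(-2.35, abs=0.2)
    assert res["ci_low"] < res["mean_iod"] < res["ci_high"]
    assert res["p"] < 1e-6
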