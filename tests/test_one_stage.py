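"""One-stage mixed models: oracle cross-checks (statsmodels MixedLM,
pooled OLS), aggregation-bias separation, Satterthwaite intervals, and
the binary-outcome adaptive-quadrature fit."""

import warnings

import numpy as np
import pandas as pd
import pytest

from deftmeta import (IPDDataset, OneStageInteraction, SynthConfig,
                      TwoStageInteraction, fit_onestage_centered,
                      fit_onestage_deluded, fit_onestage_stratified,
                      generate_ipd, satterthwaite_interval)


@pytest.fixture(scope="module")
def small_ds():
    return generate_ipd(SynthConfig(n_trials=5, n_per_trial=150, tau2=0.02,
                                    with_baseline=False), seed=6)


class TestOracles:
    def test_matches_statsmodels_mixedlm(self, small_ds):
        """Same model (common residual variance, one random interaction
        slope) fitted by an independent implementation."""
        import statsmodels.formula.api as smf

        mine = fit_onestage_stratified(small_ds, "age",
                                       residual_variances="common")
        df = small_ds.df.copy()
        df["zc"] = df.groupby("trial")["age"].transform(lambda s: s - s.mean())
        df["xzc"] = df["arm"] * df["zc"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(
                "y ~ 0 + C(trial) + C(trial):zc + C(trial):arm + xzc",
                df, groups=df["trial"], re_formula="0 + xzc")
            mf = md.fit(reml=True)
        assert mine.gamma == pytest.approx(float(mf.params["xzc"]), abs=1e-4)
        assert mine.tau2_interaction == pytest.approx(
            float(mf.cov_re.iloc[0, 0]), abs=1e-4)
        assert float(mine.sigma2.iloc[0]) == pytest.approx(float(mf.scale),
                                                           rel=1e-4)

    def test_tau_zero_matches_stratified_ols(self):
        """When REML puts the interaction heterogeneity at zero, the
        stratified one-stage (common sigma^2) is exactly the pooled OLS
        fit with trial-stratified nuisance parameters."""
        import statsmodels.formula.api as smf

        ds = generate_ipd(SynthConfig(n_trials=4, n_per_trial=80, tau2=0.0,
                                      with_baseline=False), seed=18)
        mine = fit_onestage_stratified(ds, "age", residual_variances="common")
        assert mine.tau2_interaction == 0.0  # boundary REML solution
        df = ds.df.copy()
        df["zc"] = df.groupby("trial")["age"].transform(lambda s: s - s.mean())
        df["xzc"] = df["arm"] * df["zc"]
        ols = smf.ols("y ~ 0 + C(trial) + C(trial):zc + C(trial):arm + xzc",
                      df).fit()
        assert mine.gamma == pytest.approx(float(ols.params["xzc"]), abs=1e-4)


class TestDeftProperties:
    def test_centered_and_stratified_agree(self, agreement_ds):
        c = fit_onestage_centered(agreement_ds, "age")
        s = fit_onestage_stratified(agreement_ds, "age")
        assert c.gamma == pytest.approx(s.gamma, abs=0.01)
        assert c.phi is not None and s.phi is None

    def test_onestage_matches_twostage_reml(self, agreement_ds):
        ts = TwoStageInteraction(covariate="age").fit(agreement_ds)
        c = fit_onestage_centered(agreement_ds, "age")
        assert abs(c.gamma - ts.gamma_w_) <= 0.01 * ts.se_

    def test_bias_separation_point_estimates(self):
        ds = generate_ipd(SynthConfig(gamma_w=0.0, gamma_a=-0.3), seed=5)
        c = fit_onestage_centered(ds, "age")
        assert abs(c.gamma) < 3 * c.se
        se_a = np.nan  # gamma_a SE not exposed; use a generous recovery band
        assert c.gamma_a == pytest.approx(-0.3, abs=0.15)

    def test_centering_invariance_to_trial_shift(self, small_ds):
        """Adding a constant to one trial's covariate leaves gamma_W
        essentially unchanged: exactly so under full stratification
        (the shift is absorbed by that trial's own parameters), and up
        to the covariate-mean meta-regression reweighting -- a small
        fraction of one SE -- under the centered approach."""
        df = small_ds.df.copy()
        df.loc[df["trial"] == "T02", "age"] += 37.5
        shifted_ds = IPDDataset(df, "continuous", ["age"])

        base_s = fit_onestage_stratified(small_ds, "age")
        shift_s = fit_onestage_stratified(shifted_ds, "age")
        assert shift_s.gamma == pytest.approx(base_s.gamma, abs=1e-6)

        base_c = fit_onestage_centered(small_ds, "age")
        shift_c = fit_onestage_centered(shifted_ds, "age")
        assert shift_c.gamma == pytest.approx(base_c.gamma,
                                              abs=0.01 * base_c.se)

    def test_constant_covariate_trial_contributes_no_interaction_info(self):
        ds = generate_ipd(SynthConfig(n_trials=4, n_per_trial=120,
                                      with_baseline=False), seed=21)
        df = ds.df.copy()
        df.loc[df["trial"] == "T04", "age"] = 60.0
        with_const = fit_onestage_stratified(
            IPDDataset(df, "continuous", ["age"]), "age")
        without = fit_onestage_stratified(
            IPDDataset(df[df["trial"] != "T04"], "continuous", ["age"]), "age")
        assert with_const.gamma == pytest.approx(without.gamma, abs=1e-6)

    def test_fewer_than_two_trials_error(self):
        ds = generate_ipd(SynthConfig(n_trials=1), seed=1)
        with pytest.raises(ValueError, match="2 trials"):
            fit_onestage_centered(ds, "age")


class TestDeluded:
    def test_equals_deft_without_ecological_discrepancy(self):
        ds = generate_ipd(SynthConfig(n_per_trial=600), seed=30)
        deft = fit_onestage_centered(ds, "age")
        deluded = fit_onestage_deluded(ds, "age")
        assert deluded.diagnostic_only
        assert "NOT" in deluded.to_dict()["warning"].upper() or \
               "amalgamates" in deluded.to_dict()["warning"]
        assert deluded.gamma == pytest.approx(deft.gamma, abs=3 * deft.se)

    def test_pulled_toward_across_trial_trend(self):
        """gamma_W = 0, gamma_A = -0.3, spread trial means: the amalgamated
        estimate lies between the deft estimate and the trend in most
        replicates."""
        between = 0
        m = 40
        defts, deludeds = [], []
        for seed in range(m):
            ds = generate_ipd(SynthConfig(n_trials=6, n_per_trial=120,
                                          gamma_w=0.0, gamma_a=-0.3,
                                          with_baseline=False), seed=1000 + seed)
            deft = fit_onestage_centered(ds, "age")
            deluded = fit_onestage_deluded(ds, "age")
            defts.append(deft.gamma)
            deludeds.append(deluded.gamma)
            lo, hi = sorted([deft.gamma, -0.3])
            between += lo - 1e-9 <= deluded.gamma <= hi + 1e-9
        assert between / m >= 0.85
        # on average the amalgamated estimate sits clearly closer to the
        # across-trial trend than the deft estimate does
        assert np.mean(deludeds) < np.mean(defts) - 0.02

    def test_bias_grows_with_mean_spread(self):
        biases = []
        for spread in (2.0, 15.0, 40.0):
            means = tuple(55 + spread * np.linspace(-1, 1, 6))
            est = []
            for seed in (3, 4, 5):
                ds = generate_ipd(
                    SynthConfig(n_trials=6, n_per_trial=150, gamma_w=0.0,
                                gamma_a=-0.3, covariate_means=means,
                                with_baseline=False), seed=seed)
                est.append(fit_onestage_deluded(ds, "age").gamma)
            biases.append(abs(np.mean(est)))
        assert biases[0] < biases[1] < biases[2]

    def test_binary_outcome_rejected(self):
        ds = generate_ipd(SynthConfig(n_trials=3, n_per_trial=60,
                                      outcome_type="binary", phi=-0.3,
                                      gamma_w=0.0, beta_z=0.1, alpha_sd=0.2,
                                      covariate_means=(0.0, 0.5, 1.0),
                                      covariate_sd=1.0, with_baseline=False),
                          seed=2)
        with pytest.raises(ValueError, match="continuous"):
            fit_onestage_deluded(ds, "age")


class TestSatterthwaite:
    def test_wider_than_wald_and_near_hksj(self, agreement_ds):
        c = fit_onestage_centered(agreement_ds, "age",
                                  ci_method="satterthwaite")
        wald_width = 2 * 1.959963984540054 * c.se
        satt_width = c.ci[1] - c.ci[0]
        assert satt_width > wald_width
        ts = TwoStageInteraction(covariate="age", ci_method="hksj").fit(
            agreement_ds)
        hksj_width = ts.ci_[1] - ts.ci_[0]
        assert satt_width == pytest.approx(hksj_width, rel=0.05)

    def test_binary_fit_rejected(self):
        ds = generate_ipd(SynthConfig(n_trials=4, n_per_trial=300,
                                      outcome_type="binary", phi=-0.3,
                                      gamma_w=0.2, beta_z=0.2, alpha_sd=0.2,
                                      covariate_means=(0.0, 0.5, 1.0, 1.5),
                                      covariate_sd=1.0, with_baseline=False),
                          seed=3)
        fit = OneStageInteraction(covariate="age", approach="stratified",
                                  outcome_type="binary").fit(ds)
        with pytest.raises(ValueError, match="continuous"):
            satterthwaite_interval(fit.result_)


class TestBinary:
    def test_interaction_recovery(self):
        cfg = SynthConfig(n_trials=5, n_per_trial=400, outcome_type="binary",
                          phi=-0.5, gamma_w=0.4, gamma_a=0.4, beta_z=0.3,
                          covariate_means=(0.0, 0.5, 1.0, 1.5, 2.0),
                          covariate_sd=1.0, alpha_sd=0.3, with_baseline=False)
        ds = generate_ipd(cfg, seed=4)
        s = fit_onestage_stratified(ds, "age", outcome_type="binary")
        assert abs(s.gamma - 0.4) < 3 * s.se
        ts = TwoStageInteraction(covariate="age", outcome_type="binary").fit(ds)
        # the one-stage ML and two-stage log-OR pooling agree closely here
        assert s.gamma == pytest.approx(ts.gamma_w_, abs=0.5 * ts.se_)
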