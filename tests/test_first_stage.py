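"""Per-trial interaction fits: exact identities, closed-form oracle,
variance formulas, parameter recovery, and flagging contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deftmeta import (SplineBasisSpec, TrialFitError, closed_form_interaction,
                      fit_first_stage, fit_trial_cox, fit_trial_linear,
                      fit_trial_logistic, fit_trial_spline_interaction)
from deftmeta.first_stage import estimates_from_frame, estimates_to_frame
from deftmeta.synthetic import SynthConfig, generate_ipd


def balanced_trial(rng, n=200, sigma=1.0, gamma=0.0, binary_z=True):
    """Balanced two-arm trial with equal covariate distribution per arm."""
    half = n // 2
    if binary_z:
        z_arm = np.tile([0.0, 1.0], half // 2)
    else:
        z_arm = rng.normal(50, 10, size=half)
    z = np.concatenate([z_arm, z_arm])
    x = np.repeat([0.0, 1.0], half)
    y = 1.0 + 0.3 * z - 2.0 * x + gamma * x * z + rng.normal(0, sigma, n)
    return pd.DataFrame({"trial": "T", "arm": x.astype(int), "z": z, "y": y})


class TestLinear:
    def test_exact_noise_free_fit(self, toy_trial):
        est, fit = fit_trial_linear(toy_trial, "z")
        assert est.gamma == pytest.approx(2.0, abs=1e-10)
        assert est.var_gamma < 1e-20
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_variance_formula_binary_z(self):
        # balanced, binary z, sigma_z^2 = 0.25: var ~ 4 sigma^2/(n sigma_z^2)
        rng = np.random.default_rng(0)
        g = balanced_trial(rng, n=100, sigma=1.0)
        est, fit = fit_trial_linear(g, "z")
        expected = 4.0 * fit.sigma2 / (100 * 0.25)
        assert est.var_gamma == pytest.approx(expected, rel=0.02)

    def test_recovery_within_3se(self):
        cfg = SynthConfig(n_trials=1, n_per_trial=2000)
        ds = generate_ipd(cfg, seed=77)
        est, _ = fit_trial_linear(ds.df, "age", adjusters=["baseline"])
        assert abs(est.gamma - (-0.1)) < 3 * est.se

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=-100, max_value=100, allow_nan=False))
    def test_shift_invariance(self, shift):
        rng = np.random.default_rng(12)
        g = balanced_trial(rng, n=60, sigma=2.0, gamma=0.7, binary_z=False)
        est0, _ = fit_trial_linear(g, "z")
        g2 = g.assign(z=g["z"] + shift)
        est1, _ = fit_trial_linear(g2, "z")
        assert est1.gamma == pytest.approx(est0.gamma, abs=1e-8)

    def test_constant_covariate_flagged(self):
        g = pd.DataFrame({"trial": "T", "arm": [0, 1, 0, 1],
                          "z": [1.0] * 4, "y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(TrialFitError, match="rank-deficient"):
            fit_trial_linear(g, "z")


class TestClosedForm:
    def test_constant_outcome_gives_zero(self):
        # both arms see the same covariate values (symmetric design)
        g = pd.DataFrame({"trial": "T", "arm": np.repeat([0, 1], 10),
                          "z": np.tile(np.arange(10.0), 2),
                          "y": np.full(20, 7.0)})
        assert closed_form_interaction(g, "z") == pytest.approx(0.0, abs=1e-12)

    def test_equals_regression_under_balance(self):
        rng = np.random.default_rng(3)
        g = balanced_trial(rng, n=120, sigma=1.5, gamma=0.4)
        cf = closed_form_interaction(g, "z")
        est, _ = fit_trial_linear(g, "z")
        # exact equality needs equal arms and identical arm-wise zbar
        assert cf == pytest.approx(est.gamma, abs=1e-6)

    def test_single_arm_errors(self):
        g = pd.DataFrame({"trial": "T", "arm": [1, 1], "z": [0.0, 1.0],
                          "y": [1.0, 2.0]})
        with pytest.raises(TrialFitError, match="both arms"):
            closed_form_interaction(g, "z")


class TestLogistic:
    def test_recovery_log_or(self):
        rng = np.random.default_rng(8)
        n = 2000
        z = rng.normal(0, 1, n)
        x = np.zeros(n)
        x[rng.permutation(n)[: n // 2]] = 1
        lp = -0.3 + 0.2 * z + 0.3 * x + np.log(1.5) * x * z
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        g = pd.DataFrame({"trial": "T", "arm": x.astype(int), "z": z, "y": y})
        est, _ = fit_trial_logistic(g, "z")
        assert est.scale == "log_or"
        assert abs(est.gamma - np.log(1.5)) < 3 * est.se

    def test_zero_events_in_arm_flagged(self):
        g = pd.DataFrame({"trial": "T", "arm": [0] * 5 + [1] * 5,
                          "z": np.arange(10.0),
                          "y": [0, 1, 0, 1, 0] + [0] * 5})
        with pytest.raises(TrialFitError, match="zero events"):
            fit_trial_logistic(g, "z")

    def test_null_type_one_error(self):
        # Wald test of the interaction rejects at roughly the nominal 5%
        rng = np.random.default_rng(123)
        rejections = 0
        m = 800
        for _ in range(m):
            n = 150
            z = rng.normal(0, 1, n)
            x = np.repeat([0.0, 1.0], n // 2)
            lp = -0.2 + 0.3 * x + 0.2 * z
            y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
            g = pd.DataFrame({"trial": "T", "arm": x.astype(int), "z": z, "y": y})
            try:
                est, _ = fit_trial_logistic(g, "z")
            except TrialFitError:
                continue
            if abs(est.gamma) / est.se > 1.96:
                rejections += 1
        rate = rejections / m
        assert 0.03 <= rate <= 0.07


class TestCox:
    @staticmethod
    def _surv_trial(rng, n, log_hr_int):
        z = rng.normal(0, 1, n)
        x = np.repeat([0.0, 1.0], n // 2)
        rate = 0.2 * np.exp(0.1 * z - 0.4 * x + log_hr_int * x * z)
        t = rng.exponential(1 / rate)
        c = rng.uniform(0, 12, n)
        return pd.DataFrame({"trial": "T", "arm": x.astype(int), "z": z,
                             "time": np.minimum(t, c),
                             "event": (t <= c).astype(int)})

    def test_null_recovery(self):
        g = self._surv_trial(np.random.default_rng(4), 600, 0.0)
        est, _ = fit_trial_cox(g, "z")
        assert abs(est.gamma) < 3 * est.se

    def test_ratio_of_hazard_ratios_recovery(self):
        g = self._surv_trial(np.random.default_rng(5), 4000, np.log(1.3))
        est, _ = fit_trial_cox(g, "z")
        assert est.scale == "log_hr"
        assert abs(est.gamma - np.log(1.3)) < 3 * est.se

    def test_all_censored_flagged(self):
        g = self._surv_trial(np.random.default_rng(6), 100, 0.0)
        g["event"] = 0
        with pytest.raises(TrialFitError, match="no events"):
            fit_trial_cox(g, "z")


class TestSplineTrialFit:
    SPEC = SplineBasisSpec((40.0, 55.0, 70.0), reference=55.0)

    def test_linear_truth_has_no_curvature(self):
        rng = np.random.default_rng(11)
        n = 1500
        z = rng.uniform(35, 75, n)
        x = np.repeat([0.0, 1.0], n // 2)
        y = 0.2 * z - 8.0 * x - 0.2 * x * (z - 55.0) + rng.normal(0, 5, n)
        g = pd.DataFrame({"trial": "T", "arm": x.astype(int), "age": z, "y": y})
        est = fit_trial_spline_interaction(g, "age", self.SPEC)
        se2 = np.sqrt(est.cov[2, 2])
        assert abs(est.gammas[1]) < 3 * se2
        assert abs(est.gammas[0] - (-0.2)) < 3 * np.sqrt(est.cov[1, 1])
        assert abs(est.beta2 - (-8.0)) < 3 * np.sqrt(est.cov[0, 0])

    def test_narrow_range_masks_nonlinear_component(self):
        rng = np.random.default_rng(13)
        n = 200
        z = rng.uniform(30, 39, n)  # entirely below the second knot
        x = np.repeat([0.0, 1.0], n // 2)
        y = 0.1 * z - 5.0 * x + rng.normal(0, 3, n)
        g = pd.DataFrame({"trial": "T", "arm": x.astype(int), "age": z, "y": y})
        est = fit_trial_spline_interaction(g, "age", self.SPEC)
        assert est.mask.tolist() == [False, True]
        assert np.isnan(est.gammas[1])


def test_first_stage_orchestration_logs_unusable_trials(default_ds):
    # sabotage one trial to a single arm
    df = default_ds.df.copy()
    df.loc[df["trial"] == "T01", "arm"] = 1
    from deftmeta import IPDDataset

    ds = IPDDataset(df, "continuous", ["age"])
    ests, fits, log = fit_first_stage(ds, "age")
    assert len(ests) == 9
    assert any("T01" in entry for entry in log)


def test_estimate_frame_round_trip(default_ds):
    ests, _, _ = fit_first_stage(default_ds, "age")
    frame = estimates_to_frame(ests)
    back = estimates_from_frame(frame)
    assert [e.gamma for e in back] == pytest.approx([e.gamma for e in ests])
    assert [e.var_gamma for e in back] == pytest.approx(
        [e.var_gamma for e in ests])
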