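"""Second-stage pooling: inverse-variance arithmetic, REML against a grid
oracle and R's metafor, HKSJ identities, prediction intervals, and
multivariate pooling with missing components."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from deftmeta import (MultiMetaResult, TrialEstimate, pool_common,
                      pool_multivariate, pool_random, prediction_interval)
from deftmeta.meta import reml_loglik_uni


def ests(ys, vs):
    return [TrialEstimate(i, y, v) for i, (y, v) in enumerate(zip(ys, vs))]


class TestCommon:
    def test_single_study_identity(self):
        r = pool_common(ests([0.5], [0.04]))
        assert (r.gamma, r.var) == (0.5, pytest.approx(0.04))

    def test_equal_variance_symmetry(self):
        r = pool_common(ests([0.0, 1.0], [0.3, 0.3]))
        assert r.gamma == pytest.approx(0.5)

    def test_hand_inverse_variance_arithmetic(self):
        # weights (1, 2, 4): mean 17/7, variance 1/7
        r = pool_common(ests([1.0, 2.0, 3.0], [1.0, 0.5, 0.25]))
        assert r.gamma == pytest.approx(17.0 / 7.0, abs=1e-12)
        assert r.var == pytest.approx(1.0 / 7.0, abs=1e-12)

    def test_mixed_scales_fatal(self):
        e = [TrialEstimate(0, 0.1, 0.1, scale="log_or"),
             TrialEstimate(1, 0.1, 0.1, scale="log_hr")]
        with pytest.raises(ValueError, match="mixed scales"):
            pool_common(e)


class TestRandom:
    def test_identical_estimates_collapse_to_common(self):
        e = ests([0.4, 0.4, 0.4], [0.1, 0.1, 0.1])
        r = pool_random(e, ci_method="wald")
        c = pool_common(e)
        assert r.tau2 == 0.0
        assert r.gamma == pytest.approx(c.gamma)
        assert r.se == pytest.approx(c.se)

    def test_reml_matches_grid_oracle(self):
        y = np.array([0.0, 1.0, 2.0])
        v = np.array([1.0, 1.0, 1.0])
        r = pool_random(ests(y, v))
        grid = np.linspace(0, 20, 200001)
        lls = [reml_loglik_uni(t, y, v) for t in grid]
        assert r.tau2 == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_reml_and_hksj_match_metafor(self):
        """Independent oracle: R metafor rma(..., method='REML', test='knha')."""
        y = [0.2, -0.1, 0.5, 0.9, -0.3, 0.4]
        v = [0.04, 0.09, 0.05, 0.12, 0.07, 0.06]
        r = pool_random(ests(y, v), ci_method="hksj")
        code = (
            "suppressMessages(library(metafor));"
            f"y<-c({','.join(map(str, y))});v<-c({','.join(map(str, v))});"
            "m<-rma(yi=y,vi=v,method='REML',test='knha',control=list(tol=1e-10));"
            "cat(sprintf('%.10f %.10f %.10f %.10f %.10f', m$b, m$tau2, m$se,"
            " m$ci.lb, m$ci.ub))"
        )
        out = subprocess.run(["Rscript", "-e", code], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        mu, tau2, se, lo, hi = map(float, out.stdout.split())
        assert r.gamma == pytest.approx(mu, abs=1e-6)
        assert r.tau2 == pytest.approx(tau2, abs=1e-6)
        assert r.se == pytest.approx(se, abs=1e-6)
        assert r.ci == pytest.approx((lo, hi), abs=1e-5)

    def test_k1_directs_to_common(self):
        with pytest.raises(ValueError, match="pool_common"):
            pool_random(ests([0.5], [0.1]))

    def test_zero_weight_study_changes_nothing(self):
        base = ests([0.1, 0.6, 0.3, 0.2], [0.05, 0.08, 0.06, 0.04])
        inflated = base + [TrialEstimate(9, 5.0, 1e12)]
        r0 = pool_random(base, ci_method="hksj")
        r1 = pool_random(inflated, ci_method="hksj")
        assert r1.gamma == pytest.approx(r0.gamma, abs=1e-6)
        assert r1.tau2 == pytest.approx(r0.tau2, abs=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.01, 1.0)),
                    min_size=3, max_size=8))
    def test_hksj_algebraic_identity(self, pairs):
        e = ests(*zip(*pairs))
        r = pool_random(e, ci_method="hksj")
        w = 1.0 / (np.array([x.var_gamma for x in e]) + r.tau2)
        y = np.array([x.gamma for x in e])
        q = np.sum(w * (y - r.gamma) ** 2) / (len(e) - 1)
        # HKSJ half-width = Wald half-width * sqrt(q) * t/z quantile ratio
        t = stats.t.ppf(0.975, len(e) - 1)
        z = stats.norm.ppf(0.975)
        wald_half = z * r.se_wald
        hksj_half = (r.ci[1] - r.ci[0]) / 2
        assert hksj_half == pytest.approx(wald_half * np.sqrt(q) * t / z,
                                          rel=1e-9)

    def test_reml_calibration_and_hksj_coverage(self):
        """k=10 studies, true interaction 0.77, true tau^2 = 1: REML is
        nearly unbiased and HKSJ intervals cover at ~95%."""
        rng = np.random.default_rng(20250924)
        m = 1000
        tau2s = np.empty(m)
        covered = 0
        for j in range(m):
            v = rng.uniform(0.8, 1.2, 10)
            y = 0.77 + rng.standard_normal(10) * np.sqrt(v + 1.0)
            r = pool_random(ests(y, v), ci_method="hksj")
            tau2s[j] = r.tau2
            covered += r.ci[0] <= 0.77 <= r.ci[1]
        assert abs(tau2s.mean() - 1.0) < 0.10
        assert 0.93 <= covered / m <= 0.97


class TestPredictionInterval:
    def test_closed_form_half_width(self):
        r = pool_random(ests(np.linspace(-1, 3, 10), np.full(10, 0.5)))
        r.tau2, r.se_wald = 1.0, 0.3
        lo, hi = prediction_interval(r)
        half = stats.t.ppf(0.975, 8) * np.sqrt(1.09)
        assert (hi - lo) / 2 == pytest.approx(half, rel=1e-12)

    def test_matches_ci_when_tau2_zero_large_k(self):
        e = ests(np.full(60, 0.2) + np.linspace(-1e-9, 1e-9, 60),
                 np.full(60, 0.1))
        r = pool_random(e, ci_method="wald")
        assert r.tau2 == pytest.approx(0.0, abs=1e-12)
        # only the t_{58}-vs-z quantile gap (~4% of one SE) remains
        assert r.pi[0] == pytest.approx(r.ci[0], abs=0.05 * r.se)

    def test_two_studies_error(self):
        r = pool_random(ests([0.0, 1.0], [0.5, 0.5]))
        with pytest.raises(ValueError, match="3 studies"):
            prediction_interval(r)


class _Rec:
    def __init__(self, coef, cov):
        self.coef = np.asarray(coef, dtype=float)
        self.cov = np.asarray(cov, dtype=float)


class TestMultivariate:
    def test_diagonal_separability_matches_univariate(self):
        rng = np.random.default_rng(9)
        k = 8
        y1 = rng.normal(0.5, 0.4, k)
        y2 = rng.normal(-0.2, 0.3, k)
        v1 = rng.uniform(0.02, 0.1, k)
        v2 = rng.uniform(0.02, 0.1, k)
        recs = [_Rec([a, b], np.diag([va, vb]))
                for a, b, va, vb in zip(y1, y2, v1, v2)]
        mv = pool_multivariate(recs, tau_structure="diagonal")
        u1 = pool_random(ests(y1, v1), ci_method="wald")
        u2 = pool_random(ests(y2, v2), ci_method="wald")
        assert mv.coef[0] == pytest.approx(u1.gamma, abs=1e-6)
        assert mv.coef[1] == pytest.approx(u2.gamma, abs=1e-6)
        assert np.sqrt(mv.cov[0, 0]) == pytest.approx(u1.se, abs=1e-6)

    def test_single_component_reduces_to_univariate(self):
        rng = np.random.default_rng(10)
        y = rng.normal(0.3, 0.5, 6)
        v = rng.uniform(0.05, 0.2, 6)
        recs = [_Rec([a], [[b]]) for a, b in zip(y, v)]
        mv = pool_multivariate(recs, tau_structure="unstructured")
        u = pool_random(ests(y, v), ci_method="wald")
        assert mv.coef[0] == pytest.approx(u.gamma, abs=1e-6)
        assert mv.psi[0, 0] == pytest.approx(u.tau2, abs=1e-6)

    def test_missing_component_reduced_data_oracle(self):
        rng = np.random.default_rng(14)
        k = 6
        y1 = rng.normal(0.5, 0.3, k)
        y2 = rng.normal(-0.2, 0.3, k)
        v = 0.05
        recs = [_Rec([a, b], np.diag([v, v])) for a, b in zip(y1, y2)]
        # drop component 2 from the last trial
        recs[-1] = _Rec([y1[-1], np.nan],
                        np.array([[v, np.nan], [np.nan, np.nan]]))
        mv = pool_multivariate(recs, tau_structure="diagonal")
        u2 = pool_random(ests(y2[:-1], np.full(k - 1, v)), ci_method="wald")
        assert mv.coef[1] == pytest.approx(u2.gamma, abs=1e-5)

    def test_simulation_unbiased_and_reml_optimal(self):
        """Two-component truth with known between-study covariance: pooled
        estimates unbiased within MC error; the REML optimum beats the
        likelihood at the generating psi on nearly all replicates."""
        rng = np.random.default_rng(33)
        truth = np.array([0.4, -0.3])
        psi_true = np.array([[0.04, 0.012], [0.012, 0.02]])
        m = 300
        k = 8
        means = np.empty((m, 2))
        wins = 0
        from deftmeta.meta import _mv_reml_loglik

        for j in range(m):
            recs = []
            ys, covs, avails = [], [], []
            for i in range(k):
                S = np.diag(rng.uniform(0.01, 0.05, 2))
                mu = rng.multivariate_normal(truth, psi_true)
                yi = rng.multivariate_normal(mu, S)
                recs.append(_Rec(yi, S))
                ys.append(yi)
                covs.append(S)
                avails.append(np.array([0, 1]))
            mv = pool_multivariate(recs, tau_structure="unstructured")
            means[j] = mv.coef
            ll_true = _mv_reml_loglik(psi_true, ys, covs, avails, 2)
            wins += mv.loglik >= ll_true - 1e-8
        mc_se = means.std(axis=0) / np.sqrt(m)
        assert np.all(np.abs(means.mean(axis=0) - truth) < 3 * mc_se)
        assert wins / m >= 0.95

    def test_non_psd_within_covariance_fatal(self):
        recs = [_Rec([0.1, 0.2], [[0.05, 0.9], [0.9, 0.05]]),
                _Rec([0.0, 0.1], np.diag([0.05, 0.05])),
                _Rec([0.2, 0.3], np.diag([0.05, 0.05]))]
        with pytest.raises(ValueError, match="not PSD"):
            pool_multivariate(recs)

    def test_component_in_fewer_than_two_trials(self):
        recs = [_Rec([0.1, np.nan], np.diag([0.05, np.nan])),
                _Rec([0.0, np.nan], np.diag([0.05, np.nan]))]
        with pytest.raises(ValueError, match="fewer than 2"):
            pool_multivariate(recs)
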