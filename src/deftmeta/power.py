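"""Power to detect a treatment-covariate interaction in a planned IPD
meta-analysis.

Before IPD collection, the variance of each trial's interaction
estimate for a continuous outcome follows from published trial
characteristics: with equal-sized arms and equal per-arm covariate
variance,

    var(gamma_hat_Wi) = 4 sigma_i^2 / (n_i sigma_zi^2),

and in general 4 sigma_i^2 / (sum of squared centered covariate
values).  The common-effect summary variance is the reciprocal of the
summed inverse trial variances, and the two-sided power at significance
threshold z is

    Phi(-z + |gamma_W|/sqrt(var)) + Phi(-z - |gamma_W|/sqrt(var)).

The closed form assumes no between-study heterogeneity in the
interaction; heterogeneity scenarios (and non-continuous outcomes) are
handled by the simulation-based calculator, which generates IPD per the
planning table, runs the two-stage analysis, and counts rejections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import meta as _meta
from .first_stage import TrialEstimate

__all__ = [
    "PowerSpec",
    "trial_interaction_variance",
    "summary_variance",
    "power_closed_form",
    "power_from_spec",
    "power_simulation",
]


@dataclass
class PowerSpec:
    """Per-trial planning characteristics plus the assumed interaction.

    ``table`` columns: ``trial``, ``n`` (and optionally ``n_treat``,
    ``n_control``), ``sigma2`` (residual -- or, as a proxy, total --
    outcome variance), ``sigma2_z`` (covariate variance), and, for
    simulation only, ``mean_z``.  Missing ``sigma2``/``sigma2_z``
    entries are imputed by the n-weighted average of the other trials.
    """

    table: pd.DataFrame
    gamma_w: float
    z_crit: float = 1.96
    tau2: float = 0.0

    def __post_init__(self):
        t = self.table.copy()
        for col in ("n", "sigma2", "sigma2_z"):
            if col not in t.columns:
                raise ValueError(f"planning table must have a {col!r} column")
        if (t["n"] < 2).any():
            raise ValueError("every trial needs n >= 2")
        for col in ("sigma2", "sigma2_z"):
            miss = t[col].isna()
            if miss.all():
                raise ValueError(f"no usable values in column {col!r}")
            if miss.any():
                avg = np.average(t.loc[~miss, col], weights=t.loc[~miss, "n"])
                t.loc[miss, col] = avg
            if (t[col] <= 0).any():
                raise ValueError(f"column {col!r} must be positive")
        if "n_treat" in t.columns and "n_control" in t.columns:
            ok = t["n_treat"] + t["n_control"] == t["n"]
            if not ok.all():
                raise ValueError("n_treat + n_control must equal n")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        self.table = t

    @classmethod
    def from_csv(cls, path, gamma_w: float, **kwargs) -> "PowerSpec":
        """Read the planning-table CSV (columns trial, n, n_treat,
        n_control, sd_outcome_or_residual, sd_covariate, mean_covariate)."""
        raw = pd.read_csv(path)
        t = pd.DataFrame({"trial": raw["trial"], "n": raw["n"]})
        for src, dst in (("n_treat", "n_treat"), ("n_control", "n_control"),
                         ("mean_covariate", "mean_z")):
            if src in raw.columns:
                t[dst] = raw[src]
        t["sigma2"] = raw["sd_outcome_or_residual"] ** 2
        t["sigma2_z"] = raw["sd_covariate"] ** 2
        return cls(t, gamma_w, **kwargs)


def trial_interaction_variance(n: int | None = None, sigma2: float = None,
                               sigma2_z: float | None = None,
                               ss_treat: float | None = None,
                               ss_control: float | None = None) -> float:
    """Variance of one trial's interaction estimate (continuous outcome).

    Balanced path (``n`` and ``sigma2_z``): 4 sigma^2 / (n sigma_z^2).
    Unbalanced path (per-arm sums of squared covariate deviations about
    the *trial* mean): 4 sigma^2 (ssT + ssC) / (ssT + ssC)^2, which
    reduces exactly to the balanced formula when ssT = ssC = n sigma_z^2 / 2.

    A zero covariate variance yields ``inf``: the trial contributes no
    interaction information.
    """
    if sigma2 is None or sigma2 <= 0:
        raise ValueError("sigma2 must be a positive residual (or proxy) variance")
    if ss_treat is not None or ss_control is not None:
        if ss_treat is None or ss_control is None:
            raise ValueError("the unbalanced path needs both ss_treat and ss_control")
        total = ss_treat + ss_control
        if total <= 0:
            return np.inf
        return float(4.0 * sigma2 * total / total**2)
    if n is None or sigma2_z is None:
        raise ValueError("the balanced path needs n and sigma2_z")
    if sigma2_z <= 0:
        return np.inf
    return float(4.0 * sigma2 / (n * sigma2_z))


def summary_variance(variances) -> float:
    """Common-effect summary variance: reciprocal of the summed inverse
    trial variances.  Non-finite entries contribute zero weight."""
    v = np.asarray(list(variances), dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("no finite trial variances; summary variance undefined")
    if np.any(v[finite] <= 0):
        raise ValueError("trial variances must be positive")
    return float(1.0 / np.sum(1.0 / v[finite]))


def power_closed_form(gamma_w: float, var: float, z_crit: float = 1.96) -> float:
    """Two-sided power Phi(-z + |g|/sqrt(var)) + Phi(-z - |g|/sqrt(var));
    symmetric in the sign of gamma_w; equals the type-I error 2*Phi(-z)
    at gamma_w = 0."""
    if var <= 0:
        raise ValueError("var must be positive")
    shift = abs(gamma_w) / np.sqrt(var)
    return float(stats.norm.cdf(-z_crit + shift) + stats.norm.cdf(-z_crit - shift))


def power_from_spec(spec: PowerSpec) -> dict:
    """Closed-form power for a planning table (no heterogeneity assumed)."""
    per_trial = [
        trial_interaction_variance(n=int(r["n"]), sigma2=float(r["sigma2"]),
                                   sigma2_z=float(r["sigma2_z"]))
        for _, r in spec.table.iterrows()
    ]
    var = summary_variance(per_trial)
    return {
        "per_trial_variance": per_trial,
        "summary_variance": var,
        "power": power_closed_form(spec.gamma_w, var, spec.z_crit),
    }


# ----------------------------------------------------------------------
# simulation


def _fast_trial_fit(y, x, z):
    """OLS interaction fit on [1, z, x, x*(z - zbar)]; returns
    (gamma_hat, var_gamma).  Matches fit_trial_linear without adjusters."""
    zc = z - z.mean()
    X = np.column_stack([np.ones_like(y), zc, x, x * zc])
    XtX = X.T @ X
    Xty = X.T @ y
    beta = np.linalg.solve(XtX, Xty)
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - X.shape[1])
    var = s2 * np.linalg.inv(XtX)[3, 3]
    return float(beta[3]), float(var)


def power_simulation(spec: PowerSpec, m: int = 1000, seed: int = 0,
                     pool: str = "common", ci_method: str = "wald",
                     level: float = 0.95) -> dict:
    """Simulation-based power: generate IPD matching the planning table,
    run the two-stage analysis, and report the rejection proportion.

    Per replicate and per trial, covariates are drawn N(mean_z,
    sigma_z), arms split as specified (1:1 when arm sizes are absent),
    per-trial interactions drawn N(gamma_w, tau2), and Gaussian outcomes
    generated with the table's residual variance; the first stage is the
    trial-wise interaction regression and the second stage the requested
    pooling, with significance judged by the CI method the analysis
    plan uses.  ``m >= 100`` replicates; repeatable under a fixed seed.
    """
    if m < 100:
        raise ValueError("use at least 100 replicates")
    if pool not in ("common", "random"):
        raise ValueError("pool must be 'common' or 'random'")
    t = spec.table
    if "mean_z" not in t.columns:
        raise ValueError("simulation needs a mean_z column in the planning table")
    rng = np.random.default_rng(seed)
    rows = list(t.itertuples(index=False))
    rejections = 0
    failures = 0
    tau = np.sqrt(spec.tau2)
    for _ in range(m):
        ests = []
        try:
            for r in rows:
                n = int(r.n)
                n_treat = int(getattr(r, "n_treat", n // 2) or n // 2)
                z = rng.normal(float(r.mean_z), np.sqrt(float(r.sigma2_z)), size=n)
                x = np.zeros(n)
                x[rng.permutation(n)[:n_treat]] = 1.0
                g_i = spec.gamma_w + (tau * rng.standard_normal() if tau > 0 else 0.0)
                y = x * g_i * (z - z.mean()) + rng.normal(
                    0.0, np.sqrt(float(r.sigma2)), size=n)
                gamma, var = _fast_trial_fit(y, x, z)
                ests.append(TrialEstimate(r.trial, gamma, var, n=n))
            if pool == "common":
                res = _meta.pool_common(ests, level=level)
            else:
                res = _meta.pool_random(ests, ci_method=ci_method, level=level)
        except (np.linalg.LinAlgError, ValueError):
            failures += 1
            continue
        if res.ci[0] > 0 or res.ci[1] < 0:
            rejections += 1
    n_ok = m - failures
    if failures > 0.05 * m:
        import warnings

        warnings.warn(f"{failures}/{m} replicates failed to fit", stacklevel=2)
    p = rejections / n_ok
    return {
        "power": p,
        "mc_se": float(np.sqrt(p * (1 - p) / n_ok)),
        "replicates": n_ok,
        "failures": failures,
    }
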