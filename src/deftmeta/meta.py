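"""Second-stage pooling of per-trial interaction estimates.

Univariate common-effect and random-effects (REML or DerSimonian-Laird)
inverse-variance meta-analysis with Hartung-Knapp-Sidik-Jonkman (HKSJ)
confidence intervals and Higgins-style prediction intervals, plus a
multivariate random-effects meta-analysis for vectors of correlated
per-trial coefficients (e.g. spline-interaction slopes), estimated by
REML with trials contributing only their observed subvector when some
components are inestimable in that trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .first_stage import TrialEstimate, TrialSplineEstimate

__all__ = [
    "MetaResult",
    "MultiMetaResult",
    "pool_common",
    "pool_random",
    "prediction_interval",
    "pool_multivariate",
    "reml_loglik_uni",
]


@dataclass
class MetaResult:
    """Pooled interaction with heterogeneity and interval estimates.

    ``se`` is the standard error backing ``ci`` (the HKSJ-rescaled one
    when ``ci_method='hksj'``); ``se_wald`` is always the plain
    inverse-variance standard error.
    """

    gamma: float
    se: float
    tau2: float
    ci: tuple[float, float]
    k: int
    method: str  # 'common' | 'random_reml' | 'random_dl'
    ci_method: str = "wald"  # 'wald' | 'hksj'
    level: float = 0.95
    pi: tuple[float, float] | None = None
    se_wald: float = 0.0
    scale: str = "mean_difference"

    @property
    def var(self) -> float:
        return self.se**2


@dataclass
class MultiMetaResult:
    """Pooled coefficient vector with pooled and between-study covariance."""

    names: list[str]
    coef: np.ndarray
    cov: np.ndarray  # covariance of the pooled coefficients
    psi: np.ndarray  # between-study covariance estimate
    k: int
    converged: bool = True
    loglik: float = np.nan
    log: list[str] = field(default_factory=list)


def _check_estimates(estimates) -> tuple[np.ndarray, np.ndarray, str]:
    if len(estimates) == 0:
        raise ValueError("no estimates to pool")
    scales = {e.scale for e in estimates}
    if len(scales) > 1:
        raise ValueError(
            f"estimates are on mixed scales {sorted(scales)}; cannot pool"
        )
    y = np.array([e.gamma for e in estimates], dtype=float)
    v = np.array([e.var_gamma for e in estimates], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all within-trial variances must be positive")
    return y, v, scales.pop()


def _pooled(y, v, tau2):
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    var = float(1.0 / np.sum(w))
    return mu, var, w


def pool_common(estimates, level: float = 0.95) -> MetaResult:
    """Common-effect (fixed-effect) inverse-variance pooling.

    The pooled variance is the reciprocal of the summed inverse
    within-trial variances.
    """
    y, v, scale = _check_estimates(estimates)
    mu, var, _ = _pooled(y, v, 0.0)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + level / 2)
    return MetaResult(
        mu, se, 0.0, (mu - z * se, mu + z * se), k=len(y),
        method="common", ci_method="wald", level=level, se_wald=se, scale=scale,
    )


def reml_loglik_uni(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of the univariate random-effects model
    (up to a constant); the objective behind the REML tau^2 estimate."""
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return float(
        -0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                + np.sum(w * (y - mu) ** 2))
    )


def _tau2_reml(y, v) -> float:
    upper = max(1e-6, 10.0 * float(np.var(y)) + 10.0 * float(np.max(v)))
    res = optimize.minimize_scalar(
        lambda t2: -reml_loglik_uni(t2, y, v),
        bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-12, "maxiter": 500},
    )
    t2 = float(res.x)
    # keep the boundary exactly when it is at least as good
    if -res.fun <= reml_loglik_uni(0.0, y, v) + 1e-12:
        t2 = 0.0
    return t2


def _tau2_dl(y, v) -> float:
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    return max(0.0, (q - (len(y) - 1)) / c) if c > 0 else 0.0


def pool_random(estimates, tau2_method: str = "reml", ci_method: str = "hksj",
                level: float = 0.95, truncate_hksj: bool = False) -> MetaResult:
    """Random-effects pooling of per-trial interaction estimates.

    tau^2 is estimated by REML (default) or DerSimonian-Laird, floored
    at zero; the pooled estimate uses weights 1/(v_i + tau^2).  The HKSJ
    interval rescales the pooled variance by the weighted residual sum
    of squares over k-1 and uses t-quantiles with k-1 degrees of
    freedom (no truncation of the scale factor by default).  A 95%
    prediction interval is attached when k >= 3.
    """
    y, v, scale = _check_estimates(estimates)
    k = len(y)
    if k < 2:
        raise ValueError(
            "random-effects pooling needs >= 2 estimates; use pool_common"
        )
    if tau2_method == "reml":
        tau2 = _tau2_reml(y, v)
        method = "random_reml"
    elif tau2_method == "dl":
        tau2 = _tau2_dl(y, v)
        method = "random_dl"
    else:
        raise ValueError(f"tau2_method must be 'reml' or 'dl', got {tau2_method!r}")

    mu, var, w = _pooled(y, v, tau2)
    se_wald = float(np.sqrt(var))
    if ci_method == "wald":
        crit = stats.norm.ppf(0.5 + level / 2)
        se = se_wald
    elif ci_method == "hksj":
        q = float(np.sum(w * (y - mu) ** 2)) / (k - 1)
        if truncate_hksj:
            q = max(q, 1.0)
        se = float(np.sqrt(q * var))
        crit = stats.t.ppf(0.5 + level / 2, df=k - 1)
    else:
        raise ValueError(f"ci_method must be 'wald' or 'hksj', got {ci_method!r}")
    result = MetaResult(
        mu, se, tau2, (mu - crit * se, mu + crit * se), k=k,
        method=method, ci_method=ci_method, level=level,
        se_wald=se_wald, scale=scale,
    )
    if k >= 3:
        result.pi = prediction_interval(result)
    return result


def prediction_interval(result: MetaResult, level: float = 0.95):
    """Interval expected to contain the true interaction in a new trial:
    gamma +/- t_{k-2} * sqrt(tau^2 + se_wald^2)."""
    if result.k < 3:
        raise ValueError("a prediction interval needs at least 3 studies")
    half = stats.t.ppf(0.5 + level / 2, df=result.k - 2) * np.sqrt(
        result.tau2 + result.se_wald**2
    )
    return (result.gamma - half, result.gamma + half)


# ----------------------------------------------------------------------
# multivariate random-effects meta-analysis


def _mv_structure(p: int, structure: str):
    """Map an unconstrained parameter vector to a PSD between-study
    covariance Psi."""
    if structure == "unstructured":
        n_par = p * (p + 1) // 2
        tril = np.tril_indices(p)

        def build(theta):
            L = np.zeros((p, p))
            L[tril] = theta
            return L @ L.T

    elif structure == "diagonal":
        n_par = p

        def build(theta):
            return np.diag(np.asarray(theta) ** 2)

    elif structure == "zero":
        n_par = 0

        def build(theta):
            return np.zeros((p, p))

    else:
        raise ValueError(
            "tau_structure must be 'unstructured', 'diagonal' or 'zero', "
            f"got {structure!r}"
        )
    return n_par, build


def _mv_reml_loglik(psi, ys, covs, avails, p):
    """Restricted log-likelihood using each trial's observed subvector."""
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    parts = []
    for y, S, a in zip(ys, covs, avails):
        V = S + psi[np.ix_(a, a)]
        try:
            c, low = np.linalg.cholesky(V), True
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = np.linalg.inv(V)
        X = np.zeros((len(a), p))
        X[np.arange(len(a)), a] = 1.0
        XtVX += X.T @ Vinv @ X
        XtVy += X.T @ Vinv @ y
        parts.append((y, Vinv, X, logdet))
    sign, logdet_fisher = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    mu = np.linalg.solve(XtVX, XtVy)
    ll = -0.5 * logdet_fisher
    for y, Vinv, X, logdet in parts:
        r = y - X @ mu
        ll += -0.5 * (logdet + r @ Vinv @ r)
    return float(ll)


def pool_multivariate(estimates, include_reference: bool = True,
                      tau_structure: str = "unstructured") -> MultiMetaResult:
    """Multivariate REML pooling of per-trial spline-interaction vectors.

    Each trial contributes its observed components (beta2 plus the
    available interaction slopes) and their joint within-trial
    covariance; components masked in a trial enter through the marginal
    likelihood of the observed subvector.  ``include_reference=False``
    pools the interaction slopes alone, so they borrow no information
    through their correlation with the per-trial reference treatment
    effects -- the aggregation-bias-free pooling used for de-biased
    individualized predictions.

    Accepts TrialSplineEstimate objects or generic records with
    ``coef`` (NaN for missing components) and ``cov`` attributes.
    """
    if len(estimates) < 2:
        raise ValueError("multivariate pooling needs >= 2 trials")
    ys_full, covs_full = [], []
    for e in estimates:
        if isinstance(e, TrialSplineEstimate):
            vec = np.concatenate(([e.beta2], e.gammas))
            cov = np.asarray(e.cov, dtype=float)
        else:
            vec = np.asarray(e.coef, dtype=float)
            cov = np.asarray(e.cov, dtype=float)
        if not include_reference and isinstance(e, TrialSplineEstimate):
            vec, cov = vec[1:], cov[1:, 1:]
        ys_full.append(vec)
        covs_full.append(cov)
    p = len(ys_full[0])
    if any(len(y) != p for y in ys_full):
        raise ValueError("all trials must supply vectors of the same length")

    names = (["beta2"] if include_reference and isinstance(estimates[0], TrialSplineEstimate)
             else [])
    m = p - len(names)
    names = names + [f"gamma_w{j + 1}" for j in range(m)]

    ys, covs, avails = [], [], []
    observed_count = np.zeros(p, dtype=int)
    log = []
    for tid_idx, (vec, cov) in enumerate(zip(ys_full, covs_full)):
        a = np.where(np.isfinite(vec))[0]
        if len(a) == 0:
            log.append(f"trial index {tid_idx}: no observed components, skipped")
            continue
        sub = cov[np.ix_(a, a)]
        if not np.all(np.isfinite(sub)):
            raise ValueError(
                f"trial index {tid_idx}: within-trial covariance has missing "
                "entries on observed components"
            )
        eigmin = np.min(np.linalg.eigvalsh((sub + sub.T) / 2))
        if eigmin < -1e-8 * max(1.0, np.max(np.abs(sub))):
            raise ValueError(
                f"trial index {tid_idx}: within-trial covariance is not PSD "
                f"(min eigenvalue {eigmin:.3g}); check the first-stage fit or "
                "supply a repaired (e.g. nearest-PSD) matrix"
            )
        observed_count[a] += 1
        ys.append(vec[a])
        covs.append(sub)
        avails.append(a)
    short = [names[j] for j in range(p) if observed_count[j] < 2]
    if short:
        raise ValueError(
            f"components {short} observed in fewer than 2 trials; inestimable"
        )

    n_par, build = _mv_structure(p, tau_structure)
    # start from component-wise univariate REML tau
    start_sd = []
    for j in range(p):
        yj = np.array([y[list(a).index(j)] for y, a in zip(ys, avails) if j in a])
        vj = np.array([S[list(a).index(j), list(a).index(j)]
                       for S, a in zip(covs, avails) if j in a])
        start_sd.append(np.sqrt(_tau2_reml(yj, vj)) if len(yj) >= 2 else 0.0)
    if tau_structure == "unstructured":
        theta0 = np.zeros(n_par)
        L0 = np.diag(np.maximum(start_sd, 1e-4))
        theta0 = L0[np.tril_indices(p)]
    elif tau_structure == "diagonal":
        theta0 = np.maximum(start_sd, 1e-4)
    else:
        theta0 = np.zeros(0)

    def nll(theta):
        return -_mv_reml_loglik(build(theta), ys, covs, avails, p)

    if n_par:
        res = optimize.minimize(
            nll, theta0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000,
                     "maxfev": 20000},
        )
        psi = build(res.x)
        converged = bool(res.success)
        loglik = -float(res.fun)
        log.append(f"REML optimizer: {res.message} ({res.nfev} evaluations)")
    else:
        psi = build(theta0)
        converged, loglik = True, -nll(theta0)

    # pooled vector and covariance at the REML psi
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    for y, S, a in zip(ys, covs, avails):
        V = S + psi[np.ix_(a, a)]
        Vinv = np.linalg.inv(V)
        X = np.zeros((len(a), p))
        X[np.arange(len(a)), a] = 1.0
        XtVX += X.T @ Vinv @ X
        XtVy += X.T @ Vinv @ y
    pooled_cov = np.linalg.inv(XtVX)
    coef = pooled_cov @ XtVy
    return MultiMetaResult(
        names, coef, (pooled_cov + pooled_cov.T) / 2, psi, k=len(ys),
        converged=converged, loglik=loglik, log=log,
    )


def result_to_dict(result: MetaResult) -> dict:
    """JSON-ready summary of a pooled result."""
    return {
        "estimate": result.gamma,
        "se": result.se,
        "tau2": result.tau2,
        "ci": list(result.ci),
        "pi": list(result.pi) if result.pi is not None else None,
        "k": result.k,
        "method": result.method,
        "ci_method": result.ci_method,
        "scale": result.scale,
    }
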