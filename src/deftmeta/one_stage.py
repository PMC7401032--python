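"""One-stage IPD meta-analysis models for treatment-covariate interactions.

Three specifications are provided for continuous (and, except the
deluded model, binary) outcomes:

* ``centered``  -- "deft" approach (i): the covariate is centered at its
  study-specific mean inside the interaction term, and a meta-regression
  component phi + gamma_A * zbar_i with a random treatment effect
  (variance tau1^2) explains between-study variation in the treatment
  effect; the random interaction slope has mean gamma_W and variance
  tau2^2.  gamma_W and gamma_A are thereby disentangled: gamma_W uses
  only within-trial information, gamma_A carries the across-trial trend.
* ``stratified`` -- "deft" approach (ii): every nuisance parameter
  (intercept, covariate and adjuster effects, and the treatment effect
  at the reference) is a separate fixed effect per trial; the only
  random effect is the interaction slope (variance tau^2).
* ``deluded``   -- the flawed amalgamated model: an uncentered
  treatment-by-covariate product with no covariate-mean meta-regression,
  so the interaction estimate is a weighted average of the within-trial
  interaction and the across-trial trend.  Provided for diagnostics
  only and labeled as such.

Continuous outcomes are fitted by REML with a solver written for the
per-trial block covariance sigma^2 I + sum_c tau_c^2 g_ic g_ic'
(rank <= 2 per trial), which also exposes the profile restricted
likelihood needed for Satterthwaite degrees of freedom.  Binary
outcomes are fitted by maximum likelihood with per-trial adaptive
Gauss-Hermite quadrature over the (independent) random effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import IPDDataset

__all__ = [
    "OneStageResult",
    "fit_onestage_centered",
    "fit_onestage_stratified",
    "fit_onestage_deluded",
    "satterthwaite_interval",
]

DELUDED_LABEL = (
    "diagnostic-only: amalgamates within-trial and across-trial information; "
    "not a valid participant-level interaction estimate"
)


@dataclass
class OneStageResult:
    """Fitted one-stage interaction model.

    ``gamma`` is gamma_W for the deft approaches and gamma_WA for the
    deluded model (``diagnostic_only`` is then True).
    """

    gamma: float
    se: float
    ci: tuple[float, float]
    tau2_interaction: float
    approach: str  # 'centered_metareg' | 'stratified' | 'deluded'
    outcome_type: str
    k: int
    ci_method: str = "wald"
    level: float = 0.95
    phi: float | None = None
    gamma_a: float | None = None
    tau2_treatment: float | None = None
    sigma2: pd.Series | None = None  # trial-specific residual variances
    df: float | None = None
    nuisance: pd.Series | None = None
    converged: bool = True
    diagnostic_only: bool = False
    note: str = ""
    # handles for Satterthwaite (continuous fits only)
    _satt: dict | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "estimate": self.gamma,
            "se": self.se,
            "ci": list(self.ci),
            "tau2": self.tau2_interaction,
            "k": self.k,
            "method": "onestage_" + self.approach,
            "ci_method": self.ci_method,
        }
        if self.phi is not None:
            d["phi"] = self.phi
        if self.gamma_a is not None:
            d["gamma_a"] = self.gamma_a
        if self.diagnostic_only:
            d["warning"] = DELUDED_LABEL
        return d


# ----------------------------------------------------------------------
# design construction


def _blocks(ds: IPDDataset, covariate: str, adjusters, approach: str):
    """Per-trial outcome vector, fixed-effect matrix and random-effect
    columns for the requested one-stage specification.

    Prognostic nuisance columns (covariate main effect, adjusters) are
    stratified by trial and centered at trial means for conditioning;
    this changes only the interpretation of the nuisance parameters.
    """
    trials = ds.trials
    S = len(trials)
    if S < 2:
        raise ValueError("a one-stage model needs at least 2 trials")

    use_cols = ["y", "arm", covariate, *adjusters]
    frames = []
    for tid in trials:
        g = ds.trial_data(tid).dropna(subset=[c for c in use_cols if c in ds.df.columns])
        frames.append(g)
    n_varying = sum(
        1 for g in frames if g[covariate].nunique() > 1
    )
    if n_varying < 2:
        raise ValueError(
            f"covariate {covariate!r} varies within fewer than 2 trials; "
            "no poolable within-trial interaction information"
        )

    zbar = {tid: float(g[covariate].mean()) for tid, g in zip(trials, frames)}

    names: list[str] = []
    for tid in trials:
        names.append(f"alpha[{tid}]")
    for tid in trials:
        names.append(f"b_z[{tid}]")
    for a in adjusters:
        for tid in trials:
            names.append(f"b_{a}[{tid}]")
    if approach == "centered":
        names += ["phi", "gamma_a", "gamma_w"]
    elif approach == "stratified":
        names += [f"beta2[{tid}]" for tid in trials] + ["gamma_w"]
    elif approach == "deluded":
        names += ["beta2", "gamma_wa"]
    else:
        raise ValueError(f"unknown approach {approach!r}")
    p = len(names)
    col = {nm: j for j, nm in enumerate(names)}

    ys, Xs, Gs = [], [], []
    for tid, g in zip(trials, frames):
        n = len(g)
        z = g[covariate].to_numpy(dtype=float)
        x = g["arm"].to_numpy(dtype=float)
        zc = z - zbar[tid]
        X = np.zeros((n, p))
        X[:, col[f"alpha[{tid}]"]] = 1.0
        X[:, col[f"b_z[{tid}]"]] = zc
        for a in adjusters:
            av = g[a].to_numpy(dtype=float)
            X[:, col[f"b_{a}[{tid}]"]] = av - av.mean()
        if approach == "centered":
            X[:, col["phi"]] = x
            X[:, col["gamma_a"]] = x * zbar[tid]
            X[:, col["gamma_w"]] = x * zc
            G = [x, x * zc]  # treatment effect, interaction slope
        elif approach == "stratified":
            X[:, col[f"beta2[{tid}]"]] = x
            X[:, col["gamma_w"]] = x * zc
            G = [x * zc]
        else:  # deluded: uncentered product, no mean meta-regression
            X[:, col["beta2"]] = x
            X[:, col["gamma_wa"]] = x * z
            G = [x, x * z]
        ys.append(g["y"].to_numpy(dtype=float))
        Xs.append(X)
        Gs.append(G)

    gamma_name = {"centered": "gamma_w", "stratified": "gamma_w",
                  "deluded": "gamma_wa"}[approach]

    # drop identically-zero fixed columns (e.g. the stratified covariate
    # effect of a trial whose covariate is constant)
    Xall = np.concatenate(Xs)
    keep = np.where(np.max(np.abs(Xall), axis=0) > 1e-12)[0]
    if len(keep) < p:
        if col[gamma_name] not in keep:
            raise ValueError(
                f"covariate {covariate!r} carries no within-trial interaction "
                "information in any trial"
            )
        names = [names[j] for j in keep]
        Xs = [X[:, keep] for X in Xs]
        col = {nm: j for j, nm in enumerate(names)}
    return ys, Xs, Gs, names, col[gamma_name], col, trials


# ----------------------------------------------------------------------
# continuous: block-structured REML


class _LMMBlocks:
    """Precomputed per-trial sufficient statistics for the block REML
    likelihood with trial-specific residual variances.

    Each trial's marginal covariance is
    V_i = sigma_i^2 I + sum_c tau_c^2 g_ic g_ic' (rank <= 2), so every
    likelihood evaluation needs only the small matrices M_i'M_i,
    U_i'M_i and U_i'U_i where M_i = [X_i, y_i]; the random-effect
    columns are pre-scaled to unit RMS so the variance parameters are
    on comparable scales.
    """

    def __init__(self, ys, Xs, Gs, p, common_sigma: bool = False):
        self.p = p
        self.S = len(ys)
        self.C = len(Gs[0])
        self.common_sigma = common_sigma
        self.n_sigma = 1 if common_sigma else self.S
        self.scales = []
        for c in range(self.C):
            ss = np.sqrt(np.mean(np.concatenate([G[c] for G in Gs]) ** 2))
            self.scales.append(ss if ss > 0 else 1.0)
        self.blocks = []
        for y, X, G in zip(ys, Xs, Gs):
            M = np.concatenate([X, y[:, None]], axis=1)
            U = np.column_stack([G[c] / self.scales[c] for c in range(self.C)]) \
                if self.C else np.zeros((len(y), 0))
            self.blocks.append(
                (len(y), M.T @ M, U.T @ M, U.T @ U)
            )

    def quantities(self, theta):
        """theta = (sigma2_1..sigma2_S, tau2_1..tau2_C); returns
        (restricted loglik, cov(beta), beta)."""
        theta = np.asarray(theta, dtype=float)
        s2 = theta[: self.n_sigma]
        taus = theta[self.n_sigma:]
        if np.any(s2 <= 0) or np.any(taus < 0):
            return -np.inf, None, None
        p = self.p
        active = np.where(taus > 1e-12)[0]
        Ctot = np.zeros((p + 1, p + 1))
        logdetV = 0.0
        for i, (n, T, UtM, UtU) in enumerate(self.blocks):
            s2i = s2[0] if self.common_sigma else s2[i]
            if len(active) == 0:
                Ctot += T / s2i
                logdetV += n * np.log(s2i)
                continue
            d = taus[active]
            K = np.diag(s2i / d) + UtU[np.ix_(active, active)]
            sign, logdetK = np.linalg.slogdet(K)
            if sign <= 0:
                return -np.inf, None, None
            Ua = UtM[active]
            Ctot += (T - Ua.T @ np.linalg.solve(K, Ua)) / s2i
            logdetV += ((n - len(d)) * np.log(s2i) + np.sum(np.log(d))
                        + logdetK)
        A = Ctot[:p, :p]
        b = Ctot[:p, p]
        yVy = Ctot[p, p]
        try:
            cho = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        beta = np.linalg.solve(A, b)
        rVr = yVy - b @ beta
        logdetA = 2.0 * np.sum(np.log(np.diag(cho)))
        ll = -0.5 * (logdetV + rVr + logdetA)
        if not np.isfinite(ll):
            return -np.inf, None, None
        return float(ll), np.linalg.inv(A), beta


def _fit_lmm(ys, Xs, Gs, p, gamma_idx, common_sigma: bool = False):
    """REML fit over (sigma_i^2 per trial or shared, tau_c^2 per random
    component)."""
    bl = _LMMBlocks(ys, Xs, Gs, p, common_sigma=common_sigma)
    S, C = bl.n_sigma, bl.C

    # starting values: per-trial residual variance about the global OLS fit
    _, _, beta0 = bl.quantities(np.concatenate([np.ones(S), np.zeros(C)]))
    resid = [y - X @ beta0 for y, X in zip(ys, Xs)]
    if common_sigma:
        rss = sum(float(r @ r) for r in resid)
        ntot = sum(len(y) for y in ys)
        s2_0 = np.array([max(rss / max(ntot - p, 1), 1e-8)])
    else:
        s2_0 = np.array([max(float(r @ r) / max(len(r) - 2, 1), 1e-8)
                         for r in resid])

    def nll_sq(t):  # square-root parameterization: always feasible
        ll, _, _ = bl.quantities(np.asarray(t, dtype=float) ** 2)
        return -ll

    t0 = np.sqrt(np.concatenate([s2_0, np.full(C, 0.1 * np.mean(s2_0))]))
    res = optimize.minimize(
        nll_sq, t0, method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-9},
    )
    best = res
    if not res.success or not np.isfinite(res.fun):
        res2 = optimize.minimize(  # derivative-free fallback
            nll_sq, res.x if np.isfinite(res.fun) else t0,
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxfev": 5000},
        )
        if res2.fun <= res.fun:
            best = res2
    theta = best.x**2
    # snap tiny variance components to the boundary
    floor = 1e-10 * np.mean(theta[:S])
    theta[S:][theta[S:] < floor] = 0.0
    ll, Ainv, beta = bl.quantities(theta)

    def profile_ll(th):
        v, _, _ = bl.quantities(th)
        return v

    def var_gamma(th):
        _, Ai, _ = bl.quantities(th)
        return np.inf if Ai is None else float(Ai[gamma_idx, gamma_idx])

    satt = {"theta": theta, "n_sigma": S, "profile_ll": profile_ll,
            "var_gamma": var_gamma}
    tau2 = theta[S:] / np.asarray(bl.scales) ** 2 if C else np.zeros(0)
    return theta[:S], tau2, ll, beta, Ainv, bool(best.success or res.success), satt


def _fit_continuous(ds, covariate, adjusters, approach, ci_method, level,
                    residual_variances: str = "per_trial"):
    if residual_variances not in ("per_trial", "common"):
        raise ValueError(
            "residual_variances must be 'per_trial' or 'common', "
            f"got {residual_variances!r}"
        )
    ys, Xs, Gs, names, gidx, col, trials = _blocks(ds, covariate, adjusters,
                                                   approach)
    p = len(names)
    sigma2s, tau2, ll, beta, Ainv, ok, satt = _fit_lmm(
        ys, Xs, Gs, p, gidx, common_sigma=(residual_variances == "common"))
    gamma = float(beta[gidx])
    se = float(np.sqrt(Ainv[gidx, gidx]))

    if approach == "centered":
        tau2_treat, tau2_int = float(tau2[0]), float(tau2[1])
        phi = float(beta[col["phi"]])
        gamma_a = float(beta[col["gamma_a"]])
    elif approach == "stratified":
        tau2_treat, tau2_int = None, float(tau2[0])
        phi = gamma_a = None
    else:
        tau2_treat, tau2_int = float(tau2[0]), float(tau2[1])
        phi = float(beta[col["beta2"]])
        gamma_a = None

    result = OneStageResult(
        gamma, se, (np.nan, np.nan), tau2_int,
        approach=("centered_metareg" if approach == "centered" else approach),
        outcome_type="continuous", k=len(trials), ci_method=ci_method,
        level=level, phi=phi, gamma_a=gamma_a, tau2_treatment=tau2_treat,
        sigma2=pd.Series(sigma2s, index=([str(t) for t in trials]
                                         if len(sigma2s) == len(trials)
                                         else ["common"])),
        nuisance=pd.Series(beta, index=names),
        converged=ok, diagnostic_only=(approach == "deluded"),
        note=DELUDED_LABEL if approach == "deluded" else "",
        _satt=satt,
    )
    if ci_method == "wald":
        z = stats.norm.ppf(0.5 + level / 2)
        result.ci = (gamma - z * se, gamma + z * se)
    elif ci_method == "satterthwaite":
        result.ci = satterthwaite_interval(result, level)
    else:
        raise ValueError(f"ci_method must be 'wald' or 'satterthwaite', got {ci_method!r}")
    return result


def satterthwaite_interval(result: OneStageResult, level: float = 0.95):
    """t-interval for the interaction with Satterthwaite-approximated
    denominator degrees of freedom.

    df = 2 f^2 / (g' H^-1 g) with f(theta) = var(gamma_hat | theta),
    g its gradient over the variance components and H the observed
    information of the restricted likelihood; variance components on
    the boundary are held fixed.  Continuous-outcome fits only.
    """
    if result.outcome_type != "continuous" or result._satt is None:
        raise ValueError(
            "Satterthwaite intervals are available for continuous-outcome "
            "one-stage fits only"
        )
    satt = result._satt
    theta = np.asarray(satt["theta"], dtype=float)
    f0 = satt["var_gamma"](theta)
    n_sigma = satt["n_sigma"]
    scale = float(np.mean(theta[:n_sigma]))
    # residual variances are always interior; tau components on the
    # boundary are held fixed
    free = [j for j in range(len(theta))
            if j < n_sigma or theta[j] > 1e-8 * scale]
    steps = np.array([max(1e-6 * scale, 1e-4 * theta[j]) for j in free])

    def perturb(j, h):
        t = theta.copy()
        t[free[j]] = max(t[free[j]] + h, 0.0)
        return t

    grad = np.zeros(len(free))
    for j, h in enumerate(steps):
        grad[j] = (satt["var_gamma"](perturb(j, h))
                   - satt["var_gamma"](perturb(j, -h))) / (2 * h)
    ll = satt["profile_ll"]
    H = np.zeros((len(free), len(free)))
    ll0 = ll(theta)
    for j, hj in enumerate(steps):
        for k in range(j, len(free)):
            hk = steps[k]
            if j == k:
                H[j, j] = -(ll(perturb(j, hj)) - 2 * ll0 + ll(perturb(j, -hj))) / hj**2
            else:
                tpp = theta.copy(); tpp[free[j]] += hj; tpp[free[k]] += hk
                tpm = theta.copy(); tpm[free[j]] += hj; tpm[free[k]] -= hk
                tmp = theta.copy(); tmp[free[j]] -= hj; tmp[free[k]] += hk
                tmm = theta.copy(); tmm[free[j]] -= hj; tmm[free[k]] -= hk
                H[j, k] = H[k, j] = -(ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * hj * hk)
    try:
        var_theta = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        var_theta = np.linalg.pinv(H)
    denom = float(grad @ var_theta @ grad)
    df = 2.0 * f0**2 / denom if denom > 0 else np.inf
    if df <= 0:
        raise ValueError(f"Satterthwaite df came out non-positive ({df:.3g})")
    result.df = float(df)
    crit = stats.t.ppf(0.5 + level / 2, df=df)
    return (result.gamma - crit * result.se, result.gamma + crit * result.se)


# ----------------------------------------------------------------------
# binary: adaptive Gauss-Hermite maximum likelihood


def _agh_trial_ll(beta, sds, y, X, G, nodes, wts):
    """Marginal log-likelihood of one trial's Bernoulli-logit data,
    integrating the independent random effects by adaptive Gauss-Hermite
    quadrature centered at the posterior mode."""
    eta0 = X @ beta
    active = [c for c in range(len(G)) if sds[c] > 1e-6]
    if not active:
        p = 1.0 / (1.0 + np.exp(-eta0))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    U = np.column_stack([G[c] for c in active])
    d = np.array([sds[c] ** 2 for c in active])
    C = len(active)

    def h_parts(u):
        eta = eta0 + U @ u
        p = 1.0 / (1.0 + np.exp(-eta))
        ll = np.sum(y * eta - np.log1p(np.exp(eta)))
        prior = -0.5 * np.sum(u**2 / d) - 0.5 * np.sum(np.log(2 * np.pi * d))
        return ll + prior, p

    # Newton to the mode of the joint density in u
    u = np.zeros(C)
    for _ in range(50):
        eta = eta0 + U @ u
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = U.T @ (y - p) - u / d
        W = p * (1 - p)
        Hm = U.T @ (U * W[:, None]) + np.diag(1.0 / d)
        step = np.linalg.solve(Hm, grad)
        u_new = u + step
        if np.max(np.abs(step)) < 1e-10:
            u = u_new
            break
        u = u_new
    eta = eta0 + U @ u
    p = 1.0 / (1.0 + np.exp(-eta))
    W = p * (1 - p)
    Q = U.T @ (U * W[:, None]) + np.diag(1.0 / d)  # -h''(u_hat)
    L = np.linalg.cholesky(Q)

    # tensor-product nodes: u_k = u_hat + sqrt(2) L^-T t_k
    if C == 1:
        T = nodes[:, None]
        Wq = wts
    else:
        T = np.array([[a, b] for a in nodes for b in nodes])
        Wq = np.array([wa * wb for wa in wts for wb in wts])
    shift = np.sqrt(2.0) * np.linalg.solve(L.T, T.T).T
    vals = np.empty(len(T))
    for k in range(len(T)):
        hk, _ = h_parts(u + shift[k])
        vals[k] = hk + np.sum(T[k] ** 2)
    vmax = np.max(vals)
    integral = np.sum(Wq * np.exp(vals - vmax))
    log_int = (vmax + np.log(integral) + 0.5 * C * np.log(2.0)
               - np.sum(np.log(np.diag(L))))
    return float(log_int)


def _fit_binary(ds, covariate, adjusters, approach, ci_method, level,
                n_nodes: int = 9):
    if ci_method == "satterthwaite":
        raise ValueError(
            "Satterthwaite intervals are available for continuous-outcome "
            "one-stage fits only"
        )
    ys, Xs, Gs, names, gidx, col, trials = _blocks(ds, covariate, adjusters,
                                                   approach)
    p = len(names)
    n_comp = len(Gs[0])
    scales = []
    for c in range(n_comp):
        ss = np.sqrt(np.mean(np.concatenate([G[c] for G in Gs]) ** 2))
        scales.append(ss if ss > 0 else 1.0)
    Gs_n = [[G[c] / scales[c] for c in range(n_comp)] for G in Gs]
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)

    # starting values from the no-random-effects logistic fit
    import statsmodels.api as sm

    Xall = np.concatenate(Xs)
    yall = np.concatenate(ys)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(yall, Xall, family=sm.families.Binomial()).fit(maxiter=200)
    beta0 = np.asarray(glm.params)

    def nll(par):
        beta = par[:p]
        sds = np.abs(par[p:])
        tot = 0.0
        for y, X, G in zip(ys, Xs, Gs_n):
            tot += _agh_trial_ll(beta, sds, y, X, G, nodes, wts)
        return -tot

    par0 = np.concatenate([beta0, np.full(n_comp, 0.3)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(nll, par0, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
    par = res.x
    beta = par[:p]
    sds = np.abs(par[p:])

    # observed-information standard errors (numerical Hessian)
    keep = list(range(p)) + [p + c for c in range(n_comp) if sds[c] > 1e-4]
    hsteps = np.full(len(keep), 1e-4)

    def nll_sub(sub):
        full = par.copy()
        full[keep] = sub
        return nll(full)

    H = _num_hessian(nll_sub, par[keep], hsteps)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se = float(np.sqrt(max(cov[gidx, gidx], 0.0)))
    if not np.isfinite(se) or se == 0.0:
        raise RuntimeError(
            "binary one-stage fit did not yield a usable standard error; "
            "consider simplifying the random-effects structure"
        )
    gamma = float(beta[gidx])
    tau2 = (sds / np.asarray(scales)) ** 2
    z = stats.norm.ppf(0.5 + level / 2)
    if approach == "centered":
        phi, gamma_a = float(beta[col["phi"]]), float(beta[col["gamma_a"]])
        tau2_treat, tau2_int = float(tau2[0]), float(tau2[1])
    else:
        phi = gamma_a = tau2_treat = None
        tau2_int = float(tau2[0])
    return OneStageResult(
        gamma, se, (gamma - z * se, gamma + z * se), tau2_int,
        approach=("centered_metareg" if approach == "centered" else approach),
        outcome_type="binary", k=len(trials), ci_method="wald", level=level,
        phi=phi, gamma_a=gamma_a, tau2_treatment=tau2_treat,
        nuisance=pd.Series(beta, index=names), converged=bool(res.success),
    )


def _num_hessian(f, x, steps):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for j in range(n):
        for k in range(j, n):
            hj, hk = steps[j], steps[k]
            if j == k:
                xp = x.copy(); xp[j] += hj
                xm = x.copy(); xm[j] -= hj
                H[j, j] = (f(xp) - 2 * f0 + f(xm)) / hj**2
            else:
                xpp = x.copy(); xpp[j] += hj; xpp[k] += hk
                xpm = x.copy(); xpm[j] += hj; xpm[k] -= hk
                xmp = x.copy(); xmp[j] -= hj; xmp[k] += hk
                xmm = x.copy(); xmm[j] -= hj; xmm[k] -= hk
                H[j, k] = H[k, j] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * hj * hk)
    return H


# ----------------------------------------------------------------------
# public API


def _dispatch(ds, covariate, adjusters, approach, outcome_type, ci_method,
              level, **kwargs):
    outcome_type = outcome_type or ds.outcome_type
    if outcome_type not in ("continuous", "binary"):
        raise ValueError(
            "one-stage models support continuous and binary outcomes; "
            "use the two-stage approach for time-to-event data"
        )
    adjusters = list(adjusters)
    if ds.has_baseline and "baseline" not in adjusters:
        adjusters = ["baseline"] + adjusters
    # adjusters constant everywhere would break stratification; drop globally
    adjusters = [a for a in adjusters if ds.df[a].nunique(dropna=True) > 1]
    if outcome_type == "continuous":
        kwargs.pop("n_nodes", None)
        return _fit_continuous(ds, covariate, adjusters, approach, ci_method,
                               level, **kwargs)
    kwargs.pop("residual_variances", None)
    return _fit_binary(ds, covariate, adjusters, approach, ci_method, level,
                       **kwargs)


def fit_onestage_centered(ds: IPDDataset, covariate: str, adjusters=(),
                          outcome_type: str | None = None,
                          ci_method: str = "wald", level: float = 0.95,
                          **kwargs) -> OneStageResult:
    """Deft one-stage model, approach (i): study-mean centering of the
    interaction covariate plus a covariate-mean meta-regression on the
    treatment effect.  Returns gamma_W (within-trial) and gamma_A
    (across-trial) estimates."""
    return _dispatch(ds, covariate, adjusters, "centered", outcome_type,
                     ci_method, level, **kwargs)


def fit_onestage_stratified(ds: IPDDataset, covariate: str, adjusters=(),
                            outcome_type: str | None = None,
                            ci_method: str = "wald", level: float = 0.95,
                            **kwargs) -> OneStageResult:
    """Deft one-stage model, approach (ii): all nuisance parameters
    (including the per-trial treatment effect) stratified by trial; the
    interaction slope is the only random effect."""
    return _dispatch(ds, covariate, adjusters, "stratified", outcome_type,
                     ci_method, level, **kwargs)


def fit_onestage_deluded(ds: IPDDataset, covariate: str,
                         adjusters=(), level: float = 0.95) -> OneStageResult:
    """The flawed amalgamated one-stage model (diagnostic only):
    uncentered treatment-by-covariate product, random treatment effect,
    no covariate-mean meta-regression.  Its estimate is a weighted
    average of the within-trial interaction and the across-trial trend
    and must not be interpreted as a participant-level interaction."""
    if ds.outcome_type != "continuous":
        raise ValueError("the deluded diagnostic model is continuous-outcome only")
    return _dispatch(ds, covariate, adjusters, "deluded", "continuous",
                     "wald", level)


def deft_deluded_comparison(ds: IPDDataset, covariate: str, adjusters=()) -> pd.DataFrame:
    """Side-by-side deft vs deluded estimates for reporting."""
    rows = []
    for label, fn in [
        ("deft: centered + mean meta-regression", fit_onestage_centered),
        ("deft: fully stratified", fit_onestage_stratified),
        ("deluded (diagnostic only)", fit_onestage_deluded),
    ]:
        r = fn(ds, covariate, adjusters)
        rows.append({
            "model": label, "estimate": r.gamma, "se": r.se,
            "ci_low": r.ci[0], "ci_high": r.ci[1],
            "tau2_interaction": r.tau2_interaction,
            "warning": DELUDED_LABEL if r.diagnostic_only else "",
        })
    return pd.DataFrame(rows)
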