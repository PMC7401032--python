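"""Per-trial interaction models: the first stage of a two-stage IPD
meta-analysis.

Each trial is analyzed separately with a model matching its outcome
type -- linear regression (mean difference scale), logistic or
log-link binomial regression (log OR / log RR), or Cox proportional
hazards (log HR) -- always including the covariate main effect, the
treatment indicator, optional adjusters (the baseline outcome whenever
present), and the treatment-by-covariate product.  The product-term
coefficient is the within-trial interaction gamma_Wi; it and its Wald
variance feed the second-stage pooling.

Because every trial is fitted on its own, all nuisance parameters are
naturally stratified by trial and the interaction estimates carry only
within-trial information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import SplineBasisSpec, rcs_basis

__all__ = [
    "TrialEstimate",
    "TrialModelFit",
    "TrialSplineEstimate",
    "TrialFitError",
    "fit_trial_linear",
    "fit_trial_logistic",
    "fit_trial_cox",
    "fit_trial_spline_interaction",
    "closed_form_interaction",
    "fit_first_stage",
    "estimates_to_frame",
    "estimates_from_frame",
]

SCALES = ("mean_difference", "log_or", "log_rr", "log_hr")


class TrialFitError(ValueError):
    """A trial cannot contribute an interaction estimate (rank deficiency,
    separation, no events, ...); the message carries the diagnostic."""


@dataclass(frozen=True)
class TrialEstimate:
    """One trial's interaction estimate on the linear-predictor scale."""

    trial_id: object
    gamma: float
    var_gamma: float
    n: int = 0
    events: int | None = None
    scale: str = "mean_difference"

    def __post_init__(self):
        if not self.var_gamma > 0:
            raise ValueError(
                f"var_gamma must be positive, got {self.var_gamma} "
                f"(trial {self.trial_id!r})"
            )
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_gamma))


@dataclass
class TrialModelFit:
    """Full first-stage fit: coefficients, covariance, residual variance."""

    trial_id: object
    params: pd.Series
    cov: pd.DataFrame
    sigma2: float | None = None  # residual variance, continuous outcome only
    converged: bool = True
    message: str = ""


@dataclass
class TrialSplineEstimate:
    """Per-trial spline-interaction fit: reference treatment effect beta2
    plus the spline-interaction slopes, with their joint covariance.

    ``mask[m]`` is True when interaction component m is inestimable in
    this trial (covariate window too narrow for that basis column); the
    corresponding entries of ``gammas``/``cov`` are NaN.
    """

    trial_id: object
    beta2: float
    gammas: np.ndarray
    cov: np.ndarray  # (1+M, 1+M), ordered (beta2, gamma_1, ..., gamma_M)
    mask: np.ndarray  # bool over the M interaction components
    n: int = 0

    @property
    def available(self) -> np.ndarray:
        """Index of observed rows of (beta2, gammas) within the full vector."""
        return np.concatenate(([True], ~self.mask))


# ----------------------------------------------------------------------
# design-matrix helpers


def _check_two_arms(g: pd.DataFrame, trial_id):
    arms = set(g["arm"])
    if arms != {0, 1}:
        raise TrialFitError(
            f"trial {trial_id!r} has participants in only one arm ({sorted(arms)})"
        )


def _base_design(g: pd.DataFrame, covariate: str, adjusters) -> pd.DataFrame:
    X = pd.DataFrame(index=g.index)
    X["const"] = 1.0
    X[covariate] = g[covariate].astype(float)
    X["treat"] = g["arm"].astype(float)
    for a in adjusters:
        X[a] = g[a].astype(float)
    X["treat:" + covariate] = X["treat"] * X[covariate]
    return X

def _complete_cases(g, cols):
    g = g.dropna(subset=[c for c in cols if c in g.columns])
    return g


def _check_rank(X: pd.DataFrame, trial_id):
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise TrialFitError(
            f"trial {trial_id!r}: rank-deficient design "
            f"(constant covariate or collinear adjusters); interaction inestimable"
        )


# ----------------------------------------------------------------------
# per-trial fits


def fit_trial_linear(g: pd.DataFrame, covariate: str, adjusters=()):
    """Least-squares interaction model for a continuous outcome in one trial.

    Fits y on intercept, covariate, treatment, adjusters and
    treatment*covariate, with a single residual variance shared by both
    arms; the interaction coefficient is the change in mean difference
    per unit covariate.

    Returns
    -------
    (TrialEstimate, TrialModelFit)
    """
    import statsmodels.api as sm

    trial_id = g["trial"].iloc[0]
    g = _complete_cases(g, ["y", "arm", covariate, *adjusters])
    _check_two_arms(g, trial_id)
    X = _base_design(g, covariate, adjusters)
    _check_rank(X, trial_id)
    res = sm.OLS(g["y"].astype(float), X).fit()
    key = "treat:" + covariate
    fit = TrialModelFit(
        trial_id,
        params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        sigma2=float(res.scale),  # SSR / residual df (unbiased)
    )
    est = TrialEstimate(
        trial_id, float(res.params[key]), float(res.cov_params().loc[key, key]),
        n=len(g), scale="mean_difference",
    )
    return est, fit


def fit_trial_logistic(g: pd.DataFrame, covariate: str, adjusters=(),
                       link: str = "logit"):
    """Binomial interaction model for a binary outcome in one trial.

    With the logit link the interaction is a log ratio of odds ratios
    per unit covariate; with the log link a log ratio of risk ratios.

    Raises
    ------
    TrialFitError
        If an arm has zero events or zero non-events, on separation, or
        when a log-link fit implies probabilities >= 1.
    """
    import statsmodels.api as sm

    if link not in ("logit", "log"):
        raise ValueError(f"link must be 'logit' or 'log', got {link!r}")
    trial_id = g["trial"].iloc[0]
    g = _complete_cases(g, ["y", "arm", covariate, *adjusters])
    _check_two_arms(g, trial_id)
    for arm in (0, 1):
        ys = g.loc[g["arm"] == arm, "y"]
        if ys.sum() == 0 or (1 - ys).sum() == 0:
            raise TrialFitError(
                f"trial {trial_id!r}: arm {arm} has zero events or zero "
                f"non-events; interaction inestimable"
            )
    X = _base_design(g, covariate, adjusters)
    _check_rank(X, trial_id)
    fam = (sm.families.Binomial() if link == "logit"
           else sm.families.Binomial(link=sm.families.links.Log()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(g["y"].astype(float), X, family=fam).fit(maxiter=200)
        except Exception as exc:  # noqa: BLE001 - surfaced as a flag
            raise TrialFitError(f"trial {trial_id!r}: fit failed ({exc})") from exc
    if not res.converged:
        raise TrialFitError(f"trial {trial_id!r}: IRLS did not converge")
    if link == "log" and np.any(res.fittedvalues >= 1.0):
        raise TrialFitError(
            f"trial {trial_id!r}: log-link fit implies probabilities >= 1"
        )
    key = "treat:" + covariate
    se = float(np.sqrt(res.cov_params().loc[key, key]))
    if not np.isfinite(se) or se > 100:
        raise TrialFitError(
            f"trial {trial_id!r}: separation suspected (SE={se:.3g})"
        )
    fit = TrialModelFit(
        trial_id, params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
    )
    est = TrialEstimate(
        trial_id, float(res.params[key]), float(res.cov_params().loc[key, key]),
        n=len(g), events=int(g["y"].sum()),
        scale="log_or" if link == "logit" else "log_rr",
    )
    return est, fit


def fit_trial_cox(g: pd.DataFrame, covariate: str, adjusters=()):
    """Cox interaction model (Efron ties) for a time-to-event outcome in one
    trial; the interaction is a log ratio of hazard ratios per unit
    covariate.  The baseline hazard is profiled out by partial
    likelihood.  A baseline outcome value, if adjusted for, is treated
    as an ordinary adjuster column."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    trial_id = g["trial"].iloc[0]
    g = _complete_cases(g, ["time", "event", "arm", covariate, *adjusters])
    _check_two_arms(g, trial_id)
    for arm in (0, 1):
        if g.loc[g["arm"] == arm, "event"].sum() == 0:
            raise TrialFitError(
                f"trial {trial_id!r}: no events in arm {arm}; interaction inestimable"
            )
    cols = [covariate, "treat", *adjusters, "treat:" + covariate]
    d = pd.DataFrame({
        "time": g["time"].astype(float),
        "event": g["event"].astype(int),
        covariate: g[covariate].astype(float),
        "treat": g["arm"].astype(float),
    })
    for a in adjusters:
        d[a] = g[a].astype(float)
    d["treat:" + covariate] = d["treat"] * d[covariate]
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(d, duration_col="time", event_col="event")
        except (ConvergenceError, Exception) as exc:  # noqa: BLE001
            raise TrialFitError(
                f"trial {trial_id!r}: Cox fit failed ({exc})"
            ) from exc
    key = "treat:" + covariate
    se = float(cph.standard_errors_[key])
    if not np.isfinite(se) or se > 100:
        raise TrialFitError(
            f"trial {trial_id!r}: monotone likelihood suspected (SE={se:.3g})"
        )
    fit = TrialModelFit(
        trial_id, params=cph.params_,
        cov=pd.DataFrame(cph.variance_matrix_, index=cols, columns=cols),
    )
    est = TrialEstimate(
        trial_id, float(cph.params_[key]), se**2,
        n=len(d), events=int(d["event"].sum()), scale="log_hr",
    )
    return est, fit


def fit_trial_spline_interaction(g: pd.DataFrame, covariate: str,
                                 spec: SplineBasisSpec, adjusters=(),
                                 outcome_type: str = "continuous") -> TrialSplineEstimate:
    """Per-trial restricted-cubic-spline interaction fit.

    The outcome is regressed on the spline basis of the covariate (main
    effects), the treatment indicator, adjusters, and treatment times
    the basis *centered at the reference value*, so the treatment
    coefficient beta2 is the treatment effect for a reference
    individual and the interaction slopes are poolable across trials
    sharing the same knots and reference.

    Interaction components whose centered basis column is degenerate in
    this trial (covariate window not spanning the relevant knots) are
    masked rather than fitted.
    """
    import statsmodels.api as sm

    if spec.reference is None:
        raise ValueError("spec must define a reference value")
    trial_id = g["trial"].iloc[0]
    core = ["y", "arm", covariate] if outcome_type != "time_to_event" else [
        "time", "event", "arm", covariate]
    g = _complete_cases(g, core + list(adjusters))
    _check_two_arms(g, trial_id)

    z = g[covariate].to_numpy(dtype=float)
    x = g["arm"].to_numpy(dtype=float)
    B = rcs_basis(z, spec)
    Bc = B - rcs_basis(spec.reference, spec)
    M = spec.n_basis

    # main-effect basis columns: drop those with no within-trial variation
    X = pd.DataFrame(index=g.index)
    if outcome_type != "time_to_event":
        X["const"] = 1.0
    for m in range(M):
        col = B[:, m]
        if np.std(col) > 1e-10 * (1.0 + np.abs(col).mean()):
            X[f"z_b{m}"] = col
    X["treat"] = x
    for a in adjusters:
        X[a] = g[a].astype(float)
    mask = np.zeros(M, dtype=bool)
    for m in range(M):
        col = x * Bc[:, m]
        treated = col[x == 1]
        if np.std(treated) > 1e-10 * (1.0 + np.abs(treated).mean()):
            X[f"treat:z_b{m}"] = col
        else:
            mask[m] = True
    if mask[0]:
        raise TrialFitError(
            f"trial {trial_id!r}: covariate constant; no interaction information"
        )
    _check_rank(X, trial_id)

    if outcome_type == "continuous":
        res = sm.OLS(g["y"].astype(float), X).fit()
        params, cov = res.params, res.cov_params()
    elif outcome_type == "binary":
        res = sm.GLM(g["y"].astype(float), X, family=sm.families.Binomial()).fit()
        params, cov = res.params, res.cov_params()
    elif outcome_type == "time_to_event":
        from lifelines import CoxPHFitter

        d = X.copy()
        d["time"] = g["time"].astype(float)
        d["event"] = g["event"].astype(int)
        cph = CoxPHFitter()
        cph.fit(d, duration_col="time", event_col="event")
        params = cph.params_
        cov = pd.DataFrame(cph.variance_matrix_, index=X.columns, columns=X.columns)
    else:
        raise ValueError(f"unknown outcome_type {outcome_type!r}")

    names = ["treat"] + [f"treat:z_b{m}" for m in range(M) if not mask[m]]
    sub_cov = np.asarray(pd.DataFrame(cov).loc[names, names], dtype=float)
    gammas = np.full(M, np.nan)
    avail = [m for m in range(M) if not mask[m]]
    for j, m in enumerate(avail):
        gammas[m] = params[f"treat:z_b{m}"]
    full_cov = np.full((1 + M, 1 + M), np.nan)
    idx = np.array([0] + [1 + m for m in avail])
    full_cov[np.ix_(idx, idx)] = sub_cov
    return TrialSplineEstimate(
        trial_id, float(params["treat"]), gammas, full_cov, mask, n=len(g)
    )


def closed_form_interaction(g: pd.DataFrame, covariate: str) -> float:
    """Closed-form ML interaction estimate for a continuous outcome.

    With the covariate centered at the trial mean (z' = z - zbar),

        gamma_hat = (2 / sum z'^2) * (sum_T y z' - sum_C y z'),

    the maximum-likelihood interaction in a two-arm trial without
    adjusters.  Exactly equals the regression coefficient when arms are
    equally sized with equal arm-wise covariate means; useful as an
    independent cross-check of the regression fit, and the estimator
    underlying the closed-form power calculations.
    """
    trial_id = g["trial"].iloc[0] if "trial" in g.columns else "<trial>"
    arms = set(g["arm"])
    if arms != {0, 1}:
        raise TrialFitError(
            f"trial {trial_id!r}: both arms required for the closed-form estimate"
        )
    z = g[covariate].to_numpy(dtype=float)
    y = g["y"].to_numpy(dtype=float)
    x = g["arm"].to_numpy()
    zc = z - z.mean()
    ss = float(np.sum(zc**2))
    if ss == 0.0:
        raise TrialFitError(f"trial {trial_id!r}: zero covariate variation")
    return float(2.0 / ss * (np.sum(y[x == 1] * zc[x == 1]) - np.sum(y[x == 0] * zc[x == 0])))


# ----------------------------------------------------------------------
# orchestration over a dataset


_FITTERS = {
    "continuous": fit_trial_linear,
    "binary": fit_trial_logistic,
    "time_to_event": fit_trial_cox,
}


def fit_first_stage(ds, covariate: str, adjusters=(), link: str = "logit",
                    include_baseline: bool = True):
    """Fit the per-trial interaction model in every usable trial.

    The baseline outcome value is adjusted for whenever present (and
    ``include_baseline``); the same adjuster list is attempted in every
    trial and dropped per trial when constant, with a log entry.

    Returns
    -------
    (estimates, fits, log) : (list of TrialEstimate, dict, list of str)
        Trials flagged inestimable appear in ``log`` only.
    """
    adjusters = list(adjusters)
    if include_baseline and ds.has_baseline and "baseline" not in adjusters:
        adjusters = ["baseline"] + adjusters
    estimates, fits, log = [], {}, []
    for tid in ds.trials:
        g = ds.trial_data(tid)
        adj = []
        for a in adjusters:
            if g[a].nunique(dropna=True) > 1:
                adj.append(a)
            else:
                log.append(f"trial {tid!r}: adjuster {a!r} constant, dropped")
        kwargs = {"link": link} if ds.outcome_type == "binary" else {}
        try:
            est, fit = _FITTERS[ds.outcome_type](g, covariate, adj, **kwargs)
        except TrialFitError as exc:
            log.append(str(exc))
            continue
        estimates.append(est)
        fits[tid] = fit
    return estimates, fits, log


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Per-trial estimates as the CSV-ready exchange table (the format the
    pooling stage accepts, so estimates extracted from non-IPD trials
    can be mixed in)."""
    return pd.DataFrame(
        {
            "trial": [e.trial_id for e in estimates],
            "estimate": [e.gamma for e in estimates],
            "se": [e.se for e in estimates],
            "n": [e.n for e in estimates],
            "events": [e.events for e in estimates],
            "scale": [e.scale for e in estimates],
        }
    )


def estimates_from_frame(df: pd.DataFrame) -> list[TrialEstimate]:
    out = []
    for _, r in df.iterrows():
        events = r.get("events")
        out.append(
            TrialEstimate(
                r["trial"], float(r["estimate"]), float(r["se"]) ** 2,
                n=int(r.get("n", 0) or 0),
                events=None if pd.isna(events) else int(events),
                scale=str(r.get("scale", "mean_difference")),
            )
        )
    return out
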