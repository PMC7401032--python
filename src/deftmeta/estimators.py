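"""Estimator classes: the pipeline-level interface.

Each estimator follows the scikit-learn protocol -- constructor
parameters are stored verbatim, ``fit`` accepts a long-format
participant-level table (DataFrame or IPDDataset) and sets
trailing-underscore attributes, and ``get_params``/``set_params``/
``clone`` work as usual -- so the analyses compose with sklearn
tooling.  The module-level functions in ``first_stage``, ``meta``,
``one_stage`` etc. do the actual work; the estimators orchestrate them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import IPDDataset
from .first_stage import fit_first_stage, fit_trial_spline_interaction, TrialFitError
from .meta import pool_common, pool_multivariate, pool_random
from .one_stage import (fit_onestage_centered, fit_onestage_deluded,
                        fit_onestage_stratified)
from .prediction import build_prediction_equation
from .splines import SplineBasisSpec, default_knots, summary_curve

__all__ = [
    "TwoStageInteraction",
    "OneStageInteraction",
    "SplineInteractionTwoStage",
]


def as_ipd(X, outcome_type: str, covariates) -> IPDDataset:
    """Coerce a DataFrame with canonical columns (or pass through an
    IPDDataset) for estimator ``fit`` methods."""
    if isinstance(X, IPDDataset):
        return X
    return IPDDataset(pd.DataFrame(X), outcome_type, covariates)


class TwoStageInteraction(BaseEstimator):
    """Two-stage IPD meta-analysis of a treatment-covariate interaction.

    Stage one fits the outcome-appropriate interaction regression in
    each trial separately; stage two pools the per-trial estimates by
    inverse variance (common-effect, or random-effects with REML/DL
    heterogeneity and HKSJ or Wald intervals).

    Parameters
    ----------
    covariate : str
        Effect-modifier column.
    outcome_type : {"continuous", "binary", "time_to_event"}
    adjusters : tuple of str
        Extra prognostic adjusters; the baseline outcome column is
        adjusted for automatically when present.
    link : {"logit", "log"}
        Binary-outcome link (log OR vs log RR interaction scale).
    method : {"random", "common"}
    tau2_method : {"reml", "dl"}
    ci_method : {"hksj", "wald"}

    Attributes
    ----------
    gamma_w_, se_, tau2_, ci_, pi_, k_ : pooled summaries
    result_ : MetaResult
    trial_estimates_ : list of TrialEstimate
    trial_fits_ : dict of TrialModelFit
    log_ : list of str (trials flagged inestimable, dropped adjusters)
    """

    def __init__(self, covariate: str = "z", outcome_type: str = "continuous",
                 adjusters: tuple = (), link: str = "logit",
                 method: str = "random", tau2_method: str = "reml",
                 ci_method: str = "hksj", level: float = 0.95):
        self.covariate = covariate
        self.outcome_type = outcome_type
        self.adjusters = adjusters
        self.link = link
        self.method = method
        self.tau2_method = tau2_method
        self.ci_method = ci_method
        self.level = level

    def fit(self, X, y=None):
        ds = as_ipd(X, self.outcome_type, [self.covariate])
        ests, fits, log = fit_first_stage(
            ds, self.covariate, adjusters=self.adjusters, link=self.link)
        if not ests:
            raise ValueError(
                "no trial yielded an interaction estimate; see log: " + "; ".join(log)
            )
        if self.method == "common" or len(ests) == 1:
            result = pool_common(ests, level=self.level)
        else:
            result = pool_random(ests, tau2_method=self.tau2_method,
                                 ci_method=self.ci_method, level=self.level)
        self.trial_estimates_ = ests
        self.trial_fits_ = fits
        self.log_ = log
        self.result_ = result
        self.gamma_w_ = result.gamma
        self.se_ = result.se
        self.tau2_ = result.tau2
        self.ci_ = result.ci
        self.pi_ = result.pi
        self.k_ = result.k
        return self


class OneStageInteraction(BaseEstimator):
    """One-stage mixed-model IPD meta-analysis of an interaction.

    ``approach="centered"`` (study-mean centering plus covariate-mean
    meta-regression) and ``approach="stratified"`` (all nuisance
    parameters stratified by trial) both restrict the interaction to
    within-trial information; ``approach="deluded"`` fits the flawed
    amalgamated model for diagnostic comparison only.

    Attributes: ``gamma_w_``, ``se_``, ``ci_``, ``tau2_``, plus
    ``phi_``/``gamma_a_`` for the centered approach, and ``result_``.
    """

    def __init__(self, covariate: str = "z", approach: str = "centered",
                 outcome_type: str = "continuous", adjusters: tuple = (),
                 ci_method: str = "wald", residual_variances: str = "per_trial",
                 level: float = 0.95):
        self.covariate = covariate
        self.approach = approach
        self.outcome_type = outcome_type
        self.adjusters = adjusters
        self.ci_method = ci_method
        self.residual_variances = residual_variances
        self.level = level

    def fit(self, X, y=None):
        ds = as_ipd(X, self.outcome_type, [self.covariate])
        kw = ({"residual_variances": self.residual_variances}
              if ds.outcome_type == "continuous" else {})
        if self.approach == "centered":
            res = fit_onestage_centered(ds, self.covariate, self.adjusters,
                                        ci_method=self.ci_method,
                                        level=self.level, **kw)
        elif self.approach == "stratified":
            res = fit_onestage_stratified(ds, self.covariate, self.adjusters,
                                          ci_method=self.ci_method,
                                          level=self.level, **kw)
        elif self.approach == "deluded":
            res = fit_onestage_deluded(ds, self.covariate, self.adjusters,
                                       level=self.level)
        else:
            raise ValueError(
                f"approach must be 'centered', 'stratified' or 'deluded', "
                f"got {self.approach!r}"
            )
        self.result_ = res
        self.gamma_w_ = res.gamma
        self.se_ = res.se
        self.ci_ = res.ci
        self.tau2_ = res.tau2_interaction
        self.phi_ = res.phi
        self.gamma_a_ = res.gamma_a
        self.df_ = res.df
        return self


class SplineInteractionTwoStage(BaseEstimator):
    """Two-stage multivariate meta-analysis of a nonlinear interaction.

    Stage one fits, in each trial, the outcome on a restricted cubic
    spline of the covariate, the treatment, and treatment-by-spline
    terms centered at a shared reference value; stage two pools the
    per-trial (beta2, gamma_W1, ...) vectors by multivariate REML,
    handling components inestimable in narrow-covariate trials.  The
    fitted object exposes the summary interaction curve and an
    individualized treatment-effect prediction equation (optionally
    de-biased: interaction coefficients pooled ignoring their
    correlation with the per-trial reference effects).

    Attributes
    ----------
    spec_ : SplineBasisSpec (knots resolved from the pooled distribution
        when not supplied)
    trial_estimates_ : list of TrialSplineEstimate
    pooled_ : MultiMetaResult for (beta2, gammas)
    pooled_debias_ : interaction-only MultiMetaResult (when debias=True)
    equation_ : PredictionEquation
    """

    def __init__(self, covariate: str = "z", outcome_type: str = "continuous",
                 adjusters: tuple = (), knots: tuple | None = None,
                 n_knots: int = 3, reference: float | None = None,
                 tau_structure: str = "unstructured", debias: bool = False):
        self.covariate = covariate
        self.outcome_type = outcome_type
        self.adjusters = adjusters
        self.knots = knots
        self.n_knots = n_knots
        self.reference = reference
        self.tau_structure = tau_structure
        self.debias = debias

    def fit(self, X, y=None):
        ds = as_ipd(X, self.outcome_type, [self.covariate])
        zall = ds.df[self.covariate].dropna().to_numpy(dtype=float)
        knots = (tuple(self.knots) if self.knots is not None
                 else default_knots(zall, self.n_knots))
        reference = (self.reference if self.reference is not None
                     else float(np.median(zall)))
        spec = SplineBasisSpec(knots, reference)

        adjusters = list(self.adjusters)
        if ds.has_baseline and "baseline" not in adjusters:
            adjusters = ["baseline"] + adjusters
        ests, log = [], []
        for tid in ds.trials:
            g = ds.trial_data(tid)
            adj = [a for a in adjusters if g[a].nunique(dropna=True) > 1]
            try:
                ests.append(fit_trial_spline_interaction(
                    g, self.covariate, spec, adj, outcome_type=ds.outcome_type))
            except TrialFitError as exc:
                log.append(str(exc))
        if len(ests) < 2:
            raise ValueError(
                "fewer than 2 trials yielded spline-interaction estimates; "
                "log: " + "; ".join(log)
            )
        pooled = pool_multivariate(ests, include_reference=True,
                                   tau_structure=self.tau_structure)
        debias_pooled = None
        if self.debias:
            debias_pooled = pool_multivariate(ests, include_reference=False,
                                              tau_structure=self.tau_structure)
        self.spec_ = spec
        self.trial_estimates_ = ests
        self.pooled_ = pooled
        self.pooled_debias_ = debias_pooled
        self.log_ = log
        self.data_range_ = (float(zall.min()), float(zall.max()))
        self.grid_range_ = tuple(np.quantile(zall, [0.01, 0.99]))
        self.equation_ = build_prediction_equation(
            pooled, spec, debias_pooled=debias_pooled,
            data_range=self.data_range_)
        return self

    def curve(self, grid=None) -> pd.DataFrame:
        """Summary difference-in-treatment-effect curve vs the reference."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "pooled_")
        if grid is None:
            # default: 100 points between the pooled 1st and 99th percentiles
            grid = np.linspace(*self.grid_range_, 100)
        # interaction-only block of the pooled result feeds the curve
        src = self.pooled_debias_ if self.debias else self.pooled_
        return summary_curve(src, self.spec_, grid, data_range=self.data_range_)

    def predict(self, values) -> np.ndarray:
        """Individualized predicted treatment effects."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "equation_")
        return self.equation_.predict(np.asarray(values, dtype=float))["effect"].to_numpy()
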