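"""Reporting utilities: the subgroup-vs-interaction diagnostic and
forest-plot data for interaction estimates.

Comparing meta-analyzed treatment effects between covariate-defined
subgroups amalgamates within-trial and across-trial information -- a
trial containing only one subgroup contributes to that subgroup's
summary but carries zero within-trial interaction information.  The
diagnostic here computes both quantities side by side and labels the
subgroup difference as invalid for interaction inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import IPDDataset
from .first_stage import TrialFitError, fit_first_stage
from .meta import MetaResult, pool_common, pool_random

__all__ = [
    "SUBGROUP_WARNING",
    "SubgroupContrast",
    "subgroup_difference",
    "subgroup_contrast",
    "forest_data",
    "forest_plot",
]

SUBGROUP_WARNING = "subgroup difference is NOT a valid interaction estimate"


@dataclass
class SubgroupContrast:
    """Side-by-side subgroup summaries and the within-trial interaction."""

    subgroup_results: dict  # level -> MetaResult
    difference: float
    difference_se: float
    within_result: MetaResult
    weights: pd.DataFrame  # per-trial weight share in each quantity
    label: str = SUBGROUP_WARNING

    @property
    def discrepancy(self) -> float:
        return self.difference - self.within_result.gamma

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": f"subgroup {lev} summary treatment effect",
             "estimate": r.gamma, "se": r.se, "ci_low": r.ci[0], "ci_high": r.ci[1]}
            for lev, r in sorted(self.subgroup_results.items())
        ]
        rows.append({
            "quantity": f"difference of subgroup summaries ({self.label})",
            "estimate": self.difference, "se": self.difference_se,
            "ci_low": np.nan, "ci_high": np.nan,
        })
        w = self.within_result
        rows.append({
            "quantity": "within-trial pooled interaction",
            "estimate": w.gamma, "se": w.se, "ci_low": w.ci[0], "ci_high": w.ci[1],
        })
        rows.append({
            "quantity": "discrepancy (subgroup difference - interaction)",
            "estimate": self.discrepancy, "se": np.nan,
            "ci_low": np.nan, "ci_high": np.nan,
        })
        return pd.DataFrame(rows)


def subgroup_difference(summary_high: MetaResult | float,
                        summary_low: MetaResult | float) -> float:
    """Difference between two subgroup summary treatment effects.  This
    amalgamates within- and across-trial information; it is printed only
    to be contrasted with the within-trial interaction."""
    hi = summary_high.gamma if isinstance(summary_high, MetaResult) else float(summary_high)
    lo = summary_low.gamma if isinstance(summary_low, MetaResult) else float(summary_low)
    return hi - lo


def _trial_treatment_effect(g, adjusters, outcome_type):
    """Per-trial overall treatment effect (no interaction term)."""
    import statsmodels.api as sm

    tid = g["trial"].iloc[0]
    arms = set(g["arm"])
    if arms != {0, 1}:
        raise TrialFitError(f"trial {tid!r}: only one arm in this subgroup")
    X = pd.DataFrame(index=g.index)
    if outcome_type != "time_to_event":
        X["const"] = 1.0
    X["treat"] = g["arm"].astype(float)
    for a in adjusters:
        if g[a].nunique(dropna=True) > 1:
            X[a] = g[a].astype(float)
    if outcome_type == "continuous":
        res = sm.OLS(g["y"].astype(float), X).fit()
        return float(res.params["treat"]), float(res.cov_params().loc["treat", "treat"])
    if outcome_type == "binary":
        for arm in (0, 1):
            ys = g.loc[g["arm"] == arm, "y"]
            if ys.sum() == 0 or (1 - ys).sum() == 0:
                raise TrialFitError(f"trial {tid!r}: no events/non-events in arm {arm}")
        res = sm.GLM(g["y"].astype(float), X, family=sm.families.Binomial()).fit()
        return float(res.params["treat"]), float(res.cov_params().loc["treat", "treat"])
    from lifelines import CoxPHFitter

    d = X.copy()
    d["time"] = g["time"].astype(float)
    d["event"] = g["event"].astype(int)
    cph = CoxPHFitter()
    cph.fit(d, duration_col="time", event_col="event")
    return float(cph.params_["treat"]), float(cph.standard_errors_["treat"] ** 2)


def subgroup_contrast(ds: IPDDataset, covariate: str, adjusters=(),
                      tau2_method: str = "reml") -> SubgroupContrast:
    """Run the subgroup-vs-interaction diagnostic for a binary covariate.

    A full random-effects meta-analysis of the overall treatment effect
    is run within each covariate level separately; the difference of the
    two summaries is reported next to the deft within-trial pooled
    interaction, together with each trial's weight share in each
    quantity (a single-subgroup trial has positive weight in its
    subgroup summary but zero within-trial interaction weight).
    """
    from .first_stage import TrialEstimate

    levels = sorted(pd.unique(ds.df[covariate].dropna()))
    if set(levels) != {0, 1}:
        raise ValueError(
            f"subgroup_contrast needs a 0/1 covariate; {covariate!r} has "
            f"levels {levels}"
        )
    adjusters = list(adjusters)
    if ds.has_baseline and "baseline" not in adjusters:
        adjusters = ["baseline"] + adjusters

    results = {}
    weights = {}
    for lev in (0, 1):
        ests = []
        for tid in ds.trials:
            g = ds.trial_data(tid)
            g = g[g[covariate] == lev]
            if len(g) < 4:
                continue
            try:
                eff, var = _trial_treatment_effect(g, adjusters, ds.outcome_type)
            except TrialFitError:
                continue
            ests.append(TrialEstimate(tid, eff, var, n=len(g)))
        if not ests:
            raise ValueError(f"subgroup {covariate}={lev} absent in all trials")
        res = (pool_random(ests, tau2_method=tau2_method) if len(ests) > 1
               else pool_common(ests))
        results[lev] = res
        w = np.array([1.0 / (e.var_gamma + res.tau2) for e in ests])
        weights[lev] = pd.Series(w / w.sum(), index=[e.trial_id for e in ests])

    interaction_ests, _, _ = fit_first_stage(ds, covariate)
    within = (pool_random(interaction_ests, tau2_method=tau2_method)
              if len(interaction_ests) > 1 else pool_common(interaction_ests))
    w_int = np.array([1.0 / (e.var_gamma + within.tau2) for e in interaction_ests])
    weights["interaction"] = pd.Series(
        w_int / w_int.sum(), index=[e.trial_id for e in interaction_ests])

    wtab = pd.DataFrame({
        f"subgroup_{lev}": weights[lev] for lev in (0, 1)
    })
    wtab["interaction"] = weights["interaction"]
    wtab = wtab.reindex(ds.trials).fillna(0.0)

    diff = subgroup_difference(results[1], results[0])
    diff_se = float(np.sqrt(results[1].se**2 + results[0].se**2))
    return SubgroupContrast(results, diff, diff_se, within, wtab)


def forest_data(estimates, pooled: MetaResult, level: float = 0.95) -> pd.DataFrame:
    """Plot-ready forest table: per-trial rows, the pooled row, and (when
    available) the prediction-interval row.  Interaction forest plots
    use circle markers to distinguish them from treatment-effect plots.
    """
    from scipy import stats

    scales = {e.scale for e in estimates} | {pooled.scale}
    if len(scales) > 1:
        raise ValueError(f"mixed scales in forest table: {sorted(scales)}")
    z = stats.norm.ppf(0.5 + level / 2)
    w = np.array([1.0 / (e.var_gamma + pooled.tau2) for e in estimates])
    w = 100.0 * w / w.sum()
    rows = [
        {
            "label": str(e.trial_id), "kind": "trial", "estimate": e.gamma,
            "low": e.gamma - z * e.se, "high": e.gamma + z * e.se,
            "weight_pct": wi, "marker": "circle",
        }
        for e, wi in zip(estimates, w)
    ]
    rows.append({
        "label": f"Pooled ({pooled.method}, {pooled.ci_method} CI)",
        "kind": "pooled", "estimate": pooled.gamma,
        "low": pooled.ci[0], "high": pooled.ci[1],
        "weight_pct": 100.0, "marker": "diamond",
    })
    if pooled.pi is not None:
        rows.append({
            "label": "95% prediction interval", "kind": "prediction",
            "estimate": pooled.gamma, "low": pooled.pi[0], "high": pooled.pi[1],
            "weight_pct": np.nan, "marker": "bar",
        })
    return pd.DataFrame(rows)


def forest_plot(table: pd.DataFrame, ax=None, xlabel="Interaction estimate"):
    """Render a forest table; deterministic under a fixed style so the
    figure regenerates identically from the same table."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1.5))
    ys = np.arange(len(table))[::-1]
    for y, (_, r) in zip(ys, table.iterrows()):
        ax.plot([r["low"], r["high"]], [y, y], color="0.3", lw=1.2)
        if r["kind"] == "trial":
            size = 4 + 0.1 * (r["weight_pct"] if np.isfinite(r["weight_pct"]) else 0)
            ax.plot(r["estimate"], y, "o", color="tab:blue", ms=size,
                    mfc="white")
        elif r["kind"] == "pooled":
            ax.plot(r["estimate"], y, "D", color="tab:red", ms=6)
    ax.axvline(0.0, color="0.7", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels(table["label"])
    ax.set_xlabel(xlabel)
    ax.figure.tight_layout()
    return ax.figure
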