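"""Individualized treatment-effect prediction from pooled results.

A prediction equation combines the pooled reference treatment effect
beta2 (the summary effect for an individual at the reference covariate
value) with the pooled spline-interaction coefficients:

    effect(z) = beta2 + sum_m gamma_m * (basis_m(z) - basis_m(reference)).

The basis values at the reference are the equation's centering
constants, so the prediction at the reference equals beta2 exactly.
When the interaction coefficients come from a pooling that ignores
their correlation with the per-trial reference effects, the equation is
free of aggregation bias in its interaction part (``debias=True``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .meta import MultiMetaResult
from .splines import SplineBasisSpec, rcs_basis

__all__ = ["PredictionEquation", "build_prediction_equation", "predict_effect"]


@dataclass
class PredictionEquation:
    """Pooled prediction equation for an individual's treatment effect."""

    beta2: float
    gammas: np.ndarray
    spec: SplineBasisSpec
    cov: np.ndarray  # (1+M, 1+M) covariance of (beta2, gammas)
    debias: bool = False
    data_range: tuple[float, float] | None = None

    def __post_init__(self):
        self.gammas = np.asarray(self.gammas, dtype=float)
        if self.spec.reference is None:
            raise ValueError("spec must define a reference value")
        if len(self.gammas) != self.spec.n_basis:
            raise ValueError(
                f"{len(self.gammas)} interaction coefficients for a basis of "
                f"{self.spec.n_basis} columns"
            )
        self.cov = np.asarray(self.cov, dtype=float)

    @property
    def centering(self) -> np.ndarray:
        """Basis values at the reference (e.g. 55 and 3.16 for age with
        knots 39/60/75 and reference 55)."""
        return rcs_basis(self.spec.reference, self.spec)[0]

    def predict(self, values, level: float = 0.95) -> pd.DataFrame:
        """Predicted treatment effect (and delta-rule CI) per covariate value.

        The curve is treated as fixed at the pooled coefficients; the CI
        reflects their sampling covariance only.  Values outside the
        observed covariate range are flagged ``extrapolated``.
        """
        values = np.atleast_1d(np.asarray(values, dtype=float))
        D = rcs_basis(values, self.spec) - self.centering
        A = np.concatenate([np.ones((len(values), 1)), D], axis=1)
        est = A @ np.concatenate([[self.beta2], self.gammas])
        var = np.einsum("ij,jk,ik->i", A, self.cov, A)
        se = np.sqrt(np.clip(var, 0.0, None))
        z = stats.norm.ppf(0.5 + level / 2)
        if self.data_range is None:
            extrap = np.zeros(len(values), dtype=bool)
        else:
            extrap = (values < self.data_range[0]) | (values > self.data_range[1])
        return pd.DataFrame({
            "x": values, "effect": est, "se": se,
            "low": est - z * se, "high": est + z * se, "extrapolated": extrap,
        })

    def to_json(self) -> str:
        """Serialize so external consumers reproduce predictions bit-exactly."""
        return json.dumps({
            "beta2": self.beta2,
            "gammas": self.gammas.tolist(),
            "knots": list(self.spec.knots),
            "reference": self.spec.reference,
            "centering": self.centering.tolist(),
            "debias": self.debias,
        })


def build_prediction_equation(pooled: MultiMetaResult, spec: SplineBasisSpec,
                              debias_pooled: MultiMetaResult | None = None,
                              data_range=None) -> PredictionEquation:
    """Assemble a prediction equation from a pooled multivariate result.

    ``pooled`` must include the reference treatment-effect component
    (beta2) ahead of the spline-interaction coefficients.  When
    ``debias_pooled`` (an interaction-only pooling that ignores any
    correlation with the per-trial reference effects) is supplied, its
    coefficients replace the interaction terms; beta2 is kept from the
    correlated pooling and the cross-covariance is set to zero,
    consistent with the interaction terms borrowing nothing through
    beta2.
    """
    M = spec.n_basis
    if len(pooled.coef) != 1 + M:
        raise ValueError(
            "pooled result must contain the reference treatment effect plus "
            f"{M} interaction components; got {len(pooled.coef)}"
        )
    beta2 = float(pooled.coef[0])
    if debias_pooled is None:
        return PredictionEquation(beta2, pooled.coef[1:].copy(),
                                  spec, pooled.cov.copy(), debias=False,
                                  data_range=data_range)
    if len(debias_pooled.coef) != M:
        raise ValueError(
            f"debias_pooled must contain exactly the {M} interaction components"
        )
    cov = np.zeros((1 + M, 1 + M))
    cov[0, 0] = pooled.cov[0, 0]
    cov[1:, 1:] = debias_pooled.cov
    return PredictionEquation(beta2, debias_pooled.coef.copy(), spec, cov,
                              debias=True, data_range=data_range)


def predict_effect(eq: PredictionEquation, value: float, level: float = 0.95):
    """Point prediction and CI at one covariate value."""
    row = eq.predict([value], level=level).iloc[0]
    return float(row["effect"]), (float(row["low"]), float(row["high"]))
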