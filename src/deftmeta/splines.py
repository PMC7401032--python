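"""Restricted cubic splines for nonlinear treatment-covariate interactions.

A restricted cubic spline (RCS) is a piecewise-cubic function that is
constrained to be linear beyond its boundary knots.  With K knots the
basis has K-1 columns: the covariate itself plus K-2 nonlinear terms
built from truncated third powers.  The cubic terms are normalized by
the squared distance between the outer knots, so the nonlinear columns
are on a scale comparable to the linear one.

When the same knots are used in every trial of an individual participant
data (IPD) meta-analysis, the per-trial spline coefficients are
combinable across trials, which is what makes the two-stage multivariate
pooling of interaction curves possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SplineBasisSpec", "rcs_basis", "default_knots", "summary_curve"]

# Harrell's recommended knot quantiles by number of knots.
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


@dataclass(frozen=True)
class SplineBasisSpec:
    """Knots and reference value defining an RCS basis.

    Parameters
    ----------
    knots : tuple of float
        Strictly increasing, length K >= 3.  The basis has K-1 columns.
    reference : float, optional
        Covariate value at which treatment-effect curves are anchored
        (the "reference individual").  Must lie within [knots[0], knots[-1]].
    """

    knots: tuple[float, ...]
    reference: float | None = None

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 3:
            raise ValueError("an RCS basis needs at least 3 knots")
        if not np.all(np.diff(knots) > 0):
            raise ValueError(f"knots must be strictly increasing, got {knots}")
        if self.reference is not None:
            if not (knots[0] <= self.reference <= knots[-1]):
                raise ValueError(
                    f"reference value {self.reference} lies outside the knot "
                    f"span [{knots[0]}, {knots[-1]}]"
                )

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 1

    def basis_names(self, covariate: str = "z") -> list[str]:
        return [covariate] + [
            f"{covariate}_rcs{m}" for m in range(1, len(self.knots) - 1)
        ]


def rcs_basis(x, spec: SplineBasisSpec) -> np.ndarray:
    """Evaluate the restricted cubic spline basis.

    Column 0 is ``x`` itself; nonlinear column m (m = 1..K-2) is

        [(x-k_m)+^3 - (x-k_{K-1})+^3 (k_K-k_m)/(k_K-k_{K-1})
                    + (x-k_K)+^3 (k_{K-1}-k_m)/(k_K-k_{K-1})] / (k_K-k_1)^2

    which makes the function linear outside [k_1, k_K] with continuous
    first and second derivatives at every knot.

    Parameters
    ----------
    x : array_like or scalar
    spec : SplineBasisSpec

    Returns
    -------
    ndarray of shape (n, K-1); a 1-d input of shape () returns (1, K-1).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    k = np.asarray(spec.knots)
    K = len(k)
    norm = (k[-1] - k[0]) ** 2

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    denom = k[-1] - k[-2]
    for m in range(K - 2):
        term = (
            pos3(x - k[m])
            - pos3(x - k[-2]) * (k[-1] - k[m]) / denom
            + pos3(x - k[-1]) * (k[-2] - k[m]) / denom
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def default_knots(values, n_knots: int = 3) -> tuple[float, ...]:
    """Place knots at Harrell's recommended quantiles of the pooled covariate.

    Knots are shared across all trials (placement on the pooled
    distribution), so per-trial spline coefficients refer to the same
    basis and can be meta-analyzed.

    Raises
    ------
    ValueError
        If ``n_knots`` is unsupported or ties collapse adjacent knots.
    """
    if n_knots not in _KNOT_QUANTILES:
        raise ValueError(f"n_knots must be one of {sorted(_KNOT_QUANTILES)}")
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(np.unique(values)) < n_knots:
        raise ValueError(
            f"need at least {n_knots} distinct covariate values to place knots"
        )
    knots = tuple(np.quantile(values, _KNOT_QUANTILES[n_knots]))
    if not np.all(np.diff(knots) > 0):
        raise ValueError(
            "tied quantiles collapse adjacent knots; reduce the number of knots"
        )
    return knots


def summary_curve(
    pooled,
    spec: SplineBasisSpec,
    grid=None,
    data_range: tuple[float, float] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Difference-in-treatment-effect curve versus the reference individual.

    For each grid value x the curve is

        d(x) = sum_m gamma_m * (basis_m(x) - basis_m(reference)),

    i.e. the pooled change in treatment effect for an individual with
    covariate x relative to one at the reference value; the pointwise CI
    follows from the pooled coefficient covariance by the delta rule.
    The curve and its CI width are exactly zero at the reference.

    Parameters
    ----------
    pooled : MultiMetaResult
        Pooled spline-interaction coefficients (components named after
        the basis; a reference treatment-effect component, if present,
        is excluded from the curve).
    spec : SplineBasisSpec
        Must carry a reference value.
    grid : array_like, optional
        Covariate values; default 100 points spanning the knot range.
    data_range : (low, high), optional
        Observed covariate range; grid values outside it are flagged
        ``extrapolated``.

    Returns
    -------
    DataFrame with columns x, estimate, se, low, high, extrapolated.
    """
    from scipy import stats

    if spec.reference is None:
        raise ValueError("spec must define a reference value for summary_curve")
    gammas, cov = _interaction_block(pooled, spec)
    if grid is None:
        grid = np.linspace(spec.knots[0], spec.knots[-1], 100)
    grid = np.atleast_1d(np.asarray(grid, dtype=float))

    B = rcs_basis(grid, spec) - rcs_basis(spec.reference, spec)
    est = B @ gammas
    var = np.einsum("ij,jk,ik->i", B, cov, B)
    se = np.sqrt(np.clip(var, 0.0, None))
    z = stats.norm.ppf(0.5 + level / 2)
    if data_range is None:
        extrapolated = np.zeros(len(grid), dtype=bool)
    else:
        extrapolated = (grid < data_range[0]) | (grid > data_range[1])
    return pd.DataFrame(
        {
            "x": grid,
            "estimate": est,
            "se": se,
            "low": est - z * se,
            "high": est + z * se,
            "extrapolated": extrapolated,
        }
    )


def _interaction_block(pooled, spec: SplineBasisSpec):
    """Extract the spline-interaction coefficients (dropping any reference
    treatment-effect component) from a MultiMetaResult-like object."""
    coef = np.asarray(pooled.coef, dtype=float)
    cov = np.asarray(pooled.cov, dtype=float)
    names = list(getattr(pooled, "names", range(len(coef))))
    n_gam = spec.n_basis
    if len(coef) == n_gam:
        return coef, cov
    if len(coef) == n_gam + 1:
        # leading component is the reference treatment effect
        return coef[1:], cov[1:, 1:]
    raise ValueError(
        f"pooled result has {len(coef)} components {names}; expected "
        f"{n_gam} interaction terms (optionally preceded by the reference effect)"
    )
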