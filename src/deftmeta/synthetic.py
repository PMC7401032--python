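"""Synthetic IPD with the statistical structure the interaction models
assume.

The generator emulates a collection of parallel-group randomized trials
with trial-specific covariate distributions, trial-specific intercepts,
a true within-trial interaction gamma_W (optionally heterogeneous
across trials, tau^2), and an across-trial coefficient gamma_A linking
the trial-level treatment effect to the trial's covariate mean.
Setting gamma_A != gamma_W creates aggregation-bias scenarios in which
deft and deluded estimators separate.

Default conditions are an antihypertensive-like setting: 10 trials of
200 participants randomized 1:1, an SBP-like continuous outcome
(residual SD 10 mmHg, reference treatment effect -10 mmHg), an age-like
covariate with trial means spread over 45-75 years (SD 10), and a
within-trial interaction of -0.1 mmHg per year.

The participant-level linear predictor is

    alpha_i + beta_z z + beta_0 y0
        + x * (phi + gamma_A (zbar_i - mean(zbar)) + gamma_Wi (z - zbar_i))

with gamma_Wi ~ N(gamma_W, tau^2); the across-trial term is
parameterized on centered trial means so phi keeps its interpretation
as the summary treatment effect at the average trial.  Outcomes are
Gaussian, Bernoulli-logit, or exponential survival times with uniform
administrative censoring, per ``outcome_type``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import IPDDataset
from .splines import SplineBasisSpec, rcs_basis

__all__ = ["SynthConfig", "generate_ipd", "generate_nonlinear_ipd"]


@dataclass(frozen=True)
class SynthConfig:
    """Scenario parameters for the synthetic IPD generator."""

    n_trials: int = 10
    n_per_trial: int | tuple[int, ...] = 200
    allocation: float = 0.5  # treated fraction
    outcome_type: str = "continuous"
    covariate: str = "age"

    gamma_w: float = -0.1           # within-trial interaction, per unit covariate
    tau2: float = 0.0               # between-trial variance of gamma_Wi
    gamma_a: float | None = None    # across-trial trend; None -> equals gamma_w
    phi: float = -10.0              # treatment effect at the average trial, ref covariate
    beta_z: float = 0.5             # prognostic covariate effect
    beta_baseline: float = 0.5
    alpha_sd: float = 3.0           # spread of trial intercepts

    sigma: float = 10.0             # residual SD (continuous outcome)
    covariate_means: tuple[float, ...] | None = None  # default linspace(45, 75)
    covariate_sd: float = 10.0
    covariate_ranges: tuple[tuple[float, float], ...] | None = None
    binary_covariate: bool = False
    prevalences: tuple[float, ...] | None = None  # default spread 0.23-0.70

    with_baseline: bool = True
    baseline_mean: float = 150.0
    baseline_sd: float = 15.0

    # binary outcome (the linear predictor is then on the logit scale)
    # survival outcome
    base_rate: float = 0.1
    censor_time: float = 10.0

    def sizes(self) -> np.ndarray:
        if np.isscalar(self.n_per_trial):
            return np.full(self.n_trials, int(self.n_per_trial))
        n = np.asarray(self.n_per_trial, dtype=int)
        if len(n) != self.n_trials:
            raise ValueError("n_per_trial length must equal n_trials")
        return n

    def trial_means(self) -> np.ndarray:
        if self.binary_covariate:
            prev = (np.linspace(0.23, 0.70, self.n_trials)
                    if self.prevalences is None else np.asarray(self.prevalences))
            if np.any((prev <= 0) | (prev >= 1)):
                raise ValueError("prevalences must lie in (0, 1)")
            return prev
        if self.covariate_means is None:
            return np.linspace(45.0, 75.0, self.n_trials)
        m = np.asarray(self.covariate_means, dtype=float)
        if len(m) != self.n_trials:
            raise ValueError("covariate_means length must equal n_trials")
        return m

    def __post_init__(self):
        if self.sigma <= 0 or self.covariate_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("all SDs must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if not 0 < self.allocation < 1:
            raise ValueError("allocation must be in (0, 1)")


def _draw_covariate(rng, cfg: SynthConfig, i: int, n: int, means) -> np.ndarray:
    if cfg.binary_covariate:
        return (rng.random(n) < means[i]).astype(float)
    z = rng.normal(means[i], cfg.covariate_sd, size=n)
    if cfg.covariate_ranges is not None:
        low, high = cfg.covariate_ranges[i]
        for _ in range(200):
            bad = (z < low) | (z > high)
            if not bad.any():
                break
            z[bad] = rng.normal(means[i], cfg.covariate_sd, size=bad.sum())
        z = np.clip(z, low, high)
    return z


def _assemble(rng, cfg: SynthConfig, interaction_fn) -> IPDDataset:
    """Common machinery: ``interaction_fn(i, z, zbar_i)`` returns the
    participant-level contribution of the interaction to the treatment
    effect (already including any per-trial random deviation)."""
    sizes = cfg.sizes()
    means = cfg.trial_means()
    grand = float(np.mean(means))
    alphas = rng.normal(0.0, cfg.alpha_sd, size=cfg.n_trials)
    rows = []
    for i in range(cfg.n_trials):
        n = int(sizes[i])
        z = _draw_covariate(rng, cfg, i, n, means)
        n_treat = int(round(cfg.allocation * n))
        x = np.zeros(n)
        x[rng.permutation(n)[:n_treat]] = 1.0
        effect = cfg.phi + (cfg.gamma_a if cfg.gamma_a is not None else cfg.gamma_w) \
            * (means[i] - grand) + interaction_fn(i, z, means[i])
        lp = alphas[i] + cfg.beta_z * z + x * effect
        rec = {
            "trial": np.repeat(f"T{i + 1:02d}", n),
            "arm": x.astype(int),
            cfg.covariate: z,
        }
        if cfg.with_baseline and cfg.outcome_type != "time_to_event":
            y0 = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
            lp = lp + cfg.beta_baseline * (y0 - cfg.baseline_mean)
            rec["baseline"] = y0
        if cfg.outcome_type == "continuous":
            rec["y"] = lp + rng.normal(0.0, cfg.sigma, size=n)
        elif cfg.outcome_type == "binary":
            p = 1.0 / (1.0 + np.exp(-lp))
            rec["y"] = (rng.random(n) < p).astype(int)
        elif cfg.outcome_type == "time_to_event":
            rate = cfg.base_rate * np.exp(lp)
            t = rng.exponential(1.0 / np.clip(rate, 1e-12, None))
            c = rng.uniform(0.0, cfg.censor_time, size=n)
            rec["time"] = np.minimum(t, c)
            rec["event"] = (t <= c).astype(int)
        else:
            raise ValueError(f"unknown outcome_type {cfg.outcome_type!r}")
        rows.append(pd.DataFrame(rec))
    df = pd.concat(rows, ignore_index=True)
    return IPDDataset(df, cfg.outcome_type, [cfg.covariate])


def generate_ipd(cfg: SynthConfig, seed: int | np.random.Generator = 0) -> IPDDataset:
    """Generate a linear-interaction IPD dataset; bit-identical under a
    fixed seed and config."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gammas = {}

    def interaction(i, z, zbar_i):
        if i not in gammas:
            gammas[i] = cfg.gamma_w + (np.sqrt(cfg.tau2) * rng.standard_normal()
                                       if cfg.tau2 > 0 else 0.0)
        return gammas[i] * (z - zbar_i)

    return _assemble(rng, cfg, interaction)


def generate_nonlinear_ipd(cfg: SynthConfig, truth_spec: SplineBasisSpec,
                           truth_coefs, seed: int | np.random.Generator = 0) -> IPDDataset:
    """Generate IPD whose treatment-covariate interaction follows a stored
    restricted-cubic-spline curve: the treatment effect for covariate z is

        phi + sum_m coef_m * (basis_m(z) - basis_m(reference)),

    so the effect at the reference equals phi.  Trials may be given
    narrow covariate windows (``covariate_ranges``) to exercise pooling
    with masked spline components."""
    if truth_spec.reference is None:
        raise ValueError("truth_spec must define a reference value")
    coefs = np.asarray(truth_coefs, dtype=float)
    if len(coefs) != truth_spec.n_basis:
        raise ValueError(
            f"truth_coefs must have {truth_spec.n_basis} entries for this basis"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ref_basis = rcs_basis(truth_spec.reference, truth_spec)

    def interaction(i, z, zbar_i):
        B = rcs_basis(z, truth_spec) - ref_basis
        return B @ coefs

    cfg = replace(cfg, gamma_a=0.0)  # the curve carries the whole interaction
    return _assemble(rng, cfg, interaction)
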