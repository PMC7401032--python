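"""Participant-level data model for IPD meta-analysis of treatment-covariate
interactions.

The canonical in-memory container is :class:`IPDDataset`: a long-format
pandas DataFrame with one row per participant, a trial identifier, a 0/1
treatment arm, an outcome (continuous value, 0/1 event, or time+event
pair), an optional baseline outcome value, and named covariate columns.
Validation happens at construction; trials that cannot contribute
within-trial interaction information (single arm, constant covariate)
are flagged rather than silently used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOME_TYPES",
    "ColumnMap",
    "IPDDataset",
    "load_ipd",
    "summarize_trials",
]

OUTCOME_TYPES = ("continuous", "binary", "time_to_event")


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from role names to source-file column headers."""

    trial: str = "trial"
    arm: str = "arm"
    outcome: str | None = "y"
    time: str | None = None
    event: str | None = None
    baseline: str | None = None
    covariates: tuple[str, ...] = ()

    def required_roles(self, outcome_type: str) -> dict[str, str | None]:
        roles = {"trial": self.trial, "arm": self.arm}
        if outcome_type == "time_to_event":
            roles["time"] = self.time
            roles["event"] = self.event
        else:
            roles["outcome"] = self.outcome
        return roles


class IPDDataset:
    """Validated participant-level rows from a set of parallel-group trials.

    Parameters
    ----------
    df : DataFrame
        Canonical columns: ``trial``, ``arm`` (0 control / 1 treatment),
        then ``y`` (continuous or binary outcome) or ``time``+``event``
        (time-to-event), optional ``baseline``, plus covariate columns.
    outcome_type : {"continuous", "binary", "time_to_event"}
    covariates : sequence of str
        Covariate column names in ``df``.

    Attributes
    ----------
    problems : list of str
        Human-readable warnings collected at validation time (single-arm
        trials, dropped rows, ...).  Trials with problems remain in the
        data but are excluded by :meth:`usable_trials`.
    """

    def __init__(self, df: pd.DataFrame, outcome_type: str, covariates=(),
                 baseline: bool | None = None):
        if outcome_type not in OUTCOME_TYPES:
            raise ValueError(
                f"outcome_type must be one of {OUTCOME_TYPES}, got {outcome_type!r}"
            )
        df = df.copy()
        self.outcome_type = outcome_type
        self.covariates = list(covariates)
        self.problems: list[str] = []

        required = ["trial", "arm"]
        required += ["time", "event"] if outcome_type == "time_to_event" else ["y"]
        for col in required + self.covariates:
            if col not in df.columns:
                raise ValueError(f"required column {col!r} missing from data")
        if baseline is None:
            baseline = "baseline" in df.columns
        self.has_baseline = bool(baseline)

        n_missing_core = df[required].isna().any(axis=1).sum()
        if n_missing_core:
            self.problems.append(
                f"dropped {n_missing_core} rows missing trial, arm or outcome"
            )
            df = df.dropna(subset=required)

        arm_vals = set(pd.unique(df["arm"]))
        if not arm_vals <= {0, 1}:
            raise ValueError(
                f"column 'arm' must be coded 0 (control) / 1 (treatment); "
                f"found values {sorted(arm_vals)}"
            )
        df["arm"] = df["arm"].astype(int)
        if outcome_type == "binary":
            yv = set(pd.unique(df["y"].dropna()))
            if not yv <= {0, 1}:
                raise ValueError(
                    f"binary outcome 'y' must be coded 0/1; found {sorted(yv)}"
                )
            df["y"] = df["y"].astype(int)
        if outcome_type == "time_to_event":
            if (df["time"] <= 0).any():
                raise ValueError("event times must be strictly positive")
            ev = set(pd.unique(df["event"].dropna()))
            if not ev <= {0, 1}:
                raise ValueError(f"'event' must be coded 0/1; found {sorted(ev)}")
            df["event"] = df["event"].astype(int)

        self.df = df.reset_index(drop=True)
        self._check_arms()

    # -- structure ---------------------------------------------------------

    @property
    def trials(self) -> list:
        return list(pd.unique(self.df["trial"]))

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def __len__(self) -> int:
        return len(self.df)

    def trial_data(self, trial_id) -> pd.DataFrame:
        return self.df[self.df["trial"] == trial_id]

    def _check_arms(self) -> None:
        self._single_arm: set = set()
        for tid, g in self.df.groupby("trial", sort=False):
            arms = set(g["arm"])
            if arms != {0, 1}:
                self._single_arm.add(tid)
                self.problems.append(
                    f"trial {tid!r} has participants in only one arm; "
                    "unusable for within-trial interaction fitting"
                )

    def usable_trials(self, covariate: str | None = None) -> list:
        """Trials with both arms and, if given, within-trial covariate
        variation -- the trials that carry within-trial interaction
        information."""
        out = []
        for tid in self.trials:
            if tid in self._single_arm:
                continue
            if covariate is not None:
                z = self.trial_data(tid)[covariate].dropna()
                if len(z) < 2 or float(np.var(z)) == 0.0:
                    continue
            out.append(tid)
        return out

    def covariate_missingness(self) -> pd.Series:
        return self.df[self.covariates].isna().sum() if self.covariates else pd.Series(dtype=int)

    # -- IO ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def load_report(self) -> str:
        lines = [
            f"IPD dataset: {self.n_trials} trials, {len(self)} participants, "
            f"outcome_type={self.outcome_type}",
        ]
        for tid, g in self.df.groupby("trial", sort=False):
            n_t = int((g["arm"] == 1).sum())
            n_c = int((g["arm"] == 0).sum())
            line = f"  trial {tid}: n={len(g)} (treat {n_t} / control {n_c})"
            for cov in self.covariates:
                z = g[cov].dropna()
                if len(z):
                    line += f"; {cov} mean={z.mean():.3g} sd={z.std(ddof=1):.3g}"
            lines.append(line)
        lines += [f"  note: {p}" for p in self.problems]
        return "\n".join(lines)


def load_ipd(path, column_map: ColumnMap | None = None,
             outcome_type: str = "continuous", sep: str | None = None,
             categorical_reference: dict | None = None) -> IPDDataset:
    """Read a delimited participant-level file into a validated IPDDataset.

    Categorical (non-numeric) covariates are expanded to 0/1 indicator
    columns with a declared reference level (default: the
    lexicographically first level), and the interaction is then
    estimable per indicator.

    Parameters
    ----------
    path : str or file
    column_map : ColumnMap
        Roles required by ``outcome_type`` must be mapped and exist in
        the file header.
    outcome_type : {"continuous", "binary", "time_to_event"}
    sep : str, optional
        Field delimiter; sniffed by pandas when omitted.
    categorical_reference : dict, optional
        ``{covariate: reference_level}`` for indicator coding.
    """
    column_map = column_map or ColumnMap()
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")

    roles = column_map.required_roles(outcome_type)
    rename = {}
    for role, col in roles.items():
        if col is None:
            raise ValueError(f"column_map does not map required role {role!r}")
        if col not in raw.columns:
            raise ValueError(f"mapped column {col!r} (role {role!r}) not in file")
        rename[col] = role if role != "outcome" else "y"
    if column_map.baseline is not None:
        if column_map.baseline not in raw.columns:
            raise ValueError(f"mapped baseline column {column_map.baseline!r} not in file")
        rename[column_map.baseline] = "baseline"
    for cov in column_map.covariates:
        if cov not in raw.columns:
            raise ValueError(f"mapped covariate column {cov!r} not in file")

    df = raw.rename(columns=rename)
    covariates = list(column_map.covariates)

    # indicator-code categorical covariates
    categorical_reference = categorical_reference or {}
    for cov in list(covariates):
        if not pd.api.types.is_numeric_dtype(df[cov]):
            levels = sorted(df[cov].dropna().unique())
            ref = categorical_reference.get(cov, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not a level of {cov!r}")
            covariates.remove(cov)
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{cov}_{lev}"
                df[name] = (df[cov] == lev).astype(float)
                covariates.append(name)
            df = df.drop(columns=cov)

    keep = ["trial", "arm"]
    keep += ["time", "event"] if outcome_type == "time_to_event" else ["y"]
    if "baseline" in df.columns:
        keep.append("baseline")
    keep += covariates
    return IPDDataset(df[keep], outcome_type, covariates)


def summarize_trials(ds: IPDDataset, covariate: str, ddof: int = 1) -> pd.DataFrame:
    """Per-trial planning summaries: sizes, covariate moments, outcome spread.

    ``ddof=1`` gives the sample (n-1) variance convention used for
    reporting and as sigma_z^2 in power inputs; set ``ddof=0`` for the
    population convention.

    Trials where the covariate is all-missing or constant are emitted
    with a ``flag`` rather than raising.
    """
    if covariate not in ds.df.columns:
        raise ValueError(f"covariate {covariate!r} not in dataset")
    rows = []
    for tid, g in ds.df.groupby("trial", sort=False):
        z = g[covariate].dropna().astype(float)
        rec = {
            "trial": tid,
            "n": len(g),
            "n_treat": int((g["arm"] == 1).sum()),
            "n_control": int((g["arm"] == 0).sum()),
            "mean_covariate": z.mean() if len(z) else np.nan,
            "var_covariate": z.var(ddof=ddof) if len(z) > ddof else np.nan,
            "flag": "",
        }
        if len(z) == 0:
            rec["flag"] = "covariate all missing"
        elif len(z) <= ddof:
            rec["flag"] = "too few observations for variance"
        elif rec["var_covariate"] == 0:
            rec["flag"] = "constant covariate: no within-trial interaction information"
        if ds.outcome_type == "continuous":
            rec["mean_outcome"] = g["y"].mean()
            rec["sd_outcome"] = g["y"].std(ddof=ddof) if len(g) > ddof else np.nan
        elif ds.outcome_type == "binary":
            rec["events"] = int(g["y"].sum())
        else:
            rec["events"] = int(g["event"].sum())
        rows.append(rec)
    return pd.DataFrame(rows)
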