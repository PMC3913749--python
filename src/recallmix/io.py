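"""Reading and writing the delimited-text tables the pipeline exchanges.

One flat comma-separated trial table (UTF-8, one header line) holds the
whole cohort; angles are stored in radians by default, with an explicit
degrees dialect for files whose feature columns are recorded in degrees
(orientation in [0, 180) mapped through the double-angle transform, colour
as a hue angle in [0, 360)).  Malformed rows are collected into an error
report with their line numbers rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
from collections import namedtuple

import numpy as np
import pandas as pd
import yaml

from .circstats import orientation_to_angle, wrap
from .simulate import CohortSpec, TRIAL_COLUMNS

__all__ = [
    "RunConfig",
    "TrialTableResult",
    "read_trial_table",
    "write_trial_table",
    "read_estimates",
    "write_manifest",
    "read_manifest",
]

ANGLE_COLUMNS = ["target", "nontarget1", "nontarget2", "response"]

TrialTableResult = namedtuple("TrialTableResult", ["trials", "errors"])


@dataclasses.dataclass
class RunConfig:
    """Run settings: every stochastic stage's seed is recorded here so a run
    is exactly reproducible from its saved configuration."""

    seed: int = 0
    n_starts: int = 6
    tol: float = 1e-6
    max_iter: int = 10_000
    n_chance_reps: int = 10_000
    cohort: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _convert_degrees(df: pd.DataFrame) -> pd.DataFrame:
    """Map degree-valued feature columns onto wrapped radians in place."""
    out = df.copy()
    ori = out["dimension"] == "orientation"
    for col in ANGLE_COLUMNS:
        vals = out[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        conv = np.full_like(vals, np.nan)
        o = ori.to_numpy() & ok
        c = ~ori.to_numpy() & ok
        if o.any():
            conv[o] = orientation_to_angle(np.mod(vals[o], 180.0))
        if c.any():
            conv[c] = wrap(np.deg2rad(vals[c]))
        out[col] = conv
    return out


def read_trial_table(path, units: str = "radians", strict: bool = False) -> TrialTableResult:
    """Read and validate a trial table.

    Angles are wrapped on load.  ``units='degrees'`` maps orientation rows
    through the double-angle transform and colour rows from hue degrees.
    Returns ``(trials, errors)`` where ``errors`` lists malformed rows
    (1-based file line numbers, data lines start at 2); ``strict=True``
    raises instead when any row is malformed.  A missing required column is
    always a hard failure.
    """
    if units not in ("radians", "degrees"):
        raise ValueError("units must be 'radians' or 'degrees'")
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing required column(s): {missing}")

    errors = []
    for col in ANGLE_COLUMNS + ["age", "exposure_ms", "load", "trial"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        for i in df.index[bad]:
            errors.append({"line": int(i) + 2, "column": col, "value": df.loc[i, col]})
        df[col] = coerced

    # low-load rows may have empty nontargets; anything else must be numeric
    need = df["load"] != 1
    for col in ["target", "response"]:
        bad = df[col].isna()
        for i in df.index[bad]:
            errors.append({"line": int(i) + 2, "column": col, "value": "missing"})
    for col in ["nontarget1", "nontarget2"]:
        bad = df[col].isna() & need
        for i in df.index[bad]:
            errors.append({"line": int(i) + 2, "column": col, "value": "missing"})

    if errors and strict:
        raise ValueError(f"{len(errors)} malformed value(s); first: {errors[0]}")
    bad_lines = {e["line"] - 2 for e in errors}
    df = df.drop(index=[i for i in bad_lines if i in df.index]).reset_index(drop=True)

    if units == "degrees":
        df = _convert_degrees(df)
    else:
        for col in ANGLE_COLUMNS:
            vals = df[col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            vals[ok] = wrap(vals[ok])
            df[col] = vals
    return TrialTableResult(df[TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]], pd.DataFrame(errors))


def write_trial_table(trials: pd.DataFrame, path):
    """Write a trial table as comma-separated text with full float precision."""
    trials.to_csv(path, index=False, float_format="%.17g")


def read_estimates(path) -> pd.DataFrame:
    """Read a subject-estimates table, checking the core columns exist."""
    df = pd.read_csv(path)
    required = ["subject_id", "dimension", "load", "alpha", "beta", "gamma", "sigma"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"estimates table is missing required column(s): {missing}")
    return df


def write_manifest(spec: CohortSpec, path):
    """Record a cohort's generative description (including seed) for exact regeneration."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_manifest(), fh, sort_keys=False)


def read_manifest(path) -> CohortSpec:
    with open(path) as fh:
        return CohortSpec.from_manifest(yaml.safe_load(fh))
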