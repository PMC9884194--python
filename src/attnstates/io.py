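"""Validated CSV readers/writers for the pipeline's table schemas.

Schemas (UTF-8, '.' decimal, missing values as empty fields):

* trials:  participant, block, trial, stimulus, responded, rt_s, correct
* probes:  participant, block, trial_position, task_focus, task_related,
           external, tut
* states:  participant, t, state

Readers validate strictly and report the offending row; writers use a fixed
float format so identical data round-trips to identical bytes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import CHANNELS, LEVELS

TRIAL_COLUMNS = ["participant", "block", "trial", "stimulus",
                 "responded", "rt_s", "correct"]
PROBE_COLUMNS = ["participant", "block", "trial_position", *CHANNELS]
STATE_COLUMNS = ["participant", "t", "state"]

FLOAT_FORMAT = "%.17g"   # round-trips float64 exactly


class ValidationError(ValueError):
    """A table violates its schema; the message names the row."""


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    if list(df.columns) != expected:
        unknown = [c for c in df.columns if c not in expected]
        missing = [c for c in expected if c not in df.columns]
        raise ValidationError(
            f"{what}: bad header; unknown columns {unknown}, "
            f"missing columns {missing}")


def _to_bool(s: pd.Series, what: str, col: str) -> np.ndarray:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    vals = s.astype(str).str.strip().str.lower().map(mapping)
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0])
        raise ValidationError(f"{what}: row {row}: {col!r} is not boolean")
    return vals.to_numpy(dtype=bool)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant": str},
                     float_precision="round_trip")
    _check_columns(df, TRIAL_COLUMNS, "trials")
    df["responded"] = _to_bool(df["responded"], "trials", "responded")
    df["correct"] = _to_bool(df["correct"], "trials", "correct")
    stim = df["stimulus"].to_numpy()
    bad = ~np.isin(stim, np.arange(1, 10))
    if bad.any():
        raise ValidationError(
            f"trials: row {int(np.flatnonzero(bad)[0])}: "
            f"stimulus {stim[bad][0]!r} not a digit 1-9")
    rt = df["rt_s"].to_numpy(dtype=float)
    resp = df["responded"].to_numpy()
    mism = resp != ~np.isnan(rt)
    if mism.any():
        raise ValidationError(
            f"trials: row {int(np.flatnonzero(mism)[0])}: "
            "rt_s must be present iff responded")
    neg = resp & (rt <= 0)
    if np.nansum(neg):
        raise ValidationError(
            f"trials: row {int(np.flatnonzero(neg)[0])}: rt_s must be > 0")
    return df


def read_probes(path, allow_missing: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant": str},
                     float_precision="round_trip")
    _check_columns(df, PROBE_COLUMNS, "probes")
    legal = np.asarray(LEVELS, dtype=float)
    for c in CHANNELS:
        vals = df[c].to_numpy(dtype=float)
        missing = np.isnan(vals)
        if missing.any() and not allow_missing:
            raise ValidationError(
                f"probes: row {int(np.flatnonzero(missing)[0])}: "
                f"{c!r} missing")
        bad = ~missing & ~np.isin(vals, legal)
        if bad.any():
            raise ValidationError(
                f"probes: row {int(np.flatnonzero(bad)[0])}: "
                f"{c!r} = {vals[bad][0]!r} not on the 25% grid")
    return df


def read_states(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant": str},
                     float_precision="round_trip")
    _check_columns(df, STATE_COLUMNS, "states")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a CSV deterministically (fixed float format, no index)."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
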