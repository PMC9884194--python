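"""Trial- and probe-level preprocessing.

Turns raw session tables into analysis inputs: correct-go RT streams,
pre-probe window statistics, the sliding response-time-variability (RTV)
series, cleaned and classified probe reports, and centered predictors.
RTV is the coefficient of variation — sample SD divided by mean — over a
window of correct go-trial RTs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CHANNELS, LEVELS, _cap_total

DEFAULT_WIDTH = 5


class ImputationError(ValueError):
    """Raised when a channel cannot be imputed (all values missing)."""


def extract_correct_go_rts(trials: pd.DataFrame,
                           target_digit: int = 5) -> pd.DataFrame:
    """Return the correct-go RT series with original trial indices.

    A trial contributes iff it is a non-target, a response was made and the
    response was correct; target trials never contribute even if they were
    (incorrectly) responded to.  The returned frame has columns ``t`` (the
    positional index within the session) and ``rt``.
    """
    t = np.arange(len(trials))
    mask = ((trials["stimulus"].to_numpy() != target_digit)
            & trials["responded"].to_numpy()
            & trials["correct"].to_numpy())
    return pd.DataFrame({"t": t[mask], "rt": trials["rt_s"].to_numpy()[mask]})


@dataclass
class WindowStats:
    """Summary of the correct-go RTs immediately preceding a probe."""

    mean_rt: float
    rtv: float
    n_trials: int
    valid: bool


def _cv(rts: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(rts))
    sd = float(np.std(rts, ddof=1))
    return mean, sd / mean


def preprobe_window_stats(trials: pd.DataFrame, probe_position: int,
                          width: int = DEFAULT_WIDTH,
                          target_digit: int = 5) -> WindowStats:
    """Mean RT and RTV over the ``width`` correct-go trials before a probe.

    The window is invalid when fewer than ``width`` correct-go RTs precede
    the probe, or when the go trial immediately preceding the probe was
    answered incorrectly (the correctness gate applied before a probe enters
    the regression).
    """
    if width < 2:
        raise ValueError("width must be >= 2 (SD undefined otherwise)")
    pre = trials.iloc[: probe_position + 1]
    go = pre[pre["stimulus"].to_numpy() != target_digit]
    go_ok = go[go["responded"].to_numpy() & go["correct"].to_numpy()]
    gate = bool(len(go)) and bool(go["correct"].iloc[-1])
    if len(go_ok) < width or not gate:
        return WindowStats(math.nan, math.nan, width, False)
    rts = go_ok["rt_s"].to_numpy()[-width:]
    mean, rtv = _cv(rts)
    return WindowStats(mean, rtv, width, True)


def sliding_rtv_series(trials: pd.DataFrame, width: int = DEFAULT_WIDTH,
                       target_digit: int = 5) -> pd.DataFrame:
    """RTV over every window of ``width`` consecutive correct-go RTs.

    The window advances one correct-go trial at a time, from the first trial
    to the end of the session; the anchor ``t`` of each value is the session
    index of the last trial in its window.  Returns an empty frame (with a
    warning) when fewer than ``width`` correct-go RTs exist.
    """
    go = extract_correct_go_rts(trials, target_digit)
    n = len(go) - width + 1
    if n < 1:
        warnings.warn("fewer correct go RTs than the window width; "
                      "empty RTV series", stacklevel=2)
        return pd.DataFrame({"t": pd.Series(dtype=int),
                             "rtv": pd.Series(dtype=float)})
    rts = go["rt"].to_numpy()
    sw = np.lib.stride_tricks.sliding_window_view(rts, width)
    means = sw.mean(axis=1)
    sds = sw.std(axis=1, ddof=1)
    return pd.DataFrame({"t": go["t"].to_numpy()[width - 1:],
                         "rtv": sds / means})


def _round_to_level(x: float) -> int:
    # round-half-up onto the 0/25/50/75/100 grid
    return int(np.clip(np.floor(x / 25.0 + 0.5), 0, 4)) * 25


def clean_responses(probes: pd.DataFrame,
                    method: str = "linear") -> tuple[pd.DataFrame, dict]:
    """Flag over-100 % probe totals and impute them from neighbouring probes.

    Any probe whose four immersion codes sum to more than 100 has all four
    channels set missing; missing channels are then imputed per participant
    and per channel by linear interpolation over probe order, rounded to the
    nearest legal level, with boundary gaps filled from the nearest probe.
    If rounding pushes an imputed total back above 100 the largest channels
    are stepped down until the total is legal, so cleaning is idempotent.
    """
    if method != "linear":
        raise ValueError(f"unknown imputation method: {method!r}")
    out = probes.copy()
    ch = list(CHANNELS)
    vals = out[ch].astype(float)
    totals = vals.sum(axis=1, skipna=False)
    over = totals > 100
    vals[over.to_numpy()] = np.nan
    n_missing_in = int(vals.isna().to_numpy().sum())

    for _, idx in out.groupby("participant", sort=False).groups.items():
        block = vals.loc[idx]
        if block.isna().all(axis=None):
            raise ImputationError(
                "participant has no observed probe values to impute from")
        for c in ch:
            col = block[c]
            if col.isna().all():
                raise ImputationError(
                    f"channel {c!r} entirely missing for a participant")
            if col.isna().any():
                filled = col.reset_index(drop=True).interpolate(
                    method="linear", limit_direction="both")
                vals.loc[idx, c] = filled.to_numpy()

    imputed = vals.map(_round_to_level).astype(int)
    fix = imputed.sum(axis=1) > 100
    for i in imputed.index[fix]:
        imputed.loc[i] = _cap_total(imputed.loc[i].to_numpy())
    out[ch] = imputed
    report = {
        "n_probes": int(len(out)),
        "n_over_total": int(over.sum()),
        "over_total_rows": out.index[over].tolist(),
        "n_values_imputed": n_missing_in,
        "n_recapped": int(fix.sum()),
    }
    return out, report


@dataclass
class ProbeLabel:
    """Categorical reading of one probe report."""

    category: str              # mind_blank | single_thought | coexistence
    fifty_fifty: bool
    n_nonzero_channels: int
    full_immersion: bool


def classify_probe(probe) -> ProbeLabel:
    """Classify a cleaned probe report.

    mind-blank: every channel 0 %; single thought: exactly one channel at
    25 % or more with the rest 0 %; coexistence: two or more non-zero
    channels.  ``fifty_fifty`` marks the 50/50 split across exactly two
    thoughts; ``full_immersion`` marks any 100 % channel.
    """
    codes = np.asarray([probe[c] for c in CHANNELS], dtype=float)
    if np.isnan(codes).any():
        raise ValueError("classify_probe requires a cleaned probe "
                         "(no missing channels)")
    nz = int((codes > 0).sum())
    if nz == 0:
        cat = "mind_blank"
    elif nz == 1:
        cat = "single_thought"
    else:
        cat = "coexistence"
    fifty = nz == 2 and np.all(np.sort(codes)[-2:] == 50)
    return ProbeLabel(cat, bool(fifty), nz, bool((codes == 100).any()))


def center(values) -> np.ndarray:
    """Subtract the mean; used on predictors before fitting interactions."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot center an empty series")
    return arr - arr.mean()


def summarize_reports(probes: pd.DataFrame) -> dict:
    """Cohort-level report-frequency summary.

    Returns ``level_counts`` — per-channel mean and SD (across participants)
    of the number of probes at each immersion level — and the cohort
    fractions of mind-blank, single-thought, coexistence, fifty-fifty and
    100 %-immersion reports.
    """
    rows = []
    for c in CHANNELS:
        counts = (probes.groupby("participant")[c]
                  .value_counts().unstack(fill_value=0)
                  .reindex(columns=list(LEVELS), fill_value=0))
        for lev in LEVELS:
            rows.append({"channel": c, "level": lev,
                         "mean_count": float(counts[lev].mean()),
                         "sd_count": float(counts[lev].std(ddof=1))
                         if len(counts) > 1 else 0.0})
    labels = [classify_probe(r) for _, r in probes.iterrows()]
    n = len(labels)
    frac = lambda pred: sum(pred(l) for l in labels) / n if n else math.nan
    return {
        "level_counts": pd.DataFrame(rows),
        "fractions": {
            "mind_blank": frac(lambda l: l.category == "mind_blank"),
            "single_thought": frac(lambda l: l.category == "single_thought"),
            "coexistence": frac(lambda l: l.category == "coexistence"),
            "fifty_fifty": frac(lambda l: l.fifty_fifty),
            "full_immersion": frac(lambda l: l.full_immersion),
        },
    }


def rt_bimodality(trials: pd.DataFrame) -> float:
    """Sarle's bimodality coefficient of a participant's correct-go RTs.

    Values above ~0.555 (the uniform-distribution benchmark) suggest a
    bimodal RT distribution; reported as a diagnostic only — no automatic
    exclusion is performed.
    """
    rts = extract_correct_go_rts(trials)["rt"].to_numpy()
    n = len(rts)
    if n < 4:
        return math.nan
    from scipy import stats
    g1 = stats.skew(rts, bias=False)
    g2 = stats.kurtosis(rts, bias=False)
    return float((g1 ** 2 + 1) / (g2 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))))
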