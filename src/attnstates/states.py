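"""Post-decoding analytics for estimated attentional states.

Occupancy (total time per state per participant), transition-persistence
summaries, per-state RTV comparison via a repeated-measures one-way ANOVA
with Tukey HSD, FDR-corrected correlations between the occupancies of the
self-report and RTV state models, and heuristic interpretive labels for
fitted states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .hmm import HmmModel, StateDecoding


@dataclass
class OccupancyTable:
    """Participant x state time-spent table (counts and proportions)."""

    counts: pd.DataFrame       # index participant, columns state 0..K-1
    proportions: pd.DataFrame


def occupancy(decodings: dict[str, StateDecoding], n_states: int,
              mode: str = "viterbi") -> OccupancyTable:
    """Total time each participant spends in each state.

    ``mode='viterbi'`` counts Viterbi-path visits; ``mode='posterior'`` sums
    posterior mass.  Per-participant proportions are normalised to 1.
    """
    rows = {pid: dec.occupancy(n_states, mode)
            for pid, dec in decodings.items()}
    counts = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=range(n_states)).sort_index()
    props = counts.div(counts.sum(axis=1), axis=0)
    return OccupancyTable(counts, props)


def transition_summary(model: HmmModel,
                       persistence_threshold: float = 0.8) -> dict:
    """Transition matrix with per-state persistence diagnostics."""
    A = model.transmat
    persist = np.diag(A)
    return {
        "transmat": A,
        "self_transition": persist,
        "persistent_states": [int(k) for k in np.flatnonzero(
            persist >= persistence_threshold)],
        "threshold": persistence_threshold,
    }


def transition_long(model: HmmModel) -> pd.DataFrame:
    """Transition matrix in long (from_state, to_state, probability) form."""
    K = model.n_states
    i, j = np.meshgrid(range(K), range(K), indexing="ij")
    return pd.DataFrame({"from_state": i.ravel(), "to_state": j.ravel(),
                         "probability": model.transmat.ravel()})


def per_state_rtv(paths: dict[str, np.ndarray],
                  rtv: pd.DataFrame, n_states: int) -> pd.DataFrame:
    """Mean RTV over time points decoded into each state, per participant.

    ``paths`` maps participant to a decoded state path aligned one-to-one
    with that participant's rows of the sliding-RTV table ``rtv``
    (columns participant, t, rtv).  States a participant never visits are
    left missing.
    """
    rows = {}
    for pid, grp in rtv.groupby("participant", sort=True):
        path = np.asarray(paths[str(pid)])
        vals = grp.sort_values("t")["rtv"].to_numpy()
        if len(path) != len(vals):
            raise ValueError(
                f"path/series misalignment for participant {pid!r}: "
                f"{len(path)} states vs {len(vals)} RTV points")
        rows[pid] = {k: float(vals[path == k].mean())
                     if np.any(path == k) else np.nan
                     for k in range(n_states)}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=range(n_states)).sort_index()


@dataclass
class AnovaResult:
    F: float
    df: tuple[float, float]
    p: float
    eta_squared: float
    pairwise: pd.DataFrame   # group1, group2, meandiff, p_adj, lower, upper
    n_complete: int


def rm_anova_tukey(table: pd.DataFrame) -> AnovaResult:
    """Repeated-measures one-way ANOVA across states, then Tukey HSD.

    Rows are participants, columns are states; participants missing any
    state are dropped listwise.  The subject term is removed from the error
    (SS_error = SS_total - SS_subject - SS_state) and the effect size is
    eta^2 = SS_state / SS_total.
    """
    complete = table.dropna(axis=0, how="any")
    n, k = complete.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 complete participants and >= 2 states")
    x = complete.to_numpy(dtype=float)
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_subject = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_state = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_state
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_state, ms_error = ss_state / df1, ss_error / df2
    F = ms_state / ms_error if ms_error > 0 else 0.0
    p = float(stats.f.sf(F, df1, df2)) if ms_error > 0 else 1.0
    eta2 = ss_state / ss_total if ss_total > 0 else 0.0

    long_vals = x.ravel()
    long_groups = np.tile(complete.columns.to_numpy(), n)
    if np.ptp(long_vals) > 0:
        tk = pairwise_tukeyhsd(long_vals, long_groups.astype(str))
        pairwise = pd.DataFrame(tk.summary().data[1:],
                                columns=[str(c) for c in
                                         tk.summary().data[0]])
        pairwise = pairwise.rename(columns={"p-adj": "p_adj"})
    else:
        pairs = [(a, b) for i, a in enumerate(complete.columns)
                 for b in complete.columns[i + 1:]]
        pairwise = pd.DataFrame([
            {"group1": str(a), "group2": str(b), "meandiff": 0.0,
             "p_adj": 1.0, "lower": 0.0, "upper": 0.0, "reject": False}
            for a, b in pairs])
    return AnovaResult(float(F), (df1, df2), p, float(eta2), pairwise, n)


def oneway_anova(table: pd.DataFrame) -> tuple[float, tuple[int, int], float]:
    """Between-style fallback: ordinary one-way ANOVA ignoring the subject term."""
    cols = [table[c].dropna().to_numpy() for c in table.columns]
    F, p = stats.f_oneway(*cols)
    df1 = len(cols) - 1
    df2 = sum(len(c) for c in cols) - len(cols)
    return float(F), (df1, df2), float(p)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def occupancy_correlation(occ_self: OccupancyTable,
                          occ_rtv: OccupancyTable,
                          value: str = "proportions") -> pd.DataFrame:
    """Pearson correlations between self-report and RTV state occupancies.

    One correlation per (self-report state, RTV state) pair across
    participants; all pairs form a single Benjamini–Hochberg family.
    Zero-variance occupancy columns yield missing r (excluded from the BH
    family and reported with missing q).
    """
    a = getattr(occ_self, value)
    b = getattr(occ_rtv, value)
    common = a.index.intersection(b.index)
    if not len(common) == len(a) == len(b):
        raise ValueError("occupancy tables must cover the same participants")
    a, b = a.loc[common], b.loc[common]
    rows = []
    for sa in a.columns:
        for sb in b.columns:
            x, y = a[sa].to_numpy(), b[sb].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"self_state": sa, "rtv_state": sb,
                             "r": np.nan, "p": np.nan})
            else:
                r, p = stats.pearsonr(x, y)
                rows.append({"self_state": sa, "rtv_state": sb,
                             "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def label_states(model: HmmModel, low_level: float = 1.0,
                 high_level: float = 2.5) -> list[str]:
    """Heuristic interpretive labels for a fitted probe-emission model.

    Uses the expected immersion level (0-4 units) per channel: all channels
    below ``low_level`` -> "unfocused"; a dominant task-unrelated-thought
    channel -> "tut"; a strongly dominant task-focus channel
    (>= ``high_level``, i.e. above 50 % on average) with every other channel
    low -> "task_focused"; anything else (e.g. moderate task focus alongside
    non-zero secondary thoughts) -> "mixed".  Labels are interpretive
    conveniences, reported alongside neutral state indices — never a claim
    about ground truth.
    """
    if model.family != "categorical":
        raise ValueError("labels are defined for probe-emission models")
    levels = np.arange(model.emissions.probs.shape[2])
    expect = (model.emissions.probs * levels).sum(axis=2)   # (K, 4)
    labels = []
    for k in range(model.n_states):
        e = expect[k]
        if np.all(e < low_level):
            labels.append("unfocused")
            continue
        dom = int(np.argmax(e))
        if dom == 3:
            labels.append("tut")
        elif dom == 0 and e[0] >= high_level and np.all(e[1:] < low_level):
            labels.append("task_focused")
        else:
            labels.append("mixed")
    return labels
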