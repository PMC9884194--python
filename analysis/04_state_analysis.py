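"""Relate decoded attentional states to behaviour.

Occupancy per state, transition persistence, RTV compared across the
self-report states (repeated-measures ANOVA + Tukey HSD), and the
FDR-corrected grid of correlations between self-report-state and RTV-state
occupancies across participants.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from attnstates import hmm, io, states

ROOT = Path(__file__).resolve().parents[1]


def paths_by_participant(df):
    return {str(p): g.sort_values("t")["state"].to_numpy()
            for p, g in df.groupby("participant", sort=True)}


def main(outdir: Path) -> None:
    out = outdir / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    model_probe = hmm.HmmModel.from_json(
        outdir / "hmm" / "model_selfreport.json")
    model_rtv = hmm.HmmModel.from_json(outdir / "hmm" / "model_rtv.json")
    paths_probe = paths_by_participant(
        pd.read_csv(outdir / "hmm" / "paths_selfreport.csv",
                    dtype={"participant": str}))
    paths_rtv = paths_by_participant(
        pd.read_csv(outdir / "hmm" / "paths_rtv.csv",
                    dtype={"participant": str}))
    window_stats = pd.read_csv(outdir / "preprocess" / "window_stats.csv",
                               dtype={"participant": str})

    k_probe, k_rtv = model_probe.n_states, model_rtv.n_states
    dec_probe = {p: hmm.StateDecoding(np.eye(k_probe)[v], v)
                 for p, v in paths_probe.items()}
    dec_rtv = {p: hmm.StateDecoding(np.eye(k_rtv)[v], v)
               for p, v in paths_rtv.items()}
    occ_s = states.occupancy(dec_probe, k_probe)
    occ_r = states.occupancy(dec_rtv, k_rtv)
    for occ, name in ((occ_s, "selfreport"), (occ_r, "rtv")):
        wide = occ.counts.copy()
        wide.insert(0, "participant", wide.index)
        io.write_table(wide.reset_index(drop=True),
                       out / f"occupancy_{name}.csv")
        io.write_table(states.transition_long(
            model_probe if name == "selfreport" else model_rtv),
            out / f"transitions_{name}.csv")

    ts = states.transition_summary(model_probe)
    print("self-report transition persistence:",
          np.round(ts["self_transition"], 2).tolist(),
          "| mean occupancy:",
          np.round(occ_s.proportions.mean().to_numpy(), 3).tolist())

    # RTV per self-report state over valid pre-probe windows
    valid = window_stats[window_stats["valid"]]
    pre = valid.rename(columns={"trial_position": "t"})[
        ["participant", "t", "rtv"]]
    masked = {}
    for pid, grp in window_stats.groupby("participant", sort=True):
        masked[str(pid)] = paths_probe[str(pid)][grp["valid"].to_numpy()]
    pivot = states.per_state_rtv(masked, pre, k_probe)
    wide = pivot.copy()
    wide.insert(0, "participant", wide.index)
    io.write_table(wide.reset_index(drop=True), out / "per_state_rtv.csv")

    an = states.rm_anova_tukey(pivot)
    with open(out / "anova.json", "w") as fh:
        json.dump({"F": an.F, "df": list(an.df), "p": an.p,
                   "eta_squared": an.eta_squared,
                   "n_complete": an.n_complete}, fh, indent=2)
    io.write_table(an.pairwise, out / "tukey.csv")
    print(f"per-state RTV ANOVA: F({an.df[0]}, {an.df[1]}) = {an.F:.2f}, "
          f"p = {an.p:.4f}, eta^2 = {an.eta_squared:.2f} "
          f"({an.n_complete} complete participants)")

    corr = states.occupancy_correlation(occ_s, occ_r)
    io.write_table(corr, out / "occupancy_correlations.csv")
    top = corr.loc[corr["r"].abs().idxmax()]
    print(f"occupancy correlations: strongest r = {top['r']:.2f} "
          f"(self-report state {int(top['self_state'])} x RTV state "
          f"{int(top['rtv_state'])}), q = {top['q']:.3f}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results")
    main(ap.parse_args().outdir)
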