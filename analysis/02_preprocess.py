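"""Clean probe reports and build the behavioural series.

Flags over-100 % immersion totals and imputes them, classifies every probe
(mind-blank / single thought / coexistence), computes pre-probe window
statistics (mean RT, RTV over the five preceding correct go trials) and the
sliding RTV series that feeds the behavioural HMM.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from attnstates import io, preprocess

ROOT = Path(__file__).resolve().parents[1]


def main(outdir: Path) -> None:
    trials = io.read_trials(outdir / "data" / "trials.csv")
    probes_raw = io.read_probes(outdir / "data" / "probes_raw.csv")
    out = outdir / "preprocess"
    out.mkdir(parents=True, exist_ok=True)

    probes, log = preprocess.clean_responses(probes_raw)
    io.write_table(probes, out / "probes_clean.csv")
    summary = preprocess.summarize_reports(probes)
    io.write_table(summary["level_counts"], out / "level_counts.csv")
    with open(out / "fractions.json", "w") as fh:
        json.dump(summary["fractions"], fh, indent=2, sort_keys=True)

    win_rows, rtv_frames = [], []
    for pid, tgrp in trials.groupby("participant", sort=True):
        tgrp = tgrp.reset_index(drop=True)
        for _, prow in probes[probes["participant"] == pid].iterrows():
            ws = preprocess.preprobe_window_stats(
                tgrp, int(prow["trial_position"]))
            win_rows.append({"participant": pid, "block": int(prow["block"]),
                             "trial_position": int(prow["trial_position"]),
                             "mean_rt": ws.mean_rt, "rtv": ws.rtv,
                             "valid": ws.valid})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ser = preprocess.sliding_rtv_series(tgrp)
        ser.insert(0, "participant", pid)
        rtv_frames.append(ser)
    window_stats = pd.DataFrame(win_rows)
    rtv_series = pd.concat(rtv_frames, ignore_index=True)
    io.write_table(window_stats, out / "window_stats.csv")
    io.write_table(rtv_series, out / "rtv_series.csv")

    frac = summary["fractions"]
    print(f"cleaning: {log['n_over_total']} over-total probes imputed of "
          f"{log['n_probes']}")
    print(f"report categories: mind-blank {frac['mind_blank']:.1%}, "
          f"single {frac['single_thought']:.1%}, "
          f"coexistence {frac['coexistence']:.1%} "
          f"(50/50 splits {frac['fifty_fifty']:.1%})")
    print(f"windows: {int(window_stats['valid'].sum())} valid of "
          f"{len(window_stats)}; RTV series {len(rtv_series)} points")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results")
    main(ap.parse_args().outdir)
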