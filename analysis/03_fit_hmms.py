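"""Fit both hidden Markov models and choose their state counts.

Probe sequences (four 5-level immersion channels) get product-categorical
emissions with K chosen by minimum BIC over 1..8; the sliding RTV series
gets Gaussian emissions with K chosen by the elbow rule on the BIC curve.
Writes the selection tables, fitted models and Viterbi-decoded paths.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from attnstates import hmm, io, states

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int, outdir: Path, restarts: int) -> None:
    probes = io.read_probes(outdir / "preprocess" / "probes_clean.csv")
    rtv = pd.read_csv(outdir / "preprocess" / "rtv_series.csv",
                      dtype={"participant": str})
    out = outdir / "hmm"
    out.mkdir(parents=True, exist_ok=True)

    probe_obs = hmm.ObservationSet.from_probe_table(probes)
    tbl, k_probe, fitted = hmm.select_states(
        probe_obs, range(1, 9), "categorical", "min_bic",
        n_restarts=restarts, seed=seed)
    io.write_table(tbl, out / "selection_selfreport.csv")
    model_probe = fitted[k_probe]
    model_probe.to_json(out / "model_selfreport.json")
    labels = states.label_states(model_probe)
    print(f"self-report HMM: min BIC at K={k_probe} "
          f"(BIC curve {np.round(tbl['bic'], 0).astype(int).tolist()})")
    print(f"  interpretive labels: {labels}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rtv_obs = hmm.ObservationSet.from_rtv_table(rtv)
        tbl_r, k_rtv, fitted_r = hmm.select_states(
            rtv_obs, range(1, 9), "gaussian", "elbow",
            n_restarts=restarts, seed=seed + 1)
    io.write_table(tbl_r, out / "selection_rtv.csv")
    model_rtv = fitted_r[k_rtv]
    model_rtv.to_json(out / "model_rtv.json")
    order = np.argsort(model_rtv.emissions.means)
    print(f"RTV HMM: elbow at K={k_rtv}; state means "
          f"{np.round(model_rtv.emissions.means[order], 3).tolist()}, "
          f"SDs {np.round(model_rtv.emissions.sds[order], 3).tolist()}")

    for name, model, obs in (("selfreport", model_probe, probe_obs),
                             ("rtv", model_rtv, rtv_obs)):
        dec = hmm.decode(model, obs)
        paths = pd.concat([
            pd.DataFrame({"participant": pid,
                          "t": np.arange(len(d.viterbi_path)),
                          "state": d.viterbi_path})
            for pid, d in dec.items()], ignore_index=True)
        io.write_table(paths, out / f"paths_{name}.csv")
    with open(out / "labels.json", "w") as fh:
        json.dump({"selfreport": labels}, fh, indent=2)


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results")
    ap.add_argument("--restarts", type=int, default=5)
    args = ap.parse_args()
    main(args.seed, args.outdir, args.restarts)
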