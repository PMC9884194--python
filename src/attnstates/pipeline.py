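"""End-to-end orchestration: simulate/ingest -> preprocess -> HMMs -> analyses.

Every stage writes its artifacts before the next begins, under a fixed
directory layout, so any stage can be inspected or replayed in isolation.
Identical configuration and seed reproduce identical CSV/JSON artifacts
byte for byte (the run report additionally records wall-clock timings,
which naturally differ between runs).
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hmm, io, preprocess, regression, simulate, states

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs."""

    seed: int = 0
    outdir: str | Path = "results/run"
    # data source: synthetic by default, or ingest paths
    n_participants: int = 28
    design: simulate.ExperimentDesign = field(
        default_factory=simulate.ExperimentDesign)
    model: simulate.GenerativeModel | None = None
    enforce_total_cap: bool = True
    trials_path: str | None = None
    probes_path: str | None = None
    # preprocessing
    window_width: int = 5
    imputation: str = "linear"
    # HMM estimation
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    n_restarts: int = 5
    tol: float = 1e-6
    max_iter: int = 300
    concatenate: bool = False
    probe_criterion: str = "min_bic"
    rtv_criterion: str = "elbow"
    # analysis
    occupancy_mode: str = "viterbi"
    persistence_threshold: float = 0.8

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = self.design.to_dict()
        d["model"] = self.model.to_dict() if self.model else None
        d["outdir"] = str(self.outdir)
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (also written)."""
    out = Path(config.outdir)
    report: dict = {"version": __version__, "config": config.echo(),
                    "stages": {}, "counts": {}, "exclusions": {}}
    t_all = time.perf_counter()

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                report["stages"][name] = round(
                    time.perf_counter() - self.t0, 3)
                if exc is not None:
                    _dump_json(report, out / "report.json")
                    raise StageError(name, exc) from exc
        return _Ctx()

    for sub in ("data", "preprocess", "hmm", "analysis", "regression"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4)

    # -- stage 1: simulate or ingest ---------------------------------------
    with stage("data"):
        if config.trials_path and config.probes_path:
            trials = io.read_trials(config.trials_path)
            probes_raw = io.read_probes(config.probes_path)
            true_states = None
        else:
            model = config.model or simulate.default_generative_model()
            sessions = simulate.simulate_cohort(
                model, config.design, config.n_participants,
                int(seeds[0]), config.enforce_total_cap)
            trials = simulate.cohort_trials(sessions)
            probes_raw = simulate.cohort_probes(sessions)
            true_states = simulate.cohort_states(sessions)
            io.write_table(true_states, out / "data" / "true_states.csv")
            model.to_json(out / "data" / "model_true.json")
            _dump_json(config.design.to_dict(), out / "data" / "design.json")
        io.write_table(trials, out / "data" / "trials.csv")
        io.write_table(probes_raw, out / "data" / "probes_raw.csv")
        report["counts"]["trials"] = int(len(trials))
        report["counts"]["probes"] = int(len(probes_raw))
        report["counts"]["participants"] = int(
            trials["participant"].nunique())

    # -- stage 2: preprocess ------------------------------------------------
    with stage("preprocess"):
        probes, clean_log = preprocess.clean_responses(
            probes_raw, method=config.imputation)
        io.write_table(probes, out / "preprocess" / "probes_clean.csv")
        _dump_json(clean_log, out / "preprocess" / "cleaning_log.json")

        summary = preprocess.summarize_reports(probes)
        io.write_table(summary["level_counts"],
                       out / "preprocess" / "level_counts.csv")
        _dump_json(summary["fractions"],
                   out / "preprocess" / "fractions.json")

        win_rows, rtv_frames, bimod = [], [], {}
        for pid, tgrp in trials.groupby("participant", sort=True):
            tgrp = tgrp.reset_index(drop=True)
            for _, prow in probes[probes["participant"] == pid].iterrows():
                ws = preprocess.preprobe_window_stats(
                    tgrp, int(prow["trial_position"]), config.window_width,
                    config.design.target_digit)
                win_rows.append({
                    "participant": pid, "block": int(prow["block"]),
                    "trial_position": int(prow["trial_position"]),
                    "mean_rt": ws.mean_rt, "rtv": ws.rtv, "valid": ws.valid,
                })
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ser = preprocess.sliding_rtv_series(
                    tgrp, config.window_width, config.design.target_digit)
            ser.insert(0, "participant", pid)
            rtv_frames.append(ser)
            bimod[pid] = preprocess.rt_bimodality(tgrp)
        window_stats = pd.DataFrame(win_rows)
        rtv_series = pd.concat(rtv_frames, ignore_index=True)
        io.write_table(window_stats, out / "preprocess" / "window_stats.csv")
        io.write_table(rtv_series, out / "preprocess" / "rtv_series.csv")
        _dump_json(bimod, out / "preprocess" / "rt_bimodality.json")
        n_invalid = int((~window_stats["valid"]).sum())
        report["exclusions"]["invalid_preprobe_windows"] = n_invalid
        report["counts"]["valid_preprobe_windows"] = int(
            window_stats["valid"].sum())
        report["counts"]["rtv_points"] = int(len(rtv_series))

    # -- stage 3: self-report HMM -------------------------------------------
    with stage("hmm_selfreport"):
        probe_obs = hmm.ObservationSet.from_probe_table(probes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tbl, k_probe, fitted = hmm.select_states(
                probe_obs, config.k_range, "categorical",
                config.probe_criterion, n_restarts=config.n_restarts,
                tol=config.tol, max_iter=config.max_iter,
                seed=int(seeds[1]), concatenate=config.concatenate)
        io.write_table(tbl, out / "hmm" / "selection_selfreport.csv")
        model_probe = fitted[k_probe]
        model_probe.to_json(out / "hmm" / "model_selfreport.json")
        dec_probe = hmm.decode(model_probe, probe_obs)
        paths = pd.concat([
            pd.DataFrame({"participant": pid,
                          "t": np.arange(len(d.viterbi_path)),
                          "state": d.viterbi_path})
            for pid, d in dec_probe.items()], ignore_index=True)
        io.write_table(paths, out / "hmm" / "paths_selfreport.csv")
        report["counts"]["k_selfreport"] = int(k_probe)

    # -- stage 4: RTV HMM ---------------------------------------------------
    with stage("hmm_rtv"):
        rtv_obs = hmm.ObservationSet.from_rtv_table(rtv_series)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tbl_r, k_rtv, fitted_r = hmm.select_states(
                rtv_obs, config.k_range, "gaussian",
                config.rtv_criterion, n_restarts=config.n_restarts,
                tol=config.tol, max_iter=config.max_iter,
                seed=int(seeds[2]), concatenate=config.concatenate)
        io.write_table(tbl_r, out / "hmm" / "selection_rtv.csv")
        model_rtv = fitted_r[k_rtv]
        model_rtv.to_json(out / "hmm" / "model_rtv.json")
        dec_rtv = hmm.decode(model_rtv, rtv_obs)
        paths_r = pd.concat([
            pd.DataFrame({"participant": pid,
                          "t": grp.sort_values("t")["t"].to_numpy(),
                          "state": dec_rtv[str(pid)].viterbi_path})
            for pid, grp in rtv_series.groupby("participant", sort=True)],
            ignore_index=True)
        io.write_table(paths_r, out / "hmm" / "paths_rtv.csv")
        report["counts"]["k_rtv"] = int(k_rtv)

    # -- stage 5: state analysis --------------------------------------------
    with stage("state_analysis"):
        occ_s = states.occupancy(dec_probe, k_probe, config.occupancy_mode)
        occ_r = states.occupancy(dec_rtv, k_rtv, config.occupancy_mode)
        for occ, name in ((occ_s, "selfreport"), (occ_r, "rtv")):
            wide = occ.counts.copy()
            wide.insert(0, "participant", wide.index)
            io.write_table(wide.reset_index(drop=True),
                           out / "analysis" / f"occupancy_{name}.csv")
        io.write_table(states.transition_long(model_probe),
                       out / "analysis" / "transitions_selfreport.csv")
        io.write_table(states.transition_long(model_rtv),
                       out / "analysis" / "transitions_rtv.csv")
        _dump_json({"selfreport": states.label_states(model_probe)},
                   out / "analysis" / "state_labels.json")

        # per-state RTV uses the probe decoding against pre-probe windows
        valid = window_stats[window_stats["valid"]]
        pre_rtv = valid.rename(columns={"trial_position": "t"})[
            ["participant", "t", "rtv"]]
        probe_paths_valid = {}
        for pid, grp in probes.groupby("participant", sort=True):
            mask = window_stats[window_stats["participant"] == pid][
                "valid"].to_numpy()
            probe_paths_valid[str(pid)] = dec_probe[
                str(pid)].viterbi_path[mask]
        pivot = states.per_state_rtv(probe_paths_valid, pre_rtv, k_probe)
        wide = pivot.copy()
        wide.insert(0, "participant", wide.index)
        io.write_table(wide.reset_index(drop=True),
                       out / "analysis" / "per_state_rtv.csv")
        try:
            an = states.rm_anova_tukey(pivot)
            _dump_json({"F": an.F, "df": list(an.df), "p": an.p,
                        "eta_squared": an.eta_squared,
                        "n_complete": an.n_complete},
                       out / "analysis" / "anova.json")
            io.write_table(an.pairwise, out / "analysis" / "tukey.csv")
            report["counts"]["anova_complete_participants"] = an.n_complete
        except ValueError as exc:
            _dump_json({"error": str(exc)}, out / "analysis" / "anova.json")

        corr = states.occupancy_correlation(occ_s, occ_r)
        io.write_table(corr, out / "analysis" /
                       "occupancy_correlations.csv")

    # -- stage 6: regression ------------------------------------------------
    with stage("regression"):
        merged = valid.merge(
            probes[["participant", "trial_position", "task_focus", "tut"]],
            on=["participant", "trial_position"])
        # immersion codes 0-100 -> level units 0-4, then centered
        x1 = preprocess.center(merged["task_focus"].to_numpy() / 25.0)
        x2 = preprocess.center(merged["tut"].to_numpy() / 25.0)
        res = regression.ols_interaction(merged["rtv"].to_numpy(), x1, x2)
        io.write_table(res.table(), out / "regression" / "regression.csv")
        slopes = (regression.simple_slopes(res, "task_focus", "tut")
                  + regression.simple_slopes(res, "tut", "task_focus"))
        io.write_table(pd.DataFrame([dataclasses.asdict(s) for s in slopes]),
                       out / "regression" / "simple_slopes.csv")
        _dump_json({"adj_r2": res.adj_r2, "F": res.F, "F_df": list(res.F_df),
                    "F_p": res.F_p, "n": res.n,
                    "max_vif": max(res.vif.values())},
                   out / "regression" / "regression_summary.json")
        report["counts"]["regression_n"] = res.n

    report["wall_clock_s"] = round(time.perf_counter() - t_all, 3)
    _dump_json(report, out / "report.json")
    return report
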