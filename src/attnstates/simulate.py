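"""Generative model for SART sessions with latent attentional states.

The simulator forward-samples the assumptions of the downstream analysis: a
first-order Markov chain over attentional states evolves trial by trial; each
state emits response times (lognormal, state-specific coefficient of
variation), go/no-go error rates, and — at thought-probe trials — four
conditionally independent categorical immersion ratings (task-focused,
task-related, external-stimulus-related, and task-unrelated thought) on the
0/25/50/75/100 % scale.  Ground-truth state paths are retained so every
downstream stage can be validated against the generating process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: probe channel names, in on-screen order
CHANNELS = ("task_focus", "task_related", "external", "tut")
#: legal immersion codes (percent)
LEVELS = (0, 25, 50, 75, 100)
N_LEVELS = len(LEVELS)


class ConfigurationError(ValueError):
    """Raised when a design or model violates its structural invariants."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Structural parameters of a SART session.

    Defaults mirror a 20-block session of 45 trials each, digits 1-9 with
    target digit 5, one probe per block and a minimum inter-probe spacing of
    15 trials.
    """

    n_blocks: int = 20
    trials_per_block: int = 45
    digits: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9)
    target_digit: int = 5
    stimulus_ms: int = 350
    isi_ms: int = 1150
    probes_per_block: int = 1
    min_probe_gap: int = 15

    def __post_init__(self) -> None:
        if min(self.n_blocks, self.trials_per_block, self.probes_per_block,
               self.min_probe_gap, self.stimulus_ms, self.isi_ms) <= 0:
            raise ConfigurationError("all design counts must be positive")
        if self.target_digit not in self.digits:
            raise ConfigurationError("target_digit must be one of digits")
        if self.trials_per_block < self.min_probe_gap:
            raise ConfigurationError(
                "trials_per_block must be >= min_probe_gap")
        if self.probes_per_block * self.min_probe_gap > self.trials_per_block:
            raise ConfigurationError(
                "probe spacing infeasible for requested probes_per_block")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def to_dict(self) -> dict:
        return {
            "n_blocks": self.n_blocks,
            "trials_per_block": self.trials_per_block,
            "digits": list(self.digits),
            "target_digit": self.target_digit,
            "stimulus_ms": self.stimulus_ms,
            "isi_ms": self.isi_ms,
            "probes_per_block": self.probes_per_block,
            "min_probe_gap": self.min_probe_gap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        d["digits"] = tuple(d["digits"])
        return cls(**d)


@dataclass
class GenerativeModel:
    """Latent-state generative model: chain, probe emissions, RT behaviour.

    ``probe_emissions[k, c, l]`` is the probability that a probe caught in
    state ``k`` rates channel ``c`` at immersion level ``l`` (levels index the
    0/25/50/75/100 % codes).  RT distributions are lognormal with
    state-specific mean (seconds) and coefficient of variation, so the
    sliding-window RTV statistic directly reflects the state's CV.
    """

    n_states: int
    initial_probs: np.ndarray          # (K,)
    transition_matrix: np.ndarray      # (K, K) row-stochastic
    probe_emissions: np.ndarray        # (K, 4, 5)
    rt_means: np.ndarray               # (K,) seconds
    rt_cvs: np.ndarray                 # (K,) SD/mean of the RT distribution
    omission_rates: np.ndarray         # (K,) P(no press | go trial)
    commission_rates: np.ndarray       # (K,) P(press | no-go trial)
    state_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        K = self.n_states
        self.initial_probs = np.asarray(self.initial_probs, float)
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        self.probe_emissions = np.asarray(self.probe_emissions, float)
        self.rt_means = np.asarray(self.rt_means, float)
        self.rt_cvs = np.asarray(self.rt_cvs, float)
        self.omission_rates = np.asarray(self.omission_rates, float)
        self.commission_rates = np.asarray(self.commission_rates, float)
        if not self.state_names:
            self.state_names = tuple(f"S{k + 1}" for k in range(K))
        self.validate()

    def validate(self) -> None:
        K = self.n_states
        if self.initial_probs.shape != (K,) or not np.isclose(
                self.initial_probs.sum(), 1.0):
            raise ConfigurationError("initial_probs must sum to 1")
        if self.transition_matrix.shape != (K, K) or not np.allclose(
                self.transition_matrix.sum(axis=1), 1.0):
            raise ConfigurationError("transition rows must sum to 1")
        if self.probe_emissions.shape != (K, len(CHANNELS), N_LEVELS):
            raise ConfigurationError("probe_emissions must be (K, 4, 5)")
        if not np.allclose(self.probe_emissions.sum(axis=2), 1.0):
            raise ConfigurationError("each emission vector must sum to 1")
        if np.any(self.rt_cvs <= 0) or np.any(self.rt_means <= 0):
            raise ConfigurationError("rt means and CVs must be positive")
        for r in (self.omission_rates, self.commission_rates):
            if r.shape != (K,) or np.any((r < 0) | (r > 1)):
                raise ConfigurationError("error rates must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "initial_probs": self.initial_probs.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "probe_emissions": self.probe_emissions.tolist(),
            "rt_means": self.rt_means.tolist(),
            "rt_cvs": self.rt_cvs.tolist(),
            "omission_rates": self.omission_rates.tolist(),
            "commission_rates": self.commission_rates.tolist(),
            "state_names": list(self.state_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeModel":
        d = dict(d)
        d["state_names"] = tuple(d.get("state_names", ()))
        return cls(**{k: (np.asarray(v) if isinstance(v, list) and
                          k not in ("state_names",) else v)
                      for k, v in d.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GenerativeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_generative_model() -> GenerativeModel:
    """Four attentional states: TUT-prone, unfocused, task-focused, mixed.

    Emission profiles follow the qualitative structure of the four-state
    solution the pipeline is meant to recover: a TUT state with high
    task-unrelated immersion and elevated RT variability, an unfocused state
    with low immersion everywhere, a task-focused state concentrated at high
    task immersion with the steadiest responding, and a mixed state around
    50 % task immersion with non-zero secondary thoughts.
    """
    B = np.array([
        # task_focus               task_related              external                  tut
        [[.50, .40, .09, .008, .002], [.75, .24, .008, .001, .001],
         [.70, .29, .008, .001, .001], [.01, .04, .20, .45, .30]],   # TUT
        [[.42, .55, .025, .004, .001], [.50, .48, .015, .004, .001],
         [.52, .46, .015, .004, .001], [.60, .38, .015, .004, .001]],  # unfocused
        [[.004, .016, .11, .42, .45], [.62, .35, .025, .004, .001],
         [.85, .14, .008, .001, .001], [.88, .11, .008, .001, .001]],  # task-focused
        [[.02, .14, .68, .15, .01], [.02, .20, .68, .09, .01],
         [.85, .14, .008, .001, .001], [.75, .24, .008, .001, .001]],  # mixed
    ])
    return GenerativeModel(
        n_states=4,
        initial_probs=np.array([.312, .231, .254, .203]),
        transition_matrix=np.array([
            [.9920, .0030, .0025, .0025],
            [.0040, .9900, .0030, .0030],
            [.0030, .0030, .9910, .0030],
            [.0040, .0030, .0040, .9890],
        ]),
        probe_emissions=B,
        rt_means=np.array([.33, .32, .31, .30]),
        rt_cvs=np.array([.43, .18, .09, .13]),
        omission_rates=np.array([.08, .03, .01, .02]),
        commission_rates=np.array([.60, .45, .25, .35]),
        state_names=("tut", "unfocused", "task_focused", "mixed"),
    )


@dataclass
class SimulatedSession:
    """One participant's simulated session with ground truth retained."""

    participant_id: str
    trials: pd.DataFrame       # participant, block, trial, stimulus, responded, rt_s, correct
    probes: pd.DataFrame       # participant, block, trial_position, 4 channels
    true_states: np.ndarray    # (n_trials,) latent state index per trial


def generate_design(config: ExperimentDesign, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Draw a stimulus schedule and probe positions for one session.

    Returns ``(stimuli, probe_positions)`` where ``stimuli`` is the per-trial
    digit sequence (uniform over ``config.digits``) and ``probe_positions``
    are global trial indices of the trial each probe follows.  Probes are
    placed uniformly over the positions that keep every pair of consecutive
    probes (across block boundaries) at least ``min_probe_gap`` trials apart,
    using forward feasibility filtering.
    """
    tpb = config.trials_per_block
    stimuli = rng.choice(config.digits, size=config.n_trials)
    positions: list[int] = []
    prev = -np.inf
    for b in range(config.n_blocks):
        lo, hi = b * tpb, (b + 1) * tpb - 1
        for j in range(config.probes_per_block):
            remaining = config.probes_per_block - 1 - j
            # leave room for the probes still owed to this block
            cap = hi - remaining * config.min_probe_gap
            floor_ = max(lo, int(prev + config.min_probe_gap)
                         if np.isfinite(prev) else lo)
            if floor_ > cap:
                raise ConfigurationError(
                    f"no feasible probe position in block {b}")
            pos = int(rng.integers(floor_, cap + 1))
            positions.append(pos)
            prev = pos
    return stimuli, np.array(positions)


def simulate_latent_chain(model: GenerativeModel, T: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Sample a length-``T`` state path from the Markov chain."""
    if T < 1:
        raise ValueError("T must be >= 1")
    path = np.empty(T, dtype=int)
    # inverse-CDF sampling against cumulative rows keeps this O(T) in python
    cum_pi = np.cumsum(model.initial_probs)
    cum_A = np.cumsum(model.transition_matrix, axis=1)
    u = rng.random(T)
    path[0] = np.searchsorted(cum_pi, u[0], side="right")
    for t in range(1, T):
        path[t] = np.searchsorted(cum_A[path[t - 1]], u[t], side="right")
    return np.minimum(path, model.n_states - 1)


def _cap_total(codes: np.ndarray) -> np.ndarray:
    """Reduce the largest channels one 25 %-level at a time until total <= 100."""
    codes = codes.copy()
    while codes.sum() > 100:
        codes[int(np.argmax(codes))] -= 25
    return codes


def _draw_probe(model: GenerativeModel, state: int, rng: np.random.Generator,
                enforce_total_cap: bool = True,
                max_rejections: int = 100) -> np.ndarray:
    """Draw the four immersion codes for a probe caught in ``state``.

    Channels are sampled independently given the state; when the cap is
    enforced, totals above 100 % are rejected and redrawn (preserving
    conditional independence as closely as possible), falling back to capping
    the largest channels if rejection fails repeatedly.
    """
    levels = np.asarray(LEVELS)
    probs = model.probe_emissions[state]
    for _ in range(max_rejections):
        u = rng.random(len(CHANNELS))
        idx = (u[:, None] > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)
        codes = levels[idx]
        if not enforce_total_cap or codes.sum() <= 100:
            return codes
    return _cap_total(codes)


def simulate_session(model: GenerativeModel, design: ExperimentDesign,
                     participant_id: str, rng: np.random.Generator,
                     enforce_total_cap: bool = True) -> SimulatedSession:
    """Simulate one full session: trials, probe reports, true state path."""
    T = design.n_trials
    stimuli, probe_pos = generate_design(design, rng)
    states = simulate_latent_chain(model, T, rng)

    is_target = stimuli == design.target_digit
    u_resp = rng.random(T)
    sigma = np.sqrt(np.log1p(model.rt_cvs ** 2))
    mu = np.log(model.rt_means) - sigma ** 2 / 2
    rts = rng.lognormal(mu[states], sigma[states])

    responded = np.where(is_target,
                         u_resp < model.commission_rates[states],
                         u_resp >= model.omission_rates[states])
    correct = np.where(is_target, ~responded, responded)
    rt_s = np.where(responded, rts, np.nan)

    trials = pd.DataFrame({
        "participant": participant_id,
        "block": np.repeat(np.arange(design.n_blocks), design.trials_per_block),
        "trial": np.tile(np.arange(design.trials_per_block), design.n_blocks),
        "stimulus": stimuli,
        "responded": responded,
        "rt_s": rt_s,
        "correct": correct,
    })
    probe_rows = []
    for pos in probe_pos:
        codes = _draw_probe(model, states[pos], rng, enforce_total_cap)
        probe_rows.append({
            "participant": participant_id,
            "block": int(pos // design.trials_per_block),
            "trial_position": int(pos),
            **dict(zip(CHANNELS, (int(c) for c in codes))),
        })
    probes = pd.DataFrame(probe_rows)
    return SimulatedSession(participant_id, trials, probes, states)


def simulate_cohort(model: GenerativeModel, design: ExperimentDesign,
                    n_participants: int, master_seed: int,
                    enforce_total_cap: bool = True) -> list[SimulatedSession]:
    """Simulate ``n_participants`` independent sessions.

    Per-participant streams are derived from ``master_seed`` with
    ``numpy.random.SeedSequence.spawn``, so the cohort is reproducible as a
    whole and each session is reproducible in isolation.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(n_participants)
    return [
        simulate_session(model, design, f"p{i:02d}",
                         np.random.default_rng(child), enforce_total_cap)
        for i, child in enumerate(children)
    ]


def cohort_trials(sessions: list[SimulatedSession]) -> pd.DataFrame:
    return pd.concat([s.trials for s in sessions], ignore_index=True)


def cohort_probes(sessions: list[SimulatedSession]) -> pd.DataFrame:
    return pd.concat([s.probes for s in sessions], ignore_index=True)


def cohort_states(sessions: list[SimulatedSession]) -> pd.DataFrame:
    return pd.concat([
        pd.DataFrame({"participant": s.participant_id,
                      "t": np.arange(len(s.true_states)),
                      "state": s.true_states})
        for s in sessions
    ], ignore_index=True)
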