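"""Hidden Markov models for attentional-state estimation.

Two emission families are supported, matching the two observation streams of
the analysis:

* **product-categorical** — four conditionally independent 5-level channels
  per time point, for the thought-probe immersion sequences ("multinomial"
  emissions in the mixture-modelling sense);
* **Gaussian** — a univariate normal per state, for the sliding RTV series.

Estimation is Baum–Welch EM with a proper multi-sequence E-step: each
sequence gets its own scaled forward–backward pass and the sufficient
statistics are pooled before the M-step.  A ``concatenate`` switch joins all
sequences into one chain instead, reproducing the cruder single-sequence
treatment some analyses apply.  Model size is chosen by BIC (minimum or
elbow rule).

The forward–backward recursions use per-step scaling rather than log-space
sums; sequences of equal length are processed as a single vectorised batch,
and unequal lengths are handled by padding with an activity mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm

N_CHANNELS = 4
N_LEVELS = 5
_PROB_FLOOR = 1e-10
_DENS_FLOOR = 1e-300


class ZeroProbabilityError(ValueError):
    """An observation has zero probability under every state."""


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

@dataclass
class CategoricalEmissions:
    """Per-state, per-channel categorical level distributions, shape (K, C, L)."""

    probs: np.ndarray

    family = "categorical"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    def n_params(self) -> int:
        K, C, L = self.probs.shape
        return K * C * (L - 1)

    def log_obs(self, seq: np.ndarray) -> np.ndarray:
        """Log emission probability of each observation under each state.

        ``seq`` holds integer level indices 0..L-1, shape (T, C); returns (T, K).
        """
        seq = np.atleast_2d(np.asarray(seq, dtype=int))
        logp = np.log(np.maximum(self.probs, _PROB_FLOOR))  # (K, C, L)
        out = np.zeros((seq.shape[0], self.n_states))
        for c in range(self.probs.shape[1]):
            out += logp[:, c, seq[:, c]].T
        return out

    def flat(self) -> np.ndarray:
        return self.probs.reshape(self.n_states, -1)


@dataclass
class GaussianEmissions:
    """Per-state univariate normal emissions."""

    means: np.ndarray
    sds: np.ndarray

    family = "gaussian"

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    def n_params(self) -> int:
        return 2 * self.n_states

    def log_obs(self, seq: np.ndarray) -> np.ndarray:
        seq = np.asarray(seq, dtype=float).ravel()
        return norm.logpdf(seq[:, None], self.means[None, :],
                           self.sds[None, :])

    def flat(self) -> np.ndarray:
        return np.column_stack([self.means, self.sds])


# ---------------------------------------------------------------------------
# model and data containers
# ---------------------------------------------------------------------------

@dataclass
class HmmModel:
    """A fitted (or hand-set) hidden Markov model."""

    startprob: np.ndarray
    transmat: np.ndarray
    emissions: CategoricalEmissions | GaussianEmissions
    log_likelihood: float = np.nan
    n_params: int = 0
    bic: float = np.nan
    converged: bool = False
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        if not self.n_params:
            K = self.n_states
            self.n_params = (K - 1) + K * (K - 1) + self.emissions.n_params()

    @property
    def n_states(self) -> int:
        return self.startprob.shape[0]

    @property
    def family(self) -> str:
        return self.emissions.family

    def to_dict(self) -> dict:
        em = ({"probs": self.emissions.probs.tolist()}
              if self.family == "categorical"
              else {"means": self.emissions.means.tolist(),
                    "sds": self.emissions.sds.tolist()})
        return {
            "family": self.family,
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "emissions": em,
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        em = (CategoricalEmissions(np.asarray(d["emissions"]["probs"]))
              if d["family"] == "categorical"
              else GaussianEmissions(np.asarray(d["emissions"]["means"]),
                                     np.asarray(d["emissions"]["sds"])))
        return cls(np.asarray(d["startprob"]), np.asarray(d["transmat"]), em,
                   d["log_likelihood"], d["n_params"], d["bic"],
                   d["converged"], d["n_iter"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "HmmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ObservationSet:
    """Multiple independent observation sequences for one emission family."""

    sequences: list[np.ndarray]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequences = [np.asarray(s) for s in self.sequences]
        if not self.ids:
            self.ids = [str(i) for i in range(len(self.sequences))]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.sequences])

    @property
    def n_obs(self) -> int:
        return int(self.lengths.sum())

    def concatenated(self) -> "ObservationSet":
        """Join all sequences into one chain (single-sequence fidelity mode)."""
        return ObservationSet([np.concatenate(self.sequences, axis=0)],
                              ids=["concatenated"])

    @classmethod
    def from_probe_table(cls, probes, channels=None) -> "ObservationSet":
        """Build level-index sequences (T, 4) per participant from a probe table."""
        from .simulate import CHANNELS
        channels = channels or list(CHANNELS)
        seqs, ids = [], []
        for pid, grp in probes.groupby("participant", sort=True):
            codes = grp.sort_values("trial_position")[channels].to_numpy()
            seqs.append((codes // 25).astype(int))
            ids.append(str(pid))
        return cls(seqs, ids)

    @classmethod
    def from_rtv_table(cls, rtv) -> "ObservationSet":
        """Build univariate RTV sequences per participant from a long table."""
        seqs, ids = [], []
        for pid, grp in rtv.groupby("participant", sort=True):
            seqs.append(grp.sort_values("t")["rtv"].to_numpy(dtype=float))
            ids.append(str(pid))
        return cls(seqs, ids)


@dataclass
class StateDecoding:
    """Posterior (gamma) and Viterbi decoding of one sequence."""

    posteriors: np.ndarray    # (T, K)
    viterbi_path: np.ndarray  # (T,)

    def occupancy(self, n_states: int, mode: str = "viterbi") -> np.ndarray:
        if mode == "viterbi":
            return np.bincount(self.viterbi_path, minlength=n_states).astype(float)
        if mode == "posterior":
            return self.posteriors.sum(axis=0)
        raise ValueError(f"unknown occupancy mode: {mode!r}")


# ---------------------------------------------------------------------------
# inference: scaled forward-backward, batched over sequences
# ---------------------------------------------------------------------------

def _pad_log_obs(model: HmmModel, data: ObservationSet):
    """Per-sequence emission likelihood matrices, padded to (N, Tmax, K).

    Likelihoods are scaled per time point by their max before exponentiation,
    so categorical products and narrow Gaussians never underflow; the removed
    log-scale is returned for exact log-likelihood reconstruction.
    """
    lengths = data.lengths
    N, Tmax, K = len(lengths), int(lengths.max()), model.n_states
    B = np.ones((N, Tmax, K))
    shift = np.zeros((N, Tmax))
    for i, seq in enumerate(data.sequences):
        lo = model.emissions.log_obs(seq)                    # (T, K)
        m = lo.max(axis=1)
        bad = ~np.isfinite(m)
        if bad.any():
            raise ZeroProbabilityError(
                "observation impossible under every state (-inf likelihood)")
        B[i, :len(seq)] = np.exp(lo - m[:, None])
        shift[i, :len(seq)] = m
    return B, shift, lengths


def _forward(model, B, shift, lengths):
    """Scaled forward pass.  Returns alpha-hat (N,Tmax,K), scales c, logliks."""
    N, Tmax, K = B.shape
    A, pi = model.transmat, model.startprob
    alpha = np.zeros((N, Tmax, K))
    c = np.ones((N, Tmax))
    a = pi[None, :] * B[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    if np.any(c[:, 0] <= 0):
        raise ZeroProbabilityError("zero forward mass at t=0")
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, Tmax):
        active = t < lengths
        a = (alpha[:, t - 1] @ A) * B[:, t, :]
        ct = a.sum(axis=1)
        if np.any(active & (ct <= 0)):
            raise ZeroProbabilityError(f"zero forward mass at t={t}")
        safe = np.where(ct > 0, ct, 1.0)
        alpha[:, t] = np.where(active[:, None], a / safe[:, None],
                               alpha[:, t - 1])
        c[:, t] = np.where(active, safe, 1.0)
    logliks = np.log(c).sum(axis=1) + shift.sum(axis=1)
    return alpha, c, logliks


def _backward_stats(model, B, c, lengths, alpha):
    """Backward pass; returns gamma (N,Tmax,K) and pooled xi sums (K,K)."""
    N, Tmax, K = B.shape
    A = model.transmat
    beta = np.ones((N, K))
    gamma = np.zeros((N, Tmax, K))
    last = lengths - 1
    gamma[np.arange(N), last] = alpha[np.arange(N), last]
    xi_sum = np.zeros((K, K))
    for t in range(Tmax - 2, -1, -1):
        has_next = (t + 1) <= last
        bb = B[:, t + 1, :] * beta                            # (N, K)
        bbs = bb / c[:, t + 1, None]
        # pairwise posteriors at (t, t+1), pooled over active sequences
        act = has_next & (t < lengths)
        if act.any():
            xi_sum += np.einsum("ni,ij,nj->ij", alpha[act, t], A, bbs[act])
        beta_new = bbs @ A.T
        beta = np.where(has_next[:, None], beta_new, 1.0)
        g = alpha[:, t] * beta
        gs = g.sum(axis=1, keepdims=True)
        gamma[:, t] = np.where((t <= last)[:, None],
                               g / np.where(gs > 0, gs, 1.0), 0.0)
    return gamma, xi_sum


def log_forward_backward(model: HmmModel, seq) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood, state posteriors gamma, and pairwise posteriors xi.

    ``gamma[t, k]`` is P(state_t = k | observations); ``xi[t, i, j]`` is
    P(state_t = i, state_{t+1} = j | observations), shape (T-1, K, K).
    """
    data = ObservationSet([np.asarray(seq)])
    B, shift, lengths = _pad_log_obs(model, data)
    alpha, c, logliks = _forward(model, B, shift, lengths)
    T, K = int(lengths[0]), model.n_states
    A = model.transmat
    beta = np.ones((T, K))
    for t in range(T - 2, -1, -1):
        beta[t] = (B[0, t + 1] * beta[t + 1] / c[0, t + 1]) @ A.T
    gamma = alpha[0, :T] * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = (alpha[0, :T - 1, :, None] * A[None]
          * (B[0, 1:T] * beta[1:] / c[0, 1:T, None])[:, None, :])
    return float(logliks[0]), gamma, xi


def loglik(model: HmmModel, data: ObservationSet) -> float:
    """Total log-likelihood of a multi-sequence observation set."""
    B, shift, lengths = _pad_log_obs(model, data)
    return float(_forward(model, B, shift, lengths)[2].sum())


def viterbi(model: HmmModel, seq) -> np.ndarray:
    """Most probable state path; ties break toward the lowest state index."""
    seq = np.asarray(seq)
    lo = model.emissions.log_obs(seq)
    T, K = lo.shape
    logA = np.log(np.maximum(model.transmat, _DENS_FLOOR))
    delta = np.log(np.maximum(model.startprob, _DENS_FLOOR)) + lo[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)      # first max -> lowest index
        delta = cand[back[t], np.arange(K)] + lo[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def decode(model: HmmModel, data: ObservationSet) -> dict[str, StateDecoding]:
    """Posterior and Viterbi decoding for every sequence, keyed by id."""
    out = {}
    for sid, seq in zip(data.ids, data.sequences):
        _, gamma, _ = log_forward_backward(model, seq)
        out[sid] = StateDecoding(gamma, viterbi(model, seq))
    return out


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------

def _init_model(data: ObservationSet, K: int, family: str,
                rng: np.random.Generator) -> HmmModel:
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.2 / max(K - 1, 1))
    np.fill_diagonal(A, 0.8 if K > 1 else 1.0)
    if family == "categorical":
        em = CategoricalEmissions(
            rng.dirichlet(np.ones(N_LEVELS), size=(K, N_CHANNELS)))
    elif family == "gaussian":
        pooled = np.sort(np.concatenate([s.ravel() for s in data.sequences]))
        groups = np.array_split(pooled, K)
        means = np.array([g.mean() for g in groups])
        means = means + rng.normal(0, 0.05 * (pooled.std() + 1e-12), K)
        sds = np.full(K, max(pooled.std(), 1e-3))
        em = GaussianEmissions(means, sds)
    else:
        raise ValueError(f"unknown family: {family!r}")
    return HmmModel(pi, A, em)


def _m_step(model: HmmModel, data: ObservationSet, gamma, xi_sum,
            lengths) -> HmmModel:
    N, Tmax, K = gamma.shape
    first = gamma[:, 0, :].sum(axis=0)
    pi = first / first.sum()
    if K > 1:
        denom = xi_sum.sum(axis=1, keepdims=True)
        A = np.where(denom > 0, xi_sum / np.where(denom > 0, denom, 1.0),
                     1.0 / K)
        A /= A.sum(axis=1, keepdims=True)
    else:
        A = np.ones((1, 1))
    if model.family == "categorical":
        counts = np.full((K, N_CHANNELS, N_LEVELS), _PROB_FLOOR)
        for i, seq in enumerate(data.sequences):
            g = gamma[i, :len(seq)]                       # (T, K)
            for c in range(N_CHANNELS):
                onehot = np.eye(N_LEVELS)[seq[:, c]]      # (T, L)
                counts[:, c, :] += g.T @ onehot
        em = CategoricalEmissions(counts / counts.sum(axis=2, keepdims=True))
    else:
        obs = np.concatenate([s.ravel() for s in data.sequences])
        g = np.concatenate([gamma[i, :len(s)]
                            for i, s in enumerate(data.sequences)], axis=0)
        w = g.sum(axis=0)
        means = (g * obs[:, None]).sum(axis=0) / np.maximum(w, 1e-12)
        var = (g * (obs[:, None] - means[None, :]) ** 2).sum(axis=0)
        sds = np.sqrt(var / np.maximum(w, 1e-12))
        em = GaussianEmissions(means, np.maximum(sds, 1e-6))
    return HmmModel(pi, A, em)


def _em_once(data: ObservationSet, K: int, family: str,
             rng: np.random.Generator, tol: float, max_iter: int,
             max_reseeds: int = 5) -> HmmModel:
    for _ in range(max_reseeds):
        model = _init_model(data, K, family, rng)
        try:
            return _em_iterate(model, data, tol, max_iter)
        except _EmptyStateError:
            continue  # degenerate start: draw a fresh initialisation
    raise RuntimeError("EM kept collapsing to an empty state")


class _EmptyStateError(RuntimeError):
    pass


def _em_iterate(model: HmmModel, data: ObservationSet, tol: float,
                max_iter: int) -> HmmModel:
    prev_ll = -np.inf
    converged = False
    it = 0
    evaluated = model
    for it in range(1, max_iter + 1):
        B, shift, lengths = _pad_log_obs(model, data)
        alpha, c, logliks = _forward(model, B, shift, lengths)
        ll = float(logliks.sum())
        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            raise RuntimeError(
                f"EM log-likelihood decreased ({prev_ll:.10g} -> {ll:.10g})")
        evaluated = model
        gamma, xi_sum = _backward_stats(model, B, c, lengths, alpha)
        if np.any(gamma.sum(axis=(0, 1)) < 1e-8):
            raise _EmptyStateError
        if np.isfinite(prev_ll) and (ll - prev_ll) < tol * max(1.0, abs(ll)):
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
        model = _m_step(model, data, gamma, xi_sum, lengths)
    return replace(evaluated, log_likelihood=prev_ll, converged=converged,
                   n_iter=it, bic=np.nan)


def em_fit(data: ObservationSet, K: int, family: str, n_restarts: int = 20,
           tol: float = 1e-6, max_iter: int = 500,
           seed: int | np.random.Generator | None = None,
           concatenate: bool = False) -> HmmModel:
    """Fit a K-state HMM by multi-restart Baum–Welch; best restart wins.

    Sequences are treated as independent realisations sharing one parameter
    set unless ``concatenate`` joins them into a single chain.  The
    log-likelihood trace is checked for monotonicity on every iteration.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not data.sequences:
        raise ValueError("empty observation set")
    if concatenate:
        data = data.concatenated()
    rng = np.random.default_rng(seed)
    best: HmmModel | None = None
    for _ in range(n_restarts):
        cand = _em_once(data, K, family, rng, tol, max_iter)
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    assert best is not None
    return replace(best, bic=bic(best, data))


def bic(model: HmmModel, data: ObservationSet) -> float:
    """Bayesian information criterion: -2 logL + p ln(n_obs)."""
    ll = model.log_likelihood
    if not np.isfinite(ll):
        ll = loglik(model, data)
    return float(-2.0 * ll + model.n_params * np.log(data.n_obs))


def select_states(data: ObservationSet, k_range=range(1, 9),
                  family: str = "categorical", criterion: str = "min_bic",
                  **fit_kwargs):
    """Fit every K in ``k_range`` and choose one by BIC.

    ``min_bic`` picks the argmin.  ``elbow`` picks the interior K with the
    sharpest drop in BIC improvement — the K maximising
    (BIC[K-1] - BIC[K]) - (BIC[K] - BIC[K+1]) over a monotonically
    decreasing BIC sequence — and falls back to ``min_bic`` with a warning
    when the sequence is not monotone.  Returns ``(table, chosen_k, models)``.
    """
    import pandas as pd
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    models = {}
    rows = []
    base_seed = fit_kwargs.pop("seed", None)
    for k in ks:
        seed = None if base_seed is None else int(base_seed) + k
        m = em_fit(data, k, family, seed=seed, **fit_kwargs)
        models[k] = m
        rows.append({"K": k, "log_likelihood": m.log_likelihood,
                     "n_params": m.n_params, "bic": m.bic,
                     "converged": m.converged, "n_iter": m.n_iter})
    table = pd.DataFrame(rows)
    chosen = choose_k(ks, table["bic"].to_numpy(), criterion)
    return table, chosen, models


def choose_k(ks, bics, criterion: str = "min_bic") -> int:
    """Apply a model-size criterion to a BIC sequence.

    ``min_bic`` returns the argmin.  ``elbow`` returns the interior K with
    the largest second difference (BIC[K-1]-BIC[K]) - (BIC[K]-BIC[K+1]) of a
    monotonically decreasing sequence, falling back to min-BIC with a
    warning otherwise.
    """
    ks = list(ks)
    bics = np.asarray(bics, dtype=float)
    if criterion == "min_bic":
        return ks[int(np.argmin(bics))]
    if criterion == "elbow":
        if len(ks) < 3 or np.any(np.diff(bics) >= 0):
            if len(ks) >= 3:
                warnings.warn("BIC sequence not monotonically decreasing; "
                              "falling back to min-BIC", stacklevel=2)
            return ks[int(np.argmin(bics))]
        drop = -np.diff(bics)                       # improvements
        second = drop[:-1] - drop[1:]               # interior Ks only
        return ks[1 + int(np.argmax(second))]
    raise ValueError(f"unknown criterion: {criterion!r}")


def match_states(model_a: HmmModel, model_b: HmmModel) -> np.ndarray:
    """Permutation aligning ``model_b`` states to ``model_a``.

    Minimises total L1 distance between emission parameters by optimal
    assignment; ``perm[i]`` is the state of ``model_b`` matched to state
    ``i`` of ``model_a``.
    """
    if (model_a.n_states != model_b.n_states
            or model_a.family != model_b.family):
        raise ValueError("models must share K and emission family")
    fa, fb = model_a.emissions.flat(), model_b.emissions.flat()
    cost = np.abs(fa[:, None, :] - fb[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty_like(cols)
    perm[rows] = cols
    return perm


def permute_model(model: HmmModel, perm: np.ndarray) -> HmmModel:
    """Relabel states of ``model`` by ``perm`` (new state i = old perm[i])."""
    perm = np.asarray(perm)
    if model.family == "categorical":
        em = CategoricalEmissions(model.emissions.probs[perm])
    else:
        em = GaussianEmissions(model.emissions.means[perm],
                               model.emissions.sds[perm])
    return replace(model, startprob=model.startprob[perm],
                   transmat=model.transmat[np.ix_(perm, perm)], emissions=em)
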