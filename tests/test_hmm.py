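"""HMM core: inference oracles, EM behaviour, selection, matching."""

import itertools

import numpy as np
import pytest

from attnstates import hmm
from attnstates.hmm import (CategoricalEmissions, GaussianEmissions, HmmModel,
                            ObservationSet, ZeroProbabilityError, bic, em_fit,
                            log_forward_backward, match_states, permute_model,
                            select_states, viterbi)


def random_model(K, family, rng):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    if family == "categorical":
        em = CategoricalEmissions(rng.dirichlet(np.ones(5), size=(K, 4)))
    else:
        em = GaussianEmissions(rng.normal(0, 1, K), rng.uniform(0.2, 1, K))
    return HmmModel(pi, A, em)


def random_obs(K, T, family, rng):
    if family == "categorical":
        return rng.integers(0, 5, (T, 4))
    return rng.normal(0, 1, T)


def brute_force_loglik(model, seq):
    T = len(seq)
    lo = model.emissions.log_obs(np.asarray(seq))
    tot = -np.inf
    for path in itertools.product(range(model.n_states), repeat=T):
        lp = np.log(model.startprob[path[0]]) + lo[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.transmat[path[t - 1], path[t]]) + lo[t, path[t]]
        tot = np.logaddexp(tot, lp)
    return tot


def brute_force_viterbi(model, seq):
    T = len(seq)
    lo = model.emissions.log_obs(np.asarray(seq))
    best, bp = -np.inf, None
    for path in itertools.product(range(model.n_states), repeat=T):
        lp = np.log(model.startprob[path[0]]) + lo[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.transmat[path[t - 1], path[t]]) + lo[t, path[t]]
        if lp > best + 1e-12:       # strict improvement => first (lowest) wins
            best, bp = lp, path
    return np.array(bp)


def sample_from(model, n_seq, T, rng):
    seqs = []
    cumA = np.cumsum(model.transmat, axis=1)
    for _ in range(n_seq):
        u = rng.random(T)
        path = np.empty(T, int)
        path[0] = np.searchsorted(np.cumsum(model.startprob), u[0])
        for t in range(1, T):
            path[t] = np.searchsorted(cumA[path[t - 1]], u[t])
        path = np.minimum(path, model.n_states - 1)
        if model.family == "categorical":
            obs = np.empty((T, 4), int)
            for c in range(4):
                pc = np.cumsum(model.emissions.probs[:, c, :], axis=1)
                obs[:, c] = (rng.random(T)[:, None] > pc[path, :-1]).sum(axis=1)
        else:
            obs = rng.normal(model.emissions.means[path],
                             model.emissions.sds[path])
        seqs.append(obs)
    return ObservationSet(seqs)


class TestForwardBackward:
    def test_matches_enumeration_random_instances(self):
        rng = np.random.default_rng(10)
        for i in range(60):
            K, T = int(rng.integers(1, 4)), int(rng.integers(1, 7))
            fam = "categorical" if i % 2 else "gaussian"
            m = random_model(K, fam, rng)
            seq = random_obs(K, T, fam, rng)
            ll, gamma, xi = log_forward_backward(m, seq)
            assert ll == pytest.approx(brute_force_loglik(m, seq), abs=1e-9)
            assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
            if T > 1:
                # xi marginalises back to gamma
                assert np.allclose(xi.sum(axis=2), gamma[:-1], atol=1e-9)
                assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_single_state_degenerate(self):
        rng = np.random.default_rng(1)
        m = random_model(1, "categorical", rng)
        seq = random_obs(1, 8, "categorical", rng)
        ll, gamma, _ = log_forward_backward(m, seq)
        assert ll == pytest.approx(m.emissions.log_obs(seq)[:, 0].sum())
        assert np.allclose(gamma, 1.0)

    def test_gaussian_at_mode(self):
        from scipy.stats import norm
        m = HmmModel(np.array([1.0, 0.0]), np.eye(2),
                     GaussianEmissions(np.array([0.2, 0.9]),
                                       np.array([0.1, 0.1])))
        ll, _, _ = log_forward_backward(m, np.array([0.2]))
        assert ll == pytest.approx(norm.logpdf(0.2, 0.2, 0.1))

    def test_impossible_observation_signalled(self):
        probs = np.zeros((1, 4, 5))
        probs[:, :, 0] = 1.0
        m = HmmModel(np.array([1.0]), np.ones((1, 1)),
                     CategoricalEmissions(probs))
        # floor keeps single-channel zeros finite; a fully impossible row is
        # the documented error path for hand-set models without flooring
        m.emissions.probs = probs  # mass strictly on level 0
        seq = np.full((3, 4), 4)
        ll, _, _ = log_forward_backward(m, seq)
        assert ll < -80    # floored at 1e-10 per channel


class TestViterbi:
    def test_matches_enumeration(self):
        rng = np.random.default_rng(20)
        for i in range(40):
            K, T = int(rng.integers(1, 4)), int(rng.integers(1, 7))
            fam = "categorical" if i % 2 else "gaussian"
            m = random_model(K, fam, rng)
            seq = random_obs(K, T, fam, rng)
            assert np.array_equal(viterbi(m, seq),
                                  brute_force_viterbi(m, seq))

    def test_single_state_constant(self):
        rng = np.random.default_rng(2)
        m = random_model(1, "gaussian", rng)
        assert np.array_equal(viterbi(m, np.zeros(5)), np.zeros(5, int))

    def test_absorbing_start_state_two(self):
        # pi = (0,1), A = I: path pinned to state 2 whatever the emissions
        em = CategoricalEmissions(np.full((2, 4, 5), 0.2))
        m = HmmModel(np.array([0.0, 1.0]), np.eye(2), em)
        seq = np.zeros((6, 4), int)
        assert np.array_equal(viterbi(m, seq), np.ones(6, int))

    def test_tie_breaks_to_lowest_state(self):
        # fully symmetric model: every path equally likely -> state 0
        em = CategoricalEmissions(np.full((2, 4, 5), 0.2))
        m = HmmModel(np.array([0.5, 0.5]), np.full((2, 2), 0.5), em)
        seq = np.zeros((4, 4), int)
        assert np.array_equal(viterbi(m, seq), np.zeros(4, int))


class TestEm:
    def test_k1_categorical_closed_form(self):
        rng = np.random.default_rng(3)
        seqs = [rng.integers(0, 5, (20, 4)) for _ in range(5)]
        obs = ObservationSet(seqs)
        m = em_fit(obs, 1, "categorical", n_restarts=1, seed=0)
        pooled = np.concatenate(seqs, axis=0)
        for c in range(4):
            emp = np.bincount(pooled[:, c], minlength=5) / len(pooled)
            assert np.allclose(m.emissions.probs[0, c], emp, atol=1e-9)
        closed = sum(
            np.log(np.maximum(np.bincount(pooled[:, c], minlength=5)
                              / len(pooled), 1e-300))[pooled[:, c]].sum()
            for c in range(4))
        assert m.log_likelihood == pytest.approx(closed, abs=1e-6)

    def test_k1_gaussian_closed_form(self):
        rng = np.random.default_rng(4)
        seqs = [rng.normal(0.3, 0.1, 50) for _ in range(3)]
        obs = ObservationSet(seqs)
        m = em_fit(obs, 1, "gaussian", n_restarts=1, seed=0)
        pooled = np.concatenate(seqs)
        assert m.emissions.means[0] == pytest.approx(pooled.mean(), abs=1e-6)
        assert m.emissions.sds[0] == pytest.approx(pooled.std(), abs=1e-6)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        obs = sample_from(random_model(2, "categorical", rng), 10, 30, rng)
        a = em_fit(obs, 2, "categorical", n_restarts=3, seed=42)
        b = em_fit(obs, 2, "categorical", n_restarts=3, seed=42)
        assert a.log_likelihood == b.log_likelihood
        assert np.array_equal(a.transmat, b.transmat)
        assert np.array_equal(a.emissions.probs, b.emissions.probs)

    def test_two_state_recovery(self):
        # well-separated channel emissions: mass 0.9 on level 0 vs level 4
        B = np.full((2, 4, 5), 0.025)
        B[0, :, 0] = 0.9
        B[1, :, 4] = 0.9
        true = HmmModel(np.array([0.5, 0.5]),
                        np.array([[0.9, 0.1], [0.2, 0.8]]),
                        CategoricalEmissions(B))
        rng = np.random.default_rng(6)
        obs = sample_from(true, 100, 50, rng)
        fit = em_fit(obs, 2, "categorical", n_restarts=3, seed=0)
        fit = permute_model(fit, match_states(true, fit))
        assert np.abs(fit.transmat - true.transmat).max() < 0.05
        assert np.abs(fit.emissions.probs - true.emissions.probs).max() < 0.05

    def test_monotone_loglik_enforced_internally(self):
        # the fitter raises if any iteration decreases the log-likelihood;
        # a spread of fits doubles as a regression test of that invariant
        rng = np.random.default_rng(7)
        for fam in ("categorical", "gaussian"):
            obs = sample_from(random_model(3, fam, rng), 6, 25, rng)
            for K in (1, 2, 3):
                em_fit(obs, K, fam, n_restarts=2, seed=int(rng.integers(1e6)))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        true = random_model(3, "categorical", rng)
        obs = sample_from(true, 20, 30, rng)
        fit = em_fit(obs, 3, "categorical", n_restarts=2, seed=9)
        perm = np.array([2, 0, 1])
        true_p = permute_model(true, perm)
        # matched recovery error identical whichever labelling generated it
        e1 = np.abs(permute_model(fit, match_states(true, fit)
                                  ).emissions.probs - true.emissions.probs).sum()
        e2 = np.abs(permute_model(fit, match_states(true_p, fit)
                                  ).emissions.probs - true_p.emissions.probs).sum()
        assert e1 == pytest.approx(e2, abs=1e-9)

    def test_concatenate_mode_single_chain(self):
        rng = np.random.default_rng(9)
        obs = sample_from(random_model(2, "gaussian", rng), 5, 20, rng)
        m = em_fit(obs, 2, "gaussian", n_restarts=2, seed=1, concatenate=True)
        cat = obs.concatenated()
        assert cat.lengths[0] == 100
        assert m.log_likelihood == pytest.approx(hmm.loglik(m, cat), abs=1e-6)


class TestBicSelection:
    def test_bic_arithmetic(self):
        m = HmmModel(np.array([1.0]), np.ones((1, 1)),
                     CategoricalEmissions(np.full((1, 4, 5), 0.2)),
                     log_likelihood=-100.0)
        assert m.n_params == 16
        obs = ObservationSet([np.zeros((560, 4), int)])
        # -2(-100) + 16 ln 560  (with p = 10: 200 + 10 ln 560 = 263.28)
        assert bic(m, obs) == pytest.approx(200 + 16 * np.log(560))
        assert 200 + 10 * np.log(560) == pytest.approx(263.28, abs=0.01)

    def test_param_counts(self):
        g = HmmModel(np.full(3, 1 / 3), np.full((3, 3), 1 / 3),
                     GaussianEmissions(np.zeros(3), np.ones(3)))
        assert g.n_params == 2 + 6 + 6
        c = HmmModel(np.full(2, 0.5), np.full((2, 2), 0.5),
                     CategoricalEmissions(np.full((2, 4, 5), 0.2)))
        assert c.n_params == 1 + 2 + 32

    def test_elbow_second_difference(self):
        # (1000, 600, 550, 545, 543): improvement drops sharpest after K=2
        assert hmm.choose_k([1, 2, 3, 4, 5],
                            [1000.0, 600, 550, 545, 543], "elbow") == 2

    def test_elbow_nonmonotone_falls_back(self):
        with pytest.warns(UserWarning):
            k = hmm.choose_k([1, 2, 3, 4], [1000.0, 600, 650, 700], "elbow")
        assert k == 2

    def test_select_k1_only(self):
        rng = np.random.default_rng(11)
        obs = sample_from(random_model(1, "gaussian", rng), 3, 20, rng)
        for crit in ("min_bic", "elbow"):
            _, k, _ = select_states(obs, [1], "gaussian", crit,
                                    n_restarts=1, seed=0)
            assert k == 1

    def test_elbow_on_fitted_sequence(self):
        rng = np.random.default_rng(12)
        true = HmmModel(np.array([0.5, 0.5]),
                        np.array([[0.9, 0.1], [0.1, 0.9]]),
                        GaussianEmissions(np.array([0.0, 2.0]),
                                          np.array([0.3, 0.3])))
        obs = sample_from(true, 30, 60, rng)
        tbl, k, _ = select_states(obs, range(1, 5), "gaussian", "elbow",
                                  n_restarts=2, seed=0)
        if np.all(np.diff(tbl["bic"]) < 0):
            assert k == 2
        # non-monotone sequences fall back to min-BIC with a warning

    def test_elbow_fallback_warns(self):
        rng = np.random.default_rng(13)
        # white noise: BIC rises with K, triggering the fallback
        obs = ObservationSet([rng.normal(0, 1, 80)])
        with pytest.warns(UserWarning):
            tbl, k, _ = select_states(obs, range(1, 4), "gaussian", "elbow",
                                      n_restarts=1, seed=0, max_iter=100)
        assert k == int(tbl.loc[tbl["bic"].idxmin(), "K"])

    def test_added_state_never_hurts_loglik(self):
        rng = np.random.default_rng(14)
        obs = sample_from(random_model(2, "categorical", rng), 10, 30, rng)
        lls = [em_fit(obs, k, "categorical", n_restarts=4, seed=3
                      ).log_likelihood for k in (1, 2, 3)]
        assert lls[0] <= lls[1] + 1e-6
        assert lls[1] <= lls[2] + 1e-6


class TestMatchStates:
    def test_identity(self):
        rng = np.random.default_rng(15)
        m = random_model(3, "categorical", rng)
        assert np.array_equal(match_states(m, m), [0, 1, 2])

    def test_swap(self):
        rng = np.random.default_rng(16)
        m = random_model(3, "gaussian", rng)
        perm = np.array([1, 2, 0])
        mp = permute_model(m, perm)
        assert np.array_equal(match_states(m, mp), np.argsort(perm))
        # applying the returned permutation restores the original ordering
        assert np.allclose(permute_model(mp, match_states(m, mp)
                                         ).emissions.means,
                           m.emissions.means)

    def test_assignment_is_bruteforce_minimum(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            a = random_model(3, "categorical", rng)
            b = random_model(3, "categorical", rng)
            perm = match_states(a, b)
            fa, fb = a.emissions.flat(), b.emissions.flat()
            cost = np.abs(fa[:, None, :] - fb[None, :, :]).sum(axis=2)
            got = cost[np.arange(3), perm].sum()
            best = min(cost[np.arange(3), list(p)].sum()
                       for p in itertools.permutations(range(3)))
            assert got == pytest.approx(best, abs=1e-12)

    def test_mismatched_models_rejected(self):
        rng = np.random.default_rng(18)
        with pytest.raises(ValueError):
            match_states(random_model(2, "categorical", rng),
                         random_model(3, "categorical", rng))
        with pytest.raises(ValueError):
            match_states(random_model(2, "categorical", rng),
                         random_model(2, "gaussian", rng))


class TestObservationSet:
    def test_probe_table_levels(self, small_probes):
        from attnstates.preprocess import clean_responses
        clean, _ = clean_responses(small_probes)
        obs = ObservationSet.from_probe_table(clean)
        assert obs.n_obs == len(clean)
        for s in obs.sequences:
            assert s.min() >= 0 and s.max() <= 4

    def test_rtv_table(self):
        import pandas as pd
        df = pd.DataFrame({"participant": ["a"] * 3 + ["b"] * 2,
                           "t": [0, 1, 2, 0, 1],
                           "rtv": [.1, .2, .3, .4, .5]})
        obs = ObservationSet.from_rtv_table(df)
        assert list(obs.lengths) == [3, 2]
        assert obs.n_obs == 5
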