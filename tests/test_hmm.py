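import itertools
import math

import numpy as np
import pandas as pd
import pytest

from arraycna.emission import EmissionParams, SNPProbe, emission_logdensity
from arraycna.hmm import (em_fit, fit_with_restarts, forward_backward,
                          likelihood_surface, rho, transition_probs, viterbi)
from arraycna.io import ProbeSet
from arraycna.priors import Hyperparams
from arraycna.simulate import SimConfig, simulate_sample
from conftest import toy_probeset


class TestTransitionModel:
    def test_zero_distance(self):
        stay, switch = transition_probs(100, 100, 2e6, 21)
        assert stay == 1.0 and switch == 0.0

    def test_large_distance_limit(self):
        assert rho(1e12, 2e6) == pytest.approx(0.5, abs=1e-12)

    def test_characteristic_length_value(self):
        expect = 0.5 * (1.0 - math.exp(-0.5))
        assert rho(2_000_000, 2_000_000) == pytest.approx(expect, abs=1e-12)

    def test_row_stochastic(self):
        stay, switch = transition_probs(0, 350_000, 2e6, 21)
        assert stay + 20 * switch == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_distance(self):
        d = np.linspace(0, 2e7, 50)
        r = np.array([rho(x, 2e6) for x in d])
        assert np.all(np.diff(r) > 0)
        assert np.all(r <= 0.5)

    def test_negative_distance_error(self):
        with pytest.raises(ValueError):
            transition_probs(200, 100, 2e6, 21)


def _pi_prior_masses(grid, alpha, beta):
    grid = np.asarray(grid, dtype=float)
    n_pos = (grid > 0).sum()
    m = np.where(grid == 0.0, alpha, beta / n_pos if n_pos else 0.0)
    return m / m.sum()


def _state_weights(states, bias):
    u = np.array([bias if s.id == 3 else 1.0 for s in states])
    return u / u.sum()


def _kernel_state(rho_val, u, switch_to_prior):
    S = len(u)
    if switch_to_prior:
        return (1 - rho_val) * np.eye(S) + rho_val * np.outer(np.ones(S), u)
    A = np.full((S, S), rho_val / (S - 1))
    np.fill_diagonal(A, 1 - rho_val)
    return A


def _kernel_uniform(rho_val, P):
    if P == 1:
        return np.ones((1, 1))
    A = np.full((P, P), rho_val / (P - 1))
    np.fill_diagonal(A, 1 - rho_val)
    return A


def _enumerate_chain(emis, trans, init):
    """Brute-force path enumeration: (per-position marginals, evidence, best path)."""
    n, S = emis.shape
    marg = np.zeros((n, S))
    evidence = 0.0
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(S), repeat=n):
        p = init[path[0]] * emis[0, path[0]]
        for t in range(1, n):
            p *= trans[t - 1][path[t - 1], path[t]] * emis[t, path[t]]
        evidence += p
        for t, s in enumerate(path):
            marg[t, s] += p
        lp = math.log(p) if p > 0 else -np.inf
        if lp > best_lp + 1e-15:
            best_lp, best_path = lp, path
    return marg / evidence, evidence, best_path


@pytest.fixture
def small_states(states):
    return [s for s in states if s.id in (2, 3, 4)]


def _emission_matrix(ps, small_states, params, pi0, pi_grid):
    """Collapsed (pi-marginalized) emission densities via the scalar reference."""
    masses = _pi_prior_masses(pi_grid, 1.0, 2.0)
    emis = np.zeros((len(ps), len(small_states)))
    for i in range(len(ps)):
        probe = SNPProbe("p", "1", int(ps.pos[i]), ps.lrr[i], ps.baf[i], ps.gc[i])
        for si, st_ in enumerate(small_states):
            vals = [math.log(m) + emission_logdensity(probe, st_, params, pi0, pi)
                    for pi, m in zip(pi_grid, masses)]
            emis[i, si] = math.exp(max(vals)) * sum(
                math.exp(v - max(vals)) for v in vals)
    return emis


class TestForwardBackwardOracle:
    @pytest.mark.parametrize("switch_to_prior", [True, False])
    def test_marginals_and_evidence(self, small_states, switch_to_prior):
        pi_grid = (0.0, 0.2)
        hyper = Hyperparams(pi_grid=pi_grid, switch_to_prior=switch_to_prior,
                            pi0_grid=(0.0, 0.3))
        params = EmissionParams.default(K=2)
        ps = toy_probeset(n=8, spacing=700_000, seed=9)
        emis = _emission_matrix(ps, small_states, params, 0.3, pi_grid)
        u = _state_weights(small_states, hyper.init_state_bias)
        trans = [_kernel_state(rho(float(d), hyper.L), u, switch_to_prior)
                 for d in np.diff(ps.pos)]
        want_marg, want_ev, _ = _enumerate_chain(emis, trans, u)
        got_marg, got_pi, got_ll = forward_backward(
            ps, params, 0.3, hyper, states=small_states)
        assert got_ll == pytest.approx(math.log(want_ev), abs=1e-10)
        assert np.allclose(got_marg, want_marg, atol=1e-10)

    def test_joint_chain_mode(self, small_states):
        # pi_i as part of the chain: enumerate over the product space
        pi_grid = (0.0, 0.3)
        hyper = Hyperparams(pi_grid=pi_grid, pi_iid=False,
                            switch_to_prior=True, pi0_grid=(0.0, 0.3))
        params = EmissionParams.default(K=2)
        ps = toy_probeset(n=5, spacing=900_000, seed=13)
        S, P = len(small_states), len(pi_grid)
        emis = np.zeros((len(ps), S * P))
        for i in range(len(ps)):
            probe = SNPProbe("p", "1", int(ps.pos[i]), ps.lrr[i], ps.baf[i],
                             ps.gc[i])
            for si, st_ in enumerate(small_states):
                for pj, pi in enumerate(pi_grid):
                    emis[i, si * P + pj] = math.exp(
                        emission_logdensity(probe, st_, params, 0.3, pi))
        u = _state_weights(small_states, hyper.init_state_bias)
        masses = _pi_prior_masses(pi_grid, hyper.alpha_pi, hyper.beta_pi)
        init = np.kron(u, masses)
        trans = [np.kron(_kernel_state(rho(float(d), hyper.L), u, True),
                         _kernel_uniform(rho(float(d), hyper.L), P))
                 for d in np.diff(ps.pos)]
        want_marg, want_ev, want_path = _enumerate_chain(emis, trans, init)
        got_marg, got_pi, got_ll = forward_backward(
            ps, params, 0.3, hyper, states=small_states)
        assert got_ll == pytest.approx(math.log(want_ev), abs=1e-10)
        joint = want_marg.reshape(len(ps), S, P)
        assert np.allclose(got_marg, joint.sum(axis=2), atol=1e-10)
        assert np.allclose(got_pi, joint.sum(axis=1), atol=1e-10)
        ids, pis = viterbi(ps, params, 0.3, hyper, states=small_states)
        want_s = [divmod(s, P)[0] for s in want_path]
        want_p = [divmod(s, P)[1] for s in want_path]
        assert list(ids) == [small_states[s].id for s in want_s]
        assert list(pis) == want_p

    def test_single_probe(self, small_states):
        hyper = Hyperparams(pi_grid=(0.0,), pi0_grid=(0.0,))
        params = EmissionParams.default(K=2)
        df = toy_probeset(n=1).df
        ps = ProbeSet(df)
        emis = _emission_matrix(ps, small_states, params, 0.0, (0.0,))
        u = _state_weights(small_states, hyper.init_state_bias)
        want = u * emis[0]
        want /= want.sum()
        got_marg, _, got_ll = forward_backward(ps, params, 0.0, hyper,
                                               states=small_states)
        assert np.allclose(got_marg[0], want, atol=1e-12)
        assert got_ll == pytest.approx(math.log((u * emis[0]).sum()), abs=1e-10)

    def test_uniform_emissions_give_prior_marginals(self, small_states):
        # eta = 1 makes the emission identical across states
        hyper = Hyperparams(pi_grid=(0.0,), pi0_grid=(0.0,))
        params = EmissionParams.default(K=2)
        params.eta = 1.0
        ps = toy_probeset(n=6, lrr_scale=0.1)
        u = _state_weights(small_states, hyper.init_state_bias)
        marg, _, _ = forward_backward(ps, params, 0.0, hyper,
                                      states=small_states)
        # prior chain marginals: init propagated through the kernels
        expect = [u]
        for d in np.diff(ps.pos):
            expect.append(expect[-1] @ _kernel_state(rho(float(d), hyper.L),
                                                     u, True))
        assert np.allclose(marg, expect, atol=1e-12)

    def test_unsorted_input_error(self):
        df = toy_probeset(n=4).df
        df.loc[2, "pos"] = 1  # out of order
        with pytest.raises(ValueError, match="sorted"):
            ProbeSet(df, sort=False)

    def test_nonfinite_emission_error(self, small_states):
        params = EmissionParams.default(K=2)
        params.eta = 1.0
        params.r_min, params.r_max = -0.01, 0.01  # data falls outside
        hyper = Hyperparams(pi_grid=(0.0,), pi0_grid=(0.0,))
        ps = toy_probeset(n=4)
        with pytest.raises(FloatingPointError):
            forward_backward(ps, params, 0.0, hyper, states=small_states)


class TestViterbiOracle:
    @pytest.mark.parametrize("switch_to_prior", [True, False])
    def test_matches_enumeration(self, small_states, switch_to_prior):
        pi_grid = (0.0,)
        hyper = Hyperparams(pi_grid=pi_grid, switch_to_prior=switch_to_prior,
                            pi0_grid=(0.0, 0.3))
        params = EmissionParams.default(K=2)
        ps = toy_probeset(n=8, spacing=600_000, seed=21)
        emis = _emission_matrix(ps, small_states, params, 0.3, pi_grid)
        u = _state_weights(small_states, hyper.init_state_bias)
        trans = [_kernel_state(rho(float(d), hyper.L), u, switch_to_prior)
                 for d in np.diff(ps.pos)]
        _, _, want_path = _enumerate_chain(emis, trans, u)
        ids, _ = viterbi(ps, params, 0.3, hyper, states=small_states)
        assert list(ids) == [small_states[s].id for s in want_path]

    def test_overwhelming_emissions_constant_path(self, states):
        cfg = SimConfig(n_probes=120, n_chroms=1, state_weights={4: 1.0},
                        noise_scale_lrr=0.02, noise_scale_baf=0.01,
                        outlier_rate_true=0.0, seed=4)
        probes, truth = simulate_sample(cfg)
        hyper = Hyperparams(pi_grid=(0.0,))
        params = EmissionParams.default(K=2)
        ids, _ = viterbi(probes, params, 0.0, hyper)
        assert set(ids.tolist()) == {4}

    def test_tie_break_lower_state_id(self, small_states):
        # eta = 1: all states emit identically, unbiased init -> full tie
        params = EmissionParams.default(K=2)
        params.eta = 1.0
        hyper = Hyperparams(pi_grid=(0.0,), init_state_bias=1.0)
        ps = toy_probeset(n=5)
        ids, _ = viterbi(ps, params, 0.0, hyper, states=small_states)
        assert ids.tolist() == [2] * 5


def _easy_sample(pi0=0.25, n=1200, seed=0, **kw):
    cfg = SimConfig(n_probes=n, n_chroms=4, pi0_true=pi0, seed=seed,
                    noise_scale_lrr=0.15, noise_scale_baf=0.03, **kw)
    return simulate_sample(cfg)


class TestEmFit:
    def test_monotone_trace(self, hyper_small):
        for seed in (0, 1, 2):
            probes, _ = _easy_sample(pi0=0.2, n=400, seed=seed)
            init = EmissionParams.default(K=2, lrr=probes["lrr"].to_numpy())
            fit = em_fit(probes, init=init, hyper=hyper_small, n_iters=8)
            diffs = np.diff(fit.loglik_trace)
            floor = -1e-6 * np.maximum(1.0, np.abs(fit.loglik_trace[:-1]))
            assert np.all(diffs >= floor), fit.loglik_trace

    def test_posteriors_normalized(self, hyper_small):
        probes, _ = _easy_sample(n=300)
        fit = em_fit(probes, init=EmissionParams.default(K=2),
                     hyper=hyper_small, n_iters=3)
        assert np.allclose(fit.state_posteriors.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(fit.pi_posterior.sum(axis=1), 1.0, atol=1e-8)

    def test_near_truth_is_stable(self, hyper_small):
        probes, _ = _easy_sample(pi0=0.25, n=4000, seed=7)
        init = EmissionParams.default(K=2, lrr=probes["lrr"].to_numpy())
        fit = em_fit(probes, init=init, pi0_init=0.25, hyper=hyper_small,
                     n_iters=15)
        assert fit.pi0 == pytest.approx(0.25, abs=0.051)
        assert abs(fit.params.beta0) < 0.05

    def test_unknown_variant(self, hyper_small):
        probes, _ = _easy_sample(n=50)
        with pytest.raises(ValueError):
            em_fit(probes, hyper=hyper_small, variant="bogus")

    def test_germline_variant_pins_parameters(self, hyper_small):
        probes, _ = _easy_sample(n=300)
        fit = em_fit(probes, init=EmissionParams.default(K=2),
                     hyper=hyper_small, n_iters=3, variant="germline")
        assert fit.pi0 == 0.0
        assert fit.params.beta0 == 0.0


class TestRestartsAndVariants:
    def test_grid_of_one_equals_em_fit(self):
        hyper = Hyperparams(pi_grid=(0.0,))
        probes, _ = _easy_sample(n=400, seed=3)
        init = EmissionParams.default(K=2, lrr=probes["lrr"].to_numpy())
        init.beta0 = 0.1
        direct = em_fit(probes, init=init, hyper=hyper, n_iters=10)
        wrapped = fit_with_restarts(probes, hyper=hyper, baseline_grid=[0.1],
                                    pi0_init_grid=(0.0,), init=init,
                                    n_iters=10)
        assert wrapped.penalized_loglik == pytest.approx(
            direct.penalized_loglik, abs=1e-6)
        assert wrapped.pi0 == direct.pi0
        assert wrapped.params.beta0 == pytest.approx(direct.params.beta0,
                                                     abs=1e-9)
        assert np.array_equal(wrapped.viterbi_path, direct.viterbi_path)

    def test_empty_grid_error(self, hyper_small):
        probes, _ = _easy_sample(n=50)
        with pytest.raises(ValueError):
            fit_with_restarts(probes, hyper=hyper_small, baseline_grid=[])

    def test_variant_nesting(self, hyper_small):
        # every restricted optimum is a feasible start for the full model, so
        # warm-starting the full EM there guarantees it cannot end lower
        probes, _ = _easy_sample(pi0=0.25, n=1500, seed=5)
        init = EmissionParams.default(K=2, lrr=probes["lrr"].to_numpy())
        fits = {v: fit_with_restarts(probes, hyper=hyper_small, init=init,
                                     variant=v, n_iters=10)
                for v in ("germline", "ploidy_only", "normal_only", "full")}
        full_ll = fits["full"].penalized_loglik
        for v in ("germline", "ploidy_only", "normal_only"):
            warm = em_fit(probes, init=fits[v].params, pi0_init=fits[v].pi0,
                          hyper=hyper_small, n_iters=10, variant="full")
            full_ll = max(full_ll, warm.penalized_loglik)
            assert full_ll >= fits[v].penalized_loglik - 1e-6, v

    def test_restart_summaries_recorded(self, hyper_small):
        probes, _ = _easy_sample(n=300)
        fit = fit_with_restarts(probes, hyper=hyper_small,
                                baseline_grid=[0.0, -0.4],
                                pi0_init_grid=(0.0,), n_iters=4)
        assert len(fit.restarts) == 2
        assert {r["beta0_init"] for r in fit.restarts} == {0.0, -0.4}


class TestLikelihoodSurface:
    def test_one_by_one_grid(self):
        hyper = Hyperparams(pi_grid=(0.0,))
        probes, _ = _easy_sample(n=300, seed=2)
        init = EmissionParams.default(K=2, lrr=probes["lrr"].to_numpy())
        surf = likelihood_surface(probes, [0.0], [0.1], hyper, init=init,
                                  refine_iters=4)
        from dataclasses import replace
        direct = em_fit(probes, init=init, hyper=replace(hyper, pi0_grid=(0.0,)),
                        n_iters=4, tol=0.0, fix_pi0=0.0, fix_beta0=0.1)
        assert surf.shape == (1, 1)
        assert surf[0, 0] == pytest.approx(direct.penalized_loglik, abs=1e-8)

    def test_empty_grid_error(self, hyper_small):
        probes, _ = _easy_sample(n=50)
        with pytest.raises(ValueError):
            likelihood_surface(probes, [], [0.0], hyper_small)
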