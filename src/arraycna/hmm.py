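"""Inhomogeneous HMM over tumor states x heterogeneity levels.

The chain runs over the product space (tumor state, pi_i level).  Both factors
follow the distance-dependent kernel: with switch probability
``rho = (1/2)(1 - exp(-d / (2 L)))`` the total switch mass is split uniformly
over the other values, so the self-transition probability matches the printed
model and every row is stochastic.  Chromosome boundaries restart the chain at
the initial distribution (normal-state biased, pi_i prior weighted).

Fitting is MAP-EM: exact forward-backward E-step plus conditional-conjugate
M-step updates (Dirichlet-smoothed weights, Normal-Inverse-Wishart offsets and
covariances with Student-t scale weights, Beta outlier rate, penalized weighted
least squares for the LRR regression, and a grid scan for pi0), so the
penalized log likelihood is non-decreasing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .emission import EmissionEngine, EmissionParams
from .io import as_probeset
from .priors import Hyperparams, log_prior, pi_log_prior, pi0_log_prior
from .state_space import NORMAL_STATE_ID, TumorState, build_state_table

log = logging.getLogger(__name__)

#: Model variants: (fixed pi0, fixed beta0); ``None`` leaves the parameter free.
VARIANTS = {
    "germline": (0.0, 0.0),
    "ploidy": (0.0, None),
    "ploidy_only": (0.0, None),
    "normal": (None, 0.0),
    "normal_only": (None, 0.0),
    "full": (None, None),
}


def rho(distance: float, L: float) -> float:
    """Switch probability of the distance-dependent transition kernel."""
    if distance < 0:
        raise ValueError("probe distance must be non-negative")
    if L <= 0:
        raise ValueError("characteristic length L must be positive")
    return 0.5 * (1.0 - math.exp(-distance / (2.0 * L)))


def transition_probs(pos_prev: float, pos_cur: float, L: float,
                     n_states: int) -> tuple[float, float]:
    """(stay, per-other-state switch) probabilities between adjacent probes."""
    r = rho(pos_cur - pos_prev, L)
    switch = r / (n_states - 1) if n_states > 1 else 0.0
    return 1.0 - r, switch


@dataclass
class HMMFit:
    """A fitted model: parameters, posteriors and the Viterbi decoding."""

    params: EmissionParams
    pi0: float
    pi_grid: tuple
    loglik_trace: list
    state_posteriors: np.ndarray       # (n, S)
    pi_posterior: np.ndarray           # (n, P)
    viterbi_path: np.ndarray           # (n,) tumor-state ids
    viterbi_pi: np.ndarray             # (n,) indices into pi_grid
    variant: str
    evidence: float
    log_prior_value: float
    n_iters_run: int
    converged: bool
    state_ids: np.ndarray = None
    restarts: list = field(default_factory=list)

    @property
    def penalized_loglik(self) -> float:
        return self.loglik_trace[-1]


def _state_init(states: Sequence[TumorState], hyper: Hyperparams) -> np.ndarray:
    w = np.ones(len(states))
    for i, s in enumerate(states):
        if s.id == NORMAL_STATE_ID:
            w[i] *= hyper.init_state_bias
    return w / w.sum()


def _initial_distribution(states: Sequence[TumorState],
                          hyper: Hyperparams) -> np.ndarray:
    pi_p = np.exp(pi_log_prior(hyper))
    return _state_init(states, hyper)[:, None] * pi_p[None, :]


def _marginal_emissions(logB: np.ndarray, hyper: Hyperparams):
    """Marginalize the i.i.d. pi_i prior out of (n, S, P) emissions.

    Returns the collapsed (n, S) log densities and the per-probe conditional
    posterior over pi levels given each state.
    """
    lp = logB + pi_log_prior(hyper)[None, None, :]
    mx = lp.max(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sums = np.exp(lp - mx[:, :, None]).sum(axis=2)
        collapsed = np.where(np.isfinite(mx), np.log(np.maximum(sums, 1e-300)) + mx,
                             -np.inf)
        w = np.where(np.isfinite(mx[:, :, None]),
                     np.exp(lp - collapsed[:, :, None]), 0.0)
    return collapsed, w


def _joint_posteriors(cache, ps, states, hyper: Hyperparams):
    """Joint (n, S, P) posteriors and log evidence under either pi_i treatment."""
    P = cache.logB.shape[2]
    u = _state_init(states, hyper) if hyper.switch_to_prior else None
    if hyper.pi_iid or P == 1:
        collapsed, w = _marginal_emissions(cache.logB, hyper)
        gamma_s, loglik = _fb_joint(collapsed[:, :, None], ps.pos, ps.blocks(),
                                    hyper.L, _state_init(states, hyper)[:, None],
                                    u)
        gamma = gamma_s * w
    else:
        init = _initial_distribution(states, hyper)
        gamma, loglik = _fb_joint(cache.logB, ps.pos, ps.blocks(), hyper.L,
                                  init, u)
    return gamma, loglik


def _decode(cache, ps, states, hyper: Hyperparams):
    """Viterbi decoding under either pi_i treatment: (state-index, pi-index) paths."""
    P = cache.logB.shape[2]
    u = _state_init(states, hyper) if hyper.switch_to_prior else None
    if hyper.pi_iid or P == 1:
        collapsed, w = _marginal_emissions(cache.logB, hyper)
        path_s, _ = _viterbi_joint(collapsed[:, :, None], ps.pos, ps.blocks(),
                                   hyper.L, _state_init(states, hyper)[:, None],
                                   u)
        path_p = w[np.arange(len(path_s)), path_s].argmax(axis=1)
    else:
        init = _initial_distribution(states, hyper)
        path_s, path_p = _viterbi_joint(cache.logB, ps.pos, ps.blocks(),
                                        hyper.L, init, u)
    return path_s, path_p


def _apply_fwd(v: np.ndarray, r: float, u) -> np.ndarray:
    """Propagate a (S, P) distribution forward through the product kernel.

    The state axis either redistributes the switch mass uniformly over the
    other states (``u is None``) or resamples the biased state prior ``u``;
    the pi axis always switches uniformly.
    """
    S, P = v.shape
    if S > 1:
        if u is None:
            v = (1.0 - r) * v + (r / (S - 1)) * (v.sum(axis=0, keepdims=True) - v)
        else:
            v = (1.0 - r) * v + r * u[:, None] * v.sum(axis=0, keepdims=True)
    if P > 1:
        v = (1.0 - r) * v + (r / (P - 1)) * (v.sum(axis=1, keepdims=True) - v)
    return v


def _apply_bwd(w: np.ndarray, r: float, u) -> np.ndarray:
    """Transpose-direction propagation (backward recursion)."""
    S, P = w.shape
    if S > 1:
        if u is None:
            w = (1.0 - r) * w + (r / (S - 1)) * (w.sum(axis=0, keepdims=True) - w)
        else:
            w = (1.0 - r) * w + r * (u[:, None] * w).sum(axis=0, keepdims=True)
    if P > 1:
        w = (1.0 - r) * w + (r / (P - 1)) * (w.sum(axis=1, keepdims=True) - w)
    return w


def _fb_joint(logB: np.ndarray, pos: np.ndarray, blocks, L: float,
              init: np.ndarray, u=None):
    """Scaled forward-backward over independent chromosome blocks.

    Returns joint posteriors (n, S, P) and the data log evidence.
    """
    n, S, P = logB.shape
    gamma = np.empty_like(logB)
    loglik = 0.0
    for i0, i1 in blocks:
        m = i1 - i0
        sub = logB[i0:i1]
        mx = sub.max(axis=(1, 2))
        if not np.all(np.isfinite(mx)):
            bad = i0 + int(np.flatnonzero(~np.isfinite(mx))[0])
            raise FloatingPointError(
                f"non-finite emission density at probe index {bad}")
        w = np.exp(sub - mx[:, None, None])
        rhos = np.array([rho(float(pos[i]) - float(pos[i - 1]), L)
                         for i in range(i0 + 1, i1)])
        alpha = np.empty((m, S, P))
        c = np.empty(m)
        a = init * w[0]
        c[0] = a.sum()
        alpha[0] = a / c[0]
        for t in range(1, m):
            a = _apply_fwd(alpha[t - 1], rhos[t - 1], u) * w[t]
            c[t] = a.sum()
            alpha[t] = a / c[t]
        beta = np.ones((S, P))
        gamma[i1 - 1] = alpha[m - 1]
        for t in range(m - 2, -1, -1):
            beta = _apply_bwd(w[t + 1] * beta, rhos[t], u) / c[t + 1]
            gm = alpha[t] * beta
            gamma[i0 + t] = gm / gm.sum()
        loglik += float(np.log(c).sum() + mx.sum())
    return gamma, loglik


def _log_kernels(r: float, S: int, P: int, u=None):
    with np.errstate(divide="ignore"):
        ls_stay = math.log1p(-r)
        lp_sw = np.log(r / (P - 1)) if P > 1 and r > 0 else -np.inf
        if u is None:
            ls_sw = np.log(r / (S - 1)) if S > 1 and r > 0 else -np.inf
            logAs = np.full((S, S), ls_sw)
            np.fill_diagonal(logAs, ls_stay if S > 1 else 0.0)
        else:
            logAs = np.log(np.maximum(r * u, 1e-300))[None, :].repeat(S, axis=0)
            np.fill_diagonal(logAs, np.log(1.0 - r + r * u))
    logAp = np.full((P, P), lp_sw)
    np.fill_diagonal(logAp, ls_stay if P > 1 else 0.0)
    return logAs, logAp


def _viterbi_joint(logB: np.ndarray, pos: np.ndarray, blocks, L: float,
                   init: np.ndarray, u=None):
    """Most probable joint (state, pi-level) path; ties break toward lower index."""
    n, S, P = logB.shape
    path_s = np.empty(n, dtype=int)
    path_p = np.empty(n, dtype=int)
    log_init = np.log(np.maximum(init, 1e-300))
    for i0, i1 in blocks:
        m = i1 - i0
        sub = logB[i0:i1]
        score = log_init + sub[0]
        back = []
        for t in range(1, m):
            r = rho(float(pos[i0 + t]) - float(pos[i0 + t - 1]), L)
            logAs, logAp = _log_kernels(r, S, P, u)
            m1 = score[:, :, None] + logAp[None, :, :]          # (S, P, P')
            b1 = m1.argmax(axis=1)
            t1 = np.take_along_axis(m1, b1[:, None, :], axis=1)[:, 0, :]
            m2 = t1[:, None, :] + logAs[:, :, None]             # (S, S', P')
            b2 = m2.argmax(axis=0)
            t2 = np.take_along_axis(m2, b2[None, :, :], axis=0)[0]
            score = t2 + sub[t]
            back.append((b1.astype(np.int16), b2.astype(np.int16)))
        s, p = np.unravel_index(int(np.argmax(score)), (S, P))
        path_s[i1 - 1], path_p[i1 - 1] = s, p
        for t in range(m - 1, 0, -1):
            b1, b2 = back[t - 1]
            s_prev = int(b2[s, p])
            p_prev = int(b1[s_prev, p])
            s, p = s_prev, p_prev
            path_s[i0 + t - 1], path_p[i0 + t - 1] = s, p
    return path_s, path_p


def forward_backward(probes, params: EmissionParams, pi0: float,
                     hyper: Hyperparams, states: Optional[list] = None,
                     pop_b_freq: float = 0.5):
    """Exact posterior marginals over states and pi_i levels, plus log evidence."""
    ps = as_probeset(probes)
    states = states or build_state_table()
    engine = EmissionEngine(states, params, hyper.pi_grid, pop_b_freq)
    cache = engine.log_b(ps, pi0)
    gamma, loglik = _joint_posteriors(cache, ps, states, hyper)
    return gamma.sum(axis=2), gamma.sum(axis=1), loglik


def viterbi(probes, params: EmissionParams, pi0: float, hyper: Hyperparams,
            states: Optional[list] = None, pop_b_freq: float = 0.5):
    """Jointly most probable path, as (state-id path, pi-level-index path)."""
    ps = as_probeset(probes)
    states = states or build_state_table()
    engine = EmissionEngine(states, params, hyper.pi_grid, pop_b_freq)
    cache = engine.log_b(ps, pi0)
    path_s, path_p = _decode(cache, ps, states, hyper)
    ids = np.array([s.id for s in states])
    return ids[path_s], path_p


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def _spd(mat: np.ndarray, floor: float = 1e-9) -> np.ndarray:
    mat = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(mat)
    return (vecs * np.maximum(vals, floor)) @ vecs.T


def _quad_total(mom, mu_r, mu_b, a, ab, c, b0, b1) -> float:
    """Sum of weighted Mahalanobis quadratic forms over all cells.

    All arguments are broadcastable to the (M, P, K) moment arrays; ``mu_*``
    exclude the beta regression, which enters through ``b0``/``b1``.
    """
    A_r = b0 * mom.M0 + b1 * mom.M0g
    srr = (mom.Myy_rr - 2 * mu_r * mom.My_r - 2 * b0 * mom.My_r
           - 2 * b1 * mom.Myg_r + mu_r * mu_r * mom.M0 + 2 * mu_r * A_r
           + b0 * b0 * mom.M0 + 2 * b0 * b1 * mom.M0g + b1 * b1 * mom.M0gg)
    srb = (mom.Myy_rb - mu_b * mom.My_r - mu_r * mom.My_b
           + mu_r * mu_b * mom.M0 - b0 * mom.My_b - b1 * mom.Myg_b
           + mu_b * A_r)
    sbb = mom.Myy_bb - 2 * mu_b * mom.My_b + mu_b * mu_b * mom.M0
    return float((a * srr + 2.0 * ab * srb + c * sbb).sum())


def _m_step(mom, engine: EmissionEngine, params: EmissionParams,
            hyper: Hyperparams, pi0: float, has_gc: bool,
            fix_pi0, fix_beta0):
    K = params.K
    new = params.copy()
    base_r, m_b, cls = engine.means(pi0)

    # mixture weights (Dirichlet MAP) and outlier rate (Beta MAP)
    for l in range(3):
        mask = cls == l
        counts = mom.N[mask].sum(axis=0) + (hyper.alpha - 1.0)
        counts = np.maximum(counts, 0.0)
        if counts.sum() > 0:
            new.weights[l] = counts / counts.sum()
    denom = mom.n + hyper.alpha_eta + hyper.beta_eta - 2.0
    eta = (mom.out_sum + hyper.alpha_eta - 1.0) / denom if denom > 0 \
        else mom.out_sum / mom.n
    new.eta = float(np.clip(eta, 1e-8, 0.9))

    # component offsets and covariances (Normal-Inverse-Wishart MAP)
    b0o, b1o = params.beta0, params.beta1
    S_prior = np.asarray(hyper.S, dtype=float)
    for l in range(3):
        mask = cls == l
        br, bb = base_r[mask], m_b[mask]           # (C,)
        for k in range(K):
            M0 = mom.M0[mask][:, k]
            M0g = mom.M0g[mask][:, k]
            sum_gl = M0.sum()
            u_r = (mom.My_r[mask][:, k].sum() - (br * M0).sum()
                   - b0o * sum_gl - b1o * M0g.sum())
            u_b = mom.My_b[mask][:, k].sum() - (bb * M0).sum()
            delta = np.array([u_r, u_b]) / (sum_gl + 1.0 / hyper.tau)
            new.delta[k, l] = delta
            mu_r = br + delta[0]
            mu_b = bb + delta[1]
            A_r = b0o * M0 + b1o * M0g
            My_r = mom.My_r[mask][:, k]
            My_b = mom.My_b[mask][:, k]
            Myg_r = mom.Myg_r[mask][:, k]
            Myg_b = mom.Myg_b[mask][:, k]
            srr = (mom.Myy_rr[mask][:, k] - 2 * mu_r * My_r - 2 * b0o * My_r
                   - 2 * b1o * Myg_r + mu_r ** 2 * M0 + 2 * mu_r * A_r
                   + b0o ** 2 * M0 + 2 * b0o * b1o * M0g
                   + b1o ** 2 * mom.M0gg[mask][:, k]).sum()
            srb = (mom.Myy_rb[mask][:, k] - mu_b * My_r - mu_r * My_b
                   + mu_r * mu_b * M0 - b0o * My_b - b1o * Myg_b
                   + mu_b * A_r).sum()
            sbb = (mom.Myy_bb[mask][:, k] - 2 * mu_b * My_b
                   + mu_b ** 2 * M0).sum()
            scatter = np.array([[srr, srb], [srb, sbb]])
            nsum = mom.N[mask][:, k].sum()
            sig = (S_prior + np.outer(delta, delta) / hyper.tau + scatter) / \
                (nsum + hyper.gamma + 4.0)
            new.sigma[k, l] = _spd(sig)

    # LRR regression (penalized weighted least squares) with the new offsets
    inv = np.stack([[np.linalg.inv(new.sigma[k, l]) for l in range(3)]
                    for k in range(K)])          # (K, 3, 2, 2)
    A = np.eye(2) / hyper.lambda_beta
    rhs = np.zeros(2)
    for l in range(3):
        mask = cls == l
        br, bb = base_r[mask], m_b[mask]
        for k in range(K):
            a = inv[k, l, 0, 0]
            ab = inv[k, l, 0, 1]
            mu_r = br + new.delta[k, l, 0]
            mu_b = bb + new.delta[k, l, 1]
            M0 = mom.M0[mask][:, k]
            M0g = mom.M0g[mask][:, k]
            A[0, 0] += a * M0.sum()
            A[0, 1] += a * M0g.sum()
            A[1, 1] += a * mom.M0gg[mask][:, k].sum()
            rhs[0] += (a * (mom.My_r[mask][:, k] - mu_r * M0).sum()
                       + ab * (mom.My_b[mask][:, k] - mu_b * M0).sum())
            rhs[1] += (a * (mom.Myg_r[mask][:, k] - mu_r * M0g).sum()
                       + ab * (mom.Myg_b[mask][:, k] - mu_b * M0g).sum())
    A[1, 0] = A[0, 1]
    if fix_beta0 is not None:
        new.beta0 = float(fix_beta0)
        new.beta1 = float((rhs[1] - A[1, 0] * new.beta0) / A[1, 1]) if has_gc else 0.0
    elif not has_gc:
        new.beta1 = 0.0
        new.beta0 = float(rhs[0] / A[0, 0])
    else:
        sol = np.linalg.solve(A, rhs)
        new.beta0, new.beta1 = float(sol[0]), float(sol[1])

    # Gauge projection: adding s to beta0 while subtracting s from every LRR
    # offset leaves the likelihood untouched, so resolve the split by
    # maximizing the prior along that direction (closed form).  This keeps
    # beta0 identifiable instead of letting it drift against the offsets.
    if fix_beta0 is None:
        prec_b = 1.0 / hyper.lambda_beta
        num, den = -new.beta0 * prec_b, prec_b
        for k in range(K):
            for l in range(3):
                P = inv[k, l] / hyper.tau
                num += P[0, 0] * new.delta[k, l, 0] + P[0, 1] * new.delta[k, l, 1]
                den += P[0, 0]
        s = num / den
        new.beta0 += s
        new.delta[:, :, 0] -= s

    # pi0 grid scan with the updated offsets/covariances/regression
    if fix_pi0 is not None:
        pi0_new = float(fix_pi0)
    else:
        grid = np.asarray(hyper.pi0_grid, dtype=float)
        lp0 = pi0_log_prior(hyper)
        nu = params.nu
        from scipy.special import gammaln
        norm_c = (gammaln((nu + 2) / 2.0) - gammaln(nu / 2.0)
                  - np.log(nu * np.pi)
                  - 0.5 * np.array([[np.linalg.slogdet(new.sigma[k, l])[1]
                                     for l in range(3)] for k in range(K)]))
        best_q, pi0_new = -np.inf, pi0
        for gi, cand in enumerate(grid):
            br_c, mb_c, cls_c = engine.means(float(cand))
            a_mk = np.moveaxis(inv[:, cls_c, 0, 0], 0, -1)     # (M, P, K)
            ab_mk = np.moveaxis(inv[:, cls_c, 0, 1], 0, -1)
            c_mk = np.moveaxis(inv[:, cls_c, 1, 1], 0, -1)
            dr = np.moveaxis(new.delta[:, cls_c, 0], 0, -1)
            db = np.moveaxis(new.delta[:, cls_c, 1], 0, -1)
            mu_r = br_c[:, :, None] + dr
            mu_b = mb_c[:, :, None] + db
            q = (-0.5 * _quad_total(mom, mu_r, mu_b, a_mk, ab_mk, c_mk,
                                    new.beta0, new.beta1)
                 + float((mom.N * np.moveaxis(norm_c[:, cls_c], 0, -1)).sum())
                 + float(lp0[gi]))
            if q > best_q:
                best_q, pi0_new = q, float(cand)
    return new, pi0_new


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

def em_fit(probes, init: Optional[EmissionParams] = None, pi0_init: float = 0.0,
           hyper: Optional[Hyperparams] = None, n_iters: int = 15,
           variant: str = "full", tol: float = 1e-6,
           states: Optional[list] = None, pop_b_freq: float = 0.5,
           fix_pi0=None, fix_beta0=None) -> HMMFit:
    """MAP-EM fit (E-step forward-backward, conditional-conjugate M-step).

    ``variant`` constrains parameters (germline: pi0 = beta0 = 0; ploidy-only:
    pi0 = 0; normal-only: beta0 = 0); explicit ``fix_*`` values override it.
    Runs at most ``n_iters`` iterations, stopping early when the penalized log
    likelihood changes by less than ``tol`` (relative).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    ps = as_probeset(probes)
    hyper = hyper or Hyperparams()
    hyper.validate()
    states = states or build_state_table()
    v_pi0, v_beta0 = VARIANTS[variant]
    fix_pi0 = v_pi0 if fix_pi0 is None else fix_pi0
    fix_beta0 = v_beta0 if fix_beta0 is None else fix_beta0
    params = (init.copy() if init is not None
              else EmissionParams.default(lrr=ps.lrr))
    if fix_beta0 is not None:
        params.beta0 = float(fix_beta0)
    params.validate()
    pi0 = float(fix_pi0) if fix_pi0 is not None else float(pi0_init)
    engine = EmissionEngine(states, params, hyper.pi_grid, pop_b_freq)
    trace: list[float] = []
    converged = False
    gamma = None
    for it in range(n_iters + 1):
        cache = engine.log_b(ps, pi0)
        gamma, loglik = _joint_posteriors(cache, ps, states, hyper)
        if not np.isfinite(loglik):
            raise FloatingPointError("non-finite data log likelihood during EM")
        pen = loglik + log_prior(params, pi0, hyper)
        trace.append(pen)
        if it >= n_iters:
            break
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= \
                tol * max(1.0, abs(trace[-2])):
            converged = True
            break
        mom = engine.estep_moments(ps, cache, gamma)
        params, pi0 = _m_step(mom, engine, params, hyper, pi0, ps.has_gc,
                              fix_pi0, fix_beta0)
        engine.set_params(params)
    path_s, path_p = _decode(cache, ps, states, hyper)
    ids = np.array([s.id for s in states])
    return HMMFit(
        params=params,
        pi0=pi0,
        pi_grid=tuple(hyper.pi_grid),
        loglik_trace=trace,
        state_posteriors=gamma.sum(axis=2),
        pi_posterior=gamma.sum(axis=1),
        viterbi_path=ids[path_s],
        viterbi_pi=path_p,
        variant=variant,
        evidence=loglik,
        log_prior_value=trace[-1] - loglik,
        n_iters_run=len(trace) - 1,
        converged=converged,
        state_ids=ids,
    )


def default_baseline_grid(params: Optional[EmissionParams] = None) -> list[float]:
    """Baseline restart inits spanning diploid through tetraploid normalization."""
    lv = (params.lrr_levels if params is not None
          else EmissionParams.default().lrr_levels)
    return [0.0, -float(lv[3]), -float(lv[4]), -float(lv[1]) / 2.0]


def fit_with_restarts(probes, hyper: Optional[Hyperparams] = None,
                      baseline_grid: Optional[Sequence[float]] = None,
                      variant: str = "full",
                      init: Optional[EmissionParams] = None,
                      pi0_init_grid: Sequence[float] = (0.0, 0.25, 0.5),
                      n_iters: int = 15,
                      tol: float = 1e-6, states: Optional[list] = None,
                      pop_b_freq: float = 0.5,
                      refine_heterogeneity: bool = True,
                      screen_iters: int = 5, n_keep: int = 3) -> HMMFit:
    """Explore baseline (and pi0) restarts and keep the most likely fit.

    The purity/ploidy selection stage runs EM from every (beta0, pi0) start
    with the heterogeneity levels pinned at zero — the restricted model keeps
    the genome-doubled and contamination-shifted readings comparable on equal
    footing — and the winner is the restart with the greatest penalized log
    likelihood.  Restarts are screened with ``screen_iters`` short EM runs and
    only the ``n_keep`` best continue to ``n_iters`` (EM is memoryless, so a
    continued run equals an uninterrupted one).  When the pi_i grid has more
    than one level (and ``refine_heterogeneity``), a final EM pass
    re-estimates the emission parameters and the per-locus heterogeneity
    posteriors at the selected (pi0, beta0).
    """
    ps = as_probeset(probes)
    hyper = hyper or Hyperparams()
    base = init.copy() if init is not None else EmissionParams.default(lrr=ps.lrr)
    v_pi0, v_beta0 = VARIANTS[variant]
    if v_beta0 is not None:
        baseline_grid = [v_beta0]
    elif baseline_grid is None:
        baseline_grid = default_baseline_grid(base)
    if not len(baseline_grid):
        raise ValueError("baseline restart grid must be nonempty")
    pi0_starts = [v_pi0] if v_pi0 is not None else list(pi0_init_grid) or [0.0]
    stage1_hyper = replace(hyper, pi_grid=(0.0,))
    screen_iters = min(screen_iters, n_iters)
    screened, errors = [], []
    for b0 in baseline_grid:
        for p0 in pi0_starts:
            p = base.copy()
            p.beta0 = float(b0)
            try:
                fit = em_fit(ps, init=p, pi0_init=float(p0), hyper=stage1_hyper,
                             n_iters=screen_iters, variant=variant, tol=tol,
                             states=states, pop_b_freq=pop_b_freq)
            except FloatingPointError as exc:
                errors.append((b0, p0, str(exc)))
                continue
            screened.append((float(b0), float(p0), fit))
    screened.sort(key=lambda t: t[2].penalized_loglik, reverse=True)
    best, summaries = None, []
    for rank, (b0, p0, fit) in enumerate(screened):
        if rank < n_keep and n_iters > screen_iters and not fit.converged:
            try:
                fit = em_fit(ps, init=fit.params, pi0_init=fit.pi0,
                             hyper=stage1_hyper, n_iters=n_iters - screen_iters,
                             variant=variant, tol=tol, states=states,
                             pop_b_freq=pop_b_freq)
            except FloatingPointError as exc:
                errors.append((b0, p0, str(exc)))
                continue
        summaries.append({
            "beta0_init": b0, "pi0_init": p0,
            "beta0": fit.params.beta0, "pi0": fit.pi0,
            "loglik": fit.penalized_loglik})
        log.info("restart beta0=%+.3f pi0=%.2f -> beta0=%+.3f pi0=%.2f "
                 "loglik=%.2f", b0, p0, fit.params.beta0, fit.pi0,
                 fit.penalized_loglik)
        if best is None or fit.penalized_loglik > best.penalized_loglik:
            best = fit
    if best is None:
        raise RuntimeError(f"all baseline restarts failed: {errors}")
    if refine_heterogeneity and len(hyper.pi_grid) > 1:
        refined = em_fit(ps, init=best.params, pi0_init=best.pi0, hyper=hyper,
                         n_iters=n_iters, variant=variant, tol=tol,
                         states=states, pop_b_freq=pop_b_freq,
                         fix_pi0=best.pi0, fix_beta0=best.params.beta0)
        refined.restarts = summaries
        return refined
    best.restarts = summaries
    return best


def likelihood_surface(probes, pi0_grid: Sequence[float],
                       beta0_grid: Sequence[float],
                       hyper: Optional[Hyperparams] = None,
                       init: Optional[EmissionParams] = None,
                       refine_iters: int = 3, states: Optional[list] = None,
                       pop_b_freq: float = 0.5) -> np.ndarray:
    """Profile penalized log likelihood over a (pi0, beta0) grid.

    Each entry fixes (pi0, beta0) and refines the remaining parameters with a
    short EM run.  Rows index ``pi0_grid``, columns ``beta0_grid``.
    """
    if not len(pi0_grid) or not len(beta0_grid):
        raise ValueError("surface grids must be nonempty")
    ps = as_probeset(probes)
    hyper = hyper or Hyperparams()
    hyper = replace(hyper, pi0_grid=tuple(float(p) for p in pi0_grid))
    base = init.copy() if init is not None else EmissionParams.default(lrr=ps.lrr)
    surface = np.empty((len(pi0_grid), len(beta0_grid)))
    for i, p0 in enumerate(pi0_grid):
        for j, b0 in enumerate(beta0_grid):
            p = base.copy()
            p.beta0 = float(b0)
            fit = em_fit(ps, init=p, hyper=hyper, n_iters=refine_iters,
                         variant="full", tol=0.0, states=states,
                         pop_b_freq=pop_b_freq, fix_pi0=float(p0),
                         fix_beta0=float(b0))
            surface[i, j] = fit.penalized_loglik
    return surface
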