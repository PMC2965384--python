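"""Bivariate (LRR, BAF) emission model.

Each probe emits a two-vector ``y = [lrr, baf]``.  Conditional on a tumor state,
a (constitutional, tumor) genotype pair, the genome-wide normal fraction ``pi0``
and the locus heterogeneity fraction ``pi_i``, the emission is a K-component
mixture of bivariate Student-t distributions around the mixed-genotype mean,
plus a uniform outlier class with probability ``eta``.  The LRR mean carries a
baseline adjustment ``beta0`` (ploidy normalization) and a GC regression term
``beta1 * gc``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .state_space import Genotype, GenotypePair, TumorState

#: Canonical LRR response levels for copy numbers 0..6 (compressive in copy number).
DEFAULT_LRR_LEVELS = np.array([-3.5, -0.66, 0.0, 0.40, 0.68, 0.85, 1.0])

#: Sentinel returned by :func:`baf_mean` when the mixed total copy number is zero.
UNDEFINED_BAF = float("nan")

_GT_CLASS_NAMES = ("AA", "AB", "BB")


@dataclass
class SNPProbe:
    """One array probe: coordinates, LRR/BAF signals and optional annotations."""

    name: str
    chrom: str
    pos: int
    lrr: float
    baf: float
    gc: float = 0.0
    normal_genotype: Optional[Genotype] = None


def _default_sigma(K: int) -> np.ndarray:
    # Heterozygous-constitution clusters get a wider BAF variance; components are
    # initialized at distinct scales to break mixture symmetry.
    base = np.array([
        np.diag([0.04, 0.0016]),   # AA
        np.diag([0.04, 0.0040]),   # AB
        np.diag([0.04, 0.0016]),   # BB
    ])
    scales = np.geomspace(0.5, 3.0, K) if K > 1 else np.array([1.0])
    return np.array([base * s for s in scales])  # (K, 3, 2, 2)


@dataclass
class EmissionParams:
    """All emission-side parameters (see module docstring)."""

    lrr_levels: np.ndarray = field(default_factory=lambda: DEFAULT_LRR_LEVELS.copy())
    delta: np.ndarray = field(default_factory=lambda: np.zeros((3, 3, 2)))
    sigma: np.ndarray = field(default_factory=lambda: _default_sigma(3))
    weights: np.ndarray = field(default_factory=lambda: np.full((3, 3), 1.0 / 3.0))
    nu: float = 8.0
    eta: float = 0.01
    beta0: float = 0.0
    beta1: float = 0.0
    r_min: float = -4.5
    r_max: float = 2.0

    @property
    def K(self) -> int:
        return self.delta.shape[0]

    def validate(self) -> None:
        if self.lrr_levels.shape != (7,):
            raise ValueError("lrr_levels must give the canonical level for copies 0..6")
        if np.any(np.diff(self.lrr_levels) <= 0):
            raise ValueError("lrr_levels must be strictly increasing in copy number")
        if self.nu <= 2:
            raise ValueError("nu must exceed 2")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")
        if self.r_min >= self.r_max:
            raise ValueError("outlier support requires r_min < r_max")
        if self.delta.shape != (self.K, 3, 2) or self.sigma.shape != (self.K, 3, 2, 2):
            raise ValueError("delta/sigma shapes inconsistent with K")
        if not np.allclose(self.weights.sum(axis=1), 1.0):
            raise ValueError("mixture weights must sum to 1 per genotype class")
        for k in range(self.K):
            for l in range(3):
                s = self.sigma[k, l]
                if not np.allclose(s, s.T) or np.any(np.linalg.eigvalsh(s) <= 0):
                    raise ValueError(f"sigma[{k},{l}] is not symmetric positive definite")

    def copy(self) -> "EmissionParams":
        return replace(
            self,
            lrr_levels=self.lrr_levels.copy(),
            delta=self.delta.copy(),
            sigma=self.sigma.copy(),
            weights=self.weights.copy(),
        )

    @classmethod
    def default(cls, K: int = 3, lrr: Optional[np.ndarray] = None,
                lrr_levels: Optional[np.ndarray] = None) -> "EmissionParams":
        """Sensible initialization; outlier support from data percentiles if given."""
        levels = DEFAULT_LRR_LEVELS.copy() if lrr_levels is None else np.asarray(
            lrr_levels, dtype=float)
        if lrr is not None and len(lrr):
            r_min = float(np.percentile(lrr, 0.1) - 1.0)
            r_max = float(np.percentile(lrr, 99.9) + 1.0)
        else:
            r_min, r_max = -4.5, 2.0
        return cls(
            lrr_levels=levels,
            delta=np.zeros((K, 3, 2)),
            sigma=_default_sigma(K),
            weights=np.full((3, K), 1.0 / K),
            r_min=r_min,
            r_max=r_max,
        )

    def to_dict(self) -> dict:
        return {
            "lrr_levels": self.lrr_levels.tolist(),
            "delta": self.delta.tolist(),
            "sigma": self.sigma.tolist(),
            "weights": self.weights.tolist(),
            "nu": self.nu,
            "eta": self.eta,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "r_min": self.r_min,
            "r_max": self.r_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmissionParams":
        return cls(
            lrr_levels=np.asarray(d["lrr_levels"], dtype=float),
            delta=np.asarray(d["delta"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            nu=float(d["nu"]),
            eta=float(d["eta"]),
            beta0=float(d["beta0"]),
            beta1=float(d["beta1"]),
            r_min=float(d["r_min"]),
            r_max=float(d["r_max"]),
        )


def _normal_weight(pi0: float, pi_i: float) -> float:
    return pi_i * (1.0 - pi0) + pi0


def noise_class(pair: GenotypePair, pi0: float, pi_i: float) -> int:
    """Noise-class index of the mixed genotype's BAF band.

    0 = all-A band (BAF pinned at 0), 2 = all-B band (pinned at 1),
    1 = interior band.  Array truncation makes the boundary bands much tighter
    than interior ones, so the class follows the mixed band position rather
    than the constitutional genotype.
    """
    wn = _normal_weight(pi0, pi_i)
    num = wn * pair.normal.b_count + (1.0 - wn) * pair.tumor.b_count
    den = wn * pair.normal.copies + (1.0 - wn) * pair.tumor.copies
    if den <= 0.0:
        return 1
    if num == 0.0:
        return 0
    if num == den:
        return 2
    return 1


def lrr_mean(pair: GenotypePair, pi0: float, pi_i: float, params: EmissionParams,
             gc: float = 0.0) -> float:
    """Expected LRR of the mixed normal/tumor genotype pair."""
    if not (0 <= pair.tumor.copies <= 6 and 0 <= pair.normal.copies <= 6):
        raise ValueError("copy number outside 0..6")
    wn = _normal_weight(pi0, pi_i)
    levels = params.lrr_levels
    return (wn * levels[pair.normal.copies] + (1.0 - wn) * levels[pair.tumor.copies]
            + params.beta0 + params.beta1 * gc)


def baf_mean(pair: GenotypePair, pi0: float, pi_i: float) -> float:
    """Expected BAF of the mixed pair; ``UNDEFINED_BAF`` when total copies are zero."""
    wn = _normal_weight(pi0, pi_i)
    num = wn * pair.normal.b_count + (1.0 - wn) * pair.tumor.b_count
    den = wn * pair.normal.copies + (1.0 - wn) * pair.tumor.copies
    if den <= 0.0:
        return UNDEFINED_BAF
    return num / den


def student_t_logpdf(y, mean, cov, nu: float) -> float:
    """Log density of the multivariate Student-t distribution."""
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if nu <= 0:
        raise ValueError("nu must be positive")
    d = y.shape[-1]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("covariance matrix is singular or not positive definite")
    diff = y - mean
    q = float(diff @ np.linalg.solve(cov, diff))
    return float(
        gammaln((nu + d) / 2.0) - gammaln(nu / 2.0) - 0.5 * d * math.log(nu * math.pi)
        - 0.5 * logdet - 0.5 * (nu + d) * math.log1p(q / nu)
    )


def _t1d_logpdf(x: float, mean: float, var: float, nu: float) -> float:
    q = (x - mean) ** 2 / var
    return (gammaln((nu + 1) / 2.0) - gammaln(nu / 2.0)
            - 0.5 * math.log(nu * math.pi) - 0.5 * math.log(var)
            - 0.5 * (nu + 1) * math.log1p(q / nu))


def genotype_priors(state: TumorState, pop_b_freq: float,
                    matched: Optional[Genotype] = None) -> np.ndarray:
    """Prior weights over a state's genotype pairs.

    With a matched constitutional genotype: an indicator on agreeing pairs (split
    evenly among them).  Otherwise Hardy-Weinberg weights on the constitutional
    genotype, split among pairs sharing it and renormalized over the pair set.
    """
    if not (0.0 <= pop_b_freq <= 1.0):
        raise ValueError("pop_b_freq must lie in [0, 1]")
    mult = np.array([sum(1 for q in state.pairs if q.normal == p.normal)
                     for p in state.pairs], dtype=float)
    if matched is not None:
        w = np.array([1.0 if p.normal == matched else 0.0 for p in state.pairs])
        w = w / mult
    else:
        p = pop_b_freq
        hw = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p * p}
        w = np.array([hw[q.normal.b_count] for q in state.pairs]) / mult
    tot = w.sum()
    return w / tot if tot > 0 else w


def genotype_prior(pair: GenotypePair, state: TumorState, pop_b_freq: float,
                   matched: Optional[Genotype] = None) -> float:
    """Prior weight of one pair within its state's pair set."""
    weights = genotype_priors(state, pop_b_freq, matched)
    return float(weights[state.pairs.index(pair)])


def emission_logdensity(probe: SNPProbe, state: TumorState, params: EmissionParams,
                        pi0: float, pi_i: float, pop_b_freq: float = 0.5,
                        matched: Optional[Genotype] = None) -> float:
    """Reference (scalar) emission log density of one probe under one state.

    Marginalizes the genotype pairs and mixture components of the state.  When
    the mixed total copy number is zero the BAF factor is replaced by a uniform
    density on [0, 1] and the LRR follows the (marginal) univariate t.
    """
    priors = genotype_priors(state, pop_b_freq, matched)
    y = np.array([probe.lrr, probe.baf])
    terms = []
    for pair, pri in zip(state.pairs, priors):
        if pri <= 0.0:
            continue
        l = noise_class(pair, pi0, pi_i)
        mr = lrr_mean(pair, pi0, pi_i, params, probe.gc)
        mb = baf_mean(pair, pi0, pi_i)
        for k in range(params.K):
            lw = math.log(pri) + math.log(params.weights[l, k])
            if math.isnan(mb):
                lp = _t1d_logpdf(probe.lrr, mr + params.delta[k, l, 0],
                                 params.sigma[k, l, 0, 0], params.nu)
            else:
                lp = student_t_logpdf(y, np.array([mr, mb]) + params.delta[k, l],
                                      params.sigma[k, l], params.nu)
            terms.append(lw + lp)
    ll_non = logsumexp(terms) if terms else -np.inf
    if params.r_min <= probe.lrr <= params.r_max:
        ll_out = math.log(params.eta) - math.log(params.r_max - params.r_min) \
            if params.eta > 0 else -np.inf
    else:
        ll_out = -np.inf
    with np.errstate(divide="ignore"):
        ll_in = np.log1p(-params.eta) + ll_non if params.eta < 1.0 else -np.inf
    return float(np.logaddexp(ll_out, ll_in))


# ---------------------------------------------------------------------------
# Vectorized engine
# ---------------------------------------------------------------------------

class PairArrays:
    """Flattened per-(state, pair) arrays over a state table."""

    def __init__(self, states: Sequence[TumorState], pop_b_freq: float = 0.5):
        self.states = list(states)
        z_n, x_n, z_t, x_t, s_idx = [], [], [], [], []
        counts = []
        for si, st in enumerate(self.states):
            counts.append(len(st.pairs))
            for p in st.pairs:
                z_n.append(p.normal.b_count)
                x_n.append(p.normal.copies)
                z_t.append(p.tumor.b_count)
                x_t.append(p.tumor.copies)
                s_idx.append(si)
        self.z_n = np.array(z_n, dtype=float)
        self.x_n = np.array(x_n, dtype=float)
        self.z_t = np.array(z_t, dtype=float)
        self.x_t = np.array(x_t, dtype=float)
        self.s_idx = np.array(s_idx, dtype=int)
        self.counts = np.array(counts, dtype=int)
        self.ptr = np.concatenate([[0], np.cumsum(self.counts)[:-1]])
        self.M = len(self.z_n)
        self.S = len(self.states)
        # Prior table: rows 0..2 = matched AA/AB/BB constitution, row 3 = HW weights.
        table = np.zeros((4, self.M))
        for si, st in enumerate(self.states):
            span = slice(self.ptr[si], self.ptr[si] + self.counts[si])
            for row, matched in enumerate(
                    (Genotype(0, 2), Genotype(1, 2), Genotype(2, 2), None)):
                table[row, span] = genotype_priors(st, pop_b_freq, matched)
        self.prior_table = table
        with np.errstate(divide="ignore"):
            self.log_prior_table = np.where(table > 0, np.log(np.maximum(table, 1e-300)),
                                            -np.inf)


class EmissionCache:
    """Per-iteration emission quantities reused between the E-step passes."""

    def __init__(self, logB: np.ndarray, lp: np.ndarray, q: np.ndarray,
                 log_out: np.ndarray):
        self.logB = logB        # (n, S, P) state x heterogeneity-level log density
        self.lp = lp            # (n, M, P, K) per-pair/component log terms (incl. priors)
        self.q = q              # (n, M, P, K) Mahalanobis distances
        self.log_out = log_out  # (n,) outlier-class log density (incl. log eta)


class Moments:
    """Weighted sufficient statistics for the M-step, per (pair-cell, pi-level, k)."""

    def __init__(self, **kw):
        self.__dict__.update(kw)


class EmissionEngine:
    """Vectorized emission computations over a state table and a pi_i grid."""

    def __init__(self, states: Sequence[TumorState], params: EmissionParams,
                 pi_grid: Sequence[float], pop_b_freq: float = 0.5):
        self.pa = PairArrays(states, pop_b_freq)
        self.pi_grid = np.asarray(pi_grid, dtype=float)
        self.P = len(self.pi_grid)
        self.set_params(params)

    def set_params(self, params: EmissionParams) -> None:
        self.params = params
        K = params.K
        inv = np.empty((K, 3, 2, 2))
        logdet = np.empty((K, 3))
        for k in range(K):
            for l in range(3):
                s = params.sigma[k, l]
                sign, ld = np.linalg.slogdet(s)
                if sign <= 0:
                    raise ValueError("emission covariance not positive definite")
                inv[k, l] = np.linalg.inv(s)
                logdet[k, l] = ld
        self._inv = inv
        self._logdet = logdet
        nu = params.nu
        self._const2d = (gammaln((nu + 2) / 2.0) - gammaln(nu / 2.0)
                         - math.log(nu * math.pi) - 0.5 * logdet)  # (K, 3)

    def means(self, pi0: float):
        """Pair-cell mean LRR (pre-beta), BAF, and noise class over the pi grid.

        All returned arrays have shape (M, P).  The class follows the mixed
        band position (0 = pinned at 0, 2 = pinned at 1, 1 = interior).
        """
        pa, levels = self.pa, self.params.lrr_levels
        wn = self.pi_grid * (1.0 - pi0) + pi0  # (P,)
        base_r = levels[pa.x_n.astype(int)][:, None] * wn[None, :] + \
            levels[pa.x_t.astype(int)][:, None] * (1.0 - wn)[None, :]
        num = pa.z_n[:, None] * wn + pa.z_t[:, None] * (1.0 - wn)
        den = pa.x_n[:, None] * wn + pa.x_t[:, None] * (1.0 - wn)
        # Tiny ridge: exact no-op where den > 0; the degenerate copy-zero cell
        # (pure tumor, null genotype) gets a smooth BAF center of 0.5 instead of
        # the reference implementation's uniform factor (documented difference).
        m_b = (num + 0.5e-300) / (den + 1e-300)
        cls = np.where(den == 0.0, 1,
                       np.where(num == 0.0, 0, np.where(num == den, 2, 1)))
        return base_r, m_b, cls.astype(int)

    def log_b(self, probes, pi0: float) -> EmissionCache:
        """Emission log densities for all probes: cache with ``logB`` of shape (n,S,P)."""
        pa, params = self.pa, self.params
        K, P = params.K, self.P
        r = probes.lrr
        b = probes.baf
        g = probes.gc
        n = len(r)
        base_r, m_b, cls = self.means(pi0)
        rshift = params.beta0 + params.beta1 * g
        er = (r - rshift)[:, None, None] - base_r[None, :, :]      # (n, M, P)
        eb = b[:, None, None] - m_b[None, :, :]
        lp = np.empty((n, pa.M, P, K))
        q = np.empty((n, pa.M, P, K))
        logw = np.log(np.maximum(params.weights, 1e-300))          # (3, K)
        inv = self._inv
        for k in range(K):
            a = inv[k, cls, 0, 0]
            bc = inv[k, cls, 0, 1]
            c = inv[k, cls, 1, 1]
            x1 = er - params.delta[k, cls, 0]
            x2 = eb - params.delta[k, cls, 1]
            qk = a * x1 * x1 + 2.0 * bc * x1 * x2 + c * x2 * x2
            q[..., k] = qk
            lp[..., k] = (self._const2d[k, cls]
                          - 0.5 * (params.nu + 2.0) * np.log1p(qk / params.nu)
                          + logw[cls, k])
        # genotype-pair priors (per probe when matched genotypes are present)
        lp += pa.log_prior_table[probes.matched_idx][:, :, None, None]
        # logsumexp over components then pairs-within-state
        m1 = lp.max(axis=3)
        with np.errstate(invalid="ignore"):
            s1 = np.where(np.isfinite(m1),
                          np.log(np.exp(lp - m1[..., None]).sum(axis=3)) + m1, -np.inf)
        mx = np.maximum.reduceat(s1, pa.ptr, axis=1)               # (n, S, P)
        rep = np.repeat(mx, pa.counts, axis=1)
        with np.errstate(invalid="ignore"):
            t = np.where(np.isfinite(rep), np.exp(s1 - rep), 0.0)
        ssum = np.add.reduceat(t, pa.ptr, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            nonout = np.where(np.isfinite(mx), np.log(np.maximum(ssum, 1e-300)) + mx,
                              -np.inf)
        in_range = (r >= params.r_min) & (r <= params.r_max)
        with np.errstate(divide="ignore"):
            log_out = np.where(
                in_range & (params.eta > 0),
                math.log(max(params.eta, 1e-300)) - math.log(params.r_max - params.r_min),
                -np.inf)
        log_in = (math.log1p(-params.eta) if params.eta < 1.0 else -np.inf) + nonout
        logB = np.logaddexp(log_out[:, None, None], log_in)
        return EmissionCache(logB, lp, q, log_out)

    def estep_moments(self, probes, cache: EmissionCache,
                      gamma: np.ndarray) -> Moments:
        """Accumulate weighted sufficient statistics given joint posteriors ``gamma``.

        ``gamma`` has shape (n, S, P).  Returns per-(cell, p, k) moments of the
        data weighted by responsibility x t-scale weight, used by conjugate MAP
        updates and the pi0 grid scan.
        """
        pa, params = self.pa, self.params
        r, b, g = probes.lrr, probes.baf, probes.gc
        nu = params.nu
        lB_rep = np.repeat(cache.logB, pa.counts, axis=1)          # (n, M, P)
        g_rep = np.repeat(gamma, pa.counts, axis=1)
        log_in = math.log1p(-params.eta) if params.eta < 1.0 else -np.inf
        with np.errstate(invalid="ignore", over="ignore"):
            resp = g_rep[..., None] * np.exp(log_in + cache.lp - lB_rep[..., None])
        resp = np.nan_to_num(resp, nan=0.0, posinf=0.0)
        lam = (nu + 2.0) / (nu + cache.q)
        gl = resp * lam
        N = resp.sum(axis=0)
        M0 = gl.sum(axis=0)
        M0g = np.einsum("i,impk->mpk", g, gl)
        M0gg = np.einsum("i,impk->mpk", g * g, gl)
        My_r = np.einsum("i,impk->mpk", r, gl)
        My_b = np.einsum("i,impk->mpk", b, gl)
        Myg_r = np.einsum("i,impk->mpk", r * g, gl)
        Myg_b = np.einsum("i,impk->mpk", b * g, gl)
        Myy_rr = np.einsum("i,impk->mpk", r * r, gl)
        Myy_rb = np.einsum("i,impk->mpk", r * b, gl)
        Myy_bb = np.einsum("i,impk->mpk", b * b, gl)
        # outlier responsibility
        with np.errstate(invalid="ignore"):
            out = gamma * np.exp(cache.log_out[:, None, None] - cache.logB)
        out_sum = float(np.nan_to_num(out, nan=0.0).sum())
        return Moments(N=N, M0=M0, M0g=M0g, M0gg=M0gg, My_r=My_r, My_b=My_b,
                       Myg_r=Myg_r, Myg_b=Myg_b, Myy_rr=Myy_rr, Myy_rb=Myy_rb,
                       Myy_bb=Myy_bb, out_sum=out_sum, n=len(r))
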