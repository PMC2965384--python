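"""Hyperparameters and log-prior terms used by MAP-EM.

Conjugate priors: Dirichlet on mixture weights, Normal-Inverse-Wishart on the
component offsets/covariances, Beta on the outlier rate, Normal on the LRR
regression coefficients, and discrete two-level masses on the normal fraction
pi0 and the locus heterogeneity levels pi_i (renormalized over their grids).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import stats

from .emission import EmissionParams

log = logging.getLogger(__name__)

DEFAULT_PI0_GRID: Tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.9001, 0.05), 2))
DEFAULT_PI_GRID: Tuple[float, ...] = (0.0, 0.2, 0.4, 0.6)


@dataclass
class Hyperparams:
    """Prior hyperparameters plus the transition characteristic length ``L``."""

    alpha: float = 1.0                 # Dirichlet concentration on mixture weights
    tau: float = 0.05                  # scale of the Normal prior on component offsets
    gamma: float = 5.0                 # Inverse-Wishart degrees of freedom
    S: np.ndarray = field(default_factory=lambda: 0.01 * np.eye(2))
    alpha_eta: float = 1.0
    beta_eta: float = 1.0
    lambda_beta: float = 0.05          # variance of the Normal prior on (beta0, beta1);
                                       # tight enough to break the exact diploid vs
                                       # genome-doubled likelihood tie toward beta0=0
    alpha_pi0: float = 1.0
    beta_pi0: float = 1.0
    alpha_pi: float = 1.0
    beta_pi: float = 2.0
    L: float = 2_000_000.0             # transition characteristic length (bp)
    pi0_grid: Tuple[float, ...] = DEFAULT_PI0_GRID
    pi_grid: Tuple[float, ...] = DEFAULT_PI_GRID
    init_state_bias: float = 10.0      # chromosome-start weight on the normal state
    pi_iid: bool = True                # pi_i prior applied per probe (else: chain)
    switch_to_prior: bool = True       # switch mass resamples the biased state prior
                                       # (else: split uniformly over other states)

    def validate(self) -> None:
        for name in ("alpha", "tau", "gamma", "alpha_eta", "beta_eta", "lambda_beta",
                     "alpha_pi0", "beta_pi0", "alpha_pi", "beta_pi", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be strictly positive")
        S = np.asarray(self.S)
        if S.shape != (2, 2) or np.any(np.linalg.eigvalsh(S) <= 0):
            raise ValueError("S must be a 2x2 positive definite matrix")


def default_hyperparams() -> Hyperparams:
    """The default hyperparameter set (flat weight/outlier priors, L = 2 Mb)."""
    return Hyperparams()


def _discrete_log_prior(grid: np.ndarray, mass_zero: float,
                        mass_pos: float) -> np.ndarray:
    """Normalized log masses: ``mass_zero`` on 0, ``mass_pos`` split over positives."""
    grid = np.asarray(grid, dtype=float)
    n_pos = int(np.sum(grid > 0))
    mass = np.where(grid == 0.0, mass_zero,
                    mass_pos / n_pos if n_pos else 0.0)
    return np.log(mass / mass.sum())


def pi0_log_prior(hyper: Hyperparams) -> np.ndarray:
    return _discrete_log_prior(np.asarray(hyper.pi0_grid), hyper.alpha_pi0,
                               hyper.beta_pi0)


def pi_log_prior(hyper: Hyperparams) -> np.ndarray:
    return _discrete_log_prior(np.asarray(hyper.pi_grid), hyper.alpha_pi,
                               hyper.beta_pi)


def log_prior(params: EmissionParams, pi0: float, hyper: Hyperparams) -> float:
    """Joint log prior density of the emission parameters and pi0.

    Returns ``-inf`` (with a warning) for parameters outside the support.
    """
    K = params.K
    total = 0.0
    try:
        for l in range(3):
            w = np.clip(params.weights[l], 1e-12, None)
            total += stats.dirichlet.logpdf(w / w.sum(), np.full(K, hyper.alpha))
        for k in range(K):
            for l in range(3):
                sig = params.sigma[k, l]
                total += stats.multivariate_normal.logpdf(
                    params.delta[k, l], mean=np.zeros(2), cov=hyper.tau * sig)
                total += stats.invwishart.logpdf(sig, df=hyper.gamma,
                                                 scale=np.asarray(hyper.S))
        total += stats.beta.logpdf(np.clip(params.eta, 1e-12, 1 - 1e-12),
                                   hyper.alpha_eta, hyper.beta_eta)
        total += stats.norm.logpdf([params.beta0, params.beta1], loc=0.0,
                                   scale=np.sqrt(hyper.lambda_beta)).sum()
        grid = np.asarray(hyper.pi0_grid)
        idx = np.flatnonzero(np.isclose(grid, pi0))
        if len(idx) == 0:
            raise ValueError(f"pi0={pi0} not on the prior grid")
        total += float(pi0_log_prior(hyper)[idx[0]])
    except (ValueError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"parameter outside prior support: {exc}")
        return -np.inf
    if not np.isfinite(total):
        warnings.warn("log prior evaluated to a non-finite value")
        return -np.inf
    return float(total)
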