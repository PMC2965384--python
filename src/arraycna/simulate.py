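"""Synthetic tumor SNP-array data with known truth.

The generative mirror of the emission model: piecewise-constant tumor-state
segments with exponential lengths, Hardy-Weinberg constitutional genotypes,
state-conditional tumor genotypes, heavy-tailed bivariate noise, a sinusoidal
GC covariate, an LRR baseline shift for polyploid genomes, uniform outliers and
mass- or cell-fraction normal:tumor dilution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .emission import DEFAULT_LRR_LEVELS
from .state_space import Genotype, build_state_table

log = logging.getLogger(__name__)

_DEFAULT_STATE_WEIGHTS = {3: 0.55, 2: 0.15, 4: 0.20, 12: 0.10}


@dataclass
class SimConfig:
    """Generator settings; every random draw flows from ``seed``."""

    n_probes: int = 20_000
    n_chroms: int = 20
    chrom_length: int = 10_000_000
    segment_mean_length: float = 2_000_000.0
    state_weights: dict = field(default_factory=lambda: dict(_DEFAULT_STATE_WEIGHTS))
    pi0_true: float = 0.0
    pi_levels_true: tuple = (0.0,)
    pop_b_freq: float = 0.5
    noise_scale_lrr: float = 0.18
    noise_scale_baf: float = 0.035
    nu_true: float = 8.0
    gc_amplitude: float = 0.0          # coefficient of the GC covariate in the LRR
    gc_period: float = 4_000_000.0
    baseline_true: float = 0.0
    outlier_rate_true: float = 0.003
    seed: int = 0
    lrr_levels: np.ndarray = field(default_factory=lambda: DEFAULT_LRR_LEVELS.copy())
    mixing: str = "cell"               # "cell" or "mass" interpretation of pi0_true

    def validate(self) -> None:
        for name in ("pi0_true", "pop_b_freq", "outlier_rate_true"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_probes <= 0 or self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("probe/chromosome counts and lengths must be positive")
        if self.mixing not in ("cell", "mass"):
            raise ValueError("mixing must be 'cell' or 'mass'")


class _Truth:
    """Latent truth shared by every rendering of one simulated tumor."""

    def __init__(self, df: pd.DataFrame, mean_tumor_copy: float):
        self.df = df
        self.mean_tumor_copy = mean_tumor_copy


def mass_to_cell_fraction(mass_fraction: float, tumor_ploidy: float) -> float:
    """Convert a by-mass normal fraction into the model's cell fraction.

    Normal cells contribute DNA proportional to 2, tumor cells proportional to
    their average copy number.
    """
    if not 0.0 <= mass_fraction <= 1.0:
        raise ValueError("mass_fraction must lie in [0, 1]")
    if mass_fraction in (0.0, 1.0):
        return mass_fraction
    num = mass_fraction / 2.0
    return num / (num + (1.0 - mass_fraction) / tumor_ploidy)


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> _Truth:
    states = {s.id: s for s in build_state_table()}
    ids = np.array(sorted(config.state_weights))
    w = np.array([config.state_weights[i] for i in ids], dtype=float)
    w = w / w.sum()
    per_chrom = config.n_probes // config.n_chroms
    extras = config.n_probes - per_chrom * config.n_chroms
    rows = []
    seg_id = 0
    p = config.pop_b_freq
    hw = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    for ci in range(config.n_chroms):
        chrom = str(ci + 1)
        n_c = per_chrom + (1 if ci < extras else 0)
        spacing = config.chrom_length / (n_c + 1)
        pos = (np.arange(1, n_c + 1) * spacing).astype(np.int64)
        gc = 0.5 + 0.1 * np.sin(2.0 * np.pi * pos / config.gc_period)
        # segment boundaries: exponential lengths along the chromosome
        cursor = 0.0
        bounds = []
        while cursor < config.chrom_length:
            cursor += rng.exponential(config.segment_mean_length)
            bounds.append(min(cursor, config.chrom_length))
        seg_states, seg_pis, seg_of_probe = [], [], np.zeros(n_c, dtype=int)
        for b in bounds:
            seg_states.append(int(rng.choice(ids, p=w)))
            seg_pis.append(float(rng.choice(config.pi_levels_true)))
        seg_of_probe = np.searchsorted(np.array(bounds), pos, side="left")
        seg_of_probe = np.minimum(seg_of_probe, len(bounds) - 1)
        for j in range(n_c):
            sid = seg_states[seg_of_probe[j]]
            st = states[sid]
            allowed = sorted({q.normal.b_count for q in st.pairs})
            zn = int(rng.choice(3, p=hw))
            if zn not in allowed:
                # e.g. germline-LOH states admit no heterozygous constitution
                sub = hw[allowed] / hw[allowed].sum()
                zn = int(rng.choice(allowed, p=sub))
            choices = [q for q in st.pairs if q.normal.b_count == zn]
            pair = choices[rng.integers(len(choices))]
            rows.append((f"snp_{chrom}_{j:06d}", chrom, int(pos[j]), float(gc[j]),
                         seg_id + seg_of_probe[j], sid, st.tumor_copy_number,
                         seg_pis[seg_of_probe[j]], pair.normal.b_count, 2,
                         pair.tumor.b_count, pair.tumor.copies))
        seg_id += len(bounds)
    df = pd.DataFrame(rows, columns=[
        "name", "chrom", "pos", "gc", "segment_id", "state_id", "copy_number",
        "pi_i", "normal_z", "normal_x", "tumor_z", "tumor_x"])
    df["normal_gt"] = [str(Genotype(z, x)) for z, x in
                       zip(df["normal_z"], df["normal_x"])]
    df["tumor_gt"] = [str(Genotype(z, x)) for z, x in
                      zip(df["tumor_z"], df["tumor_x"])]
    return _Truth(df, float(df["tumor_x"].mean()))


def _render(truth: _Truth, config: SimConfig, pi0_cell: float,
            rng: np.random.Generator):
    df = truth.df
    levels = np.asarray(config.lrr_levels, dtype=float)
    wn = df["pi_i"].to_numpy() * (1.0 - pi0_cell) + pi0_cell
    x_t = df["tumor_x"].to_numpy()
    z_t = df["tumor_z"].to_numpy()
    x_n = df["normal_x"].to_numpy()
    z_n = df["normal_z"].to_numpy()
    gc = df["gc"].to_numpy()
    m_r = (wn * levels[x_n] + (1.0 - wn) * levels[x_t]
           + config.baseline_true + config.gc_amplitude * gc)
    num = wn * z_n + (1.0 - wn) * z_t
    den = wn * x_n + (1.0 - wn) * x_t
    with np.errstate(invalid="ignore", divide="ignore"):
        m_b = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    n = len(df)
    lrr = m_r + config.noise_scale_lrr * rng.standard_t(config.nu_true, size=n)
    baf = m_b + config.noise_scale_baf * rng.standard_t(config.nu_true, size=n)
    baf = np.where(np.isnan(m_b), rng.uniform(0.0, 1.0, size=n), baf)
    baf = np.clip(baf, 0.0, 1.0)
    outlier = rng.uniform(size=n) < config.outlier_rate_true
    n_out = int(outlier.sum())
    if n_out:
        lrr[outlier] = rng.uniform(levels[0] - 0.5, levels[6] + 0.5, size=n_out)
        baf[outlier] = rng.uniform(0.0, 1.0, size=n_out)
    probes = pd.DataFrame({
        "name": df["name"], "chrom": df["chrom"], "pos": df["pos"],
        "lrr": lrr, "baf": baf, "gc": gc,
    })
    truth_out = df.drop(columns=["normal_z", "normal_x", "tumor_z", "tumor_x"]).copy()
    truth_out["pi0"] = pi0_cell
    truth_out["outlier"] = outlier.astype(int)
    return probes, truth_out


def simulate_sample(config: SimConfig):
    """Generate one sample: ``(probe table, truth table)``, reproducible from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    pi0 = config.pi0_true
    if config.mixing == "mass":
        pi0 = mass_to_cell_fraction(pi0, truth.mean_tumor_copy)
    return _render(truth, config, pi0, np.random.default_rng(config.seed + 1))


def dilution_series(base_config: SimConfig, fractions: Sequence[float],
                    mixing: Optional[str] = None):
    """Render one tumor truth at several normal fractions (independent noise).

    Returns a list of ``(probe table, truth table)`` sharing identical latent
    segments and genotypes; ``mixing`` overrides the config's convention.
    """
    base_config.validate()
    mixing = mixing or base_config.mixing
    if mixing not in ("cell", "mass"):
        raise ValueError("mixing must be 'cell' or 'mass'")
    rng = np.random.default_rng(base_config.seed)
    truth = _draw_truth(base_config, rng)
    out = []
    for idx, f in enumerate(fractions):
        if not 0.0 <= f <= 1.0:
            raise ValueError("dilution fractions must lie in [0, 1]")
        pi0 = mass_to_cell_fraction(f, truth.mean_tumor_copy) \
            if mixing == "mass" else float(f)
        noise_rng = np.random.default_rng(base_config.seed + 1000 * (idx + 1))
        out.append(_render(truth, base_config, pi0, noise_rng))
    return out


def make_confusable_sample(config: Optional[SimConfig] = None):
    """A sample whose (pi0, beta0) likelihood surface admits several interpretations.

    A genome-wide single-copy gain at moderate contamination: its four BAF bands
    and uniform LRR shift are also reproducible by a genome-wide hemizygous
    deletion or copy-neutral LOH at higher contamination under a different
    baseline, so the profile likelihood has multiple local maxima.
    """
    if config is None:
        config = SimConfig(n_probes=4000, n_chroms=8, pi0_true=0.3,
                           noise_scale_lrr=0.15, noise_scale_baf=0.03,
                           outlier_rate_true=0.0, seed=7)
    config = replace(config, state_weights={4: 1.0},
                     segment_mean_length=float(config.chrom_length))
    return simulate_sample(config)
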