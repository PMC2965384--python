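"""Segmentation of Viterbi paths, Bayes-factor scoring and summary statistics."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import as_probeset, normalize_chrom
from .state_space import (NORMAL_STATE_ID, TumorState, build_state_table,
                          is_copy_loss_loh, is_loh)

log = logging.getLogger(__name__)

DEFAULT_LOG_BF_THRESHOLD = 30.0

_POST_FLOOR = 1e-300


@dataclass
class Segment:
    """A maximal run of one Viterbi state within one chromosome."""

    chrom: str
    start_pos: int
    end_pos: int
    state_id: int
    n_probes: int
    copy_number: int
    loh: bool
    copy_loss_loh: bool
    start_index: int           # probe index range [start_index, end_index)
    end_index: int
    log_bf: float = float("nan")
    mean_lrr: float = float("nan")
    mean_baf_dev: float = float("nan")


def segments_from_path(probes, viterbi_path,
                       state_table: Optional[Sequence[TumorState]] = None
                       ) -> list[Segment]:
    """Run-length encode a state path into segments (chromosome breaks split runs)."""
    ps = as_probeset(probes)
    path = np.asarray(viterbi_path)
    if len(path) != ps.n:
        raise ValueError(
            f"path length {len(path)} does not match probe count {ps.n}")
    states = {s.id: s for s in (state_table or build_state_table())}
    segs: list[Segment] = []
    for i0, i1 in ps.blocks():
        start = i0
        for i in range(i0 + 1, i1 + 1):
            if i == i1 or path[i] != path[start]:
                sid = int(path[start])
                st = states[sid]
                lrr = ps.lrr[start:i]
                baf = ps.baf[start:i]
                segs.append(Segment(
                    chrom=str(ps.chrom[start]),
                    start_pos=int(ps.pos[start]),
                    end_pos=int(ps.pos[i - 1]),
                    state_id=sid,
                    n_probes=i - start,
                    copy_number=st.tumor_copy_number,
                    loh=is_loh(st),
                    copy_loss_loh=is_copy_loss_loh(st),
                    start_index=start,
                    end_index=i,
                    mean_lrr=float(lrr.mean()),
                    mean_baf_dev=float(np.abs(baf - 0.5).mean()),
                ))
                start = i
    return segs


def segment_log_bayes_factor(segment: Segment, state_posteriors: np.ndarray,
                             state_ids: Optional[np.ndarray] = None,
                             prior_log_odds: float = 0.0) -> float:
    """Approximate log Bayes factor of a segment's state versus the normal state.

    Sum over the segment's probes of the posterior log odds of the assigned
    state against the normal state (natural log).  ``prior_log_odds`` (per
    probe, assigned vs normal) is subtracted when supplied; the default keeps
    the score a pure posterior-odds sum.  A normal-state segment scores 0.
    """
    if segment.state_id == NORMAL_STATE_ID:
        return 0.0
    ids = state_ids if state_ids is not None else np.arange(1, 22)
    col = int(np.flatnonzero(ids == segment.state_id)[0])
    ref = int(np.flatnonzero(ids == NORMAL_STATE_ID)[0])
    post = state_posteriors[segment.start_index:segment.end_index]
    num = np.clip(post[:, col], _POST_FLOOR, None)
    den = np.clip(post[:, ref], _POST_FLOOR, None)
    return float(np.sum(np.log(num) - np.log(den) - prior_log_odds))


def score_segments(segments: list[Segment], state_posteriors: np.ndarray,
                   state_ids: Optional[np.ndarray] = None,
                   prior_log_odds: float = 0.0) -> list[Segment]:
    for seg in segments:
        seg.log_bf = segment_log_bayes_factor(seg, state_posteriors, state_ids,
                                              prior_log_odds)
    return segments


def segments_frame(segments: list[Segment]) -> pd.DataFrame:
    """Segments as a DataFrame (adds the state description for outputs)."""
    desc = {s.id: s.description for s in build_state_table()}
    rows = []
    for s in segments:
        rows.append({
            "chrom": s.chrom, "start_pos": s.start_pos, "end_pos": s.end_pos,
            "state": s.state_id, "description": desc.get(s.state_id, ""),
            "n_probes": s.n_probes, "copy_number": s.copy_number,
            "loh": int(s.loh), "copy_loss_loh": int(s.copy_loss_loh),
            "log_bf": s.log_bf, "mean_lrr": s.mean_lrr,
            "mean_baf_dev": s.mean_baf_dev,
        })
    return pd.DataFrame(rows)


def filter_segments(segments: list[Segment],
                    threshold: float = DEFAULT_LOG_BF_THRESHOLD) -> list[Segment]:
    """Aberrant segments passing the log-Bayes-factor filter."""
    return [s for s in segments
            if s.state_id != NORMAL_STATE_ID and s.log_bf >= threshold]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


DEFAULT_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X",)


def estimate_chromosome_number(probes, copy_numbers,
                               include: Optional[Sequence[str]] = None) -> int:
    """Estimated chromosome count: per-chromosome rounded mean copy number, summed.

    ``include`` restricts the chromosomes counted (default: all present).
    Chromosomes with no probes are excluded with a warning.
    """
    ps = as_probeset(probes)
    cn = np.asarray(copy_numbers, dtype=float)
    if len(cn) != ps.n:
        raise ValueError("copy-number vector length does not match probe count")
    present = {}
    for i0, i1 in ps.blocks():
        present.setdefault(str(ps.chrom[i0]), []).append((i0, i1))
    wanted = ([normalize_chrom(c) for c in include] if include is not None
              else sorted(present))
    total = 0
    for chrom in wanted:
        if chrom not in present:
            warnings.warn(f"chromosome {chrom} has no probes; excluded from "
                          "the chromosome-number estimate")
            continue
        vals = np.concatenate([cn[i0:i1] for i0, i1 in present[chrom]])
        total += _round_half_up(float(vals.mean()))
    return int(total)


def summary_report(fit, segments: list[Segment], probes,
                   threshold: float = DEFAULT_LOG_BF_THRESHOLD,
                   include_chroms: Optional[Sequence[str]] = None) -> dict:
    """MAP estimates plus genome-level summaries of a fitted model."""
    ps = as_probeset(probes)
    states = {s.id: s for s in build_state_table()}
    cn = np.array([states[i].tumor_copy_number for i in fit.viterbi_path])
    passing = filter_segments(segments, threshold)
    frac = {}
    for sid in sorted(states):
        frac[sid] = float(np.mean(fit.viterbi_path == sid))
    return {
        "beta0": float(fit.params.beta0),
        "pi0": float(fit.pi0),
        "chromosome_number": estimate_chromosome_number(ps, cn, include_chroms),
        "average_ploidy": float(cn.mean()),
        "n_segments": len(segments),
        "n_aberrant_segments_passing": len(passing),
        "n_aberrant_probes_passing": int(sum(s.n_probes for s in passing)),
        "state_fractions": frac,
    }
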