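"""Probe-table readers, GC-track attachment and output writers."""

from __future__ import annotations

import logging
import re
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("name", "chrom", "pos", "lrr", "baf")

_COLUMN_ALIASES = {
    "name": {"name", "snp name", "snp", "probe", "probe id", "probe_id", "snp_name"},
    "chrom": {"chr", "chrom", "chromosome"},
    "pos": {"pos", "position", "mapinfo", "map info"},
    "lrr": {"lrr", "log r ratio", "logrratio", "log_r_ratio"},
    "baf": {"baf", "b allele freq", "b allele frequency", "ballelefreq",
            "b_allele_freq"},
    "gc": {"gc", "gc content", "gc_content"},
    "normal_gt": {"normal_gt", "normal genotype", "gtype", "normal gtype"},
}

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def normalize_chrom(label) -> str:
    """Strip a ``chr`` prefix and uppercase sex-chromosome labels."""
    s = str(label).strip()
    s = re.sub(r"^chr", "", s, flags=re.IGNORECASE)
    return s.upper() if s.upper() in ("X", "Y", "MT", "M") else s


def chrom_sort_key(label: str):
    s = normalize_chrom(label)
    return (0, _CHROM_ORDER[s]) if s in _CHROM_ORDER else (1, s)


_GT_CODE = {"AA": 0, "AB": 1, "BA": 1, "BB": 2}


class ProbeSet:
    """Sorted per-probe arrays plus chromosome-block bookkeeping.

    Wraps a DataFrame with columns ``name, chrom, pos, lrr, baf`` and optional
    ``gc`` / ``normal_gt``.  Probes are ordered by (karyotype chromosome order,
    position); chromosome starts delimit independent HMM chains.
    """

    def __init__(self, df: pd.DataFrame, sort: bool = True):
        df = df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"probe table missing required column(s): {missing}")
        df["chrom"] = df["chrom"].map(normalize_chrom)
        if sort:
            df = df.sort_values(
                "pos", kind="stable").sort_values(
                "chrom", key=lambda s: s.map(lambda c: chrom_sort_key(c)),
                kind="stable").reset_index(drop=True)
        else:
            df = df.reset_index(drop=True)
        chrom = df["chrom"].to_numpy()
        pos = df["pos"].to_numpy(dtype=np.int64)
        starts = [0]
        for i in range(1, len(df)):
            if chrom[i] != chrom[i - 1]:
                starts.append(i)
            elif pos[i] < pos[i - 1]:
                raise ValueError(
                    f"probes not sorted by position within chromosome {chrom[i]}")
        self.df = df
        self.chrom = chrom
        self.pos = pos
        self.lrr = df["lrr"].to_numpy(dtype=float)
        self.baf = df["baf"].to_numpy(dtype=float)
        if "gc" in df.columns:
            raw = df["gc"].to_numpy(dtype=float)
            self.has_gc = bool(np.std(raw) > 0)
            # centered covariate: decouples the GC regression from the LRR
            # baseline, so beta0 reads as the baseline at average GC
            self.gc = raw - raw.mean() if self.has_gc else np.zeros(len(df))
        else:
            self.gc = np.zeros(len(df))
            self.has_gc = False
        if "normal_gt" in df.columns:
            codes = df["normal_gt"].map(
                lambda v: _GT_CODE.get(str(v).upper(), 3)).to_numpy(dtype=int)
            self.matched_idx = codes
        else:
            self.matched_idx = np.full(len(df), 3, dtype=int)
        self.chrom_starts = np.array(starts + [len(df)], dtype=int)
        self.n = len(df)

    def __len__(self) -> int:
        return self.n

    def blocks(self):
        """Yield (start, stop) index pairs, one per chromosome."""
        cs = self.chrom_starts
        for i in range(len(cs) - 1):
            yield int(cs[i]), int(cs[i + 1])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sort: bool = True) -> "ProbeSet":
        return cls(df, sort=sort)


def as_probeset(probes) -> ProbeSet:
    if isinstance(probes, ProbeSet):
        return probes
    if isinstance(probes, pd.DataFrame):
        return ProbeSet(probes, sort=False)
    raise TypeError("probes must be a ProbeSet or a DataFrame")


def read_probe_table(path) -> ProbeSet:
    """Read a tab-delimited probe table (BeadStudio-style export).

    Columns are matched case-insensitively through an alias map; rows with
    non-finite LRR/BAF are dropped (and counted in the log); duplicate
    (chrom, pos) rows keep the first occurrence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"probe table {path} is empty")
    rename = {}
    for col in df.columns:
        key = col.strip().lower().replace("-", " ")
        for canon, aliases in _COLUMN_ALIASES.items():
            if key in aliases:
                rename[col] = canon
                break
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table {path} missing required column(s): {missing}")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["lrr"] = pd.to_numeric(df["lrr"], errors="coerce")
    df["baf"] = pd.to_numeric(df["baf"], errors="coerce")
    if "gc" in df.columns:
        df["gc"] = pd.to_numeric(df["gc"], errors="coerce")
    n0 = len(df)
    df = df.dropna(subset=["pos", "lrr", "baf"])
    dropped = n0 - len(df)
    if dropped:
        log.info("dropped %d probe(s) with non-finite LRR/BAF/position", dropped)
    df["pos"] = df["pos"].astype(np.int64)
    df["chrom"] = df["chrom"].map(normalize_chrom)
    n1 = len(df)
    df = df.drop_duplicates(subset=["chrom", "pos"], keep="first")
    if n1 - len(df):
        log.info("deduplicated %d probe(s) at repeated positions", n1 - len(df))
    if df.empty:
        raise ValueError(f"probe table {path} has no usable rows")
    ps = ProbeSet(df, sort=True)
    ps.n_dropped = dropped
    return ps


def attach_gc(probes: ProbeSet, gc_path) -> ProbeSet:
    """Attach a local GC-content track from a BED-like or per-probe file.

    BED-like: ``chrom  start  end  gc`` (0-based half-open intervals, header
    optional).  Per-probe: a header with ``name`` and ``gc`` columns.  Probes
    outside every interval get the genome-wide mean (counted in the log).
    """
    first = pd.read_csv(gc_path, sep="\t", nrows=1, dtype=str)
    header_keys = {c.strip().lower() for c in first.columns}
    df = probes.df.copy()
    if "name" in header_keys and "gc" in header_keys:
        track = pd.read_csv(gc_path, sep="\t", dtype=str)
        track.columns = [c.strip().lower() for c in track.columns]
        track["gc"] = pd.to_numeric(track["gc"], errors="raise")
        gc_map = dict(zip(track["name"], track["gc"]))
        gc = df["name"].map(gc_map)
    else:
        bed = pd.read_csv(gc_path, sep="\t", header=None,
                          names=["chrom", "start", "end", "gc"],
                          dtype={"chrom": str}, comment="#")
        header_words = {"start", "chromstart", "begin"}
        if str(bed.iloc[0]["start"]).strip().lower() in header_words:
            bed = bed.iloc[1:].reset_index(drop=True)
        for col, kind in (("start", np.int64), ("end", np.int64),
                          ("gc", float)):
            converted = pd.to_numeric(bed[col], errors="coerce")
            bad = converted.isna() & bed[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 1
                raise ValueError(
                    f"malformed GC interval file {gc_path}: bad {col} value "
                    f"at line {line}")
            bed[col] = converted.astype(kind)
        bed["chrom"] = bed["chrom"].map(normalize_chrom)
        gc = pd.Series(np.nan, index=df.index)
        for chrom, sub in bed.groupby("chrom"):
            sub = sub.sort_values("start")
            mask = df["chrom"] == chrom
            if not mask.any():
                continue
            pos = df.loc[mask, "pos"].to_numpy()
            idx = np.searchsorted(sub["start"].to_numpy(), pos - 1, side="right") - 1
            ok = (idx >= 0) & (pos - 1 < sub["end"].to_numpy()[np.clip(idx, 0, None)])
            vals = np.where(ok, sub["gc"].to_numpy()[np.clip(idx, 0, None)], np.nan)
            gc.loc[mask] = vals
    n_missing = int(gc.isna().sum())
    if n_missing:
        mean_gc = float(gc.mean()) if gc.notna().any() else 0.5
        gc = gc.fillna(mean_gc)
        log.info("imputed GC for %d probe(s) with the genome-wide mean", n_missing)
    df["gc"] = gc.to_numpy(dtype=float)
    out = ProbeSet(df, sort=False)
    out.n_gc_imputed = n_missing
    return out


def write_per_snp_table(path, probes: ProbeSet, fit, segments=None,
                        state_table=None) -> pd.DataFrame:
    """Write the per-probe call table (returns the frame written)."""
    from .state_space import build_state_table, is_copy_loss_loh, is_loh

    states = state_table or build_state_table()
    by_id = {s.id: s for s in states}
    sid = np.asarray(fit.viterbi_path)
    cn = np.array([by_id[i].tumor_copy_number for i in sid])
    loh = np.array([int(is_loh(by_id[i])) for i in sid])
    closs = np.array([int(is_copy_loss_loh(by_id[i])) for i in sid])
    out = pd.DataFrame({
        "name": probes.df["name"].to_numpy(),
        "chrom": probes.chrom,
        "pos": probes.pos,
        "lrr": probes.lrr,
        "baf": probes.baf,
        "state": sid,
        "copy_number": cn,
        "loh": loh,
        "copy_loss_loh": closs,
        "max_posterior": fit.state_posteriors.max(axis=1),
        "pi_level": np.asarray(fit.pi_grid)[np.asarray(fit.viterbi_pi)],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return out


def write_segments_tsv(path, segments: pd.DataFrame) -> None:
    segments.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_segments_bed(path, segments: pd.DataFrame) -> None:
    """BED output: 0-based half-open coordinates, score = min(1000, 10*logBF)."""
    with open(path, "w") as fh:
        for _, row in segments.iterrows():
            score = int(min(1000, max(0, round(10.0 * row["log_bf"]))))
            name = str(row["description"]).replace(" ", "_")
            fh.write(f"{row['chrom']}\t{int(row['start_pos']) - 1}\t"
                     f"{int(row['end_pos'])}\t{name}\t{score}\n")


def write_summary_tsv(path, summary: dict) -> None:
    rows = [(k, v) for k, v in summary.items()]
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(
        path, sep="\t", index=False)


def write_surface_tsv(path, surface: np.ndarray, pi0_grid: Sequence[float],
                      beta0_grid: Sequence[float]) -> None:
    """Likelihood surface as a TSV matrix: rows pi0, columns beta0."""
    df = pd.DataFrame(surface, index=list(pi0_grid), columns=list(beta0_grid))
    df.index.name = "pi0\\beta0"
    df.to_csv(path, sep="\t", float_format="%.6f")
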