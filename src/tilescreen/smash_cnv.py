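"""SMASH-style copy-number profiling from chimeric read pairs.

Reads are chimeric concatenations of short genomic fragments; each read
is decomposed into Maximal Unique Matches (MUMs) against the reference
(suffix array, both strands). MUMs are filtered (match length >= 20 bp,
>= 4 bp of excess unique sequence, read-2 matches farther than 1000
bases from every read-1 match), counted in empirically sized bins
calibrated so that uniform coverage yields equal bin counts, corrected
for GC bias by LOWESS, and normalized so the length-weighted autosomal
mean copy number is exactly 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._suffix import ReferenceIndex

MIN_MATCH_LEN = 20        # bp; shorter matches are discarded
MIN_EXCESS_UNIQUE = 4     # bp of match beyond the shortest unique prefix
MATE_PROXIMITY = 1000     # bases; read-2 MUMs this close to read-1 are PCR
                          # echoes of the same fragment and are dropped


@dataclass
class MUM:
    """A maximal substring of a read occurring exactly once in the genome."""

    read_id: str
    mate: int                 # 1 or 2
    read_offset: int
    chrom: str
    genome_pos: int           # forward-strand start, 0-based
    length: int
    strand: str
    min_unique_length: int    # shortest prefix of this match that is unique

    def __post_init__(self) -> None:
        if self.length < self.min_unique_length:
            raise ValueError("length < min_unique_length")


def find_mums(read: str, index: ReferenceIndex, read_id: str = "",
              mate: int = 1) -> list[MUM]:
    """All maximal unique matches of one read against the reference.

    At each read offset the longest reference match is found via the
    suffix array; it is a MUM when it occurs exactly once (both strands
    considered) and is not contained in the match starting one position
    earlier (left-maximality).
    """
    if not read:
        return []
    match_len, occ, pos, mul = index.matching_statistics(read)
    mums: list[MUM] = []
    for i in range(len(read)):
        if occ[i] != 1 or match_len[i] == 0:
            continue
        if i > 0 and match_len[i - 1] > match_len[i]:
            continue          # contained in the previous offset's match
        chrom, strand, start = index.locate(int(pos[i]), int(match_len[i]))
        mums.append(MUM(read_id=read_id, mate=mate, read_offset=i,
                        chrom=chrom, genome_pos=start,
                        length=int(match_len[i]), strand=strand,
                        min_unique_length=int(mul[i])))
    return mums


def filter_mums(mums_read1: list[MUM],
                mums_read2: list[MUM]) -> list[MUM]:
    """Apply the three SMASH filters to one read pair's MUMs.

    Drops matches below 20 bp, matches with less than 4 bp of excess
    unique sequence, and read-2 matches within 1000 bases of any read-1
    match's genome coordinate. Order is preserved.
    """
    def basic(m: MUM) -> bool:
        return (m.length >= MIN_MATCH_LEN
                and m.length - m.min_unique_length >= MIN_EXCESS_UNIQUE)

    kept1 = [m for m in mums_read1 if basic(m)]
    anchors = [(m.chrom, m.genome_pos) for m in kept1]
    kept2 = [
        m for m in mums_read2
        if basic(m) and not any(
            c == m.chrom and abs(p - m.genome_pos) <= MATE_PROXIMITY
            for c, p in anchors)]
    return kept1 + kept2


def make_bins(genome: dict[str, str],
              calibration_positions: dict[str, np.ndarray],
              target_count: int) -> pd.DataFrame:
    """Empirically sized bins: equal calibration-MUM counts per bin.

    ``calibration_positions`` maps each chromosome to the genome
    positions of MUMs from a uniform-coverage simulation; bin edges are
    placed so each bin receives ~``target_count`` calibration MUMs, so
    regions of equal mappability and copy get equal expected counts.
    GC content is computed from the reference per bin.
    """
    rows = []
    for chrom, seq in genome.items():
        n = len(seq)
        pos = np.sort(np.asarray(calibration_positions.get(chrom, []),
                                 dtype=np.int64))
        k = max(1, int(round(pos.size / target_count))) if pos.size else 1
        interior = [int(pos[int(round(j * pos.size / k))])
                    for j in range(1, k)] if k > 1 else []
        edges = [0] + sorted(set(interior)) + [n]
        edges = [e for i, e in enumerate(edges)
                 if i == 0 or e > edges[i - 1]]
        if edges[-1] != n:
            edges.append(n)
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append({"chrom": chrom, "start": s, "end": e,
                         "gc": float(is_gc[s:e].mean()) if e > s else 0.0})
    bins = pd.DataFrame(rows)
    bins["raw_count"] = 0
    return bins


def assign_counts(bins: pd.DataFrame, mums: list[MUM]) -> pd.DataFrame:
    """Count kept MUMs per bin by genome position (each MUM in one bin)."""
    bins = bins.copy()
    counts = np.zeros(len(bins), dtype=np.int64)
    for chrom, grp in bins.groupby("chrom"):
        edges = np.append(grp["start"].to_numpy(), grp["end"].iloc[-1])
        positions = np.array([m.genome_pos for m in mums
                              if m.chrom == chrom], dtype=np.int64)
        if positions.size == 0:
            continue
        idx = np.searchsorted(edges, positions, side="right") - 1
        idx = idx[(idx >= 0) & (idx < len(grp))]
        c = np.bincount(idx, minlength=len(grp))
        counts[grp.index.to_numpy()] += c
    bins["raw_count"] = counts
    return bins


def gc_correct(bins: pd.DataFrame, frac: float = 0.3,
               eps: float = 1e-6) -> pd.DataFrame:
    """Remove GC-content effects by LOWESS of count vs GC per bin.

    corrected = raw * mean(raw) / lowess_fit(gc), with the fitted value
    floored at a small positive epsilon. With fewer than 20 bins, or
    constant GC, the correction reduces to a global identity scaling.
    """
    bins = bins.copy()
    raw = bins["raw_count"].to_numpy(dtype=float)
    gc = bins["gc"].to_numpy(dtype=float)
    mean = raw.mean()
    if len(bins) < 20 or np.ptp(gc) == 0 or mean == 0:
        bins["corrected_count"] = raw
        return bins
    fit = lowess(raw, gc, frac=frac, return_sorted=False)
    fit = np.maximum(fit, eps * max(mean, 1.0))
    bins["corrected_count"] = raw * mean / fit
    return bins


def normalize_cn(bins: pd.DataFrame,
                 sex_chroms: tuple[str, ...] = ("chrX", "chrY", "X", "Y")
                 ) -> pd.DataFrame:
    """Scale so the length-weighted autosomal mean copy number is 2."""
    bins = bins.copy()
    auto = ~bins["chrom"].isin(sex_chroms)
    lengths = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    corrected = bins["corrected_count"].to_numpy(dtype=float)
    denom = float((lengths[auto] * corrected[auto]).sum())
    if denom <= 0:
        raise ValueError("zero autosomal signal; cannot normalize")
    mean_auto = denom / lengths[auto].sum()
    bins["cn"] = corrected * 2.0 / mean_auto
    return bins


def profile_report(bins: pd.DataFrame, bedgraph_path: str | None = None,
                   min_run: int = 5,
                   gain_cut: float = 2.5, loss_cut: float = 1.5) -> dict:
    """BedGraph of per-bin copy number plus a JSON-ready summary.

    The summary holds per-chromosome mean copy number and candidate
    gained/lost runs of at least ``min_run`` consecutive bins beyond
    +-0.5 of 2.
    """
    if bedgraph_path is not None:
        write_bedgraph(bins, bedgraph_path)
    per_chrom = {
        chrom: float(np.average(grp["cn"],
                                weights=grp["end"] - grp["start"]))
        for chrom, grp in bins.groupby("chrom")}
    runs = []
    for chrom, grp in bins.groupby("chrom"):
        cn = grp["cn"].to_numpy()
        state = np.where(cn > gain_cut, 1, np.where(cn < loss_cut, -1, 0))
        i = 0
        while i < len(state):
            j = i
            while j < len(state) and state[j] == state[i]:
                j += 1
            if state[i] != 0 and j - i >= min_run:
                seg = grp.iloc[i:j]
                runs.append({
                    "chrom": chrom,
                    "start": int(seg["start"].iloc[0]),
                    "end": int(seg["end"].iloc[-1]),
                    "kind": "gain" if state[i] == 1 else "loss",
                    "n_bins": int(j - i),
                    "mean_cn": float(seg["cn"].mean())})
            i = j
    return {"per_chromosome_mean_cn": per_chrom, "candidate_runs": runs}


def write_bedgraph(bins: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for _, row in bins.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t"
                     f"{int(row['end'])}\t{row['cn']:.6g}\n")


def read_bedgraph(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       names=["chrom", "start", "end", "cn"])


def copy_number_profile(genome: dict[str, str],
                        read_pairs: list[tuple[str, str]],
                        target_count: int = 100,
                        calibration_depth: float = 2.0,
                        fragment_length: int = 80,
                        seed: int = 0,
                        sex_chroms: tuple[str, ...] = ("chrX", "chrY"),
                        index: ReferenceIndex | None = None
                        ) -> tuple[pd.DataFrame, list[MUM]]:
    """End-to-end profile: MUMs -> filters -> bins -> GC -> normalization.

    Calibration MUMs come from a seeded uniform-fragment simulation on
    the same reference (``calibration_depth`` x coverage), so bin sizes
    absorb mappability structure. Returns (bins, kept MUMs).
    """
    if index is None:
        index = ReferenceIndex(genome)
    kept: list[MUM] = []
    for rid, (r1, r2) in enumerate(read_pairs):
        m1 = find_mums(r1, index, read_id=str(rid), mate=1)
        m2 = find_mums(r2, index, read_id=str(rid), mate=2)
        kept.extend(filter_mums(m1, m2))

    rng = np.random.default_rng(seed)
    calib: dict[str, list[int]] = {c: [] for c in genome}
    for chrom, seq in genome.items():
        n = len(seq)
        n_frag = int(calibration_depth * n / fragment_length)
        starts = rng.integers(0, max(1, n - fragment_length), size=n_frag)
        for s in starts:
            frag = seq[s:s + fragment_length]
            for m in filter_mums(find_mums(frag, index), []):
                calib[m.chrom].append(m.genome_pos)
    calib_arr = {c: np.asarray(v, dtype=np.int64) for c, v in calib.items()}
    bins = make_bins(genome, calib_arr, target_count)
    bins = assign_counts(bins, kept)
    bins = gc_correct(bins)
    bins = normalize_cn(bins, sex_chroms=sex_chroms)
    return bins, kept
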