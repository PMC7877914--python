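"""Off-target search and position-weighted specificity scoring.

A guide's potential off-target sites are all genomic 23-mers ending in GG
whose first 20 bases differ from the protospacer at no more than three
positions. Each site receives a penalty that grows when mismatches sit
far from the PAM and when multiple mismatches are spread apart; the
penalties are combined into a single specificity score with 1.00 as the
maximum, attained exactly when the guide has no off-target site at up to
three mismatches.

The per-site penalty follows the Hsu-style scheme

    h = prod_p (1 - W[p]) * D(dbar) * 1/m^2

with position weights ``W`` increasing toward the PAM (position 20 =
PAM-proximal), ``dbar`` the mean pairwise distance between mismatch
positions and ``D(dbar) = 1 / (((19 - dbar) / 19) * 4 + 1)``. For sites
with fewer than two mismatches the D and 1/m^2 factors are 1; a perfect
duplicate site has h = 1. The aggregate score is ``S = 1 / (1 + sum h)``
over all sites except the single on-target perfect match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .genemodel import revcomp

#: Experimentally derived single-mismatch position weights, PAM-distal
#: (position 1) to PAM-proximal (position 20), as published. The raw
#: vector is not monotone position by position.
HSU_WEIGHTS: tuple[float, ...] = (
    0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583,
)


def _isotonic(values: tuple[float, ...]) -> tuple[float, ...]:
    """Least-squares non-decreasing fit (pool adjacent violators)."""
    blocks = [[v, 1.0] for v in values]        # (mean, weight)
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0]:
            m0, w0 = blocks[i]
            m1, w1 = blocks[i + 1]
            blocks[i] = [(m0 * w0 + m1 * w1) / (w0 + w1), w0 + w1]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out: list[float] = []
    for mean, weight in blocks:
        out.extend([mean] * int(weight))
    return tuple(out)


#: Default scoring weights: the isotonic fit of the published vector, so
#: the per-site penalty is non-increasing as a mismatch moves toward the
#: PAM, matching the scheme's stated behaviour. Config-overridable.
DEFAULT_WEIGHTS: tuple[float, ...] = _isotonic(HSU_WEIGHTS)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class OffTargetHit:
    """One genomic site matching a guide at <= 3 mismatches."""

    chrom: str
    start: int              # forward-strand start of the 23-mer site
    strand: str
    mismatch_positions: tuple[int, ...]   # sorted, 1..20, 1 = PAM-distal
    penalty: float = 0.0
    genes: str = ""

    @property
    def m(self) -> int:
        return len(self.mismatch_positions)


@dataclass
class SpecificityReport:
    guide_id: str
    score: float
    n0: int
    n1: int
    n2: int
    n3: int
    hits: list[OffTargetHit] = field(default_factory=list)


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; any other character to 255 (never matches)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def _scan_strand(seq_code: np.ndarray, proto_code: np.ndarray,
                 max_mm: int) -> list[tuple[int, tuple[int, ...]]]:
    """Pigeonhole seed search of one strand.

    The 20-mer is partitioned into ``max_mm + 1`` seeds; any site with
    <= max_mm mismatches must match at least one seed exactly. Seed hits
    are located by vectorized shifted comparison, then verified by a full
    Hamming count plus the NGG PAM check. Returns (site_start,
    mismatch_positions) tuples on this strand's coordinates.
    """
    n = len(seq_code)
    if n < 23:
        return []
    n_pos = n - 22                     # candidate 23-mer start positions
    bounds = np.linspace(0, 20, max_mm + 2).astype(int)
    candidates: list[np.ndarray] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        match = np.ones(n_pos, dtype=bool)
        for off in range(a, b):
            match &= seq_code[off:off + n_pos] == proto_code[off]
        candidates.append(np.flatnonzero(match))
    cand = np.unique(np.concatenate(candidates))
    if cand.size == 0:
        return []
    # verify: Hamming distance over the 20-mer and GG at offsets 21, 22
    mm = np.zeros(cand.size, dtype=np.int64)
    valid = np.ones(cand.size, dtype=bool)
    for off in range(20):
        site_base = seq_code[cand + off]
        valid &= site_base != 255
        mm += site_base != proto_code[off]
    g = _BASE_CODE["G"]
    valid &= (seq_code[cand + 21] == g) & (seq_code[cand + 22] == g)
    valid &= seq_code[cand + 20] != 255
    valid &= mm <= max_mm
    hits = []
    for p in cand[valid]:
        positions = tuple(
            off + 1 for off in range(20)
            if seq_code[p + off] != proto_code[off])
        hits.append((int(p), positions))
    return hits


def find_offtargets(protospacer: str, genome: dict[str, str],
                    max_mm: int = 3) -> list[OffTargetHit]:
    """All NGG-adjacent genomic sites within ``max_mm`` of a protospacer.

    Both strands of every chromosome are searched; ``start`` is always
    the forward-strand start of the 23-mer site. Sites containing
    ambiguous bases are skipped. Mismatch positions are indexed 1..20
    from the PAM-distal end.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    proto_code = _encode(protospacer)
    hits: list[OffTargetHit] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        fwd = _encode(seq)
        for p, positions in _scan_strand(fwd, proto_code, max_mm):
            hits.append(OffTargetHit(chrom, p, "+", positions))
        rev = _encode(revcomp(seq))
        n = len(seq)
        for p, positions in _scan_strand(rev, proto_code, max_mm):
            hits.append(OffTargetHit(chrom, n - p - 23, "-", positions))
    for h in hits:
        h.penalty = site_penalty(h)
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def site_penalty(hit: OffTargetHit,
                 weights: tuple[float, ...] = DEFAULT_WEIGHTS) -> float:
    """Per-site penalty from mismatch count, position and spread."""
    positions = hit.mismatch_positions
    if any(p < 1 or p > 20 for p in positions):
        raise ValueError(f"mismatch positions outside 1..20: {positions}")
    m = len(positions)
    if m == 0:
        return 1.0
    h = 1.0
    for p in positions:
        h *= 1.0 - weights[p - 1]
    if m == 1:
        return h
    dbar = float(np.mean([abs(a - b)
                          for a, b in combinations(positions, 2)]))
    d_term = 1.0 / (((19.0 - dbar) / 19.0) * 4.0 + 1.0)
    return h * d_term * (1.0 / (m * m))


def aggregate_score(hits: list[OffTargetHit]) -> float:
    """Combine site penalties into one specificity score in (0, 1].

    One on-target perfect match is excluded from the sum; a guide whose
    only site is the on-target scores exactly 1.00.
    """
    perfect = [h for h in hits if h.m == 0]
    if not perfect:
        raise ValueError("no on-target (0-mismatch) site among hits; "
                         "guide does not match the supplied genome")
    rest = [h for h in hits if h is not perfect[0]]
    return 1.0 / (1.0 + sum(h.penalty for h in rest))


def annotate_offtargets(guide_id: str, hits: list[OffTargetHit],
                        gene_annotation=None) -> SpecificityReport:
    """Tally 0-3 mismatch site counts and attach overlapping gene names.

    ``gene_annotation`` is an iterable of (chrom, start, end, name)
    intervals (BED-like, 0-based half-open).
    """
    annotation = list(gene_annotation) if gene_annotation is not None else []
    for h in hits:
        names = [name for chrom, s, e, name in annotation
                 if chrom == h.chrom and s < h.start + 23 and h.start < e]
        h.genes = ",".join(sorted(set(names)))
    counts = [0, 0, 0, 0]
    for h in hits:
        counts[h.m] += 1
    return SpecificityReport(
        guide_id=guide_id, score=aggregate_score(hits),
        n0=counts[0], n1=counts[1], n2=counts[2], n3=counts[3],
        hits=hits)
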