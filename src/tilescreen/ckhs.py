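"""CRISPR-knockout-hypersensitive (CKHS) region detection.

Per-guide depletion (LFC) is mapped onto protein residues, denoised with
a rolling-median outlier filter, segmented with a bottom-up unbalanced
Haar merge (a TGUH-style change-point scheme), and segments much more
depleted than the negative-control distribution are called CKHS regions.
Overlap of called regions with annotated domains is reported, flagging
regions outside any annotation as candidate novel functional regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .genemodel import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class ResidueSignal:
    """Per-residue depletion signal with guide coverage."""

    gene: str
    values: np.ndarray        # float, NaN where no guide covers the residue
    coverage: np.ndarray      # int, guides covering each residue

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=int)
        if self.values.shape != self.coverage.shape:
            raise ValueError("values and coverage lengths differ")


@dataclass
class CKHSRegion:
    """A called hypersensitive residue segment, 1-based inclusive."""

    gene: str
    start_res: int
    end_res: int
    segment_mean: float
    threshold_t2: float

    def __post_init__(self) -> None:
        if self.start_res > self.end_res:
            raise ValueError("start_res > end_res")


def build_residue_signal(lfcs, residue_spans, protein_length: int,
                         gene: str = "") -> ResidueSignal:
    """Average guide LFCs onto the residues each guide disrupts.

    ``lfcs`` and ``residue_spans`` are parallel sequences; a residue's
    value is the mean LFC over all guides whose span covers it. Guides
    with span None are ignored. Replicate LFCs should be averaged before
    this step.
    """
    total = np.zeros(protein_length)
    cov = np.zeros(protein_length, dtype=int)
    for lfc, span in zip(lfcs, residue_spans):
        if span is None:
            continue
        lo, hi = span
        if lo < 1 or hi > protein_length:
            raise ValueError(f"residue span ({lo}, {hi}) outside "
                             f"[1, {protein_length}]")
        total[lo - 1:hi] += lfc
        cov[lo - 1:hi] += 1
    values = np.full(protein_length, np.nan)
    covered = cov > 0
    values[covered] = total[covered] / cov[covered]
    return ResidueSignal(gene=gene, values=values, coverage=cov)


def _interpolate(values: np.ndarray) -> np.ndarray:
    """Linear interpolation of NaN gaps; flat extension at the ends."""
    values = np.asarray(values, dtype=float)
    good = np.flatnonzero(~np.isnan(values))
    if good.size == 0:
        raise ValueError("signal is entirely missing")
    idx = np.arange(values.size)
    return np.interp(idx, good, values[good])


def denoise(signal: ResidueSignal, half_width: int = 2,
            k: float = 3.0) -> ResidueSignal:
    """Replace rolling-median outliers; keep everything else unchanged.

    Missing residues are linearly interpolated first. Values deviating
    from the centered rolling median (window ``2*half_width + 1``) by
    more than ``k`` times the MAD of the rolling residuals are replaced
    by the rolling median.
    """
    x = _interpolate(signal.values)
    n = x.size
    w = 2 * half_width + 1
    if n < w:
        logger.warning("%s: protein (%d aa) shorter than window %d; "
                       "window shrunk", signal.gene, n, w)
        w = n if n % 2 == 1 else n - 1
        half_width = w // 2
    med = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half_width), min(n, i + half_width + 1)
        med[i] = np.median(x[lo:hi])
    resid = x - med
    mad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    out = x.copy()
    outliers = np.abs(resid) > k * mad
    out[outliers] = med[outliers]
    return ResidueSignal(gene=signal.gene, values=out,
                         coverage=signal.coverage)


def _sigma_mad(x: np.ndarray) -> float:
    """Noise scale from the MAD of first differences."""
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / math.sqrt(2.0)


def segment_changepoints(values: np.ndarray, t2: float) -> list[int]:
    """Bottom-up unbalanced-Haar merge; breakpoints surviving threshold t2.

    Starting from single-residue segments, the adjacent pair with the
    smallest absolute Haar contrast ``|m1 - m2| * sqrt(n1*n2/(n1+n2))``
    is merged repeatedly (ties broken leftmost) until every remaining
    contrast exceeds ``t2 * sigma * sqrt(log n)``, with sigma a MAD-based
    noise estimate. Returns the sorted list of breakpoints ``b`` meaning
    a boundary between residues ``b`` and ``b + 1`` (1-based).

    The merge order does not depend on t2, so the breakpoint set at a
    larger threshold is always a subset of that at a smaller one.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).all():
        raise ValueError("signal is entirely missing")
    if np.isnan(x).any():
        x = _interpolate(x)
    n = x.size
    tau = t2 * _sigma_mad(x) * math.sqrt(math.log(max(n, 2)))
    # segments as (start, length, mean), start 0-based
    starts = list(range(n))
    lens = [1] * n
    means = list(map(float, x))

    def contrast(i: int) -> float:
        n1, n2 = lens[i], lens[i + 1]
        return abs(means[i] - means[i + 1]) * math.sqrt(n1 * n2 / (n1 + n2))

    while len(starts) > 1:
        cons = [contrast(i) for i in range(len(starts) - 1)]
        i = int(np.argmin(cons))          # leftmost minimum
        if cons[i] > tau:
            break
        n1, n2 = lens[i], lens[i + 1]
        means[i] = (means[i] * n1 + means[i + 1] * n2) / (n1 + n2)
        lens[i] = n1 + n2
        del starts[i + 1], lens[i + 1], means[i + 1]
    return [s for s in starts[1:]]


def _segments(n: int, breakpoints: list[int]) -> list[tuple[int, int]]:
    """0-based half-open segments delimited by the breakpoints."""
    edges = [0] + sorted(breakpoints) + [n]
    return list(zip(edges[:-1], edges[1:]))


def call_ckhs(signal: ResidueSignal, breakpoints: list[int], t2: float,
              control_reference=None,
              global_cutoff: float | None = None) -> list[CKHSRegion]:
    """Call segments hypersensitive relative to the negative controls.

    A segment is CKHS iff its mean is at or below
    ``median(negatives) - t2 * (median(negatives) - min segment mean)``
    and strictly below the negative-control median. Without negative
    controls the global essentiality cutoff is used as the bound.
    Adjacent CKHS segments are merged.
    """
    x = _interpolate(signal.values)
    segs = _segments(x.size, breakpoints)
    seg_means = [float(x[a:b].mean()) for a, b in segs]
    if control_reference is not None and len(control_reference) > 0:
        med_neg = float(np.median(np.asarray(control_reference, dtype=float)))
        bound = med_neg - t2 * (med_neg - min(seg_means))
    elif global_cutoff is not None:
        med_neg = math.inf
        bound = global_cutoff
    else:
        raise ValueError("need negative-control LFCs or a global cutoff")
    regions: list[CKHSRegion] = []
    for (a, b), mean in zip(segs, seg_means):
        if mean <= bound and mean < med_neg:
            if regions and regions[-1].end_res == a:   # merge adjacent
                prev = regions[-1]
                total = (prev.segment_mean * (prev.end_res - prev.start_res + 1)
                         + mean * (b - a))
                regions[-1] = CKHSRegion(
                    signal.gene, prev.start_res, b,
                    total / (b - prev.start_res + 1), t2)
            else:
                regions.append(CKHSRegion(signal.gene, a + 1, b, mean, t2))
    return regions


def domain_overlap(regions: list[CKHSRegion],
                   gene: GeneModel) -> dict:
    """Per-domain overlap with CKHS regions, plus novel-region flags.

    For each annotated domain: total overlapping residues and the Jaccard
    index against the union of the domain with its overlapping regions.
    CKHS regions overlapping no domain are flagged as candidate novel
    functional regions.
    """
    def olap(a_lo, a_hi, b_lo, b_hi):
        return max(0, min(a_hi, b_hi) - max(a_lo, b_lo) + 1)

    per_domain = []
    for d in gene.domains:
        overlapping = [r for r in regions
                       if olap(d.start_res, d.end_res,
                               r.start_res, r.end_res) > 0]
        overlap = sum(olap(d.start_res, d.end_res, r.start_res, r.end_res)
                      for r in overlapping)
        covered = set(range(d.start_res, d.end_res + 1))
        for r in overlapping:
            covered |= set(range(r.start_res, r.end_res + 1))
        per_domain.append({
            "domain": d.name, "start_res": d.start_res,
            "end_res": d.end_res, "overlap_residues": int(overlap),
            "jaccard": overlap / len(covered) if covered else 0.0,
            "has_ckhs": bool(overlapping)})
    novel = [
        {"start_res": r.start_res, "end_res": r.end_res,
         "segment_mean": r.segment_mean}
        for r in regions
        if all(olap(d.start_res, d.end_res, r.start_res, r.end_res) == 0
               for d in gene.domains)]
    return {"gene": gene.gene_id, "domains": per_domain,
            "novel_regions": novel}
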