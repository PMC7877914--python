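"""Dropout-screen quantification, normalization and essentiality calling.

Guides are quantified from pooled-screen reads by strict exact match to
the forward primer, sample barcode and 20-nt guide sequence. Counts are
median-of-ratios normalized, converted to per-guide log2 fold changes
between the early (P1) and late (P10) passages, and essentiality is
called with a control-calibrated threshold: the cutoff is the largest
LFC at which a guide is depleted more than every negative control and at
least as much as the median depletion of every positive-control gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Forward primer used for strict-exact-match quantification (primer F2).
DEFAULT_PRIMER = "TCTTGTGGAAAGGACGAAACACCG"


@dataclass
class ScreenTable:
    """Guide x sample counts with library labels and normalization state."""

    library: pd.DataFrame            # guide_id, gene, category[, sequence]
    raw_counts: pd.DataFrame         # index guide_id, columns samples
    size_factors: pd.Series | None = None
    norm_counts: pd.DataFrame | None = None
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        missing = set(self.library["guide_id"]) - set(self.raw_counts.index)
        if missing:   # zero-fill unobserved guides
            zeros = pd.DataFrame(0, index=sorted(missing),
                                 columns=self.raw_counts.columns)
            self.raw_counts = pd.concat([self.raw_counts, zeros])
        self.raw_counts = self.raw_counts.loc[list(self.library["guide_id"])]


def count_guides(reads, library: pd.DataFrame,
                 sample_barcodes: dict[str, str],
                 primer: str = DEFAULT_PRIMER) -> tuple[ScreenTable, dict]:
    """Quantify guides from reads by strict exact match.

    A read increments cell (guide, sample) iff it contains the exact
    forward primer, immediately followed by a sample's exact barcode and
    then an exact 20-nt guide sequence from the library. Reads failing
    any exact match are discarded and tallied.

    ``reads`` is an iterable of read sequences (use
    :func:`tilescreen.io.read_fastq_seqs` for FASTQ input); ``library``
    needs columns guide_id, gene, category, sequence.
    """
    barcodes = dict(sample_barcodes)
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("duplicate sample barcodes")
    seq_to_guide: dict[str, str] = {}
    for _, row in library.iterrows():
        seq = str(row["sequence"])
        if seq in seq_to_guide:
            logger.warning("duplicate guide sequence %s; counting once "
                           "(multiplicity collapsed)", seq)
            continue
        seq_to_guide[seq] = str(row["guide_id"])
    samples = list(barcodes)
    counts = pd.DataFrame(0, index=list(library["guide_id"]),
                          columns=samples, dtype=np.int64)
    counts = counts[~counts.index.duplicated()]
    assigned = discarded = total = 0
    for read in reads:
        total += 1
        i = read.find(primer)
        if i < 0:
            discarded += 1
            continue
        rest = read[i + len(primer):]
        hit = None
        for sample, bc in barcodes.items():
            if rest.startswith(bc):
                guide_seq = rest[len(bc):len(bc) + 20]
                if guide_seq in seq_to_guide:
                    hit = (seq_to_guide[guide_seq], sample)
                break
        if hit is None:
            discarded += 1
            continue
        counts.loc[hit] += 1
        assigned += 1
    table = ScreenTable(library=library, raw_counts=counts)
    return table, {"total": total, "assigned": assigned,
                   "discarded": discarded}


def median_normalize(table: ScreenTable) -> ScreenTable:
    """Median-of-ratios size factors, as used by MAGeCK/DESeq.

    Each sample's size factor is the median, over guides with a nonzero
    geometric mean across samples, of that guide's count divided by its
    geometric mean. Normalized counts are raw / size factor.
    """
    counts = table.raw_counts
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)    # NaN when any sample is zero
    usable = log_geomean.notna()
    if not usable.any():
        raise ValueError("no guide has nonzero counts in every sample")
    ratios = np.exp(np.log(counts[usable]).sub(log_geomean[usable], axis=0))
    table.size_factors = ratios.median(axis=0)
    table.norm_counts = counts / table.size_factors
    return table


def compute_lfc(table: ScreenTable, early: str | list[str],
                late: str | list[str], alpha: float = 1.0) -> pd.DataFrame:
    """Per-guide log2 fold change late (P10) vs early (P1).

    lfc = log2((norm_late + alpha) / (norm_early + alpha)). When a list
    of replicate samples is given for either time point, per-replicate
    LFCs are averaged.
    """
    if table.norm_counts is None:
        raise ValueError("normalize first (median_normalize)")
    early = [early] if isinstance(early, str) else list(early)
    late = [late] if isinstance(late, str) else list(late)
    if len(early) != len(late):
        raise ValueError("early/late replicate lists differ in length")
    nc = table.norm_counts
    if alpha == 0 and any((nc[s] == 0).any() for s in early + late):
        raise ValueError("alpha=0 with zero counts yields infinite LFC")
    lfc = np.mean(
        [np.log2((nc[lt] + alpha) / (nc[er] + alpha))
         for er, lt in zip(early, late)], axis=0)
    out = table.library[["guide_id", "gene", "category"]].copy()
    if "domain_class" in table.library.columns:
        out["domain_class"] = table.library["domain_class"].values
    out["lfc"] = lfc
    return out


@dataclass
class EssentialityCall:
    """Control-calibrated essentiality cutoff and per-guide calls."""

    cutoff: float                    # as reported (optionally rounded)
    cutoff_raw: float
    negative_min: float
    positive_gene_medians: dict[str, float]
    essential: pd.Series = field(repr=False)     # guide_id -> bool
    gene_summary: pd.DataFrame = field(repr=False)


def essentiality_cutoff(lfcs: pd.DataFrame,
                        positive_bound: str = "min",
                        round_to_int: bool = False) -> EssentialityCall:
    """Essentiality threshold from negative and positive controls.

    The cutoff C is the minimum of (i) the lowest negative-control LFC
    and (ii) the per-gene median LFCs of the positive controls, combined
    with min (conjunction over positive genes; ``positive_bound="max"``
    exposes the looser reading). A guide is essential iff its LFC <= C
    and is strictly below every negative control. With ``round_to_int``
    the *reported* cutoff is additionally rounded toward zero to mirror
    integer presentation; calls always use the raw rule.
    """
    neg = lfcs.loc[lfcs["category"] == "negative_control", "lfc"]
    pos = lfcs[lfcs["category"] == "positive_control"]
    if neg.empty or pos.empty:
        raise ValueError("both negative-control guides and positive-control "
                         "genes are required")
    pos_medians = pos.groupby("gene")["lfc"].median()
    combine = min if positive_bound == "min" else max
    c_raw = min(float(neg.min()), combine(pos_medians))
    cutoff = float(math.trunc(c_raw)) if round_to_int else c_raw
    essential = (lfcs["lfc"] <= c_raw) & (lfcs["lfc"] < float(neg.min()))
    essential.index = lfcs["guide_id"]
    gene_summary = (lfcs.assign(essential=essential.values)
                    .groupby("gene")
                    .agg(n_guides=("guide_id", "size"),
                         n_essential=("essential", "sum"),
                         median_lfc=("lfc", "median")))
    gene_summary["fraction_essential"] = (
        gene_summary["n_essential"] / gene_summary["n_guides"])
    return EssentialityCall(
        cutoff=cutoff, cutoff_raw=c_raw, negative_min=float(neg.min()),
        positive_gene_medians=pos_medians.to_dict(),
        essential=essential, gene_summary=gene_summary)


def compare_ad_nad(lfcs: pd.DataFrame) -> dict:
    """One-sided rank-sum test: are AD guides more depleted than NAD?

    Returns the Mann-Whitney U statistic, one-sided p-value (AD < NAD)
    and both class medians; flagged not-applicable when a class is empty.
    """
    ad = lfcs.loc[lfcs["domain_class"] == "AD", "lfc"].to_numpy()
    nad = lfcs.loc[lfcs["domain_class"] == "NAD", "lfc"].to_numpy()
    if ad.size == 0 or nad.size == 0:
        return {"applicable": False, "n_ad": int(ad.size),
                "n_nad": int(nad.size)}
    u, p = stats.mannwhitneyu(ad, nad, alternative="less")
    return {"applicable": True, "U": float(u), "p_value": float(p),
            "median_ad": float(np.median(ad)),
            "median_nad": float(np.median(nad)),
            "n_ad": int(ad.size), "n_nad": int(nad.size)}


def replicate_correlation(lfcs_a: pd.DataFrame,
                          lfcs_b: pd.DataFrame) -> dict:
    """Pearson (primary) and Spearman correlation over common guides."""
    merged = lfcs_a.merge(lfcs_b, on="guide_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("fewer than 3 common guides between replicates")
    r, _ = stats.pearsonr(merged["lfc_a"], merged["lfc_b"])
    rho, _ = stats.spearmanr(merged["lfc_a"], merged["lfc_b"])
    return {"pearson_r": float(r), "spearman_rho": float(rho),
            "n": int(len(merged))}
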