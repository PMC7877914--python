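"""SpCas9 guide enumeration across the exons of a gene model.

Every 20-nt protospacer immediately 5' of an NGG PAM, on either strand, is
a candidate; a guide is kept when its predicted blunt cut site (3 bp 5' of
the PAM) falls inside an exon. Each guide is mapped to the protein
residue(s) its cut disrupts and classified by annotated-domain status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .genemodel import GeneModel, revcomp

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass
class GuideRecord:
    """One SpCas9 guide: protospacer, PAM, cut site and annotations."""

    guide_id: str
    gene: str
    protospacer: str
    pam: str
    chrom: str
    cut_pos: int            # 0-based between-base genomic coordinate
    strand: str
    oligo_sequence: str = ""
    residue_span: tuple[int, int] | None = None
    category: str = "tiling"
    domain_class: str = "none"     # AD / NAD / none
    specificity_score: float | None = None
    offtarget_counts: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20 or set(self.protospacer) - _ACGT:
            raise ValueError(f"protospacer must be 20 nt over ACGT: "
                             f"{self.protospacer!r}")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM must match NGG: {self.pam!r}")
        if not self.oligo_sequence:
            self.oligo_sequence = apply_five_prime_g(self.protospacer)


def apply_five_prime_g(protospacer: str) -> str:
    """Prepend a G to oligo designs not already starting with one.

    U6-driven transcription prefers a 5' G; guides already starting with G
    are returned unchanged (20 nt), others gain a leading G (21 nt).
    """
    if len(protospacer) != 20:
        raise ValueError(f"expected a 20-nt protospacer, "
                         f"got {len(protospacer)} nt")
    return protospacer if protospacer.startswith("G") else "G" + protospacer


def cut_site_from_pam(pam_start: int, strand: str) -> int:
    """Blunt-cut between-base coordinate, 3 bp 5' of the PAM.

    ``pam_start`` is the forward-strand start of the 3-nt PAM interval.
    On '+' the cut is 3 bases to the left of the PAM; on '-' the PAM is
    read from the reverse strand so the cut is 3 bases to the right of
    the forward-strand PAM interval.
    """
    if strand == "+":
        return pam_start - 3
    return pam_start + 3 + 3


def map_cut_site(guide: GuideRecord) -> int:
    """Cut coordinate of a guide record (between protospacer pos 17 and 18)."""
    return guide.cut_pos


def _protospacer_interval(cut_pos: int, strand: str) -> tuple[int, int]:
    """Forward-strand genomic interval occupied by the 20-nt protospacer."""
    if strand == "+":
        return (cut_pos - 17, cut_pos + 3)
    return (cut_pos - 3, cut_pos + 17)


def map_to_residues(guide: GuideRecord, gene: GeneModel,
                    mode: str = "cut") -> tuple[int, int] | None:
    """Residue span disrupted by a guide.

    mode="cut" (default): the codon(s) overlapping the blunt-cut
    coordinate; a cut exactly between two codons yields both flanking
    residues. mode="footprint": every codon overlapped by the 20-nt
    protospacer. A guide whose cut is intronic/UTR but whose protospacer
    overlaps the CDS maps to the nearest CDS residue; a guide entirely
    outside the gene maps to None.
    """
    if mode not in ("cut", "footprint"):
        raise ValueError(f"unknown residue-mapping mode {mode!r}")
    lo, hi = _protospacer_interval(guide.cut_pos, guide.strand)
    if mode == "footprint":
        offsets = [gene.genomic_to_cds(p)
                   for p in (*range(lo, hi + 1),)]
        offsets = [o for o in offsets if o is not None]
        if not offsets:
            return None
        # between-base offsets [a,b] overlap codons floor(a/3)+1 .. ceil(b/3)
        a, b = min(offsets), max(offsets)
        if a == b:
            return gene.residues_at_cut(a)
        first = a // 3 + 1
        last = (b + 2) // 3
        cds = gene.genomic_to_cds(guide.cut_pos)
        if cds is not None:     # footprint always contains the cut codons
            lo_cut, hi_cut = gene.residues_at_cut(cds)
            first, last = min(first, lo_cut), max(last, hi_cut)
        n = gene.protein_length
        return (min(max(first, 1), n), min(max(last, 1), n))

    cds = gene.genomic_to_cds(guide.cut_pos)
    if cds is not None:
        return gene.residues_at_cut(cds)
    # intronic / UTR cut: fall back to the nearest CDS base touched by the
    # protospacer, if any
    best = None
    for p in range(lo, hi + 1):
        o = gene.genomic_to_cds(p)
        if o is None:
            continue
        d = abs(p - guide.cut_pos)
        if best is None or d < best[0]:
            best = (d, o)
    if best is None:
        return None
    return gene.residues_at_cut(best[1])


def classify_domain(residue_span: tuple[int, int] | None,
                    gene: GeneModel) -> str:
    """AD if the span overlaps any annotated domain, NAD otherwise.

    Guides with no residue span are 'none'. For a gene annotated over its
    entire length no guide can be NAD.
    """
    if residue_span is None:
        return "none"
    lo, hi = residue_span
    for d in gene.domains:
        if lo <= d.end_res and d.start_res <= hi:
            return "AD"
    return "NAD"


def enumerate_guides(gene: GeneModel, genome: dict[str, str],
                     residue_mode: str = "cut") -> list[GuideRecord]:
    """All SpCas9 guides whose cut site falls inside an exon of ``gene``.

    Scans both strands of the gene's chromosome for NGG PAMs, keeps
    guides cutting within an exon (boundaries inclusive in between-base
    space), and annotates residue span and AD/NAD class. Guides whose
    protospacer or PAM contains a non-ACGT character are skipped with a
    warning. Deterministic order: (cut coordinate, then '+' before '-').
    """
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} absent from genome")
    seq = genome[gene.chrom].upper()
    n = len(seq)
    for s, e in gene.exons:
        if e > n:
            raise ValueError(f"exon ({s}, {e}) outside genome bounds "
                             f"({gene.chrom} has {n} bp)")

    def in_exon(cut: int) -> bool:
        return any(s <= cut <= e for s, e in gene.exons)

    skipped = 0
    guides: list[GuideRecord] = []
    # forward strand: PAM at [q, q+3) with seq[q+1:q+3] == "GG",
    # protospacer at [q-20, q)
    for q in range(20, n - 2):
        if seq[q + 1:q + 3] != "GG":
            continue
        cut = q - 3
        if not in_exon(cut):
            continue
        proto, pam = seq[q - 20:q], seq[q:q + 3]
        if set(proto + pam) - _ACGT:
            skipped += 1
            continue
        guides.append(GuideRecord(
            guide_id="", gene=gene.gene_id, protospacer=proto, pam=pam,
            chrom=gene.chrom, cut_pos=cut, strand="+"))
    # reverse strand: forward pattern CCN at [q, q+3), protospacer
    # at [q+3, q+23) read as revcomp
    for q in range(0, n - 22):
        if seq[q:q + 2] != "CC":
            continue
        cut = q + 6
        if not in_exon(cut):
            continue
        window = seq[q:q + 23]
        if set(window) - _ACGT:
            skipped += 1
            continue
        rc = revcomp(window)
        guides.append(GuideRecord(
            guide_id="", gene=gene.gene_id, protospacer=rc[:20],
            pam=rc[20:], chrom=gene.chrom, cut_pos=cut, strand="-"))
    if skipped:
        logger.warning("%s: skipped %d guide windows containing non-ACGT "
                       "characters", gene.gene_id, skipped)
    guides.sort(key=lambda g: (g.chrom, g.cut_pos, g.strand))
    for i, g in enumerate(guides):
        g.guide_id = f"{gene.gene_id}_{g.cut_pos}{g.strand}"
        g.residue_span = map_to_residues(g, gene, mode=residue_mode)
        g.domain_class = classify_domain(g.residue_span, gene)
    return guides


def library_table(guides: list[GuideRecord]) -> pd.DataFrame:
    """Flatten guide records into the library TSV layout."""
    rows = []
    for g in guides:
        lo, hi = g.residue_span if g.residue_span else (None, None)
        rows.append({
            "guide_id": g.guide_id, "gene": g.gene,
            "protospacer": g.protospacer, "pam": g.pam,
            "oligo_sequence": g.oligo_sequence,
            "chrom": g.chrom, "cut_pos": g.cut_pos, "strand": g.strand,
            "residue_start": lo, "residue_end": hi,
            "domain_class": g.domain_class, "category": g.category,
        })
    return pd.DataFrame(rows)


def export_library(guides: list[GuideRecord], path: str,
                   dedup_oligos: bool = False) -> pd.DataFrame:
    """Write the library TSV; optionally deduplicate by oligo sequence.

    Duplicated protospacers at distinct loci are kept as distinct records;
    with ``dedup_oligos`` the export collapses them and records the
    multiplicity.
    """
    tab = library_table(guides)
    if dedup_oligos:
        mult = tab.groupby("oligo_sequence").size().rename("multiplicity")
        tab = (tab.drop_duplicates("oligo_sequence")
               .merge(mult, left_on="oligo_sequence", right_index=True))
    tab.to_csv(path, sep="\t", index=False)
    return tab
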