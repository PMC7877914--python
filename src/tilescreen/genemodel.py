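"""Gene models: exon layout, CDS frame, and protein-domain annotation.

Coordinate conventions used throughout the package:

* genomic intervals are 0-based, half-open ``[start, end)``;
* protein residues are 1-based, inclusive;
* cut sites are 0-based *between-base* coordinates (a cut at coordinate
  ``c`` falls between genomic bases ``c-1`` and ``c``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Domain:
    """An annotated protein domain, residues 1-based inclusive."""

    name: str
    start_res: int
    end_res: int

    def __post_init__(self) -> None:
        if self.start_res < 1 or self.end_res < self.start_res:
            raise ValueError(f"bad domain interval {self.name}: "
                             f"({self.start_res}, {self.end_res})")


@dataclass
class GeneModel:
    """Exon structure, reading frame and domain annotation for one gene.

    Parameters
    ----------
    gene_id : str
        Gene symbol or identifier.
    chrom : str
        Chromosome / contig name holding the exons.
    strand : {"+", "-"}
        Strand the CDS is read from.
    exons : list of (int, int)
        Genomic exon intervals, 0-based half-open, sorted, non-overlapping.
    cds_start_phase : int
        Number of bases of the first (5') exon that precede the first
        complete codon, in 0..2.
    protein_length : int
        Length of the encoded protein in residues.
    domains : list of Domain
        Annotated domains; every interval must lie in ``[1, protein_length]``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_phase: int = 0
    protein_length: int = 0
    domains: list[Domain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.cds_start_phase not in (0, 1, 2):
            raise ValueError("cds_start_phase must be 0, 1 or 2")
        exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in exons:
            if e <= s or s < 0:
                raise ValueError(f"bad exon interval ({s}, {e})")
        if exons != sorted(exons):
            raise ValueError("exons must be sorted by start coordinate")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError("exons overlap")
        self.exons = exons
        if (self.cds_length % 3) != 0:
            raise ValueError(
                f"CDS length {self.cds_length} after phase "
                f"{self.cds_start_phase} is not a multiple of 3")
        if self.protein_length == 0:
            self.protein_length = self.cds_length // 3
        if self.protein_length != self.cds_length // 3:
            raise ValueError("protein_length inconsistent with CDS length")
        for d in self.domains:
            if d.end_res > self.protein_length:
                raise ValueError(
                    f"domain {d.name} exceeds protein length "
                    f"{self.protein_length}")

    # ------------------------------------------------------------------ #

    @property
    def cds_length(self) -> int:
        """Spliced CDS length in bases, after removing the start phase."""
        return sum(e - s for s, e in self.exons) - self.cds_start_phase

    def spliced_cds(self, genome: dict[str, str]) -> str:
        """Spliced CDS sequence read in translation order."""
        seq = genome[self.chrom]
        parts = [seq[s:e] for s, e in self.exons]
        spliced = "".join(parts)
        if self.strand == "-":
            spliced = revcomp(spliced)
        return spliced[self.cds_start_phase:]

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic between-base coordinate into CDS between-base space.

        Returns ``None`` when ``pos`` does not fall within an exon
        (exon boundaries are mapped; an intronic coordinate is not).
        The result is clipped to ``[0, cds_length]``; coordinates falling
        in the phase overhang map to 0.
        """
        offset = None
        if self.strand == "+":
            cum = 0
            for s, e in self.exons:
                if s <= pos <= e:
                    offset = cum + (pos - s)
                    break
                cum += e - s
        else:
            cum = 0
            for s, e in reversed(self.exons):
                if s <= pos <= e:
                    offset = cum + (e - pos)
                    break
                cum += e - s
        if offset is None:
            return None
        offset -= self.cds_start_phase
        return min(max(offset, 0), self.cds_length)

    def residues_at_cut(self, cds_pos: int) -> tuple[int, int]:
        """Residue span disrupted by a blunt cut at CDS between-base ``cds_pos``.

        A cut inside codon *k* returns ``(k, k)``; a cut exactly on a codon
        boundary returns both flanking residues, clipped to the protein.
        """
        n = self.protein_length
        if cds_pos % 3 == 0:
            lo, hi = cds_pos // 3, cds_pos // 3 + 1
            lo = max(lo, 1)
            hi = min(hi, n)
            return (min(lo, hi), max(lo, hi))
        k = cds_pos // 3 + 1
        k = min(max(k, 1), n)
        return (k, k)


# ---------------------------------------------------------------------- #
# TSV interfaces


def load_gene_models(genes_tsv: str, domains_tsv: str | None = None
                     ) -> dict[str, GeneModel]:
    """Read gene models from an exon TSV plus an optional domain TSV.

    The exon table needs columns ``gene_id, chrom, strand, exon_start,
    exon_end, phase`` (one row per exon; phase is taken from the first row
    of each gene). The domain table needs ``gene_id, domain, start_res,
    end_res``.
    """
    ex = pd.read_csv(genes_tsv, sep="\t")
    dom = (pd.read_csv(domains_tsv, sep="\t")
           if domains_tsv is not None else None)
    models: dict[str, GeneModel] = {}
    for gid, grp in ex.groupby("gene_id", sort=False):
        grp = grp.sort_values("exon_start")
        domains = []
        if dom is not None:
            for _, row in dom[dom["gene_id"] == gid].iterrows():
                domains.append(Domain(str(row["domain"]),
                                      int(row["start_res"]),
                                      int(row["end_res"])))
        models[str(gid)] = GeneModel(
            gene_id=str(gid),
            chrom=str(grp["chrom"].iloc[0]),
            strand=str(grp["strand"].iloc[0]),
            exons=list(zip(grp["exon_start"], grp["exon_end"])),
            cds_start_phase=int(grp["phase"].iloc[0]),
            domains=domains,
        )
    return models
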