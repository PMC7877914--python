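"""Seeded synthetic inputs carrying the structure each pipeline stage assumes.

Generators produce: an exon-structured gene embedded in a random genome;
planted off-target sites at chosen mismatch patterns; negative-binomial
P1/P10 screen counts where depletion depends on whether a guide disrupts
a planted essential residue block (with optional FASTQ rendering); paired
chimeric reads from a diploid genome with planted copy-number segments
and a GC-bias gradient; and triplicate qPCR Ct tables with a planted
exon-skipping fraction. All randomness derives from the seed and every
generator returns its ground truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genemodel import Domain, GeneModel, revcomp
from .guide_design import GuideRecord
from .screen_stats import DEFAULT_PRIMER, ScreenTable

_BASES = np.array(list("ACGT"))

# codons never drawn when emitting a CDS (keeps the ORF stop-free)
_STOPS = {"TAA", "TAG", "TGA"}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_residues: int) -> str:
    codons = []
    while len(codons) < n_residues:
        c = _random_dna(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


# --------------------------------------------------------------------- #
# gene + genome


def gen_gene_and_genome(seed: int, n_exons: int = 4,
                        protein_length: int = 300,
                        domain_layout: list[tuple[str, int, int]] | None = None,
                        intron_length: int = 120,
                        flank_length: int = 500,
                        chrom: str = "chr1",
                        strand: str = "+") -> tuple[dict[str, str], GeneModel]:
    """A random genome with one exon-structured gene embedded.

    The spliced CDS encodes ``protein_length`` residues (stop-free),
    split across ``n_exons`` exons separated by random introns. Random
    ACGT sequence yields an NGG PAM every few bases on either strand, so
    every exon carries guides.
    """
    if domain_layout is None:
        domain_layout = [("domA", protein_length // 6,
                          protein_length // 3)]
    rng = np.random.default_rng(seed)
    cds = _random_cds(rng, protein_length)
    cuts = sorted(rng.choice(
        np.arange(1, len(cds)), size=n_exons - 1, replace=False)) \
        if n_exons > 1 else []
    pieces = [cds[a:b] for a, b in
              zip([0] + list(cuts), list(cuts) + [len(cds)])]
    if strand == "-":
        pieces = [revcomp(p) for p in reversed(pieces)]
    seq_parts = [_random_dna(rng, flank_length)]
    exons = []
    pos = flank_length
    for i, piece in enumerate(pieces):
        if i > 0:
            ilen = int(intron_length + rng.integers(0, intron_length))
            seq_parts.append(_random_dna(rng, ilen))
            pos += ilen
        seq_parts.append(piece)
        exons.append((pos, pos + len(piece)))
        pos += len(piece)
    seq_parts.append(_random_dna(rng, flank_length))
    genome = {chrom: "".join(seq_parts)}
    gene = GeneModel(
        gene_id="GENE1", chrom=chrom, strand=strand, exons=exons,
        cds_start_phase=0, protein_length=protein_length,
        domains=[Domain(n, s, e) for n, s, e in domain_layout])
    return genome, gene


# --------------------------------------------------------------------- #
# planted off-targets


def plant_offtargets(genome: dict[str, str], protospacer: str,
                     patterns: list[tuple[int, ...]], seed: int = 0,
                     max_retries: int = 200
                     ) -> tuple[dict[str, str], list[dict]]:
    """Insert NGG-adjacent near-matches of a guide at random loci.

    Each pattern is a set of mismatch positions (1..20, PAM-distal
    indexing, size 0-3); the planted 23-mer differs from the guide at
    exactly those positions. Loci are drawn non-overlapping; a draw that
    would land near an existing match is redrawn (bounded retries).
    Returns the modified genome and the truth records.
    """
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    rng = np.random.default_rng(seed)
    genome = dict(genome)
    truth = []
    occupied: list[tuple[str, int]] = []
    for pattern in patterns:
        site = list(protospacer)
        for p in sorted(pattern):
            if not 1 <= p <= 20:
                raise ValueError(f"mismatch position {p} outside 1..20")
            alternatives = [b for b in "ACGT" if b != protospacer[p - 1]]
            site[p - 1] = alternatives[int(rng.integers(0, 3))]
        site_seq = "".join(site) + "AGG"
        chroms = list(genome)
        for _ in range(max_retries):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            n = len(genome[chrom])
            start = int(rng.integers(0, n - 23))
            if any(c == chrom and abs(s - start) < 30
                   for c, s in occupied):
                continue
            genome[chrom] = (genome[chrom][:start] + site_seq
                             + genome[chrom][start + 23:])
            occupied.append((chrom, start))
            truth.append({"chrom": chrom, "start": start,
                          "mismatch_positions": tuple(sorted(pattern))})
            break
        else:
            raise RuntimeError("could not place planted off-target site")
    return genome, truth


# --------------------------------------------------------------------- #
# screen counts


@dataclass
class ScreenTruth:
    """Ground truth of a simulated dropout screen."""

    seed: int
    effect_size: float              # log2 units, negative = depletion
    dispersion: float               # NB: var = mu + phi * mu^2
    depth: float                    # expected P1 counts per guide
    essential_blocks: list[tuple[int, int]]   # residue intervals
    efficacy: dict[str, float] = field(default_factory=dict)
    expected_effect: dict[str, float] = field(default_factory=dict)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             phi: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; var = mu + phi mu^2."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def gen_screen_counts(library: pd.DataFrame,
                      essential_blocks: list[tuple[int, int]],
                      seed: int = 0, effect_size: float = -4.0,
                      dispersion: float = 0.1, depth: float = 2000.0,
                      efficacy: float = 1.0,
                      samples: tuple[str, str] = ("P1", "P10")
                      ) -> tuple[ScreenTable, ScreenTruth]:
    """Negative-binomial P1/P10 counts with residue-dependent depletion.

    Tiling guides whose residue span overlaps a planted essential block
    deplete by ``effect_size * efficacy``; positive controls deplete by
    the full effect; negative controls and other tiling guides are null.
    P1 ~ NB(depth, phi) and P10 means are P1 means scaled by 2^effect.
    """
    rng = np.random.default_rng(seed)
    truth = ScreenTruth(seed=seed, effect_size=effect_size,
                        dispersion=dispersion, depth=depth,
                        essential_blocks=list(essential_blocks))
    effects = np.zeros(len(library))
    for i, (_, row) in enumerate(library.iterrows()):
        gid = str(row["guide_id"])
        cat = str(row["category"])
        e_g = efficacy
        if cat == "positive_control":
            eff = effect_size
        elif cat == "negative_control":
            eff = 0.0
        else:
            lo, hi = row.get("residue_start"), row.get("residue_end")
            in_block = (
                pd.notna(lo) and any(
                    lo <= be and bs <= hi
                    for bs, be in essential_blocks))
            eff = effect_size * e_g if in_block else 0.0
        effects[i] = eff
        truth.efficacy[gid] = e_g
        truth.expected_effect[gid] = eff
    p1 = _nb_draw(rng, np.full(len(library), depth), dispersion)
    p10 = _nb_draw(rng, depth * np.power(2.0, effects), dispersion)
    counts = pd.DataFrame({samples[0]: p1, samples[1]: p10},
                          index=list(library["guide_id"]))
    return ScreenTable(library=library, raw_counts=counts), truth


def make_library(gene_guides: pd.DataFrame, seed: int = 0,
                 n_negative: int = 1602, n_positive_genes: int = 14,
                 guides_per_positive: int = 3) -> pd.DataFrame:
    """Assemble a pooled library: tiling guides plus control categories.

    Mirrors the screened library design: the tiling set, a large panel
    of non-targeting/neutral-locus negative controls, and a median of
    three pre-validated guides per positive-control essential gene.
    """
    rng = np.random.default_rng(seed)
    gene_guides = gene_guides.copy()
    if "sequence" not in gene_guides.columns:
        gene_guides["sequence"] = gene_guides["protospacer"]
    rows = [gene_guides.assign(category="tiling")]
    neg = pd.DataFrame({
        "guide_id": [f"neg_{i}" for i in range(n_negative)],
        "gene": "neg_ctrl",
        "sequence": [_random_dna(rng, 20) for _ in range(n_negative)],
        "category": "negative_control"})
    pos_rows = []
    for g in range(n_positive_genes):
        for j in range(guides_per_positive):
            pos_rows.append({
                "guide_id": f"pos{g}_{j}", "gene": f"ess_gene_{g}",
                "sequence": _random_dna(rng, 20),
                "category": "positive_control"})
    rows += [neg, pd.DataFrame(pos_rows)]
    lib = pd.concat(rows, ignore_index=True)
    for col in ("residue_start", "residue_end", "domain_class"):
        if col not in lib.columns:
            lib[col] = np.nan
    return lib


def render_screen_fastq(table: ScreenTable,
                        barcodes: dict[str, str],
                        primer: str = DEFAULT_PRIMER,
                        filler: str = "GTTTAAGAGCTAAGCTG"
                        ) -> list[tuple[str, str]]:
    """Render counts as primer|barcode|guide reads for count_guides tests."""
    if "sequence" not in table.library.columns:
        raise ValueError("library needs a 'sequence' column")
    seqs = dict(zip(table.library["guide_id"], table.library["sequence"]))
    reads = []
    i = 0
    for sample in table.raw_counts.columns:
        bc = barcodes[sample]
        for gid, count in table.raw_counts[sample].items():
            read = primer + bc + str(seqs[gid]) + filler
            for _ in range(int(count)):
                reads.append((f"read{i}", read))
                i += 1
    return reads


# --------------------------------------------------------------------- #
# SMASH chimeric reads


@dataclass
class CNVTruth:
    seed: int
    segments: list[tuple[str, int, int, float]]   # chrom, start, end, copy
    gc_bias: float
    n_pairs: int


def gen_cnv_genome(seed: int, chrom_lengths: dict[str, int],
                   segments: list[tuple[str, int, int, float]]
                   ) -> dict[str, str]:
    """Random diploid reference; ``segments`` define non-2 copy states."""
    rng = np.random.default_rng(seed)
    return {c: _random_dna(rng, n) for c, n in chrom_lengths.items()}


def gen_smash_reads(genome: dict[str, str],
                    segments: list[tuple[str, int, int, float]],
                    n_pairs: int, seed: int = 0,
                    gc_bias: float = 0.0,
                    read_length: int = 76,
                    fragment_length_range: tuple[int, int] = (40, 120),
                    chimera_length_range: tuple[int, int] = (300, 700)
                    ) -> tuple[list[tuple[str, str]], CNVTruth]:
    """Chimeric read pairs: sub-fragments sampled ~ copy state x GC factor.

    Sub-fragments (uniform length in ``fragment_length_range``) are drawn
    with probability proportional to the local copy state (2 outside the
    planted segments) times ``1 + gc_bias * (gc - 0.5)``, concatenated
    into chimeras of 300-700 bp, and read out as fixed-length pairs from
    the chimera ends (read 2 reverse-complemented).
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()

    def copy_state(chrom: str, pos: int) -> float:
        for c, s, e, cp in segments:
            if c == chrom and s <= pos < e:
                return cp
        return 2.0

    def draw_fragment() -> str:
        while True:
            ci = int(rng.choice(len(chroms), p=chrom_p))
            chrom = chroms[ci]
            flen = int(rng.integers(*fragment_length_range))
            n = len(genome[chrom])
            if n <= flen:
                continue
            start = int(rng.integers(0, n - flen))
            frag = genome[chrom][start:start + flen]
            accept = copy_state(chrom, start) / 4.0
            if gc_bias != 0.0:
                gc = (frag.count("G") + frag.count("C")) / flen
                accept *= max(0.0, 1.0 + gc_bias * (gc - 0.5)) / \
                    max(1.0, 1.0 + abs(gc_bias) * 0.5)
            if rng.random() < accept:
                return frag

    pairs = []
    for _ in range(n_pairs):
        target = int(rng.integers(*chimera_length_range))
        chimera = ""
        while len(chimera) < target:
            chimera += draw_fragment()
        r1 = chimera[:read_length]
        r2 = revcomp(chimera[-read_length:])
        pairs.append((r1, r2))
    truth = CNVTruth(seed=seed, segments=list(segments),
                     gc_bias=gc_bias, n_pairs=n_pairs)
    return pairs, truth


# --------------------------------------------------------------------- #
# qPCR


def gen_qpcr(skipping_fraction: float, sigma: float = 0.15,
             n_replicates: int = 3, seed: int = 0,
             primers: list[str] | None = None,
             junction_primer: str = "ex6-ex7",
             base_ct: float = 22.0, ref_ct: float = 16.0
             ) -> tuple[pd.DataFrame, dict]:
    """Triplicate Ct table with a planted exon-skipping fraction.

    The junction primer's expected fold change in the test line is
    ``1 - s``; all other primers have expected fold change 1. Gaussian
    cycle noise of scale ``sigma`` is added to every Ct.
    """
    if not 0 <= skipping_fraction < 1:
        raise ValueError("skipping fraction must be in [0, 1)")
    if primers is None:
        primers = ["ex1-ex2", "ex3-ex4", "ex6-ex7", "ex8-ex9"]
    if junction_primer not in primers:
        raise ValueError("junction primer must be among the primers")
    rng = np.random.default_rng(seed)
    rows = []
    for line in ("control", "test"):
        for primer in primers:
            ct = base_ct
            if line == "test" and primer == junction_primer:
                # fc = 2^-ddct = 1 - s  =>  ddct = -log2(1 - s)
                ct = base_ct - np.log2(1.0 - skipping_fraction) \
                    if skipping_fraction > 0 else base_ct
            cts = ct + rng.normal(0.0, sigma, size=n_replicates)
            refs = ref_ct + rng.normal(0.0, sigma, size=n_replicates)
            row = {"line": line, "primer_pair": primer}
            row.update({f"ct{i+1}": float(c) for i, c in enumerate(cts)})
            row.update({f"ref_ct{i+1}": float(c)
                        for i, c in enumerate(refs)})
            rows.append(row)
    truth = {"seed": seed, "skipping_fraction": skipping_fraction,
             "sigma": sigma, "junction_primer": junction_primer}
    return pd.DataFrame(rows), truth


def save_truth(truth, path: str) -> None:
    """Serialize a truth record (dataclass or dict) as JSON."""
    obj = asdict(truth) if hasattr(truth, "__dataclass_fields__") else truth
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
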