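# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and
the design decisions that were genuinely open.

## Coordinates and conventions

Genomic intervals are 0-based half-open; protein residues are 1-based
inclusive; cut sites use a 0-based *between-base* index (a cut at `c`
falls between bases `c−1` and `c`). The SpCas9 blunt cut is placed 3 bp
5′ of the PAM, between protospacer positions 17 and 18 — the canonical
position; the cut-site definition is a convention this package fixes
explicitly since reported guide tables rarely state it. Mismatch
positions in off-target sites are indexed 1..20 from the PAM-distal end.

## Guide design

Enumeration scans both strands of the gene's chromosome for NGG PAMs and
keeps a guide when its cut coordinate lies inside an exon (boundaries
inclusive, so junction-spanning cuts are retained). Duplicate
protospacer sequences at distinct loci are distinct records; the library
export can deduplicate by oligo with a multiplicity column. Windows
containing non-ACGT characters are skipped with a logged warning rather
than failing the run.

Disrupted residues default to the codon(s) overlapping the cut
coordinate; a cut exactly between codons is attributed to both flanking
residues. This matches the per-residue granularity used when tiling
signals are plotted against amino-acid position. Because functional
disruption can extend beyond the cut, a "footprint" mode maps the whole
20-nt protospacer to codons instead; the footprint span always contains
the cut-site span. Guides whose cut is intronic/UTR but whose
protospacer overlaps the CDS map to the nearest CDS residue.

AD/NAD classification is overlap-by-≥1-residue against the annotated
domain list; it is monotone in domain size, and a gene annotated across
its entire length has no NAD guides.

## Off-target specificity

The search finds every genomic 23-mer ending in GG whose first 20 bases
are within 3 mismatches of the protospacer. The implementation is a
pigeonhole seed index — the protospacer is split into `max_mm + 1`
segments, any qualifying site must match one segment exactly, and seed
hits are verified by a full Hamming count — with a quadratic brute-force
scan kept as the test oracle. Only canonical NGG sites are considered
(no NAG, no bulges), and candidate sites containing ambiguous bases are
skipped.

Per-site penalty:

    h = Π_p (1 − W[p]) · D(d̄) · 1/m²
    D(d̄) = 1 / (((19 − d̄)/19) · 4 + 1)

where `m` is the mismatch count, `d̄` the mean pairwise distance between
mismatch positions, and `W` a 20-vector of position weights. For `m ≤ 1`
the `D` and `1/m²` factors are defined as 1 (the mean pairwise distance
does not exist below two mismatches); for `m = 0`, `h = 1`. The
aggregate score is `S = 1/(1 + Σ h)` over all sites excluding one
on-target perfect match, so a clean guide scores exactly 1.00 and every
additional site strictly lowers the score.

**Weight table.** The package ships the widely used experimentally
derived single-mismatch weight vector (`HSU_WEIGHTS`). That vector is
not monotone position by position, which would let a mismatch *closer*
to the PAM occasionally be penalized more than one farther away —
contradicting the qualitative behaviour this scoring scheme is meant to
encode. The default table (`DEFAULT_WEIGHTS`) is therefore the isotonic
least-squares fit (pool-adjacent-violators) of that vector: monotone
toward the PAM, preserving the total weight mass. Callers can pass
either table, or their own, to `site_penalty`.

## Screen statistics

Quantification is a strict exact match: a read is assigned to
(guide, sample) only when it contains the configured forward primer
immediately followed by a sample barcode and an exact 20-nt library
sequence; everything else is discarded and tallied, so assigned +
discarded = total always. The default primer is the standard U6
cassette forward primer used for sgRNA amplicon sequencing; the
primer/barcode geometry is configuration, not code.

Normalization is median-of-ratios (the "median normalization" of
MAGeCK/DESeq): each sample's size factor is the median over guides with
a nonzero across-sample geometric mean of count/geomean. Note that
rescaling one sample's library size changes all normalized counts by a
single common scalar (the geometric-mean reference moves); every
cross-sample ratio, and hence every LFC, is invariant — the per-entry
values themselves are not, and cannot be, under this definition.

LFC uses a pseudo-count α = 1 by default to keep zero-count dropouts
finite, the standard choice for dropout screens; replicate sample pairs
are averaged.

The essentiality cutoff is

    C = min( min_g∈negatives LFC_g , min_G∈positive genes median_g∈G LFC_g )

and a guide is essential iff `LFC ≤ C` **and** strictly below every
negative control. The conjunction over positive genes ("at least as
depleted as each positive-control gene's median") is the default
reading; `positive_bound="max"` exposes the looser any-gene reading.
Because the rule minimizes over the *worst* positive gene median, it is
deliberately conservative: with noisy positive controls the cutoff sits
below the typical positive median, and only strongly depleted guides
pass. Reported cutoffs can optionally be rounded toward zero to mirror
integer presentation; calls always use the raw value.

AD-vs-NAD comparison is a one-sided Mann–Whitney rank-sum test (AD more
depleted), exact for small samples — complete separation of 3 vs 3
yields exactly p = 1/20. Replicate agreement reports Pearson (primary)
and Spearman correlations.

## CKHS detection

The residue signal is the mean LFC of all guides whose disrupted-residue
span covers each position, with per-residue guide coverage recorded.
Missing residues are linearly interpolated (flat at the ends) before
smoothing and segmentation; imputed residues carry no evidence of their
own and cannot seed a region boundary.

Denoising replaces values deviating from a centered rolling median
(window 5 = half-width 2) by more than 3 rolling-residual MADs —
targeting inactive guides (outliers toward 0) and strong off-target
effects (isolated deep outliers) without moving genuine steps by more
than the half-width.

Segmentation is a bottom-up unbalanced-Haar merge: starting from
single-residue segments, the adjacent pair with the smallest absolute
Haar contrast `|m₁ − m₂|·√(n₁n₂/(n₁+n₂))` is merged (ties broken
leftmost) until every remaining contrast exceeds `t2 · σ̂ · √(log n)`,
with `σ̂` estimated as MAD(first differences)/√2. The merge order is
independent of `t2`, so the breakpoint set at a larger threshold is
always a subset of that at a smaller one — lower `t2` yields more, and
more fragmented, regions. This is a TGUH-style scheme; equivalence with
any particular published implementation is claimed at the level of
recovered regions on synthetic data, not bit for bit.

A segment is called CKHS when its mean is at or below

    median(neg) − t2 · (median(neg) − min_segment_mean)

and strictly below the negative-control median; adjacent called
segments merge. This concretizes "hypersensitive relative to controls"
with the same `t2` ∈ {0.25, 0.5} semantics as segmentation (lower
threshold → more permissive calling → higher recall, lower precision);
without negative controls the global essentiality cutoff is the bound.
Domain overlap reports per-domain overlap length and Jaccard against
the union of the domain with its overlapping regions, and flags regions
outside all domains as candidate novel functional regions.

## SMASH copy-number profiling

The reference (all chromosomes, forward and reverse complement) is
indexed with a prefix-doubling suffix array. For each read offset an
incremental binary search yields the longest reference match, its
occurrence count, and the shortest prefix length at which it becomes
unique. A maximal unique match (MUM) is a longest-match that occurs
exactly once (both strands counted) and is not contained in the match
starting one position earlier. The inner search is JIT-compiled with
numba when available; the identical pure-Python path is the fallback
and the brute-force all-substring scan is the test oracle.

Filters, applied per read pair in order: match length ≥ 20 bp; excess
unique sequence `length − min_unique_length ≥ 4 bp` (the match must
extend at least 4 bp past the point where it becomes unique — near-
threshold uniqueness is fragile to sequencing error); and read-2
matches within 1000 bases (inclusive) of any read-1 match's start
coordinate are dropped as redundant reads of the same fragment. The
proximity rule compares start coordinates, not intervals — the literal
reading of the coordinate-based filter.

Bins are empirically sized: boundaries are placed so each bin receives
approximately `target_count` MUMs from a seeded uniform-coverage
fragment simulation on the same reference, so mappability structure is
absorbed into bin width and equal copy implies equal expected count.
GC correction multiplies each bin by `mean(raw)/LOWESS_fit(gc)`
(span 0.3, fit floored at a small epsilon; degenerate inputs — under 20
bins or constant GC — fall back to the identity). Final normalization
scales so the length-weighted autosomal mean copy number is exactly
2.0; sex chromosomes are excluded from the baseline. The reported
profile is a per-bin bedGraph plus candidate gained/lost runs of ≥ 5
consecutive bins beyond ±0.5 of 2 — a deliberately simple run-based
caller; full segmentation (CBS etc.) is out of scope.

Note the normalization arithmetic: an amplified segment's normalized
level is `2·(copy/2)/(autosomal mean relative coverage)`, so a 3-copy
segment spanning a non-negligible fraction f of the autosome reads out
at `3/(1 + f/2)`, slightly below 3. Recovery tests therefore plant
segments covering ≲10% of one chromosome.

## qPCR

ΔCt subtracts the reference-gene mean Ct within a line; ΔΔCt subtracts
the control line's ΔCt; `fc = 2^(−ΔΔCt)` assumes perfect doubling
(efficiency calibration is out of scope). Both fc and log2 fc are
reported under explicit column names. For an exon-junction primer
spanning a potentially skipped exon, the skipped fraction is
`clamp(1 − fc, 0, 1)`. Missing Ct replicates are dropped with a
warning; an all-missing triplicate is an error.

## Synthetic generators

All generators derive every draw from a single integer seed
(numpy Generator streams) and return machine-readable ground truth.

* `gen_gene_and_genome` — a stop-free random CDS split across exons
  with random introns and flanks inside a random chromosome; random
  ACGT sequence carries NGG PAMs every few bases on both strands, so
  every exon is guide-dense. Phase 0, one gene per genome.
* `plant_offtargets` — inserts NGG-adjacent near-matches differing from
  a guide at exactly the requested positions, at non-overlapping random
  loci with bounded redraws.
* `gen_screen_counts` — negative binomial (variance μ + φμ², φ = 0.1 by
  default, a typical pooled-screen overdispersion) at 2000× expected
  depth, mirroring the representation targeted in real screens. Guide
  effects: tiling guides in a planted essential block deplete by
  Δ·e_g (Δ = −4 log2 default), positive controls by Δ, everything else
  null. Optional FASTQ rendering (primer|barcode|guide) feeds the
  counting path end to end. The companion `make_library` assembles
  tiling + 1602-scale negative controls + ~3 guides per positive gene.
* `gen_smash_reads` — sub-fragments (40–120 bp) accepted with
  probability ∝ local copy state × (1 + gc_bias·(gc − 0.5)),
  concatenated into 300–700 bp chimeras, read out as fixed-length pairs
  from the chimera ends (read 2 reverse-complemented).
* `gen_qpcr` — junction-primer Ct shifted so the expected fold change
  is 1 − s, Gaussian cycle noise σ (0.15 default) on every Ct.

What the generators do **not** emulate: sequencing errors beyond an
optional uniform substitution, PCR duplicates and jackpotting, guide-
efficacy heterogeneity beyond a single scalar, chromatin or copy-number
confounding of cutting efficiency, mappability structure of a real
genome (random sequence is almost everywhere unique), and real qPCR
efficiency drift. Passing tests demonstrate correctness of the
algorithms under the stated statistical model, not robustness to every
artefact of real libraries.

## Problem sizes in the shipped checks

The test suite and the acceptance script size their simulations to run
comfortably on one CPU: oracle equivalence on 20–50 kb genomes and
kilobase-scale MUM references, screens of ~1000 guides, CKHS trials at
n = 200 × 100 seeds, copy-number recovery on a 200-kb diploid reference
(~9k read pairs), and the end-to-end profile for the reproduction
script on a 1-Mb reference with 20k chimeric pairs. All scale linearly
if rerun larger.

## Known limitations

* The off-target search is exact but genome-scale indexing performance
  (GRCh38) is not a goal; the suffix-array MUM finder likewise targets
  megabase-scale synthetic references.
* Exact numeric reproduction of any particular published per-guide
  specificity score is not claimed — published tables rarely fix the
  weight vector and aggregation constants; the package guarantees the
  stated structural properties (maximum 1.00, monotonicity, spread
  behaviour) instead.
* The CKHS caller's bound is this package's concretization of
  "hypersensitive"; alternative bounds can be passed via configuration.
* `essentiality_cutoff` requires at least one negative-control guide
  and one positive-control gene; screens without controls cannot be
  calibrated by this rule.
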