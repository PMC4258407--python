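# Methods

## The problem and the model

A tandemly duplicated immune-gene locus (the motivating case is a cattle-style
KIR cluster) consists of sister genomic blocks of tens of kilobases that arose
by segmental duplication and still share 96–99% identity, each carrying the
same ordered set of paralogous genes. Two alleles of the whole haplotype
differ by SNPs (on the order of 10³ across ~200 kb). A short-read sample —
here modelled on ancient DNA with 36–70-bp fragments — is interrogated for
which individual paralogs it contains. Because paralogs within a group differ
at only a small set of positions, most reads map to several gene copies
equally well, and presence must be established from (a) the positions that
*do* distinguish the copies and (b) the coverage attainable by uniquely
mapping reads, benchmarked against what the locus structure permits.

All sequence models are substitution-only: the quantities of interest are SNP
and substitution counts, so the generator introduces no indels and the mapper
aligns ungapped end-to-end. Reads spanning a real indel or a deletion
breakpoint simply fail to map; this loses a small amount of signal and no
correctness.

## Synthetic-locus generator (`synthlocus`)

The generator produces the ground truth every other stage is tested against.

- **Block**: i.i.d. uniform random sequence carrying `n_genes` non-overlapping
  genes, group labels cycled. Gene anatomy is unconstrained by any upstream
  data and only its topology matters for the pipeline; the defaults (4–6
  exons of 36–300 bp, introns 60–140 bp, spliced CDS capped near 1.1 kb) give
  compact receptor-like genes that always fit a block of `n_genes × 2000` bp.
  Every generated gene has an intact reading frame (ATG … stop, no internal
  stop, length ≡ 0 mod 3) so frame-integrity verdicts have a clean baseline.
- **Haplotype**: `n_copies` independently mutated copies of the block,
  concatenated. Each copy receives Binomial(L, divergence) substitutions at
  uniform positions, uniformly over the three alternative bases. Note the
  *pairwise* block divergence is therefore ≈ 2 × the per-copy rate (0.02 per
  copy ⇒ ~4% between sisters). Copies may acquire premature stops — the same
  point-mutation mechanism that pseudogenises real paralog copies.
- **Allelic haplotype**: exactly `n_snps` substitutions at distinct uniform
  positions, identical gene coordinates. The default magnitude exercised in
  the acceptance script, 1008, emulates the divergence reported between the
  two reference haplotype alleles of the motivating locus.
- **Reads**: the tiling control emits every 35-bp window from both strands at
  phred 30 — exactly 2(N−L+1) reads, the convention for mappability positive
  controls. Ancient-style fragments draw uniform positions and strands;
  lengths are a mixture with 70% of the mass uniform on 40–60 bp and the rest
  uniform on the 36–39/61–70 tails, matching the reported insert-size picture
  (~36–70 bp, majority 40–60). Errors are uniform per-base substitutions at a
  configurable rate. Deamination damage (C→T at fragment ends) is *not*
  modelled: the analysed method does not use a damage model, and the uniform
  error rate is the configurable stand-in. No quality–error covariation, no
  paired-end structure.

Determinism: every operation takes an explicit integer seed and identical
seeds give byte-identical outputs (numpy `default_rng` throughout).

What passing tests on this generator do **not** show about real data:
reference bias from a single reference haplotype, indel variation, damage
patterns, contamination, GC-skewed coverage, and fragmented/gapped reference
assemblies are all outside the simulation.

## Mapper (`mapper`)

Exact k-mer positional index over the forward strand; the read and its
reverse complement are seeded at **every** offset and each candidate
placement verified end-to-end, reporting *all* placements with ≤
`max_mismatches` (default 2) substitutions. Uniqueness is best-score tie
counting: a read is `unique` iff exactly one placement attains the minimum
mismatch count — a deterministic, reproducible analogue of an aligner's
unique-mapping tag, and the definition all downstream "unique coverage"
rests on.

Sensitivity: with seeds at every offset, a placement with m mismatches is
guaranteed found when ⌊L/k⌋ > m (pigeonhole over disjoint k-mers). The
default k=13 guarantees 1-mismatch sensitivity for 35-bp reads; the pipeline
and all oracle-checked analyses use k=11, which guarantees the full
2-mismatch budget for every read ≥ 33 bp. Tie-break ordering of hits is
(mismatches, ref_id, position, strand) for diff-stable output; reverse-strand
hits are reported at the leftmost forward-reference base. Reads shorter than
k are flagged unmapped with a reason rather than erroring.

The competitive decoy filter keeps a read only when its best target score is
strictly better than its best decoy score; equal best scores are discarded
(the conservative reading of "specific to the target").

## Coverage (`covprof`)

Total depth counts each read at all tied-best placements (the "normal
coverage" view); unique depth counts only unique reads. Sliding-mean tracks
use a 300-bp window, step 1, value at window start. Per-gene coverage is the
percentage of span positions (first exon start to last exon end, introns
included) at depth ≥ `min_depth`; an exon-only mode is available by flag
since it is not knowable whether a span- or exon-based denominator was used
in the motivating analysis — both are reported. The tiling control is
evaluated at `min_depth=1`: 35-bp tiling depth is bounded by 2L=70, so the
>1000-read control convention that applies to deeply resequenced real
controls (kept as the `WindowParams` default) is not reachable in the
synthetic control and is exercised separately.

## Variants and consensus (`varcons`)

Cutoffs are implemented literally: a variant needs depth **strictly** greater
than 5 and a modal non-reference base at frequency ≥ 0.5001; a site at
exactly 50.0% is not a variant. Ties between two alternative bases are not
called. Multi-mapping reads are excluded from the pileup by default so
paralogous copies cannot inflate each other's variant frequencies; the
all-best policy is available for the normal-coverage view.

Cross-source conflict masking: where two sources' majority bases disagree, a
source with depth below its own threshold (8× for source a, 500× for source
b) is disregarded and the position masked from consensus/variant output.

Majority consensus takes any base reaching 51% of column depth; a column with
no majority, zero depth, or a mask falls back to the reference base (tie
policy `reference`, the default, which also guarantees an {A,C,G,T}-only
output; `first-alphabetical` is available and logged). Consensus of
error-free tiling reads reproduces the template byte-exactly and is
idempotent — both are asserted end-to-end in the tests.

Effect annotation substitutes the alternative base alone into its codon of
the strand-aware spliced CDS (standard genetic code); genes whose spliced CDS
length is not a multiple of 3 raise a warning and are skipped rather than
guessed at.

## Presence/absence (`paracall`)

Per paralog group:

1. **Group-exclusive reads**: a read is usable for group G iff it hits ≥1
   member of G within the mismatch budget and no gene of any other group
   (gene spans ±70-bp flank, both haplotype alleles indexed).
2. **Member assignment**: each group-exclusive read is assigned to the
   gene(s) attaining its minimum mismatch count. Reads tied between two
   *different* genes are dropped from member pileups (a tie carries no
   attribution), while ties between the two alleles of one gene are kept and
   counted once. Mapping every read to every member instead would let
   paralog reads dominate each member's pileup and would defeat the majority
   rule at diagnostic columns.
3. **Diagnostics and consistency**: diagnostic positions are all columns of
   the co-linear member set (both alleles included) with ≥2 distinct non-gap
   bases. A column is *consistent* for gene X when the majority base of X's
   pileup (depth ≥ 3) is one of X's allele bases, *inconsistent* when a
   different base dominates, *uncovered* below depth 3.
4. **Decision rule** (all knobs in `PresenceThresholds`, all logged in each
   call's rationale):
   - present if ≥2 consistent diagnostic sites with an inconsistent fraction
     ≤0.2, **or** unique coverage ≥0.5× the control;
   - absent if fewer than 2 consistent sites **and** either (a) unique
     coverage confirmed by ≥2 reads per position is <0.1× the control where
     the control is informative (≥1%), or (b) the gene has ≥3 diagnostics
     with zero consistent while a sibling member of its group is
     corroborated — i.e. the group pool demonstrably contains data, so the
     total absence of this member's defining bases is evidence of absence,
     not of missing data;
   - otherwise indeterminate; in particular a fully duplicated gene with an
     uninformative control can only be resolved through its diagnostics.

Two deliberate robustness choices deserve note. Requiring two reads per
position for the *absence* coverage comparison prevents single stray reads
(sequencing errors recreating a paralog's base) from blocking a correct
absent call. The sibling-corroboration path handles a subtler confound
observed on synthetic data: allelic SNPs in a *surviving* paralog can, by
chance, recreate the deleted copy's bases over a read-length window and
produce genuine multi-read unique coverage on a gene that is not there; the
diagnostic columns, which the confound cannot satisfy systematically, then
carry the decision. The numeric defaults (min_depth 3, min_consistent 2,
max inconsistent fraction 0.2, coverage fractions 0.5/0.1, control floor 1%)
are the package's own calibration on the synthetic suite, are all
configuration-exposed, and are echoed in every rationale string.

## Divergence analytics (`locusdiv`)

All pairwise operations assume pre-aligned input; the generator's output is
gap-free and co-linear by construction, and externally aligned input is taken
as-is. Gap conventions differ by purpose and are intentional: `p_distance`
uses pairwise deletion (gap columns excluded per pair — the phylogenetic
convention), while `window_identity_track` scores gaps as mismatches so
deletions appear as identity dips (the structural-divergence view).
`count_substitutions` excludes gap sites from the substitution count and
tallies them separately.

NS/S partitioning classifies each differing coding site by substituting it
alone into the first sequence's codon; codons hit at >1 site keep per-site
classification but are flagged, and per-region counts over a codon partition
sum exactly to whole-CDS counts. ITIM scanning is purely pattern-based
(VxYxxL canonical, VxFxxL = tyrosine-to-phenylalanine disrupted, overlapping
matches reported); membrane-proximal vs -distal labelling is left to the
caller's annotation. Adaptor classification returns `both` (with a warning)
when a flank arginine and a transmembrane lysine co-occur, rather than
silently picking one. Frame integrity requires ATG start, terminal stop, no
internal stop, and length ≡ 0 mod 3; each violation is located in CDS
coordinates. Standard genetic code only.

Coordinates are 0-based half-open everywhere in memory; 1-based inclusive
only in human-readable reports (variant TSV, SAM).

## Problem sizes

The test suite and the acceptance script run desk-scale versions of the study
conditions: two-block ~40-kb haplotypes (8 genes, 4 groups) for the
end-to-end recovery runs, randomized 2–3-block loci of 12–27 kb for the
ground-truth property sweep, references ≤5 kb for exhaustive mapper oracles,
and an 16-kb haplotype for the byte-exact consensus check. These sizes were
chosen so each brute-force oracle remains exhaustively computable while every
structural feature of the full-size locus (block duplication, paralog groups,
allelic variation, deletion) is present.

## Known limitations

- No indel calling or gapped alignment; deletion breakpoints are detectable
  only through coverage, not through split reads.
- Single-reference bias: sample reads are interpreted against one haplotype
  (plus one allelic variant); genes absent from the reference are outside
  scope beyond the unmapped fraction.
- No copy-number estimation beyond presence/absence.
- No damage-aware or GC-aware coverage normalisation; no base-quality-aware
  scoring (qualities are carried but not weighted).
- No multiple alignment; externally aligned input is trusted as given.
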