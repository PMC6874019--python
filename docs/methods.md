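# Methods

`panrecover` re-creates, at desk scale, the strategy of building a species
pan-genome from related-species assemblies: sequence missing from a
reference is found as the part of a donor assembly that refuses to align,
validated by read depth in a cohort of the focal species, purged of
cross-species divergence alleles, and extrapolated to a total pan-genome
size with a transformed Watterson estimator. Every stage runs against
synthetic genomes with fully known planted truth, so each claim the test
suite makes is a measurement, not an assumption.

## Synthetic genomes

The simulator emulates the data-generating process the method assumes:

- **Ancestor** — a single contig of i.i.d. bases at a configurable GC
  fraction (default 0.42, a typical mammalian value).
- **Reference** — the ancestor minus `n_deletions` non-overlapping planted
  segments. Segment lengths are uniform on `deletion_length_range`
  (default 500–20,000 bp; nothing below 400 bp, the minimum recoverable
  length). Segments keep a 2 kb margin from contig ends so flanks exist for
  breakpoint anchoring, and a 1 kb buffer between each other so they remain
  distinct events.
- **Donors** — the ancestor with i.i.d. substitutions at a configured
  per-site rate (never back to the same base), one donor per rate. The
  default rates span 0.21%–2.18%, the observed range between the focal
  species and its closest/most distant relatives in the group the method
  was designed for. Donors carry no indels or rearrangements; that is a
  modelling choice, not an approximation error, because the comparison
  method itself excludes translocations and inversions.
- **Cohort** — diploid individuals grouped into populations; each haplotype
  carries each planted segment independently with its population's
  frequency. An individual genome is the reference with its present
  segments re-inserted at the original junctions.
- **Reads** — fixed-length single-end reads with uniform starts and a flat
  per-base substitution error (default 100 bp, 1%). `coverage` is the total
  per-locus depth: the read count is `coverage × mean haplotype length /
  read length`, so the genome-wide median window depth of a diploid
  individual ≈ coverage, which is the scale the NRD thresholds assume.

All randomness flows from one master seed through named substreams
(`ancestor`, `deletions`, `donor:<s>`, `genotypes`, `reads:<ind>`), making
every output byte-identical under a fixed seed and each stage independently
regenerable.

What the simulator does *not* model — indel and structural divergence,
repeats and segmental duplication, paired ends, quality-dependent errors,
relatedness structure, variable coverage — bounds what passing tests show:
they validate the pipeline's logic and statistics under the method's own
assumptions, not its robustness to repeat-rich real genomes.

## Pairwise comparison (seed–chain–extend)

Two assemblies are compared with a bespoke forward-strand comparator:

1. **Anchors**: exact k-mer matches (default k = 15) unique in both
   assemblies; co-diagonal runs collapse into maximal exact segments.
2. **Chaining**: a windowed longest-increasing-subsequence dynamic program
   (lookback 64) maximizes total anchored bases, requiring monotonicity on
   both axes and per-axis gaps ≤ `max_gap` (default 2,000 bp). The default
   k and gap were chosen so a 2.2%-diverged donor still yields one chain
   per collinear region: the expected unbroken-k-mer fraction (1−p)^k is
   ≈ 0.72 at p = 0.022, so anchor deserts longer than 2 kb essentially
   never occur.
3. **Extension**: inter-anchor gaps are closed by banded global alignment
   (match +1, mismatch −1, gap −2, band 200); equal-length gaps up to 8 bp
   are closed diagonally (a gapped path there would need two −2 gap columns
   to beat at most eight ±1 diagonal columns — a tie-level difference at
   most). If a gap's length difference exceeds the band the block is split.
   Block ends are extended by a diagonal X-drop scan (x = 20), which walks
   to within a few bases of a true breakpoint before the score collapses in
   novel sequence.
4. **1:1 filter**: blocks are kept greedily by descending match count; a
   lower-scoring block overlapping a kept one (either axis) is trimmed to
   its largest non-overlapping remainder and dropped below 50 columns.
   Trimming rather than dropping preserves alignment length for the
   divergence denominator.

Identity is matches/columns with gap columns counted (BLAST-style).
Genomic divergence is divergent columns over total 1:1 alignment length;
unaligned query intervals ≥ 400 bp are the missing-sequence candidates.

## Pan-genome construction

Donors are processed in order (most distant first by convention). Per
donor: align to the current pan-genome → extract unaligned segments
≥ 400 bp → shred into 1 kb fragments → two-stage identity cascade → merge
→ deduplicate → append with ids `{contig}_{start}_{end}-{Species}`
(half-open, so length = end − start; parsing takes the rightmost two
numeric fields, which keeps accession-style contig names intact).

Cascade details. Stage 1 removes a fragment whose best anchored-alignment
identity against the pan-genome is ≥ 90%; a block spanning less than 25%
of the fragment does not count as a hit — a single chance shared 15-mer
X-drop-extends into a ~40-column high-identity micro-block, and treating
that as "the best hit" would delete genuinely novel fragments wholesale.
Stage 2 re-checks survivors with an exact (edlib) alignment of the fragment
against its best-hit region and removes those at ≥ 95%. Stage-2 identity is
computed over the aligned region; fragments with no stage-1 hit have no
region to re-check and are retained.

Merging is strictly contiguous on donor coordinates (gap 0); bridging
across a dropped fragment risks chimeric segments and is not done.
Deduplication is greedy, longest first: a segment joins a representative at
≥ 95% identity over ≥ 80% of the shorter sequence (edlib, shorter aligned
within longer; ties broken by provenance order for determinism).
Breakpoint anchoring aligns 1 kb donor flanks (truncated flanks ≥ 200 bp
allowed) to the base and requires both flanks on one contig, in order,
within 2× the pan-sequence length; the insertion point is the left flank's
end. Homolog search flags a pan-sequence when any block reaches ≥ 80%
identity covering ≥ 50% of it.

## Read mapping and NRD

Reads are placed by diagonal k-mer voting: an index of 21-mers unique
across the pan-genome is queried at every 7th read offset, each hit votes
for `hit position − offset`, and the read takes the modal diagonal
(≥ 2 votes, ties discarded). For substitution-only reads this is exact;
it has no concept of split or gapped placement, which is acceptable only
because junction-straddling reads resolve to one side's diagonal and their
overhang is clipped by every consumer.

Depth is computed in 200 bp windows stepping 100 bp (a final sub-100 bp
tail merges into the last window). The NRD of a sequence in an individual
is the *median* window depth over the individual's genome-wide median
window depth on the base assembly. The median (rather than mean) numerator
resists depleted edge windows. On this diploid-median scale
homozygous-present ≈ 1, heterozygous ≈ 0.5, absent ≈ 0, which is the only
scale on which the inherited thresholds are coherent: present ≥ 0.4 (below
the heterozygous expectation, above noise), absent ≤ 0.2, ambiguous
between. A pan-sequence is retained when present in ≥ 2 individuals;
ambiguous calls enter the PAV matrix as NA — they are the analogue of the
intermediate "divergent allele" class and must not be conflated with
absence — and presence frequency is the mean over non-NA entries.

## Divergence-site correction

Per individual, reads placed on a pan-sequence form a per-position base
count; where depth ≥ `min_depth` (default 1, inherited from the method's
polishing settings) and the majority base differs from the current one with
majority fraction strictly > 0.5, the base is substituted. Individuals are
applied serially, and full passes repeat (≤ `max_rounds`, default 3) until
a pass changes nothing. Correction is substitution-only and
length-preserving. One caveat is documented rather than hidden: at
`min_depth` 1, two individuals with conflicting single-read evidence at a
position can flip it back and forth, so such sequences report
`converged=False` at the round cap; the fixed-point property (re-running a
converged result changes nothing) holds whenever convergence is reported.
Raising `min_majority` suppresses these sites at the cost of leaving
depth-1 divergence sites uncorrected.

## Size model and cohort analyses

The pan-genome size model is `K = θL · a`, `a = 1 + 1/2 + … + 1/n`, with
θL the individual-specific sequence amount between two genomes (default
6.4 Mb) and n the effective population size (default 11,574, giving
a ≈ 9.9). The harmonic sum is computed by direct summation — no asymptotic
approximation — and the printed form (sum to n) is the default even though
classic Watterson theory sums to n−1 over sampled chromosomes; the
convention is switchable (`harmonic_convention="n-1"`). The expected
discovery curve is θL·H_n with per-genome increment exactly θL/n (the
cumulative column is the cumulative sum of increments, so the telescoping
identity holds to the bit); the observed curve is the cumulative
deduplicated pan-sequence bases per donor from build provenance.

Cohort clustering is average-linkage hierarchical clustering cut to
`n_groups`. The distance is simple matching (mean absolute disagreement of
presence profiles), not Jaccard: for two populations at presence
frequencies 0.8 vs 0.1, the within-low-frequency Jaccard distance (~0.90)
exceeds the cross-population distance (~0.81) — sparse presence sets barely
intersect — so Jaccard average linkage absorbs low-frequency individuals
into the high-frequency cluster. Simple matching treats shared absence as
informative, which for genotype-like PAV profiles it is; Jaccard remains
available (`metric="jaccard"`). NA entries are imputed to the column
frequency so ambiguous calls cannot drive distances.

## Numerical and operational choices

- Coordinates are 0-based half-open everywhere; interval files are BED.
- Contigs are laid out in one padded global coordinate space for indexing;
  spacer runs of N poison k-mers so no anchor, chain or placement can
  bridge contigs.
- Tie-breaks: correction ties keep the current base; dedupe ties order by
  provenance; chain extraction prefers higher scores, earlier indices.
- Degenerate inputs: empty alignments make divergence undefined (error),
  zero genome median makes NRD undefined (error), an all-identical PAV
  matrix clusters to a single group.
- Default problem sizes in the test suite: unit fixtures use 50–200 kb
  genomes and ≤ 6 individuals; the standard end-to-end fixture uses a 1 Mb
  ancestor, 30 planted deletions (0.5–20 kb), one 1% donor, and 20
  individuals at 10× with segment frequencies from {0.1, 0.5, 0.9}. These
  sizes give every statistic enough events to be binomially stable (≥ 2,000
  divergence sites, ≥ 250 kb planted sequence) while keeping a full run in
  the low minutes on one core.

## Known limitations

Forward strand only; substitution-only divergence and correction; no
repeat or paralog simulation beyond explicitly constructed test cases; the
voting mapper has no mapping-quality model; population frequencies are
independent per segment (no linkage); Ne is an input, never estimated.
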