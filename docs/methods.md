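# Methods

This note documents the models and procedures `ecckit` implements, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical choices a maintainer would want to know about.

## Coordinates and names

All internal coordinates are 0-based half-open. Canonical eccDNA names
(`chrom_start1_end1`) and GFF3 are 1-based inclusive and converted exactly
once, at parse/format time. Chromosome names may themselves contain
underscores; the last two `_`-separated tokens of a name are the
coordinates. Flank fetches near chromosome edges clip silently and return
the actual extent used, because flank statistics near telomeres must not
crash an analysis.

## Junction evidence model

A circular junction appears in a linear alignment as a split read whose two
segments map head-to-tail on one chromosome: the start-clipped segment at the
circle start, the end-clipped segment at the circle end. The breakpoint is
(leftmost segment start, rightmost segment end). Split reads are
deduplicated by (start, end, read sequence), so PCR/optical copies of one
molecule count once. Breakpoints from different reads that disagree by at
most 5 bp are clustered to the majority position per coordinate, ties going
leftmost — a deterministic tie-break. Discordant support is the count of
everted (reverse mate left of forward mate) pairs falling entirely inside
the candidate interval. Tail-to-head split pairs (a deletion signature) and
cross-chromosome segment pairs are ignored, the latter with a counter.

**Circle score.** The score is `Σ seg_len · (1 − 10^(−MAPQ/10))` over
supporting split reads, using per read the shorter of its two matched
segment lengths and the smaller of the two MAPQs (the conservative choice
when segments disagree). The original tool this emulates publishes the
ingredients (alignment quality, split-segment length, number of split
reads) but not the equation; this sum preserves the stated monotonicities —
additive over reads, increasing in segment length and mapping quality — and
is documented as not numerically identical to any external implementation.
Filter thresholds are taken as stated by the source analysis: evidence
(≥ 1 discordant, ≥ 2 split), score strictly > 50, coverage-ratio window
[0.33, 1] on at least one edge, coverage continuity exactly 0.

**Coverage ratio** is defined here (the source does not define it) as the
mean depth of the 50 bp just inside a breakpoint divided by the mean depth
of the whole interval, clipped to [0, 1]. Sharp-edged true circles have
edge depth at or above the interior mean (junction reads pile up at the
edges), so the clip makes the filter a test against depleted edges.

**Consensus.** The two-list intersection keeps a call when some call in the
other list overlaps it with reciprocal overlap strictly greater than 0.9
(both `overlap/len(a)` and `overlap/len(b)`). Whether the original 90%
threshold was reciprocal or one-sided is not stated; reciprocal is the
stricter reading and is what is implemented. Coordinates are taken from the
first list; output is deduplicated and sorted. The step takes any two call
lists — two parameterizations of this caller, or this caller against an
external list — because the bespoke part is the overlap rule, not a second
binary.

**Saturation.** Reads are grouped by name (mates and split segments travel
together) and subsampled without replacement by taking prefixes of one
seeded permutation per replicate, at fractions 5%, 10%, …, 100%. Nested
prefixes give a monotone coupling: within a replicate, a larger fraction
can only add evidence, so the expected curve is non-decreasing and the
100% point equals the full-data call count by construction. Independent
per-fraction draws would make monotonicity of the sampled mean a flaky
property rather than a structural one, which is why nesting was chosen.

## Repeat classification

Junction windows are `[start−100, start+50)` and `[end−50, end+100)` —
nominally 150 bp each, clipped at chromosome edges; circles of length ≤ 50
cannot host non-crossing windows and are labelled `Other` with a warning.
Maximal shared substrings ≥ `min_len` between the windows are direct
repeats; matches against the reverse-complemented right window are inverted
repeats, with offsets mapped back to original window coordinates. The
finder is k-mer-seeded with bidirectional extension and is verified
hit-for-hit against a quadratic dynamic-programming brute force in the test
suite. An optional blastn-short-like mode admits up to `max_end_mismatch`
terminal mismatches per side; it is off by default because only the exact
mode is oracle-verifiable.

`min_len = 7` follows the observation that most junction direct repeats are
7–15 bp. Note the statistical consequence: two random 150 bp windows share
at least one 7-mer with high probability (expected number of collisions
≈ 144² · p⁷ with p = Σ base-frequency² ≈ 0.25, i.e. ≈ 1.2), so the
*background* DR rate of this detector on random sequence is large (~60% at
GC 0.44). The classifier is therefore always read against its random model
rather than as an absolute rate, and planted-repeat recovery is asserted at
the hit level (exact length, orientation, offsets), not the label level.
When both orientations hit, DR takes precedence over IR; both hits are
still reported.

**Random model.** Six datasets of 1000 loci (defaults) are placed uniformly
over the genome with lengths resampled with replacement from the observed
length distribution — an empirical resample, not a parametric fit, matching
how the null is described. Observed-vs-model proportions are compared with
a pooled-variance two-tailed unpaired *t*-test (df = 10 at six-vs-six) and
a two-test Bonferroni adjustment for testing DR and IR.

## Statistics

GC content excludes ambiguity codes from the denominator (windows clipped
at edges or containing Ns would otherwise be biased); an all-ambiguous
window yields NaN with a warning. Hedges' *g* uses
`J = 1 − 3/(4(n₁+n₂) − 9)` at every sample size (J → 1 for large n; one
formula everywhere). Mann–Whitney is exact for min(n₁, n₂) ≤ 20 and
tie-free, otherwise normal-approximated with tie correction (scipy).
The chromosome count-length association is a Pearson correlation with the
two-sided p from the t transform; constant counts raise rather than return
a silent NaN.

## Annotation

Overlap fractions are relative to the eccDNA's own length (a literal
reading of "the eccDNA must overlap the feature by at least 50%");
feature-relative containment is used only for the GcE call. The genic test
runs against the union of gene bodies so nested gene parts cannot
double-count, keeping genic/intergenic a strict partition. `Retroelement`
is defined as LTR ∪ LINE. A circle overlapping two genes at ≥ 50%/each is
counted once in the two-gene class. Enrichment per category is a paired
two-tailed *t*-test across the six matched (observed, random) proportion
pairs (df = 5), with significance stars at 0.05/0.01/0.001/0.0001 and a
degenerate flag when the paired differences have zero variance.

## Microdeletion detection

The fusion sequence for a circle is `genome[start−200:start) +
genome[end:end+200)` — the chromosome after excision. (The source methods
text says the flanks are taken around "target genes", but the surrounding
analysis makes clear they are taken around the eccDNA loci; the latter is
implemented.) The aligner is an exact 15-mer seed index plus ungapped
per-diagonal comparison — sufficient for 400 bp targets and fully
reproducible, where an external aligner's tunables would not be. A read
supports a deletion when it crosses the junction with ≥ `min_side` bases on
each side (20 bp for short/NGS-like reads, 50 bp for long/TGS-like reads)
at ≥ 95% identity.

**Direct-repeat tolerance.** Excision of a DR circle by recombination
between its two repeat copies leaves exactly one copy in the chromosome, so
a true deletion read carries an insertion of up to the repeat length
relative to the naive fusion. The scanner therefore accepts a gap of
0..`dr_tolerance` read bases between the left-part and right-part
alignments, with `dr_tolerance` set to the circle's best direct-repeat
length (0 otherwise). The paired property — the same read is accepted at
tolerance ≥ k and rejected at tolerance 0 — is asserted in the tests.

**Blacklist.** A fusion is excluded when a single ungapped genomic diagonal
(either strand) covers ≥ 90% of the fusion at ≥ 95% identity somewhere
other than its own two flanks of origin: such a junction is
indistinguishable from pre-existing genomic sequence. The 90%/95%
thresholds are this package's choices (the source publishes none);
they are deliberately conservative. The trivial split match of each flank
against its own origin never blacklists by construction.

Multi-sample results are combined by set algebra over fusion identifiers;
every region of the Venn partition is reported.

## Synthetic data: what it emulates, what it does not

The generator emulates the statistical structure the analysis assumes:

- a multi-chromosome genome of i.i.d. bases at a target GC (default 0.44,
  the rice genome-wide value), with chromosome sizes graded from 1× to 2×
  the base length so count-length statistics are well defined, and a
  regular lattice of annotated genes (5'UTR/CDS/intron/CDS/3'UTR), miRNA
  and tRNA features, and LTR/LINE/DNA/RC repeat intervals;
- circles placed uniformly per bp (chromosome choice weighted by length),
  non-overlapping with ≥ 300 bp margins by rejection sampling (100 retries,
  then an error), with a truncated lognormal length law
  (μ = ln 283, σ = 0.514, truncated to [74, 5196] bp) putting ≈ 50% of the
  mass in the 200–400 bp bin;
- a fraction of circles (defaults 4.4% direct, 0.16% inverted — the
  observed study rates) carrying a 7–34 bp junction repeat written at
  `[start, start+k)` and `[end−k, end)`. This inside-both-ends geometry is
  the one under which excision retains exactly one copy *and* the retained
  copy is an insertion relative to the fusion sequence, making the
  DR-tolerance logic testable. The bases adjacent to the planted copies are
  adjusted so the repeat is maximal at exactly k bp — the truth list then
  states the realized repeat length, not a lower bound;
- junction-crossing reads (~Poisson(junction_coverage) per circle) emitted
  as two-segment split alignments, everted pairs (~Poisson(coverage/2),
  floored at 1 so evidence exists whenever junction coverage is requested),
  and tiling body reads giving uniform circle coverage; substitution errors
  at `error_rate`, no indels (the caller's evidence model is
  junction-position based);
- WGS pools (short reads at `read_length`, long reads at 5×) each at
  `wgs_depth` fold, drawn from the per-chromosome excision haplotype with
  probability `deletion_fraction` and the intact chromosome otherwise,
  strand-randomized.

Default `read_length` is 70 bp, below the 74 bp minimum circle length, so
every junction read splits into exactly two segments; real 150 bp reads on
sub-read-length circles wrap multiple times and need multi-segment
alignment, which is out of scope (see Non-goals below). Rolling-circle
amplification is *not* modelled — coverage is uniform per circle — because
circle abundance is explicitly outside the quantitative surface of the
method. Per-circle read counts are assumed Poisson; the source gives no
distribution. Chimeric amplification artifacts, platform error profiles and
organellar genomes are not modelled.

Consequently, passing the recovery tests shows the pipeline's logic is
correct under its own evidence model (exact breakpoints, two-segment
splits, substitution-only noise); it does not demonstrate robustness to
alignment ambiguity in repetitive genomes, indel noise, or amplification
chimeras.

## Problem sizes and determinism

Every generator and every stochastic analysis takes an explicit seed;
subsampling derives child seeds with `numpy.random.SeedSequence`. The
bundled test suite and the acceptance script run on synthetic worlds of
roughly 200 circles over ~1 Mb of genome, with the null model at its full
6 × 1000 size in the acceptance script and reduced (6 × 20–50) inside
statistical-calibration loops; those sizes give stable Monte-Carlo
behaviour while keeping any single test in seconds.

## Known limitations

- Multi-fragment (chimeric) circles, realignment of soft-clipped tails and
  abundance quantification are out of scope.
- The DR/IR label at `min_len = 7` has a high background rate by design and
  is only meaningful relative to the bundled random model.
- The deletion scanner's ungapped model tolerates substitutions but not
  indels inside a flank; a read with an indel within `min_side` of the
  junction will not support.
- `compare_proportions` and `enrichment_vs_random` assume six observed sets
  and six model datasets in their default reading (df quoted accordingly);
  other set counts work but change the df.
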