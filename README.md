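# ecckit

Detection and downstream analysis of **extrachromosomal circular DNA
(eccDNA)** from Circle-seq style sequencing evidence, with a built-in
synthetic-data generator so the whole pipeline is testable end to end without
any external download.

eccDNAs are chromosome-derived circular DNA molecules. In Circle-seq data a
circular junction betrays itself twice in the linear alignment: a **split
read** whose two segments map head-to-tail on one chromosome, and an
**everted (outward-facing) read pair**. `ecckit` turns that evidence into
filtered circle calls, classifies each call by the direct/inverted repeats
shared between its junction flanks, characterises the call set's physical
properties and genomic distribution, and detects the chromosomal
microdeletions that circle excision leaves behind.

## What it computes

- **Junction calling** (`ecckit.junction_caller`). Candidate circles are
  scored additively, `score = Σ seg_len · (1 − 10^(−MAPQ/10))` over
  supporting split reads, and filtered on four criteria: ≥ 1 discordant pair
  and ≥ 2 independent split reads; score > 50; edge/interior coverage ratio
  within [0.33, 1] at the start or end; zero uncovered bases inside the
  interval. Two call lists can be intersected under a strict > 90% reciprocal
  overlap rule, and library complexity is assessed with a 5%-step
  subsampling saturation curve.
- **Repeat classification** (`ecckit.repeat_classifier`). Each junction is
  described by two 150 bp windows (end coordinates extended 100 bp outward,
  contracted 50 bp inward). A shared substring ≥ 7 bp labels the circle
  **DR** (direct repeat) or **IR** (inverted repeat, reverse-complemented
  match), with DR taking precedence; non-randomness is judged against
  6 × 1000 randomly placed loci whose lengths resample the observed length
  distribution, using a pooled two-tailed unpaired *t*-test (df = 10).
- **Physical properties** (`ecckit.feature_stats`). GC content of circles
  and their 150 bp flanks against the genome baseline, 200 bp length bins,
  Hedges' *g* (with the small-sample correction `J = 1 − 3/(4(n₁+n₂) − 9)`),
  exact/asymptotic Mann–Whitney tests, and the per-chromosome
  count-vs-length Pearson correlation.
- **Annotation** (`ecckit.annotate`). A circle belongs to a feature class
  when ≥ 50% of the circle's length overlaps it; genic/intergenic is a
  partition over the union of gene bodies; enrichment against the random
  model uses a paired *t*-test across six matched proportion pairs. Gene
  relations are tallied as GcE (gene fully inside the circle) and EcG
  (circle fully inside a gene).
- **Microdeletions** (`ecckit.microdeletion`). For each circle a 400 bp
  fusion sequence (200 bp upstream of the start + 200 bp downstream of the
  end) represents the excised chromosome. Fusions indistinguishable from
  pre-existing genomic sequence are blacklisted; WGS reads support a
  deletion when they cross the junction with ≥ 20 bp (short reads) or
  ≥ 50 bp (long reads) matched on each side at ≥ 95% identity, allowing a
  retained direct-repeat copy (up to the repeat length) at the junction.
- **Synthetic data** (`ecckit.synthio`). A seeded generator producing a
  multi-chromosome annotated genome, planted circles with a truncated
  lognormal length law (≈ half the mass in 200–400 bp, range 74–5196 bp), a
  tunable fraction of 7–34 bp junction repeats, junction-crossing reads,
  and WGS reads from a mixture of intact and excision alleles — with the
  ground truth returned for recovery tests.

## Worked example

```python
from ecckit import (
    SyntheticConfig, make_genome, plant_circles, simulate_circle_reads,
    call_circles, classify, parse_ecc_name,
)

cfg = SyntheticConfig(seed=1, n_circles=50, dr_fraction=0.3, error_rate=0.0)
genome = make_genome(cfg)
truth, genome = plant_circles(genome, cfg)
reads = simulate_circle_reads(truth, genome, cfg)

calls = call_circles(reads.alignments)
print(len(calls), "calls from", len(truth), "planted circles")

labels = classify([c.record for c in calls], genome)
print(sum(1 for c in labels if c.label == "DR"), "DR-labelled calls")

rec = parse_ecc_name("chr12_20609533_20610693")
print(rec.interval.start, rec.interval.end, rec.length)
```

prints

```
50 calls from 50 planted circles
39 DR-labelled calls
20609532 20610693 1161
```

— all 50 planted circles are recovered with no false calls; 39 of 50 calls
carry a ≥ 7 bp direct repeat between their junction flanks (the planted 30%
plus the substantial background rate of coincidental 7-mers between two
150 bp windows, see `docs/methods.md`); and the canonical 1-based-inclusive
name converts to the internal 0-based half-open interval of length 1161 bp.

The same pipeline is available from a shell via the `ecc` command
(`ecc sim all`, `ecc call`, `ecc consensus`, `ecc saturation`,
`ecc repeats classify`, `ecc stats gc|lengths|chromcorr`, `ecc annotate`,
`ecc microdel scan`).

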