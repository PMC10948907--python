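"""Feature-class assignment, enrichment vs the random null, and gene tallies.

An eccDNA belongs to a feature category when at least half of the eccDNA's own
length overlaps the category's intervals (the fraction is relative to the
eccDNA, not the feature). ``genic`` is judged against the union of gene
bodies, so genic/intergenic is a partition. ``Retroelement`` is the LTR + LINE
super-class. Enrichment of six observed per-tissue proportions against six
random-model proportions uses a paired two-tailed t-test (df = 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import EccRecord, GenomicInterval, Gff3Feature

GENE_PART_CATEGORIES = {
    "five_prime_UTR": "5UTR",
    "CDS": "CDS",
    "intron": "intron",
    "three_prime_UTR": "3UTR",
    "miRNA": "miRNA",
    "tRNA": "tRNA",
}
REPEAT_CATEGORIES = ("LTR", "LINE", "DNA", "RC")
CATEGORIES = (
    "intergenic",
    "genic",
    "5UTR",
    "CDS",
    "intron",
    "3UTR",
    "miRNA",
    "tRNA",
    "LTR",
    "LINE",
    "DNA",
    "RC",
    "Retroelement",
)

MIN_OVERLAP = 0.5


@dataclass(frozen=True)
class AnnotFeature:
    interval: GenomicInterval
    category: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    observed_props: tuple[float, ...]
    random_props: tuple[float, ...]
    t: float
    p_two_sided: float
    direction: str  # enriched | depleted | ns
    stars: str
    degenerate: bool = False


def features_from_annotation(
    gff_features: Iterable[Gff3Feature],
    repeat_intervals: Iterable[tuple[GenomicInterval, str]] = (),
) -> list[AnnotFeature]:
    """Flatten GFF3 gene models + repeat BED classes into AnnotFeatures.

    Gene bodies become 'genic'; recognised parts map onto the fixed category
    vocabulary; each LTR/LINE repeat additionally emits a Retroelement copy.
    """
    out: list[AnnotFeature] = []
    for f in gff_features:
        if f.feature_type == "gene":
            out.append(AnnotFeature(f.interval, "genic", f.gene_id))
        elif f.feature_type in GENE_PART_CATEGORIES:
            out.append(
                AnnotFeature(f.interval, GENE_PART_CATEGORIES[f.feature_type], f.gene_id)
            )
    for iv, cls in repeat_intervals:
        if cls not in REPEAT_CATEGORIES:
            raise ValueError(f"unknown repeat class {cls!r}")
        out.append(AnnotFeature(iv, cls))
        if cls in ("LTR", "LINE"):
            out.append(AnnotFeature(iv, "Retroelement"))
    return out


def _category_trees(features: Iterable[AnnotFeature]) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {}
    for f in features:
        trees.setdefault(f.category, {}).setdefault(f.interval.chrom, IntervalTree()).addi(
            f.interval.start, f.interval.end
        )
    return trees


def _covered_length(tree: IntervalTree | None, iv: GenomicInterval) -> int:
    """Length of iv covered by the union of the tree's intervals."""
    if tree is None:
        return 0
    spans = sorted(
        (max(h.begin, iv.start), min(h.end, iv.end))
        for h in tree.overlap(iv.start, iv.end)
    )
    covered = 0
    cur_lo, cur_hi = None, None
    for lo, hi in spans:
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        covered += cur_hi - cur_lo
    return covered


def assign_regions(
    records: Sequence[EccRecord],
    features: Sequence[AnnotFeature],
    min_overlap: float = MIN_OVERLAP,
) -> list[set[str]]:
    """Category membership per record under the >= min_overlap-of-eccDNA rule.

    A record may belong to several categories; 'intergenic' is exactly the
    complement of 'genic' (judged against the union of gene bodies).
    """
    trees = _category_trees(features)
    memberships: list[set[str]] = []
    for r in records:
        iv = r.interval
        cats: set[str] = set()
        for cat, by_chrom in trees.items():
            covered = _covered_length(by_chrom.get(iv.chrom), iv)
            if covered / iv.length() >= min_overlap:
                cats.add(cat)
        if "genic" not in cats:
            cats.add("intergenic")
        memberships.append(cats)
    return memberships


_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for cut, mark in _STAR_LEVELS:
        if p < cut:
            return mark
    return "ns"


def enrichment_vs_random(
    observed_props_by_category: Mapping[str, Sequence[float]],
    random_props_by_category: Mapping[str, Sequence[float]],
) -> list[EnrichmentResult]:
    """Paired two-tailed t-test per category across matched proportion pairs.

    Expects the same number of observed sets and random datasets (six each in
    the emulated design; df = n - 1 = 5). Direction is the sign of the mean
    paired difference when p < 0.05, 'ns' otherwise.
    """
    out = []
    for cat, obs in observed_props_by_category.items():
        obs = np.asarray(obs, float)
        rand = np.asarray(random_props_by_category[cat], float)
        if obs.shape != rand.shape:
            raise ValueError(f"{cat}: observed and random set counts differ")
        diffs = obs - rand
        if np.allclose(diffs.var(ddof=0), 0.0):
            t = 0.0 if np.allclose(diffs, 0.0) else float("nan")
            p = 1.0 if np.allclose(diffs, 0.0) else float("nan")
            out.append(
                EnrichmentResult(
                    cat, tuple(obs), tuple(rand), t, p, "ns", "ns",
                    degenerate=not np.allclose(diffs, 0.0),
                )
            )
            continue
        t, p = stats.ttest_rel(obs, rand)
        if p < 0.05:
            direction = "enriched" if diffs.mean() > 0 else "depleted"
        else:
            direction = "ns"
        out.append(
            EnrichmentResult(cat, tuple(obs), tuple(rand), float(t), float(p), direction, _stars(p))
        )
    return out


def category_proportions(
    records: Sequence[EccRecord],
    features: Sequence[AnnotFeature],
    categories: Sequence[str] = CATEGORIES,
    min_overlap: float = MIN_OVERLAP,
) -> dict[str, float]:
    """Fraction of records belonging to each category."""
    if not records:
        return {c: float("nan") for c in categories}
    memberships = assign_regions(records, features, min_overlap=min_overlap)
    return {
        c: sum(1 for m in memberships if c in m) / len(records) for c in categories
    }


@dataclass
class GeneEccRelations:
    n_records: int
    n_overlapping: int  # records overlapping >= 1 gene at all
    overlapping_fraction: float
    n_single_gene: int  # overlap exactly one gene
    n_two_gene: int  # straddle two (or more count once here when ==2)
    n_multi_gene: int  # > 2 genes
    gce: int  # gene fully inside the eccDNA
    ecg: int  # eccDNA fully inside a gene
    ecc_per_gene: dict[str, int] = field(default_factory=dict)


def gene_ecc_relations(
    records: Sequence[EccRecord], genes: Sequence[Gff3Feature]
) -> GeneEccRelations:
    """Gene/eccDNA containment and overlap tallies.

    GcE counts eccDNAs that fully contain at least one gene; EcG counts
    eccDNAs fully inside a gene body. An eccDNA straddling two genes is
    counted once in the two-gene class.
    """
    gene_feats = [g for g in genes if g.feature_type == "gene"]
    trees: dict[str, IntervalTree] = {}
    for g in gene_feats:
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g
        )
    n_overlap = single = two = multi = gce = ecg = 0
    per_gene: dict[str, int] = {}
    for r in records:
        iv = r.interval
        tree = trees.get(iv.chrom)
        hits = list(tree.overlap(iv.start, iv.end)) if tree else []
        if not hits:
            continue
        n_overlap += 1
        if len(hits) == 1:
            single += 1
        elif len(hits) == 2:
            two += 1
        else:
            multi += 1
        if any(iv.contains(h.data.interval) for h in hits):
            gce += 1
        if any(h.data.interval.contains(iv) for h in hits):
            ecg += 1
        for h in hits:
            gid = h.data.gene_id or "?"
            per_gene[gid] = per_gene.get(gid, 0) + 1
    return GeneEccRelations(
        n_records=len(records),
        n_overlapping=n_overlap,
        overlapping_fraction=n_overlap / len(records) if records else float("nan"),
        n_single_gene=single,
        n_two_gene=two,
        n_multi_gene=multi,
        gce=gce,
        ecg=ecg,
        ecc_per_gene=per_gene,
    )
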