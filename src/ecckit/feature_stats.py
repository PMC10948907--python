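"""Physical-property statistics of eccDNA call sets.

GC content of circles and their 150 bp flanks against the genome-wide
baseline, length binning, DR-vs-Other group comparisons (Hedges' g effect
size + two-sided Mann-Whitney), and the per-chromosome count-vs-length
Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import EccRecord

logger = logging.getLogger("ecckit")

GC_FLANK = 150
LENGTH_BIN = 200
LENGTH_RANGE = (0, 5400)


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); ambiguity codes excluded from the denominator.

    Returns NaN for sequences with no unambiguous base.
    """
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    atgc = gc + seq.count("A") + seq.count("T")
    if atgc == 0:
        return float("nan")
    return gc / atgc


def gc_profile(
    records: Sequence[EccRecord], genome, flank: int = GC_FLANK
) -> pd.DataFrame:
    """Per-record GC of the circle and of each flank, plus the genome baseline.

    Columns: name, gc_ecc, gc_left_flank, gc_right_flank; the genome-average
    GC is stored in ``df.attrs['genome_gc']``. Flanks are clipped at
    chromosome edges; an all-ambiguous window yields NaN and a log warning.
    """
    seqs = getattr(genome, "sequences", genome)
    rows = []
    for r in records:
        iv = r.interval
        chrom = seqs[iv.chrom]
        ecc = str(chrom[iv.start : iv.end])
        left = str(chrom[max(0, iv.start - flank) : iv.start])
        right = str(chrom[iv.end : iv.end + flank])
        vals = {
            "name": r.name,
            "gc_ecc": gc_content(ecc),
            "gc_left_flank": gc_content(left) if left else float("nan"),
            "gc_right_flank": gc_content(right) if right else float("nan"),
        }
        if any(np.isnan(v) for k, v in vals.items() if k != "name"):
            logger.warning("GC undefined for %s (ambiguous or empty window)", r.name)
        rows.append(vals)
    df = pd.DataFrame(rows, columns=["name", "gc_ecc", "gc_left_flank", "gc_right_flank"])
    total_gc = 0
    total_atgc = 0
    for c in seqs.keys():
        s = str(seqs[c][:]).upper()
        gc = s.count("G") + s.count("C")
        total_gc += gc
        total_atgc += gc + s.count("A") + s.count("T")
    df.attrs["genome_gc"] = total_gc / total_atgc if total_atgc else float("nan")
    return df


def length_histogram(
    records: Sequence[EccRecord],
    bin_width: int = LENGTH_BIN,
    length_range: tuple[int, int] = LENGTH_RANGE,
) -> pd.DataFrame:
    """Binned length proportions (left-closed right-open bins; sum to 1)."""
    if not records:
        logger.warning("length_histogram called on an empty record set")
        return pd.DataFrame(columns=["bin_start", "bin_end", "count", "proportion"])
    lengths = np.array([r.length for r in records])
    edges = np.arange(length_range[0], length_range[1] + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": counts,
            "proportion": counts / len(lengths),
        }
    )


def hedges_g(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Standardized mean difference with small-sample correction.

    g = J * (mean1 - mean2) / s_pooled, where s_pooled is the pooled standard
    deviation over df = n1 + n2 - 2 and J = 1 - 3 / (4(n1+n2) - 9). The sign
    follows group1 - group2.
    """
    x = np.asarray(group1, float)
    y = np.asarray(group2, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("hedges_g requires n >= 2 per group")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if pooled_var == 0:
        if x.mean() == y.mean():
            return 0.0
        raise ValueError("undefined effect size: zero pooled variance")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(j * (x.mean() - y.mean()) / np.sqrt(pooled_var))


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    n1: int
    n2: int
    median1: float
    median2: float
    range1: tuple[float, float]
    range2: tuple[float, float]
    hedges_g: float
    mannwhitney_u: float
    p_two_sided: float


def group_compare(
    values_by_label: Mapping[str, Mapping[str, Sequence[float]]]
) -> list[GroupComparison]:
    """DR-vs-Other style comparison per metric.

    ``values_by_label[label][metric]`` holds the samples; exactly two labels
    are expected (order taken from the mapping; the sign of g is label1 -
    label2). Mann-Whitney is exact when min(n1, n2) <= 20 and tie-free,
    normal-approximated with tie correction otherwise.
    """
    labels = list(values_by_label)
    if len(labels) != 2:
        raise ValueError("group_compare expects exactly two labels")
    g1, g2 = values_by_label[labels[0]], values_by_label[labels[1]]
    out = []
    for metric in g1:
        x = np.asarray(g1[metric], float)
        y = np.asarray(g2[metric], float)
        method = "exact" if min(len(x), len(y)) <= 20 else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        out.append(
            GroupComparison(
                metric=metric,
                n1=len(x),
                n2=len(y),
                median1=float(np.median(x)),
                median2=float(np.median(y)),
                range1=(float(x.min()), float(x.max())),
                range2=(float(y.min()), float(y.max())),
                hedges_g=hedges_g(x, y),
                mannwhitney_u=float(res.statistic),
                p_two_sided=float(res.pvalue),
            )
        )
    return out


def chrom_count_correlation(
    records: Iterable[EccRecord], chrom_lengths: Mapping[str, int]
) -> tuple[float, float]:
    """Pearson correlation of per-chromosome call counts vs chromosome length.

    Chromosomes with zero calls count as zero. Returns (R, two-sided p from
    the t transform). Raises on < 3 chromosomes or constant counts.
    """
    chroms = sorted(chrom_lengths)
    if len(chroms) < 3:
        raise ValueError("need >= 3 chromosomes for a correlation")
    counts = {c: 0 for c in chroms}
    for r in records:
        if r.interval.chrom in counts:
            counts[r.interval.chrom] += 1
    x = np.array([chrom_lengths[c] for c in chroms], float)
    y = np.array([counts[c] for c in chroms], float)
    if np.all(y == y[0]) or np.all(x == x[0]):
        raise ValueError("constant counts or lengths: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
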