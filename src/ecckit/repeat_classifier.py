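"""Junction-flank repeat classification (DR / IR / Other) and the random null.

Each eccDNA junction is described by two 150 bp windows: the end coordinates
extended 100 bp outward and contracted 50 bp inward. A shared substring of at
least ``min_len`` bases between the two windows in the same orientation is a
direct repeat (DR); a shared substring whose right-window copy is the reverse
complement is an inverted repeat (IR). Non-randomness of the observed DR/IR
rates is judged against a model of randomly placed loci whose lengths resample
the observed length distribution (6 datasets x 1000 sequences by default),
via a pooled-variance two-tailed unpaired t-test (df = 10 at the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import (
    EccRecord,
    GenomicInterval,
    format_ecc_name,
    revcomp,
)

OUT_BP = 100  # extension outward from each end coordinate
IN_BP = 50  # contraction inward from each end coordinate
MIN_REPEAT_LEN = 7


class WindowGeometryError(Exception):
    """The eccDNA is too short for non-overlapping junction windows."""


@dataclass(frozen=True)
class RepeatHit:
    """A maximal repeat shared by the two junction-flank windows."""

    length: int
    left_offset: int
    right_offset: int
    orientation: str  # direct | inverted
    n_mismatches: int = 0
    best: bool = False


@dataclass(frozen=True)
class Classification:
    record: EccRecord
    label: str  # DR | IR | Other
    best_hit: RepeatHit | None
    warning: str = ""


@dataclass
class RandomModelSet:
    """Random-locus datasets with their per-dataset DR/IR proportions."""

    n_datasets: int
    per_dataset: int
    intervals: list[list[GenomicInterval]]
    dr_proportions: np.ndarray
    ir_proportions: np.ndarray


@dataclass(frozen=True)
class ProportionTest:
    orientation: str
    t: float
    p: float
    p_adjusted: float
    df: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def junction_windows(
    record: EccRecord,
    genome,
    out_bp: int = OUT_BP,
    in_bp: int = IN_BP,
) -> tuple[str, str]:
    """The two junction-flank sequences.

    Left window = [start-out_bp, start+in_bp), right window =
    [end-in_bp, end+out_bp), each nominally out_bp+in_bp long, clipped at
    chromosome edges. ``genome`` is anything with chromosome-keyed string
    access (pyfaidx.Fasta or SyntheticGenome.sequences-style mapping).
    """
    iv = record.interval
    if iv.length() <= in_bp:
        raise WindowGeometryError(
            f"{record.name}: length {iv.length()} <= inward contraction {in_bp}; "
            "junction windows would cross"
        )
    seqs = getattr(genome, "sequences", genome)
    chrom_seq = seqs[iv.chrom]
    left = str(chrom_seq[max(0, iv.start - out_bp) : iv.start + in_bp])
    right = str(chrom_seq[max(0, iv.end - in_bp) : iv.end + out_bp])
    return left.upper(), right.upper()


# ---------------------------------------------------------------------------
# Repeat finding
# ---------------------------------------------------------------------------


def _maximal_matches(left: str, right: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal exact shared substrings >= min_len as (i, j, length).

    Seeded by a k-mer index of the left window (k = min_len) and extended to
    maximality; a seed interior to a longer match is absorbed by it.
    """
    n, m = len(left), len(right)
    if n < min_len or m < min_len:
        return []
    index: dict[str, list[int]] = {}
    for i in range(n - min_len + 1):
        index.setdefault(left[i : i + min_len], []).append(i)
    out: set[tuple[int, int, int]] = set()
    for j in range(m - min_len + 1):
        kmer = right[j : j + min_len]
        for i in index.get(kmer, ()):
            # extend left
            a, b = i, j
            while a > 0 and b > 0 and left[a - 1] == right[b - 1]:
                a -= 1
                b -= 1
            # extend right
            length = min_len + (i - a)
            while a + length < n and b + length < m and left[a + length] == right[b + length]:
                length += 1
            out.add((a, b, length))
    return sorted(out)


def find_repeats(
    left: str,
    right: str,
    min_len: int = MIN_REPEAT_LEN,
    max_end_mismatch: int = 0,
) -> list[RepeatHit]:
    """Maximal direct and inverted repeats between the two windows.

    Direct: shared substring of left and right as-is. Inverted: shared
    substring of left and reverse-complemented right, with the right offset
    reported in original right-window coordinates. With max_end_mismatch > 0
    each hit is additionally extended by up to that many terminal positions per
    side regardless of matching (a blastn-short-like allowance; off by
    default). The longest hit per orientation carries best=True.
    """
    if not left or not right:
        raise ValueError("both windows must be non-empty")
    hits: list[RepeatHit] = []
    for i, j, length in _maximal_matches(left, right, min_len):
        hits.append(_extend_hit(left, right, i, j, length, "direct", max_end_mismatch))
    rc = revcomp(right)
    for i, j, length in _maximal_matches(left, rc, min_len):
        h = _extend_hit(left, rc, i, j, length, "inverted", max_end_mismatch)
        # map the rc coordinate back onto the original right window
        hits.append(
            RepeatHit(
                length=h.length,
                left_offset=h.left_offset,
                right_offset=len(right) - (h.right_offset + h.length),
                orientation="inverted",
                n_mismatches=h.n_mismatches,
            )
        )
    out: list[RepeatHit] = []
    for orientation in ("direct", "inverted"):
        group = [h for h in hits if h.orientation == orientation]
        if not group:
            continue
        best_len = max(h.length for h in group)
        flagged = False
        for h in sorted(group, key=lambda h: (h.left_offset, h.right_offset)):
            if not flagged and h.length == best_len:
                h = RepeatHit(h.length, h.left_offset, h.right_offset, h.orientation, h.n_mismatches, best=True)
                flagged = True
            out.append(h)
    return out


def _extend_hit(
    left: str, right: str, i: int, j: int, length: int, orientation: str, max_end_mismatch: int
) -> RepeatHit:
    mismatches = 0
    if max_end_mismatch > 0:
        lo = min(max_end_mismatch, i, j)
        hi = min(max_end_mismatch, len(left) - (i + length), len(right) - (j + length))
        mismatches = lo + hi
        i -= lo
        j -= lo
        length += lo + hi
    return RepeatHit(length, i, j, orientation, n_mismatches=mismatches)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify(
    records: Iterable[EccRecord],
    genome,
    min_len: int = MIN_REPEAT_LEN,
    max_end_mismatch: int = 0,
) -> list[Classification]:
    """Label each record DR, IR or Other (precedence DR > IR) with its best hit.

    Records whose junction windows cannot be formed are labeled Other with a
    warning instead of failing the whole batch.
    """
    out = []
    for rec in records:
        try:
            left, right = junction_windows(rec, genome)
        except WindowGeometryError as exc:
            out.append(Classification(rec, "Other", None, warning=str(exc)))
            continue
        hits = find_repeats(left, right, min_len=min_len, max_end_mismatch=max_end_mismatch)
        direct = [h for h in hits if h.orientation == "direct" and h.best]
        inverted = [h for h in hits if h.orientation == "inverted" and h.best]
        if direct:
            out.append(Classification(rec, "DR", direct[0]))
        elif inverted:
            out.append(Classification(rec, "IR", inverted[0]))
        else:
            out.append(Classification(rec, "Other", None))
    return out


# ---------------------------------------------------------------------------
# Random null model
# ---------------------------------------------------------------------------


def build_random_model(
    genome,
    length_sample: Sequence[int],
    n_datasets: int = 6,
    per_dataset: int = 1000,
    seed: int = 0,
    min_len: int = MIN_REPEAT_LEN,
) -> RandomModelSet:
    """Randomly placed loci with lengths resampled from the observed lengths.

    Each of the n_datasets datasets holds per_dataset loci (6000 sequences at
    the defaults); every locus is classified and the per-dataset DR and IR
    proportions recorded. Deterministic under seed.
    """
    if not len(length_sample):
        raise ValueError("length_sample must be non-empty")
    rng = np.random.default_rng(seed)
    seqs = getattr(genome, "sequences", genome)
    chroms = list(seqs)
    chrom_lengths = {c: len(seqs[c]) for c in chroms}
    lengths = np.asarray(length_sample, dtype=int)

    intervals: list[list[GenomicInterval]] = []
    dr = np.zeros(n_datasets)
    ir = np.zeros(n_datasets)
    for d in range(n_datasets):
        dataset: list[GenomicInterval] = []
        while len(dataset) < per_dataset:
            length = int(lengths[rng.integers(len(lengths))])
            chrom = chroms[int(rng.integers(len(chroms)))]
            hi = chrom_lengths[chrom] - length - OUT_BP
            if hi <= OUT_BP:
                continue
            start = int(rng.integers(OUT_BP, hi))
            dataset.append(GenomicInterval(chrom, start, start + length))
        records = [
            EccRecord(interval=iv, name=format_ecc_name(iv)) for iv in dataset
        ]
        labels = [c.label for c in classify(records, genome, min_len=min_len)]
        dr[d] = labels.count("DR") / per_dataset
        ir[d] = labels.count("IR") / per_dataset
        intervals.append(dataset)
    return RandomModelSet(
        n_datasets=n_datasets,
        per_dataset=per_dataset,
        intervals=intervals,
        dr_proportions=dr,
        ir_proportions=ir,
    )


def compare_proportions(
    observed_dr: Sequence[float],
    observed_ir: Sequence[float],
    model: RandomModelSet,
) -> dict[str, ProportionTest]:
    """Two-tailed unpaired t-tests (pooled variance) of observed vs random
    DR and IR proportions, with a two-test Bonferroni adjustment.

    At the defaults (6 observed tissues vs 6 random datasets) df = 10.
    """
    out = {}
    for orientation, obs, rand in (
        ("direct", np.asarray(observed_dr, float), model.dr_proportions),
        ("inverted", np.asarray(observed_ir, float), model.ir_proportions),
    ):
        df = len(obs) + len(rand) - 2
        pooled = ((len(obs) - 1) * obs.var(ddof=1) + (len(rand) - 1) * rand.var(ddof=1)) / df
        if pooled == 0:
            if obs.mean() == rand.mean():
                out[orientation] = ProportionTest(orientation, 0.0, 1.0, 1.0, df)
            else:
                out[orientation] = ProportionTest(
                    orientation, float("nan"), float("nan"), float("nan"), df, degenerate=True
                )
            continue
        t, p = stats.ttest_ind(obs, rand, equal_var=True)
        out[orientation] = ProportionTest(
            orientation, float(t), float(p), min(1.0, 2.0 * float(p)), df
        )
    return out
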