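"""eccDNA calling from split-read / discordant-pair evidence.

A circular junction shows up in a linear alignment as (a) a split read whose
two segments map head-to-tail on one chromosome — the segment clipped at its
start maps at the circle start, the segment clipped at its end maps at the
circle end — and (b) everted ("outward-facing") read pairs whose reverse mate
lies left of its forward mate. Candidate circles are scored additively
(segment length x alignment-correctness probability per split read) and pushed
through four filters: evidence counts, Circle score > 50, an edge/interior
coverage-ratio window, and zero coverage gaps across the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    EccRecord,
    GenomicInterval,
    MinimalAlignment,
    format_ecc_name,
)

# breakpoints from different split reads that disagree by at most this many bp
# are clustered into one candidate
BREAKPOINT_SLOP = 5

EDGE_WINDOW = 50  # bp just inside each breakpoint for the coverage ratio


@dataclass(frozen=True)
class SplitEvidence:
    """Split/discordant support for one candidate circle locus."""

    circle_locus: GenomicInterval
    n_split: int
    n_discordant: int
    split_segments: tuple[tuple[int, int], ...]  # (segment length, MAPQ)

    def __post_init__(self) -> None:
        if self.n_split != len(self.split_segments):
            raise ValueError("n_split must equal len(split_segments)")


@dataclass(frozen=True)
class CircleCall:
    record: EccRecord
    score: float
    coverage_ratio_start: float
    coverage_ratio_end: float
    coverage_continuity: float
    evidence: SplitEvidence


class OrderingError(Exception):
    pass


# ---------------------------------------------------------------------------
# Evidence collection
# ---------------------------------------------------------------------------


def _split_clip_sides(aln: MinimalAlignment) -> tuple[int, int]:
    """(left clip, right clip) soft/hard-clipped lengths of an alignment."""
    ops = aln.cigar_ops()
    left = ops[0][1] if ops and ops[0][0] in "SH" else 0
    right = ops[-1][1] if ops and ops[-1][0] in "SH" else 0
    return left, right


def collect_evidence(
    alignments: Sequence[MinimalAlignment],
) -> tuple[list[SplitEvidence], dict[str, int]]:
    """Group alignments into per-locus circle evidence.

    Split reads: the record pair (same qname, same chromosome) where one
    segment is end-clipped (maps at the circle end) and the other start-clipped
    (maps at the circle start), in head-to-tail order (start-clipped segment
    leftmost). Breakpoint = (leftmost segment start, rightmost segment end).
    Independent split reads are deduplicated by (start, end, read sequence);
    nearby breakpoints (<= BREAKPOINT_SLOP bp) are clustered to the majority
    position (ties -> leftmost). Discordant support: everted pairs fully inside
    the locus. Returns (evidence list, counters).

    Input must be grouped by read name (as emitted by a name-sorted SAM);
    an interleaved qname raises OrderingError.
    """
    counters = {"cross_chromosome_pairs": 0, "split_reads": 0, "discordant_pairs": 0}

    by_name: dict[str, list[MinimalAlignment]] = {}
    seen_order: list[str] = []
    last = None
    seen = set()
    for a in alignments:
        if a.qname != last:
            if a.qname in seen:
                raise OrderingError(
                    f"alignments not grouped by read name (qname {a.qname!r} recurs)"
                )
            seen.add(a.qname)
            seen_order.append(a.qname)
            last = a.qname
        by_name.setdefault(a.qname, []).append(a)

    raw_splits: list[tuple[str, int, int, str, int, int]] = []
    everted: list[tuple[str, int, int]] = []  # (chrom, rev start, fwd end)

    for qname in seen_order:
        group = by_name[qname]
        primary = [g for g in group if not g.is_supplementary]
        supp = [g for g in group if g.is_supplementary]
        # split reads: primary + supplementary segment
        if supp:
            for p in primary or supp[:1]:
                for s in supp:
                    if s is p:
                        continue
                    if s.chrom != p.chrom:
                        counters["cross_chromosome_pairs"] += 1
                        continue
                    pl, pr = _split_clip_sides(p)
                    sl, sr = _split_clip_sides(s)
                    # head-to-tail: start-clipped segment at the circle start,
                    # end-clipped segment at the circle end
                    if pr > 0 and sl > 0:
                        end_seg, start_seg = p, s
                    elif pl > 0 and sr > 0:
                        end_seg, start_seg = s, p
                    else:
                        continue
                    if start_seg.pos > end_seg.pos:
                        continue  # tail-to-head (a deletion), not circular
                    bp_start = start_seg.pos
                    bp_end = end_seg.reference_end
                    seg_len = min(p.matched_length, s.matched_length)
                    mapq = min(p.mapq, s.mapq)
                    raw_splits.append(
                        (p.chrom, bp_start, bp_end, p.seq, seg_len, mapq)
                    )
        # everted pairs
        if len(primary) == 2 and all(g.is_paired for g in primary):
            r1, r2 = primary
            if r1.chrom != r2.chrom:
                counters["cross_chromosome_pairs"] += 1
            elif r1.is_reverse != r2.is_reverse:
                fwd = r1 if not r1.is_reverse else r2
                rev = r2 if fwd is r1 else r1
                if rev.pos <= fwd.pos:  # outward-facing
                    everted.append((fwd.chrom, rev.pos, fwd.reference_end))

    # dedup split reads by (start, end, sequence)
    uniq: dict[tuple, tuple] = {}
    for chrom, s, e, seq, seg_len, mapq in raw_splits:
        uniq.setdefault((chrom, s, e, seq), (chrom, s, e, seg_len, mapq))
    counters["split_reads"] = len(uniq)
    counters["discordant_pairs"] = len(everted)

    # cluster breakpoints within slop: majority position, ties -> leftmost
    by_chrom: dict[str, list[tuple]] = {}
    for v in uniq.values():
        by_chrom.setdefault(v[0], []).append(v)

    evidence: list[SplitEvidence] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda v: (v[1], v[2]))
        clusters: list[list[tuple]] = []
        for item in items:
            placed = False
            for cl in clusters:
                if (
                    abs(item[1] - cl[0][1]) <= BREAKPOINT_SLOP
                    and abs(item[2] - cl[0][2]) <= BREAKPOINT_SLOP
                ):
                    cl.append(item)
                    placed = True
                    break
            if not placed:
                clusters.append([item])
        for cl in clusters:
            start = _majority_leftmost([v[1] for v in cl])
            end = _majority_leftmost([v[2] for v in cl])
            locus = GenomicInterval(chrom, start, end)
            n_disc = sum(
                1 for c, rs, fe in everted if c == chrom and rs >= start and fe <= end
            )
            segs = tuple((v[3], v[4]) for v in cl)
            evidence.append(
                SplitEvidence(
                    circle_locus=locus,
                    n_split=len(cl),
                    n_discordant=n_disc,
                    split_segments=segs,
                )
            )
    return evidence, counters


def _majority_leftmost(positions: list[int]) -> int:
    vals, counts = np.unique(positions, return_counts=True)
    return int(vals[counts == counts.max()].min())


# ---------------------------------------------------------------------------
# Scoring, coverage, filtering
# ---------------------------------------------------------------------------


def score_circle(evidence: SplitEvidence) -> float:
    """Circle score = sum over split reads of seg_len * (1 - 10^(-MAPQ/10)).

    Additive across reads, monotone in the number of split reads and in
    segment length; MAPQ 0 reads contribute nothing.
    """
    return float(
        sum(seg_len * (1.0 - 10.0 ** (-mapq / 10.0)) for seg_len, mapq in evidence.split_segments)
    )


def _aligned_blocks(aln: MinimalAlignment) -> list[tuple[int, int]]:
    blocks = []
    pos = aln.pos
    for op, n in aln.cigar_ops():
        if op in "M=X":
            blocks.append((pos, pos + n))
            pos += n
        elif op in "DN":
            pos += n
    return blocks


class CoverageIndex:
    """Per-chromosome aligned blocks, sorted by start, for fast local depth."""

    def __init__(self, alignments: Iterable[MinimalAlignment]):
        raw: dict[str, list[tuple[int, int]]] = {}
        self.max_span: dict[str, int] = {}
        for a in alignments:
            for b in _aligned_blocks(a):
                raw.setdefault(a.chrom, []).append(b)
        self.blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, items in raw.items():
            arr = np.array(sorted(items), dtype=np.int64)
            self.blocks[chrom] = (arr[:, 0], arr[:, 1])
            self.max_span[chrom] = int((arr[:, 1] - arr[:, 0]).max())

    def depth(self, locus: GenomicInterval) -> np.ndarray:
        out = np.zeros(locus.length(), dtype=np.int64)
        if locus.chrom not in self.blocks:
            return out
        starts, ends = self.blocks[locus.chrom]
        lo = np.searchsorted(starts, locus.start - self.max_span[locus.chrom])
        hi = np.searchsorted(starts, locus.end)
        for i in range(lo, hi):
            a = max(int(starts[i]), locus.start)
            b = min(int(ends[i]), locus.end)
            if a < b:
                out[a - locus.start : b - locus.start] += 1
        return out


def coverage_profile(
    alignments: Iterable[MinimalAlignment] | CoverageIndex, locus: GenomicInterval
) -> np.ndarray:
    """Per-base read depth over the locus from aligned (M/=/X) blocks."""
    index = (
        alignments
        if isinstance(alignments, CoverageIndex)
        else CoverageIndex(alignments)
    )
    return index.depth(locus)


def make_call(
    evidence: SplitEvidence,
    alignments: Sequence[MinimalAlignment] | CoverageIndex,
    tissue: str = "",
) -> CircleCall:
    """Attach score and coverage diagnostics to one evidence locus.

    Coverage ratio = mean depth of the EDGE_WINDOW bp just inside the
    breakpoint / mean depth of the whole interval, clipped to [0, 1];
    continuity = fraction of interval bases with zero depth.
    """
    locus = evidence.circle_locus
    depth = coverage_profile(alignments, locus)
    mean_all = float(depth.mean()) if depth.size else 0.0
    w = min(EDGE_WINDOW, depth.size)
    if mean_all > 0:
        ratio_start = min(1.0, float(depth[:w].mean()) / mean_all)
        ratio_end = min(1.0, float(depth[-w:].mean()) / mean_all)
    else:
        ratio_start = ratio_end = 0.0
    continuity = float((depth == 0).mean()) if depth.size else 1.0
    record = EccRecord(
        interval=locus, name=format_ecc_name(locus), tissue=tissue, score=None
    )
    score = score_circle(evidence)
    return CircleCall(
        record=replace(record, score=score),
        score=score,
        coverage_ratio_start=ratio_start,
        coverage_ratio_end=ratio_end,
        coverage_continuity=continuity,
        evidence=evidence,
    )


def filter_calls(calls: Iterable[CircleCall]) -> list[CircleCall]:
    """The four-filter suite; a call passes iff it passes all of:

    1. >=1 discordant pair and >=2 independent split reads;
    2. Circle score strictly greater than 50;
    3. coverage ratio at the start OR the end within [0.33, 1];
    4. coverage continuity exactly 0 (the whole circle is covered).
    """
    passing = []
    for c in calls:
        if c.evidence.n_discordant < 1 or c.evidence.n_split < 2:
            continue
        if not c.score > 50.0:
            continue
        ok_start = 0.33 <= c.coverage_ratio_start <= 1.0
        ok_end = 0.33 <= c.coverage_ratio_end <= 1.0
        if not (ok_start or ok_end):
            continue
        if c.coverage_continuity != 0.0:
            continue
        passing.append(c)
    return passing


def call_circles(
    alignments: Sequence[MinimalAlignment], tissue: str = ""
) -> list[CircleCall]:
    """Full caller: evidence -> diagnostics -> four filters."""
    evidence, _ = collect_evidence(alignments)
    index = CoverageIndex(alignments)
    calls = [make_call(ev, index, tissue=tissue) for ev in evidence]
    return filter_calls(calls)


# ---------------------------------------------------------------------------
# Two-list consensus and saturation
# ---------------------------------------------------------------------------


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when on different chromosomes."""
    ov = a.overlap_length(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length(), ov / b.length())


def consensus_intersect(
    list_a: Sequence[EccRecord], list_b: Sequence[EccRecord], min_overlap: float = 0.9
) -> list[EccRecord]:
    """Keep records of list_a reciprocally overlapping some record of list_b
    by strictly more than min_overlap; output deduplicated and sorted."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for r in list_b:
        trees.setdefault(r.interval.chrom, IntervalTree()).addi(
            r.interval.start, r.interval.end, r
        )
    kept: dict[tuple, EccRecord] = {}
    for r in list_a:
        tree = trees.get(r.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(r.interval.start, r.interval.end):
            if reciprocal_overlap(r.interval, hit.data.interval) > min_overlap:
                kept[(r.interval.chrom, r.interval.start, r.interval.end)] = r
                break
    return sorted(kept.values(), key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))


def saturation_curve(
    alignments: Sequence[MinimalAlignment],
    fractions: Sequence[float] | None = None,
    seed: int = 0,
    n_seeds: int = 1,
) -> list[tuple[float, float]]:
    """Unique passing calls at incremental read subsamples.

    Reads (grouped by qname so mates/segments travel together) are subsampled
    without replacement by taking prefixes of one seeded permutation per
    replicate — nested subsamples, so within a replicate the call count can
    only grow with the fraction. Returns [(fraction, mean call count)].
    """
    if fractions is None:
        fractions = [round(0.05 * i, 2) for i in range(1, 21)]
    fr = list(fractions)
    if any(not (0.0 < f <= 1.0) for f in fr) or any(
        b <= a for a, b in zip(fr, fr[1:])
    ):
        raise ValueError("fractions must be strictly increasing in (0, 1]")

    qnames: list[str] = []
    seen = set()
    by_name: dict[str, list[MinimalAlignment]] = {}
    for a in alignments:
        if a.qname not in seen:
            seen.add(a.qname)
            qnames.append(a.qname)
        by_name.setdefault(a.qname, []).append(a)

    counts = np.zeros(len(fr), dtype=float)
    for rep in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        perm = rng.permutation(len(qnames))
        for i, f in enumerate(fr):
            take = int(np.ceil(f * len(qnames)))
            chosen = [qnames[j] for j in sorted(perm[:take])]
            sub = [a for q in chosen for a in by_name[q]]
            counts[i] += len(call_circles(sub))
    counts /= max(1, n_seeds)
    return list(zip(fr, counts.tolist()))
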