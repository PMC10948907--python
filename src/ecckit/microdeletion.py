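"""eccDNA-induced chromosomal microdeletion detection from WGS reads.

For each eccDNA locus a 400 bp fusion sequence is built: the 200 bp
immediately upstream of the circle start concatenated with the 200 bp
immediately downstream of the circle end — the sequence a chromosome shows
after the circle has been excised. Reads are scanned for junction-crossing
alignments (exact 15-mer seeds + per-side ungapped identity), a genomic
blacklist removes fusions indistinguishable from pre-existing genomic
sequence, and per-sample support sets are intersected Venn-style.

Direct-repeat excision retains one repeat copy at the chromosomal junction,
so a true deletion read carries an insertion of up to the repeat length
relative to the naive fusion; the per-fusion ``dr_tolerance`` window admits
exactly that slack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import EccRecord, revcomp

SEED_K = 15
MIN_SIDE_NGS = 20
MIN_SIDE_TGS = 50
MIN_IDENTITY = 0.95
BLACKLIST_MIN_COVER = 0.90
BLACKLIST_MIN_IDENTITY = 0.95


@dataclass
class FusionSeq:
    """The deletion-junction sequence for one eccDNA."""

    source: EccRecord
    sequence: str
    junction_offset: int  # length of the left (upstream) part
    dr_tolerance: int = 0  # best direct-repeat length; 0 when none
    blacklisted: bool = False
    blacklist_reason: str = ""
    left_span: tuple[int, int] = (0, 0)  # genomic [lo, start) actually used
    right_span: tuple[int, int] = (0, 0)  # genomic [end, hi) actually used
    circle_head: str = ""  # first bases of the circle, for intact-read probing


@dataclass(frozen=True)
class SupportingRead:
    read_id: str
    left_matched: int
    right_matched: int
    identity: float


@dataclass
class DeletionSupport:
    fusion: FusionSeq
    supporting_reads: list[SupportingRead] = field(default_factory=list)
    n_intact_reads: int = 0

    @property
    def n_supporting(self) -> int:
        return len(self.supporting_reads)


# ---------------------------------------------------------------------------
# Fusion construction
# ---------------------------------------------------------------------------


def build_fusions(
    records: Sequence[EccRecord],
    genome,
    flank: int = 200,
    dr_lengths: Mapping[str, int] | None = None,
) -> list[FusionSeq]:
    """left [start-flank, start) + right [end, end+flank) per record.

    ``dr_lengths`` maps record name -> best direct-repeat length (from the
    repeat classifier); matching records get that as dr_tolerance. Flanks are
    clipped at chromosome edges; a record with a fully missing flank is
    skipped.
    """
    seqs = getattr(genome, "sequences", genome)
    fusions = []
    for r in records:
        iv = r.interval
        chrom = seqs[iv.chrom]
        chrom_len = len(chrom)
        lo = max(0, iv.start - flank)
        hi = min(chrom_len, iv.end + flank)
        left = str(chrom[lo : iv.start]).upper()
        right = str(chrom[iv.end : hi]).upper()
        if not left or not right:
            continue
        tol = int(dr_lengths.get(r.name, 0)) if dr_lengths else 0
        fusions.append(
            FusionSeq(
                source=r,
                sequence=left + right,
                junction_offset=len(left),
                dr_tolerance=tol,
                left_span=(lo, iv.start),
                right_span=(iv.end, hi),
                circle_head=str(chrom[iv.start : min(iv.start + flank, iv.end)]).upper(),
            )
        )
    return fusions


# ---------------------------------------------------------------------------
# Seed index + ungapped extension
# ---------------------------------------------------------------------------


class _SeedIndex:
    """Exact k-mer index of a sequence collection (forward strand only)."""

    def __init__(self, sequences: Mapping[str, str], k: int = SEED_K):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in sequences.items():
            seq = str(seq).upper()
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((name, i))

    def diagonals(self, query: str) -> dict[tuple[str, int], list[int]]:
        """{(target, diagonal = target_pos - query_pos): [query seed starts]}"""
        out: dict[tuple[str, int], list[int]] = {}
        q = query.upper()
        for i in range(0, len(q) - self.k + 1):
            for name, j in self.index.get(q[i : i + self.k], ()):
                out.setdefault((name, j - i), []).append(i)
        return out


def _ungapped_stats(query: str, target: str, diag: int) -> tuple[int, int, int]:
    """(overlap start in target, overlap length, matches) for one diagonal."""
    t_lo = max(0, diag)
    t_hi = min(len(target), len(query) + diag)
    if t_hi <= t_lo:
        return 0, 0, 0
    matches = sum(
        1 for t in range(t_lo, t_hi) if target[t] == query[t - diag]
    )
    return t_lo, t_hi - t_lo, matches


def blacklist_fusions(fusions: Sequence[FusionSeq], genome) -> list[FusionSeq]:
    """Flag fusions indistinguishable from existing genomic sequence.

    A fusion is blacklisted iff some single contiguous genomic stretch (one
    ungapped diagonal, either strand) covers >= 90% of the fusion length at
    >= 95% identity — excluding the trivial split match, i.e. diagonals on the
    source chromosome where each half matches only its own flank of origin.
    Mutates the blacklisted flags in place and returns the fusions.
    """
    seqs = getattr(genome, "sequences", genome)
    chrom_seqs = {c: str(seqs[c][:]).upper() for c in seqs.keys()}
    index = _SeedIndex(chrom_seqs)
    for f in fusions:
        f.blacklisted = False
        f.blacklist_reason = ""
        for query, strand in ((f.sequence, "+"), (revcomp(f.sequence), "-")):
            if f.blacklisted:
                break
            for (chrom, diag), _seeds in index.diagonals(query).items():
                t_lo, length, matches = _ungapped_stats(query, chrom_seqs[chrom], diag)
                if length < BLACKLIST_MIN_COVER * len(f.sequence):
                    continue
                if matches / length < BLACKLIST_MIN_IDENTITY:
                    continue
                if _is_trivial_source_match(f, chrom, diag, strand):
                    continue
                f.blacklisted = True
                f.blacklist_reason = (
                    f"{chrom}:{t_lo}({strand}) covers {length}/{len(f.sequence)} bp "
                    f"at {matches / length:.3f} identity"
                )
                break
    return list(fusions)


def _is_trivial_source_match(f: FusionSeq, chrom: str, diag: int, strand: str) -> bool:
    """Is this diagonal the fusion's own left or right flank of origin?

    The left part of the (+ strand) fusion aligns to its source at diagonal
    left_span[0]; the right part at diagonal right_span[0] - junction_offset.
    Those split matches are the expected background, never evidence of a
    duplicated junction — but by construction neither covers >= 90% of the
    fusion unless the circle is shorter than ~10% of it, which the caller's
    length floor excludes.
    """
    if strand != "+" or chrom != f.source.interval.chrom:
        return False
    return diag in (f.left_span[0], f.right_span[0] - f.junction_offset)


# ---------------------------------------------------------------------------
# Read scanning
# ---------------------------------------------------------------------------


def scan_reads(
    reads: Iterable[tuple[str, str]],
    fusions: Sequence[FusionSeq],
    min_side: int = MIN_SIDE_NGS,
    min_identity: float = MIN_IDENTITY,
    k: int = SEED_K,
) -> dict[str, DeletionSupport]:
    """Count junction-crossing read support per (non-blacklisted) fusion.

    A read supports a fusion iff, on one strand, it has an ungapped alignment
    to the left part ending at the junction and one to the right part starting
    at the junction, each with >= min_side aligned bases at >= min_identity
    identity, where the read may carry an insertion of 0..dr_tolerance bases
    between the two parts (the retained direct-repeat copy). Reads crossing
    the same boundary on the intact allele (left part continuing into circle
    sequence rather than the right part) are tallied as n_intact_reads via the
    fusion's stored flank spans. Keys of the result are fusion source names.
    """
    reads = list(reads)
    active = [f for f in fusions if not f.blacklisted]
    halves: dict[str, str] = {}
    for f in active:
        halves[f"{f.source.name}|L"] = f.sequence[: f.junction_offset]
        halves[f"{f.source.name}|R"] = f.sequence[f.junction_offset :]
    index = _SeedIndex(halves, k=k)
    by_name = {f.source.name: f for f in active}
    supports = {f.source.name: DeletionSupport(fusion=f) for f in active}

    for read_id, seq in reads:
        for read in (seq.upper(), revcomp(seq.upper())):
            hits = index.diagonals(read)
            # per fusion: best left-part diagonal (ending at junction) and
            # best right-part diagonal (starting at junction)
            left_best: dict[str, tuple[int, int, int]] = {}
            right_best: dict[str, tuple[int, int, int]] = {}
            for (half_name, diag), _ in hits.items():
                name, side = half_name.rsplit("|", 1)
                f = by_name[name]
                half = halves[half_name]
                t_lo, length, matches = _ungapped_stats(read, half, diag)
                if length < min_side or matches / length < min_identity:
                    continue
                if side == "L":
                    # must reach the junction (right edge of the left half)
                    if t_lo + length == len(half):
                        prev = left_best.get(name)
                        if prev is None or matches > prev[2]:
                            left_best[name] = (diag, length, matches)
                else:
                    if t_lo == 0:
                        prev = right_best.get(name)
                        if prev is None or matches > prev[2]:
                            right_best[name] = (diag, length, matches)
            for name in left_best.keys() & right_best.keys():
                f = by_name[name]
                ld, llen, lm = left_best[name]
                rd, rlen, rm = right_best[name]
                # read position where the left part ends / right part starts
                read_left_end = f.junction_offset - ld
                read_right_start = -rd
                gap = read_right_start - read_left_end
                if 0 <= gap <= f.dr_tolerance:
                    identity = (lm + rm) / (llen + rlen)
                    if identity >= min_identity:
                        supports[name].supporting_reads.append(
                            SupportingRead(read_id, llen, rlen, identity)
                        )
    _count_intact(reads, supports, min_side, min_identity)
    return supports


def _count_intact(
    reads: Iterable[tuple[str, str]],
    supports: dict[str, DeletionSupport],
    min_side: int,
    min_identity: float,
) -> None:
    """Intact-allele reads: cross the circle-start boundary unexcised.

    Counted per fusion as reads that contain the last min_side bases of the
    left flank followed by the circle's own first min_side bases (checked on
    both strands). Exact containment of the probe is sufficient at the scan's
    identity floor.
    """
    probes = {}
    for name, sup in supports.items():
        f = sup.fusion
        left_tail = f.sequence[f.junction_offset - min_side : f.junction_offset]
        circle_head = f.circle_head[:min_side]
        if left_tail and circle_head:
            probes[name] = left_tail + circle_head
    for read_id, seq in reads:
        for read in (seq.upper(), revcomp(seq.upper())):
            for name, probe in probes.items():
                if probe in read:
                    supports[name].n_intact_reads += 1


def intersect_samples(
    supports_by_sample: Mapping[str, Mapping[str, DeletionSupport]],
    min_reads: int = 1,
) -> dict[str, set[str]]:
    """Venn partition of supported fusion names across >= 2 samples.

    A fusion counts as detected in a sample when it has >= min_reads
    supporting reads. Returns {'sample1', 'sample1&sample2', ...} -> names,
    one entry per non-empty region of the Venn partition, plus 'shared' for
    the full intersection.
    """
    if len(supports_by_sample) < 2:
        raise ValueError("need at least two samples")
    detected = {
        sample: {
            name for name, sup in sups.items() if sup.n_supporting >= min_reads
        }
        for sample, sups in supports_by_sample.items()
    }
    samples = sorted(detected)
    out: dict[str, set[str]] = {}
    from itertools import combinations

    for r in range(1, len(samples) + 1):
        for combo in combinations(samples, r):
            inside = set.intersection(*(detected[s] for s in combo))
            outside = set().union(
                *(detected[s] for s in samples if s not in combo)
            ) if len(combo) < len(samples) else set()
            region = inside - outside
            if region or len(combo) == len(samples):
                out["&".join(combo)] = region
    out["shared"] = set.intersection(*(detected[s] for s in samples))
    return out
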