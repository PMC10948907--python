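"""Synthetic Circle-seq / WGS data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a small multi-chromosome genome with gene/repeat annotation, planted
circles whose length law peaks in the 200-400 bp bin with a tail to ~5 kb, an
adjustable fraction of circles carrying a 7-34 bp direct (or inverted) repeat
at the junction, junction-crossing paired-end read evidence, and whole-genome
reads drawn from a mixture of intact and excision alleles.

Direct-repeat geometry: the two repeat copies are written at ``[start,
start+k)`` and ``[end-k, end)`` — one at each end, both inside the circle.
Under this geometry excision by recombination between the copies leaves
exactly one copy in the chromosome, so the deletion allele reads carry a k bp
insertion relative to the 400 bp fusion sequence built from the reported
coordinates; that insertion is what the microdeletion scanner's dr_tolerance
window absorbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io_formats import (
    EccRecord,
    GenomicInterval,
    Gff3Feature,
    MinimalAlignment,
    format_ecc_name,
    revcomp,
)

BASES = np.array(list("ACGT"))


class PlacementError(Exception):
    """Raised when circles cannot be placed without overlap."""


class SizingError(Exception):
    """Raised when the requested genome is too small for its features."""


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_chroms: int = 3
    chrom_length: int = 200_000
    gc_target: float = 0.44
    n_circles: int = 200
    length_log_mu: float = float(np.log(283.0))  # ~50% of mass in [200, 400)
    length_log_sigma: float = 0.514
    length_min: int = 74
    length_max: int = 5196
    dr_fraction: float = 0.044
    ir_fraction: float = 0.0016
    dr_length_range: tuple[int, int] = (7, 34)
    read_length: int = 70  # kept below length_min so junction reads split in two
    insert_size: int = 200
    junction_coverage: float = 20.0
    wgs_depth: float = 10.0
    deletion_fraction: float = 0.5
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_target", "dr_fraction", "ir_fraction", "deletion_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dr_length_range[0] < 4:
            raise ValueError("minimum direct-repeat length must be >= 4 bp")
        if self.dr_length_range[0] > self.dr_length_range[1]:
            raise ValueError("dr_length_range must be (min, max) with min <= max")


@dataclass(frozen=True)
class TruthCircle:
    """Ground truth for one planted circle."""

    interval: GenomicInterval
    repeat_len: int = 0
    repeat_orientation: str = "none"  # direct | inverted | none
    deletion_planted: bool = False

    @property
    def name(self) -> str:
        return format_ecc_name(self.interval)


@dataclass
class SyntheticGenome:
    """In-memory genome: mutable per-chromosome sequences + annotation."""

    sequences: dict[str, str]
    genes: list[Gff3Feature] = field(default_factory=list)
    repeats: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, interval: GenomicInterval, flank: int = 0) -> tuple[str, GenomicInterval]:
        seq = self.sequences[interval.chrom]
        lo = max(0, interval.start - flank)
        hi = min(len(seq), interval.end + flank)
        return seq[lo:hi], GenomicInterval(interval.chrom, lo, hi)

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

_GENE_PART_TYPES = ("five_prime_UTR", "CDS", "intron", "CDS", "three_prime_UTR")
_REPEAT_CLASSES = ("LTR", "LINE", "DNA", "RC")


def make_genome(config: SyntheticConfig) -> SyntheticGenome:
    """Random genome at the target GC with gene and repeat annotation.

    Genes are laid out on a deterministic grid (one gene per ~10 kb) with
    5'UTR/CDS/intron/CDS/3'UTR parts plus interspersed miRNA and tRNA
    features; repeat intervals cycle through LTR/LINE/DNA/RC classes.
    """
    if config.chrom_length < 20_000:
        raise SizingError("chrom_length must be >= 20000 to host annotation")
    rng = np.random.default_rng(config.seed)
    # chromosome sizes graded from chrom_length up to 2x chrom_length, so
    # count-vs-length statistics are well defined on synthetic data
    n = config.n_chroms
    sizes = [
        int(config.chrom_length * (1 + (i / (n - 1) if n > 1 else 0))) for i in range(n)
    ]
    sequences = {
        f"chr{i + 1}": _random_sequence(rng, sizes[i], config.gc_target)
        for i in range(n)
    }
    genome = SyntheticGenome(sequences=sequences)

    part_lengths = {"five_prime_UTR": 200, "CDS": 600, "intron": 400, "three_prime_UTR": 300}
    gene_span = 200 + 600 + 400 + 600 + 300
    gene_idx = repeat_idx = 0
    for chrom in sequences:
        pos = 2_000
        while pos + gene_span + 3_000 < config.chrom_length:
            gene_id = f"gene{gene_idx:04d}"
            strand = "+" if gene_idx % 2 == 0 else "-"
            genome.genes.append(
                Gff3Feature(
                    GenomicInterval(chrom, pos, pos + gene_span, strand),
                    "gene",
                    {"ID": gene_id},
                )
            )
            part_pos = pos
            for part in _GENE_PART_TYPES:
                plen = part_lengths[part]
                genome.genes.append(
                    Gff3Feature(
                        GenomicInterval(chrom, part_pos, part_pos + plen, strand),
                        part,
                        {"Parent": gene_id},
                    )
                )
                part_pos += plen
            # one small RNA feature and one repeat in each intergenic gap
            rna_type = "miRNA" if gene_idx % 2 == 0 else "tRNA"
            rna_start = pos + gene_span + 500
            genome.genes.append(
                Gff3Feature(
                    GenomicInterval(chrom, rna_start, rna_start + 120, strand),
                    rna_type,
                    {"ID": f"{rna_type}{gene_idx:04d}"},
                )
            )
            rep_start = rna_start + 500
            rep_class = _REPEAT_CLASSES[repeat_idx % len(_REPEAT_CLASSES)]
            genome.repeats.append(
                (GenomicInterval(chrom, rep_start, rep_start + 400), rep_class)
            )
            gene_idx += 1
            repeat_idx += 1
            pos += 10_000
    return genome


# ---------------------------------------------------------------------------
# Circle planting
# ---------------------------------------------------------------------------


def sample_circle_lengths(rng: np.random.Generator, n: int, config: SyntheticConfig) -> np.ndarray:
    """Truncated lognormal circle lengths (resampled until inside bounds)."""
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.lognormal(config.length_log_mu, config.length_log_sigma, size=2 * (n - filled) + 8)
        draw = draw[(draw >= config.length_min) & (draw <= config.length_max)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = np.round(draw[:take]).astype(int)
        filled += take
    return out


def plant_circles(
    genome: SyntheticGenome, config: SyntheticConfig, max_retries: int = 100
) -> tuple[list[TruthCircle], SyntheticGenome]:
    """Place non-overlapping circles and write junction repeats into the genome.

    Returns the truth list and the (edited in place) genome. For repeat-bearing
    circles the same k-mer (reverse complement for inverted) is written at both
    circle ends; deletion_planted is drawn per circle at deletion_fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chroms = list(genome.sequences)
    # uniform placement per bp: chromosome choice weighted by length
    weights = np.array([len(genome.sequences[c]) for c in chroms], float)
    weights /= weights.sum()
    lengths = sample_circle_lengths(rng, config.n_circles, config)
    margin = 300
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    truth: list[TruthCircle] = []
    seqs = {c: list(genome.sequences[c]) for c in chroms}

    for i in range(config.n_circles):
        length = int(lengths[i])
        for attempt in range(max_retries + 1):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            hi = len(seqs[chrom]) - length - margin
            if hi <= margin:
                continue
            start = int(rng.integers(margin, hi))
            end = start + length
            if all(end + margin <= s or e + margin <= start for s, e in placed[chrom]):
                break
        else:
            raise PlacementError(
                f"could not place circle {i} (length {length}) after {max_retries} retries"
            )
        placed[chrom].append((start, end))

        u = rng.random()
        if u < config.dr_fraction:
            orientation = "direct"
        elif u < config.dr_fraction + config.ir_fraction:
            orientation = "inverted"
        else:
            orientation = "none"
        repeat_len = 0
        if orientation != "none":
            lo, hi_k = config.dr_length_range
            repeat_len = int(rng.integers(lo, hi_k + 1))
            kmer = _random_sequence(rng, repeat_len, config.gc_target)
            left_copy = kmer
            right_copy = kmer if orientation == "direct" else revcomp(kmer)
            seqs[chrom][start : start + repeat_len] = list(left_copy)
            seqs[chrom][end - repeat_len : end] = list(right_copy)
            _break_extension(seqs[chrom], rng, start, end, repeat_len, orientation)
        deletion = bool(rng.random() < config.deletion_fraction)
        truth.append(
            TruthCircle(
                interval=GenomicInterval(chrom, start, end),
                repeat_len=repeat_len,
                repeat_orientation=orientation,
                deletion_planted=deletion,
            )
        )

    genome.sequences = {c: "".join(seqs[c]) for c in chroms}
    truth.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return truth, genome


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _break_extension(
    seq: list[str], rng: np.random.Generator, start: int, end: int, k: int, orientation: str
) -> None:
    """Make the planted repeat exactly k bp: mutate the bases adjacent to the
    left copy so that a maximal-match search cannot extend past either end.

    For a direct repeat the left-end extension compares genome[start-1] with
    genome[end-k-1] and the right-end extension genome[start+k] with
    genome[end]; for an inverted repeat the partners are the complements of
    genome[end] and genome[end-k-1] respectively.
    """
    if orientation == "direct":
        partners = {start - 1: seq[end - k - 1], start + k: seq[end]}
    else:
        partners = {start - 1: _COMP[seq[end]], start + k: _COMP[seq[end - k - 1]]}
    for pos, banned in partners.items():
        if seq[pos] == banned:
            options = [b for b in "ACGT" if b != banned]
            seq[pos] = options[int(rng.integers(3))]


def excision_allele(genome: SyntheticGenome, circle: TruthCircle) -> str:
    """Chromosome sequence of the deletion allele for one circle.

    The circle [start, end) is removed; for direct-repeat circles the planted
    geometry (copies at both circle ends) means the flanking sequence already
    realizes the 'single retained copy' junction: the retained copy is
    re-inserted at the junction, exactly as recombination between the two
    internal copies leaves it.
    """
    seq = genome.sequences[circle.interval.chrom]
    retained = ""
    if circle.repeat_orientation == "direct" and circle.repeat_len > 0:
        retained = seq[circle.interval.start : circle.interval.start + circle.repeat_len]
    return seq[: circle.interval.start] + retained + seq[circle.interval.end :]


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


@dataclass
class CircleReadSet:
    """Output of simulate_circle_reads: alignments + FASTQ-able reads."""

    alignments: list[MinimalAlignment]
    reads: list[tuple[str, str]]  # (read id, sequence)

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_circle_reads(
    truth: Iterable[TruthCircle], genome: SyntheticGenome, config: SyntheticConfig
) -> CircleReadSet:
    """Simulate Circle-seq evidence per circle.

    Three read classes per circle: (a) junction-crossing reads, emitted as
    split alignments (two CIGAR-clipped segments joined head-to-tail, SA tags
    cross-referencing); count ~ Poisson(junction_coverage); (b) outward-facing
    (everted) pairs spanning the junction — the discordant evidence, count ~
    Poisson(junction_coverage / 2) with at least the expectation's floor; (c)
    concordant body reads tiling the whole circle so coverage continuity is 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rl = config.read_length
    alignments: list[MinimalAlignment] = []
    reads: list[tuple[str, str]] = []
    min_seg = 20

    for ci, circ in enumerate(sorted(truth, key=lambda t: (t.interval.chrom, t.interval.start))):
        chrom, start, end = circ.interval.chrom, circ.interval.start, circ.interval.end
        if rl >= circ.interval.length():
            raise ValueError("read_length must be shorter than the smallest circle")
        cseq = genome.sequences[chrom][start:end]
        L = len(cseq)

        # (a) junction-crossing -> split reads
        n_junc = int(rng.poisson(config.junction_coverage))
        for j in range(n_junc):
            s = int(rng.integers(min_seg, rl - min_seg + 1))  # bases from circle end
            read = cseq[L - s :] + cseq[: rl - s]
            read = _mutate(rng, read, config.error_rate)
            qname = f"c{ci}_junc{j}"
            reads.append((qname, read))
            sa_b = f"{chrom},{start + 1},+,{s}S{rl - s}M,60,0;"
            sa_a = f"{chrom},{end - s + 1},+,{s}M{rl - s}S,60,0;"
            alignments.append(
                MinimalAlignment(qname, 0, chrom, end - s, 60, f"{s}M{rl - s}S", read, sa=sa_b)
            )
            alignments.append(
                MinimalAlignment(qname, 0x800, chrom, start, 60, f"{s}S{rl - s}M", read, sa=sa_a)
            )

        # (b) everted (outward-facing) discordant pairs across the junction
        n_disc = int(rng.poisson(config.junction_coverage / 2.0))
        if config.junction_coverage > 0:
            n_disc = max(n_disc, 1)
        for j in range(n_disc):
            gap = max(0, config.insert_size - 2 * rl)
            max_left = min((L - rl) // 2, rl + gap)  # keeps the pair everted
            left_off = int(rng.integers(0, max_left + 1)) if max_left > 0 else 0
            # R2 (reverse) near circle start, R1 (forward) near circle end
            r2_start = start + left_off
            r1_end = end - left_off
            r1_start = max(start, r1_end - rl)
            qname = f"c{ci}_disc{j}"
            seq1 = _mutate(rng, genome.sequences[chrom][r1_start : r1_start + rl], config.error_rate)
            seq2 = _mutate(rng, revcomp(genome.sequences[chrom][r2_start : r2_start + rl]), config.error_rate)
            reads.append((qname + "/1", seq1))
            reads.append((qname + "/2", seq2))
            # flags: paired, mate mapped; R1 forward, R2 reverse
            alignments.append(MinimalAlignment(qname, 0x1 | 0x40 | 0x20, chrom, r1_start, 60, f"{rl}M", seq1))
            alignments.append(MinimalAlignment(qname, 0x1 | 0x80 | 0x10, chrom, r2_start, 60, f"{rl}M", seq2))

        # (c) concordant body reads tiling the circle (uniform coverage)
        step = max(1, rl // 2)
        b = 0
        for off in range(0, max(1, L - rl + 1), step):
            qname = f"c{ci}_body{b}"
            seq = _mutate(rng, cseq[off : off + rl], config.error_rate)
            reads.append((qname, seq))
            alignments.append(MinimalAlignment(qname, 0, chrom, start + off, 60, f"{rl}M", seq))
            b += 1
        if L > rl:  # make sure the last bases are covered
            qname = f"c{ci}_body{b}"
            seq = _mutate(rng, cseq[L - rl :], config.error_rate)
            reads.append((qname, seq))
            alignments.append(MinimalAlignment(qname, 0, chrom, end - rl, 60, f"{rl}M", seq))

    return CircleReadSet(alignments=alignments, reads=reads)


@dataclass
class WgsReadSet:
    short_reads: list[tuple[str, str]]
    long_reads: list[tuple[str, str]]

    def write_fasta(self, path, which: str = "both") -> None:
        with open(path, "w") as fh:
            pools = {"short": self.short_reads, "long": self.long_reads}
            selected = pools[which] if which in pools else self.short_reads + self.long_reads
            for rid, seq in selected:
                fh.write(f">{rid}\n{seq}\n")


def simulate_wgs_reads(
    truth: Iterable[TruthCircle], genome: SyntheticGenome, config: SyntheticConfig
) -> WgsReadSet:
    """Whole-genome reads from a mixture of intact and excision alleles.

    Short (NGS-like, read_length) and long (TGS-like, 5x read_length) pools
    are each drawn to wgs_depth fold coverage. Each read's template is the
    per-chromosome excision haplotype (all planted deletions applied) with
    probability deletion_fraction, the intact chromosome otherwise — so reads
    crossing a deletion junction carry the fused flanks plus one retained
    repeat copy for direct-repeat circles. Reads are strand-randomized.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    short_len = config.read_length
    long_len = 5 * config.read_length
    short_reads: list[tuple[str, str]] = []
    long_reads: list[tuple[str, str]] = []

    deletions = [t for t in truth if t.deletion_planted]
    del_by_chrom: dict[str, list[TruthCircle]] = {}
    for t in deletions:
        del_by_chrom.setdefault(t.interval.chrom, []).append(t)

    for chrom, seq in genome.sequences.items():
        # build the per-chromosome excision haplotype once (all planted
        # deletions on it applied left-to-right)
        circles = sorted(del_by_chrom.get(chrom, []), key=lambda t: t.interval.start)
        parts = []
        cursor = 0
        for c in circles:
            parts.append(seq[cursor : c.interval.start])
            if c.repeat_orientation == "direct" and c.repeat_len > 0:
                parts.append(seq[c.interval.start : c.interval.start + c.repeat_len])
            cursor = c.interval.end
        parts.append(seq[cursor:])
        del_seq = "".join(parts)

        for pool, read_len, tag in ((short_reads, short_len, "ngs"), (long_reads, long_len, "tgs")):
            n_reads = int(np.ceil(config.wgs_depth * len(seq) / read_len))
            for i in range(n_reads):
                template = del_seq if (circles and rng.random() < config.deletion_fraction) else seq
                if len(template) <= read_len:
                    continue
                off = int(rng.integers(0, len(template) - read_len))
                read = _mutate(rng, template[off : off + read_len], config.error_rate)
                if rng.random() < 0.5:
                    read = revcomp(read)
                pool.append((f"{tag}_{chrom}_{i}", read))
    return WgsReadSet(short_reads=short_reads, long_reads=long_reads)
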