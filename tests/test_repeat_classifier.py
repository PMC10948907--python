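"""Junction windows, repeat finding vs a DP oracle, and the random null."""

import numpy as np
import pytest

from ecckit.io_formats import parse_ecc_name, revcomp
from ecckit.repeat_classifier import (
    WindowGeometryError,
    build_random_model,
    classify,
    compare_proportions,
    find_repeats,
    junction_windows,
)

BASES = "ACGT"


def random_window(rng, n=150):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# Independent quadratic DP oracle for maximal shared substrings
# ---------------------------------------------------------------------------


def dp_maximal_matches(left, right, min_len):
    """All maximal exact shared substrings >= min_len, by full DP."""
    n, m = len(left), len(right)
    L = np.zeros((n + 1, m + 1), dtype=int)
    eq = np.zeros((n + 1, m + 1), dtype=bool)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if left[i - 1] == right[j - 1]:
                eq[i, j] = True
                L[i, j] = L[i - 1, j - 1] + 1
    hits = set()
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if L[i, j] >= min_len and not (i < n and j < m and eq[i + 1, j + 1]):
                length = L[i, j]
                hits.add((i - length, j - length, int(length)))
    return hits


def oracle_hits(left, right, min_len=7):
    """(orientation, left_offset, right_offset, length) set via the DP oracle."""
    out = set()
    for i, j, length in dp_maximal_matches(left, right, min_len):
        out.add(("direct", i, j, length))
    rc = revcomp(right)
    for i, j, length in dp_maximal_matches(left, rc, min_len):
        out.add(("inverted", i, len(right) - (j + length), length))
    return out


def impl_hits(left, right, min_len=7):
    return {
        (h.orientation, h.left_offset, h.right_offset, h.length)
        for h in find_repeats(left, right, min_len=min_len)
    }


class TestFindRepeats:
    def test_planted_direct_7mer(self):
        rng = np.random.default_rng(0)
        left = random_window(rng)
        right = random_window(rng)
        left = left[:30] + "GCTGCTA" + left[37:]
        right = right[:90] + "GCTGCTA" + right[97:]
        hits = find_repeats(left, right)
        direct = [h for h in hits if h.orientation == "direct"]
        assert any(h.length >= 7 for h in direct)
        assert impl_hits(left, right) == oracle_hits(left, right)

    def test_planted_inverted_10mer(self):
        rng = np.random.default_rng(1)
        left = random_window(rng)
        right = random_window(rng)
        tenmer = "ACCGTTAGCA"
        left = left[:10] + tenmer + left[20:]
        right = right[:100] + revcomp(tenmer) + right[110:]
        hits = [h for h in find_repeats(left, right) if h.orientation == "inverted"]
        assert any(h.length >= 10 for h in hits)

    def test_no_shared_7mer_yields_empty(self):
        # exhaustively verified disjoint k-mer sets: A/C-only vs G/T-only windows
        rng = np.random.default_rng(2)
        left = "".join("AC"[i] for i in rng.integers(0, 2, size=150))
        right = "".join("GT"[i] for i in rng.integers(0, 2, size=150))
        left_kmers = {left[i : i + 7] for i in range(len(left) - 6)}
        right_kmers = {right[i : i + 7] for i in range(len(right) - 6)}
        assert not left_kmers & right_kmers
        # inverted orientation shares k-mers (revcomp maps G/T -> A/C), so
        # restrict the assertion to direct hits
        assert not [h for h in find_repeats(left, right) if h.orientation == "direct"]

    def test_equals_dp_oracle_on_random_windows(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            left, right = random_window(rng), random_window(rng)
            assert impl_hits(left, right) == oracle_hits(left, right)

    def test_strand_symmetry(self):
        """Swapping the windows maps direct hits to direct hits with mirrored
        offsets."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            left, right = random_window(rng), random_window(rng)
            fwd = {
                (h.left_offset, h.right_offset, h.length)
                for h in find_repeats(left, right, min_len=5)
                if h.orientation == "direct"
            }
            rev = {
                (h.right_offset, h.left_offset, h.length)
                for h in find_repeats(right, left, min_len=5)
                if h.orientation == "direct"
            }
            assert fwd == rev

    def test_best_flag_marks_longest(self):
        left = "A" * 20 + "GATTACAGATTACA" + "C" * 20
        right = "T" * 20 + "GATTACAGATTACA" + "G" * 20
        hits = [h for h in find_repeats(left, right) if h.orientation == "direct"]
        best = [h for h in hits if h.best]
        assert len(best) == 1
        assert best[0].length == max(h.length for h in hits)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            find_repeats("", "ACGTACG")


class TestJunctionWindows:
    def test_interior_windows_are_150bp(self, small_genome):
        rec = parse_ecc_name("chr1_1001_1300")  # length 300, interior
        left, right = junction_windows(rec, small_genome)
        assert len(left) == len(right) == 150
        s = small_genome.sequences["chr1"]
        assert left == s[900:1050]
        assert right == s[1250:1400]

    def test_clipped_at_chromosome_start(self, small_genome):
        rec = parse_ecc_name("chr1_31_330")  # starts at 0-based 30
        left, _ = junction_windows(rec, small_genome)
        assert len(left) == 80  # 30 upstream bases + 50 inward

    def test_too_short_rejected(self, small_genome):
        with pytest.raises(WindowGeometryError):
            junction_windows(parse_ecc_name("chr1_1001_1050"), small_genome)


class TestClassify:
    def test_planted_direct_labeled_dr(self, planted_world):
        genome, truth, _ = planted_world
        recs = [parse_ecc_name(t.name) for t in truth]
        results = classify(recs, genome)
        for t, c in zip(truth, results):
            if t.repeat_orientation == "direct":
                assert c.label == "DR"
                assert c.best_hit.length == t.repeat_len

    def test_planted_inverted_found(self, planted_world):
        """Inverted planting is recovered in the hit list; the label is IR
        unless a coincidental direct >=7-mer wins by the DR > IR precedence."""
        genome, truth, _ = planted_world
        for t in truth:
            if t.repeat_orientation != "inverted":
                continue
            left, right = junction_windows(parse_ecc_name(t.name), genome)
            hits = find_repeats(left, right)
            assert any(
                h.orientation == "inverted" and h.length == t.repeat_len for h in hits
            )

    def test_ir_label_when_no_direct_hit(self):
        """On windows sharing only an inverted repeat, the label is IR."""
        left = "".join("AC"[i % 2] for i in range(150))
        tenmer = "ACAACCACCA"
        left = left[:40] + tenmer + left[50:]
        right = "".join("GT"[i % 2] for i in range(100)) + revcomp(tenmer) + "G" * 40
        hits = find_repeats(left, right)
        assert [h.orientation for h in hits if h.best] == ["inverted"]

    def test_short_record_labeled_other_with_warning(self, small_genome):
        (c,) = classify([parse_ecc_name("chr1_1001_1040")], small_genome)
        assert c.label == "Other"
        assert c.warning


class TestRandomModel:
    def test_default_totals_and_determinism(self, small_genome):
        model = build_random_model(
            small_genome, [200, 300, 400], n_datasets=6, per_dataset=50, seed=5
        )
        assert model.n_datasets == 6
        assert sum(len(d) for d in model.intervals) == 300
        again = build_random_model(
            small_genome, [200, 300, 400], n_datasets=6, per_dataset=50, seed=5
        )
        assert np.array_equal(model.dr_proportions, again.dr_proportions)

    def test_per_dataset_one_gives_binary_proportions(self, small_genome):
        model = build_random_model(small_genome, [250], n_datasets=6, per_dataset=1, seed=1)
        assert set(model.dr_proportions) <= {0.0, 1.0}

    def test_lengths_resampled_from_observed(self, small_genome):
        model = build_random_model(small_genome, [333], n_datasets=2, per_dataset=10, seed=2)
        assert all(iv.length() == 333 for d in model.intervals for iv in d)


class TestCompareProportions:
    def test_identical_proportions(self, small_genome):
        model = build_random_model(
            small_genome, [200, 300], n_datasets=6, per_dataset=40, seed=3
        )
        res = compare_proportions(model.dr_proportions, model.ir_proportions, model)
        assert res["direct"].t == pytest.approx(0.0, abs=1e-12) or res["direct"].p == 1.0
        assert res["direct"].df == 10

    def test_textbook_pooled_t(self, small_genome):
        """{1..6} vs {2..7}: t = -1 / (sqrt(3.5) * sqrt(1/3)) by the pooled
        formula."""
        model = build_random_model(small_genome, [200], n_datasets=6, per_dataset=5, seed=4)
        model.dr_proportions = np.array([2.0, 3, 4, 5, 6, 7])
        model.ir_proportions = np.array([2.0, 3, 4, 5, 6, 7])
        res = compare_proportions([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6], model)
        expected_t = -1.0 / (np.sqrt(3.5) * np.sqrt(1 / 6 + 1 / 6))
        assert res["direct"].t == pytest.approx(expected_t, rel=1e-12)
        assert res["direct"].df == 10
        assert res["direct"].p_adjusted == pytest.approx(min(1.0, 2 * res["direct"].p))

    def test_degenerate_variance_flagged(self, small_genome):
        model = build_random_model(small_genome, [200], n_datasets=6, per_dataset=5, seed=4)
        model.dr_proportions = np.zeros(6)
        model.ir_proportions = np.zeros(6)
        res = compare_proportions([0.5] * 6, [0.0] * 6, model)
        assert res["direct"].degenerate
        assert np.isnan(res["direct"].p)
        assert res["inverted"].p == 1.0
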