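"""ORBITA read classification, dedup, valency filtering, subsampling."""

import numpy as np
import pytest

from snfold import synthetic
from snfold.genome import RestrictionMap
from snfold.orbita import (
    AlignmentRecord,
    ContactRecord,
    Rejection,
    classify_read,
    classify_reads,
    contacts_per_fragment_histogram,
    dedupe_contacts,
    filter_fragment_valency,
    subsampling_curve,
    write_pairs,
)


def rec(read_id, *parts):
    return AlignmentRecord(read_id, tuple(parts))


def contact(f1, f2, chrom="c", read_id=""):
    a, b = min(f1, f2), max(f1, f2)
    return ContactRecord(chrom, 0, a, chrom, 0, b, "J", read_id)


class TestClassifyRead:
    def test_true_junction_both_ends_at_cuts(self, toy_rmap):
        out = classify_read(
            rec("r1", ("chr1", 800, 1000, "+", 60), ("chr1", 5000, 5200, "+", 60)),
            toy_rmap,
        )
        assert isinstance(out, ContactRecord)
        assert out.pair_type == "J"
        # ligated ends 1000 and 5000 -> fragments containing 999 and 5000
        assert (out.frag1, out.frag2) == (0, 3)

    def test_template_switch_off_site_end(self, toy_rmap):
        out = classify_read(
            rec("r1", ("chr1", 800, 1000, "+", 60), ("chr1", 4985, 5200, "+", 60)),
            toy_rmap,
        )
        assert isinstance(out, Rejection) and out.reason == "H"

    def test_tolerance_is_strict(self, toy_rmap):
        # distance exactly 10 -> H; distance 9 -> J
        at_10 = rec("a", ("chr1", 800, 1000, "+", 60), ("chr1", 5010, 5200, "+", 60))
        at_9 = rec("b", ("chr1", 800, 1000, "+", 60), ("chr1", 5009, 5200, "+", 60))
        assert classify_read(at_10, toy_rmap).reason == "H"
        assert classify_read(at_9, toy_rmap).pair_type == "J"

    def test_three_parts_discarded(self, toy_rmap):
        out = classify_read(
            rec(
                "r1",
                ("chr1", 800, 1000, "+", 60),
                ("chr1", 2000, 2100, "+", 60),
                ("chr1", 5000, 5100, "+", 60),
            ),
            toy_rmap,
        )
        assert out.reason == "multi-part"

    def test_single_part_is_p(self, toy_rmap):
        assert classify_read(rec("r1", ("chr1", 100, 200, "+", 60)), toy_rmap).reason == "P"

    def test_low_mapq_rejected(self, toy_rmap):
        out = classify_read(
            rec("r1", ("chr1", 800, 1000, "+", 1), ("chr1", 5000, 5200, "+", 60)),
            toy_rmap,
        )
        assert out.reason == "low-mapq"

    def test_minus_strand_ligated_ends(self, toy_rmap):
        # left part '-': ligated (read-3') end at genomic start = 2000;
        # right part '-': ligated (read-5') end at genomic end = 1000
        out = classify_read(
            rec("r1", ("chr1", 2000, 2200, "-", 60), ("chr1", 800, 1000, "-", 60)),
            toy_rmap,
        )
        assert isinstance(out, ContactRecord) and out.pair_type == "J"
        # bodies in fragments 2 ([2000,5000)) and 0 ([0,1000)), canonicalized
        assert (out.frag1, out.frag2) == (0, 2)

    def test_self_fragment_dropped(self, toy_rmap):
        out = classify_read(
            rec("r1", ("chr1", 2000, 2200, "-", 60), ("chr1", 4800, 5000, "-", 60)),
            toy_rmap,
        )
        assert isinstance(out, Rejection) and out.reason == "self-fragment"


class TestDedupe:
    def test_duplicate_pairs_collapse(self):
        cs = [contact(1, 5, read_id="a"), contact(5, 1, read_id="b"), contact(1, 5, read_id="c")]
        out = dedupe_contacts(cs)
        assert len(out) == 1 and out[0].read_id == "a"

    def test_empty(self):
        assert dedupe_contacts([]) == []

    def test_distinct_pair_count(self):
        rng = np.random.default_rng(1)
        cs = [contact(int(a), int(b)) for a, b in rng.integers(0, 3, size=(10, 2)) if a != b]
        expect = len({(min(c.frag1, c.frag2), max(c.frag1, c.frag2)) for c in cs})
        assert len(dedupe_contacts(cs)) == expect


class TestValencyFilter:
    def test_overvalent_fragment_removed_entirely(self):
        cs = [contact(3, x) for x in (0, 1, 2, 4, 5)] + [contact(6, 7)]
        kept, removed = filter_fragment_valency(cs, max_contacts=4)
        assert removed == [("c", 3)]
        assert len(kept) == 1 and kept[0].fragment_pair() == (("c", 6), ("c", 7))

    def test_identity_when_all_within_bound(self):
        cs = [contact(0, 1), contact(2, 3)]
        kept, removed = filter_fragment_valency(cs)
        assert kept == cs and removed == []

    def test_haploid_bound_of_two(self):
        cs = [contact(3, x, chrom="chrX") for x in (0, 1, 2)] + [contact(5, 6, chrom="chrX")]
        kept, removed = filter_fragment_valency(
            cs, max_contacts=4, max_contacts_per_chrom={"chrX": 2}
        )
        assert ("chrX", 3) in removed
        hist = contacts_per_fragment_histogram(kept)
        assert max(hist, default=0) <= 2

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        cs = dedupe_contacts(
            [contact(int(a), int(b)) for a, b in rng.integers(0, 12, size=(60, 2)) if a != b]
        )
        once, _ = filter_fragment_valency(cs)
        twice, removed2 = filter_fragment_valency(once)
        assert twice == once and removed2 == []


class TestHistogram:
    def test_single_contact(self):
        assert contacts_per_fragment_histogram([contact(1, 2)]) == {1: 2}

    def test_empty(self):
        assert contacts_per_fragment_histogram([]) == {}

    def test_sum_rule(self):
        rng = np.random.default_rng(3)
        cs = dedupe_contacts(
            [contact(int(a), int(b)) for a, b in rng.integers(0, 20, size=(50, 2)) if a != b]
        )
        hist = contacts_per_fragment_histogram(cs)
        assert sum(k * v for k, v in hist.items()) == 2 * len(cs)


class TestToleranceSensitivity:
    def test_jittered_junctions_flip_at_zero_tolerance(self, small_genome):
        """J reads with ligated ends jittered 1-9 bp stay J at tol=10 but
        flip to H at tol=0 (every end is then 'off site')."""
        _, _, rmap = small_genome
        edges = rmap.fragment_edges("chrS")
        # pick interior fragments long enough to jitter into
        rng = np.random.default_rng(4)
        reads = []
        for _ in range(50):
            f1, f2 = sorted(rng.choice(rmap.n_fragments("chrS") - 1, 2, replace=False))
            jit = int(rng.integers(1, 10))
            end1 = int(edges[f1 + 1]) - jit  # pulled inside fragment f1
            start2 = int(edges[f2])
            reads.append(
                rec(f"r{f1}-{f2}",
                    ("chrS", max(0, end1 - 60), end1, "+", 60),
                    ("chrS", start2, start2 + 60, "+", 60))
            )
        with_tol, _ = classify_reads(reads, rmap, tolerance=10)
        assert len(with_tol) > 0.8 * len(reads)  # a few may hit self-fragment
        none_tol, rej = classify_reads(reads, rmap, tolerance=0)
        assert none_tol == []
        assert all(r.reason == "H" for r in rej)


class TestSubsamplingCurve:
    def _reads(self, rmap, n_pairs, dup_rate, seed=5):
        rng = np.random.default_rng(seed)
        nf = rmap.n_fragments("chrS")
        pairs = set()
        while len(pairs) < n_pairs:
            a, b = sorted(rng.choice(nf, 2, replace=False))
            pairs.add((int(a), int(b)))
        contacts = [("chrS", a, "chrS", b) for a, b in sorted(pairs)]
        return synthetic.simulate_chimeric_reads(
            contacts, rmap, switch_rate=0.0, dup_rate=dup_rate, seed=seed,
            p_read_rate=0.0,
        )

    def test_duplicate_free_curve_is_linear(self, small_genome):
        _, _, rmap = small_genome
        reads = self._reads(rmap, 200, dup_rate=0.0)
        depths, means = subsampling_curve(
            reads.reads, rmap, depth_step=50, reps=3, seed=1
        )
        # every read contributes a new pair (minus rare self-fragment drops)
        assert means[-1] >= 0.95 * len(reads)
        ratio = means[1:] / np.maximum(depths[1:], 1)
        assert np.all(np.abs(ratio - ratio[-1]) < 0.05 * ratio[-1] + 1e-9)

    def test_fully_duplicated_library_saturates(self, small_genome):
        _, _, rmap = small_genome
        base = self._reads(rmap, 1, dup_rate=0.0)
        one = base.reads[0]
        reads = [one] * 40
        depths, means = subsampling_curve(reads, rmap, depth_step=10, reps=3, seed=2)
        assert means[-1] == 1.0
        assert np.all(means[1:] == 1.0)

    def test_monotone_in_expectation(self, small_genome):
        _, _, rmap = small_genome
        reads = self._reads(rmap, 150, dup_rate=0.5)
        depths, means = subsampling_curve(
            reads.reads, rmap, depth_step=40, reps=8, seed=3
        )
        assert np.all(np.diff(means) >= -1.0)  # sampling noise tolerance

    def test_hypergeometric_expectation(self, small_genome):
        """Mean unique pairs at depth m matches the closed-form expectation
        E = Σ_pairs (1 − C(n−k_p, m)/C(n, m)) for a library with known
        per-pair multiplicities."""
        from scipy.special import comb

        _, _, rmap = small_genome
        base = self._reads(rmap, 30, dup_rate=0.0, seed=7)
        # duplicate every 3rd read twice
        reads = []
        for idx, r in enumerate(base.reads):
            reads.append(r)
            if idx % 3 == 0:
                reads.append(r)
                reads.append(r)
        n = len(reads)
        m = n // 2
        mult = {}
        for r in reads:
            mult[r.read_id] = mult.get(r.read_id, 0) + 1
        expect = sum(
            1 - comb(n - k, m) / comb(n, m) for k in mult.values()
        )
        depths, means = subsampling_curve(reads, rmap, depth_step=m, reps=40, seed=8)
        got = means[list(depths).index(m)]
        assert got == pytest.approx(expect, rel=0.1)


def test_write_pairs_one_based(tmp_path, small_genome):
    _, _, rmap = small_genome
    c = ContactRecord("chrS", 100, 1, "chrS", 500, 5, "J", "r1")
    path = tmp_path / "out.pairs"
    write_pairs([c], path, {"chrS": 60_000})
    lines = path.read_text().splitlines()
    body = [l for l in lines if not l.startswith("#")]
    assert body == ["r1\tchrS\t101\tchrS\t501\t+\t+\tJ"]
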