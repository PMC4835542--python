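"""Exact matching, fragmentation and allocation, checked against naive scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cassetteseq.junctions import JunctionRef, JunctionKey, build_junction_library
from cassetteseq.locus import reverse_complement
from cassetteseq.mapping import (
    HitSet,
    ReadRecord,
    allocate_multimapped,
    count_correlation,
    map_exact,
    match_breakpoint_reads,
    match_junction_reads,
    split_reads,
)


def brute_force_junction_counts(reads, refs, min_overlap):
    """Independent oracle: scan every ref position with str.find."""
    counts = {}
    for read in reads:
        if len(read.sequence) < 2 * min_overlap:
            continue
        matched = set()
        for ri, ref in enumerate(refs):
            for seq in (read.sequence, reverse_complement(read.sequence)):
                pos = ref.sequence.find(seq)
                while pos != -1:
                    if (
                        pos <= ref.breakpoint_offset - min_overlap
                        and pos + len(seq) >= ref.breakpoint_offset + min_overlap
                    ):
                        matched.add(ri)
                    pos = ref.sequence.find(seq, pos + 1)
    # noqa
        for ri in matched:
            counts[ri] = counts.get(ri, 0.0) + 1.0 / len(matched)
    return counts


def brute_force_map(query, targets):
    hits = []
    for tid in sorted(targets):
        seq = targets[tid]
        for probe, strand in (
            (query, "+"),
            (reverse_complement(query), "-"),
        ):
            if probe == query and strand == "-":
                continue
            pos = seq.find(probe)
            while pos != -1:
                hits.append((tid, pos, strand))
                pos = seq.find(probe, pos + 1)
    return tuple(sorted(hits))


def _ref(donor: str, acceptor: str, gene="g") -> JunctionRef:
    key = JunctionKey(gene, donor, acceptor)
    return key


class TestMatchJunctionReads:
    def _one_ref(self, rng, left=115, right=115):
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, size=left + right)])
        key = JunctionKey("g", "e1.1", "e2.1")
        return JunctionRef(key, seq, left, left, right)

    def test_ten_base_overlap_counts_nine_does_not(self):
        rng = np.random.default_rng(0)
        ref = self._one_ref(rng)
        bp = ref.breakpoint_offset
        # read covering exactly 10 bases each side of the breakpoint
        balanced = ReadRecord("r10", ref.sequence[bp - 10 : bp + 10])
        # read with only 9 bases on the acceptor side
        lopsided = ReadRecord("r9", ref.sequence[bp - 100 : bp + 9])
        counts = match_junction_reads([balanced, lopsided], [ref], 10)
        assert counts == {ref.key: 1.0}

    def test_reverse_complement_reads_are_counted(self):
        rng = np.random.default_rng(1)
        ref = self._one_ref(rng)
        bp = ref.breakpoint_offset
        read = ReadRecord(
            "r", reverse_complement(ref.sequence[bp - 60 : bp + 65])
        )
        counts = match_junction_reads([read], [ref], 10)
        assert counts == {ref.key: 1.0}

    def test_non_spanning_read_not_counted(self):
        rng = np.random.default_rng(2)
        ref = self._one_ref(rng)
        read = ReadRecord("r", ref.sequence[:100])  # donor side only
        assert match_junction_reads([read], [ref], 10) == {}

    def test_matches_brute_force_on_simulated_reads(self, sim_small):
        loci, genome = sim_small["loci"], sim_small["genome"]
        reads = sim_small["reads"][:1000]
        refs = []
        for locus in loci:
            refs.extend(build_junction_library(locus, genome, 125, 10))
        expected_idx = brute_force_junction_counts(reads, refs, 10)
        expected = {}
        for ri, c in expected_idx.items():
            expected[refs[ri].key] = expected.get(refs[ri].key, 0.0) + c
        got = match_junction_reads(reads, refs, 10)
        assert set(got) == set(expected)
        for key in expected:
            assert got[key] == pytest.approx(expected[key])


class TestSplitReads:
    def test_125nt_read_tilings(self):
        read = ReadRecord("r", "A" * 125)
        frags25 = split_reads([read], [25])
        assert [f.offset for f in frags25] == [0, 25, 50, 75, 100]
        frags50 = split_reads([read], [50])
        assert [f.offset for f in frags50] == [0, 50]  # 25-nt tail dropped

    @given(st.integers(20, 200), st.sampled_from([25, 50]))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_fragments_are_parent_substrings(self, read_len, flen):
        rng = np.random.default_rng(read_len)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, read_len)])
        read = ReadRecord("r", seq)
        frags = split_reads([read], [flen])
        assert len(frags) == read_len // flen
        for f in frags:
            assert f.sequence == seq[f.offset : f.offset + f.length]


class TestMapExact:
    def test_unique_and_duplicated_targets(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, size=200)])
        targets = {"A": a, "B": a[:100] + "".join(bases[rng.integers(0, 4, 100)])}
        unique_query = a[150:175]
        shared_query = a[10:35]
        (h1, h2) = map_exact(
            [("q1", unique_query), ("q2", shared_query)], targets
        )
        assert h1.multiplicity == 1 and h1.hits[0][0] == "A"
        assert h2.multiplicity == 2 and h2.target_ids == ("A", "B")

    def test_query_with_n_has_no_hits_by_default(self):
        targets = {"A": "ACGTACGTACGT"}
        (h,) = map_exact([("q", "ACGTN")], targets)
        assert h.hits == ()

    def test_matches_brute_force_scan(self, sim_small):
        genome = sim_small["genome"]
        loci = sim_small["loci"]
        targets = {
            f"{l.gene_id}|{e.name}": genome[e.interval.chrom][
                e.interval.start : e.interval.end
            ]
            for l in loci
            for e in l.variable_exons
        }
        rng = np.random.default_rng(4)
        queries = []
        tids = sorted(targets)
        for i in range(300):
            tid = tids[rng.integers(0, len(tids))]
            seq = targets[tid]
            start = rng.integers(0, len(seq) - 25 + 1)
            q = seq[start : start + 25]
            if rng.random() < 0.5:
                q = reverse_complement(q)
            queries.append((f"q{i}", q))
        hitsets = map_exact(queries, targets)
        for (qid, q), hs in zip(queries, hitsets):
            assert hs.hits == brute_force_map(q, targets), qid


class TestAllocation:
    def test_parent_anchor_assigns_full_weight(self):
        frag = HitSet("read1:0:25", (("A", 0, "+"), ("B", 0, "+")))
        full = HitSet("read1", (("A", 10, "+"),))
        alloc = allocate_multimapped([frag], [full])
        assert alloc.per_target == {"A": 1.0}
        assert alloc.tier_counts == {2: 1}

    def test_proportional_tier_uses_unique_fulllength_weights(self):
        frag = HitSet("rX:0:25", (("A", 0, "+"), ("B", 0, "+")))
        fulls = [
            HitSet(f"u{i}", (("A", 0, "+"),)) for i in range(3)
        ] + [HitSet("u3", (("B", 0, "+"),))]
        alloc = allocate_multimapped([frag], fulls)
        assert alloc.per_target["A"] == pytest.approx(0.75)
        assert alloc.per_target["B"] == pytest.approx(0.25)
        assert alloc.tier_counts == {3: 1}

    def test_uniform_tier_without_any_evidence(self):
        frag = HitSet("rX:0:25", (("A", 0, "+"), ("B", 5, "+"), ("C", 9, "-")))
        alloc = allocate_multimapped([frag], [])
        assert alloc.per_target == pytest.approx(
            {"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}
        )
        assert alloc.tier_counts == {4: 1}

    @given(st.integers(0, 10000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_conservation_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        targets = [f"t{i}" for i in range(5)]
        frags = []
        for i in range(rng.integers(1, 40)):
            k = rng.integers(0, 4)
            hits = tuple(
                (targets[t], int(rng.integers(0, 100)), "+")
                for t in rng.choice(5, size=k, replace=False)
            )
            frags.append(HitSet(f"r{i}:0:25", hits))
        fulls = []
        for i in range(rng.integers(0, 20)):
            hits = tuple(
                (targets[t], 0, "+")
                for t in rng.choice(5, size=rng.integers(1, 3), replace=False)
            )
            fulls.append(HitSet(f"r{i}", hits))
        alloc = allocate_multimapped(frags, fulls)
        mapped = sum(1 for f in frags if f.hits)
        assert alloc.total_allocated == pytest.approx(mapped, abs=1e-9)

    def test_identical_copies_degrade_to_uniform_without_anchors(self):
        # divergence 0: every fragment hits both copies, no unique evidence
        frags = [
            HitSet(f"r{i}:0:25", (("A", 0, "+"), ("B", 0, "+")))
            for i in range(10)
        ]
        alloc = allocate_multimapped(frags, [])
        assert alloc.per_target == pytest.approx({"A": 5.0, "B": 5.0})
        assert alloc.total_allocated == pytest.approx(10.0)


class TestAmbiguousJunctionPolicies:
    def test_rescue_redistributes_by_unique_support(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        shared = "".join(bases[rng.integers(0, 4, 115)])
        a_right = "".join(bases[rng.integers(0, 4, 115)])
        # second ref: same donor flank, acceptor differing after 20 bases
        b_right = a_right[:20] + "".join(bases[rng.integers(0, 4, 95)])
        ra = JunctionRef(JunctionKey("g", "e2.1", "e3.1"), shared + a_right, 115, 115, 115)
        rb = JunctionRef(JunctionKey("g", "e2.1", "e3.2"), shared + b_right, 115, 115, 115)
        ambiguous = ReadRecord("amb", (shared + a_right)[115 - 110 : 115 + 15])
        unique_a = [
            ReadRecord(f"ua{i}", (shared + a_right)[115 - 50 : 115 + 75])
            for i in range(3)
        ]
        counts, _ = match_breakpoint_reads(
            unique_a + [ambiguous], [ra, rb], 10, ambiguous="rescue"
        )
        assert counts["g|e2.1|e3.1"] == pytest.approx(4.0)
        assert "g|e2.1|e3.2" not in counts
        frac, _ = match_breakpoint_reads(
            unique_a + [ambiguous], [ra, rb], 10, ambiguous="fractional"
        )
        assert frac["g|e2.1|e3.1"] == pytest.approx(3.5)
        assert frac["g|e2.1|e3.2"] == pytest.approx(0.5)


class TestCountCorrelation:
    def test_identical_vectors(self):
        r = count_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert r["pearson"] == pytest.approx(1.0)
        assert r["spearman"] == pytest.approx(1.0)

    def test_negated_around_mean(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = 2 * a.mean() - a
        assert count_correlation(a, b)["pearson"] == pytest.approx(-1.0)

    def test_zero_variance_is_flagged(self):
        with pytest.raises(ValueError):
            count_correlation([1, 1, 1], [1, 2, 3])
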