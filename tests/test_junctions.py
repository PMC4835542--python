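"""Junction library: enumeration counts, flank geometry, slice oracles."""

import pytest

from cassetteseq.fixtures import fixture_genome, fixture_path
from cassetteseq.junctions import (
    JunctionKey,
    build_exon_intron_refs,
    build_junction_library,
    build_junction_ref,
    enumerate_candidate_junctions,
)
from cassetteseq.locus import (
    CONSTANT,
    Cassette,
    Exon,
    GeneLocus,
    GenomicInterval,
    read_gene_model,
    reverse_complement,
)

from conftest import build_locus, random_genome_for


class TestEnumerate:
    def test_two_by_two_cassettes_give_ten_keys(self):
        locus, _ = build_locus("g", "alpha", 2)  # 2 cassettes x 2 exons
        keys = enumerate_candidate_junctions(locus)
        assert len(keys) == 10  # 6 variable-variable + 4 variable-constant

    def test_count_formula_over_fixture_loci(self):
        loci = read_gene_model(fixture_path("beta"))
        for locus in loci:
            v = len(locus.variable_exons)
            keys = enumerate_candidate_junctions(locus)
            assert len(keys) == v * (v - 1) // 2 + v
            assert len(set(keys)) == len(keys)

    def test_known_cross_cassette_key_present_in_beta1(self):
        loci = read_gene_model(fixture_path("beta"))
        beta1 = loci[0]
        keys = set(enumerate_candidate_junctions(beta1))
        assert JunctionKey(beta1.gene_id, "e2.1", "e3.2") in keys

    def test_single_one_exon_cassette(self):
        iv = GenomicInterval("c", 100, 220, "+")
        cassette = Cassette(1, (Exon(1, 1, iv),), 2)
        locus = GeneLocus(
            "g1",
            "alpha",
            (cassette,),
            (Exon(CONSTANT, 1, GenomicInterval("c", 400, 600, "+")),),
            GenomicInterval("c", 0, 700, "+"),
        )
        keys = enumerate_candidate_junctions(locus)
        assert len(keys) == 1
        assert keys[0].acceptor_exon == "const1"


class TestJunctionRefGeometry:
    def test_long_exons_give_230nt_reference(self):
        locus, length = build_locus("g", "beta", 2, exon_len=150)
        genome = random_genome_for(locus, length)
        key = JunctionKey("g", "e2.1", "e3.1")
        ref = build_junction_ref(key, locus, genome, 125, 10)
        assert len(ref.sequence) == 230
        assert ref.breakpoint_offset == 115

    def test_short_donor_truncates_left_flank(self):
        locus, length = build_locus("g", "beta", 2, exon_len=60)
        genome = random_genome_for(locus, length)
        # acceptor long enough: use a constant exon (200 nt)
        key = JunctionKey("g", "e4.2", "const1")
        ref = build_junction_ref(key, locus, genome, 125, 10)
        assert len(ref.sequence) == 60 + 115
        assert ref.breakpoint_offset == 60

    def test_sequences_match_slice_oracle(self, sim_small):
        loci, genome = sim_small["loci"], sim_small["genome"]
        for locus in loci:
            refs = build_junction_library(locus, genome, 125, 10)
            for ref in refs[:50]:
                donor = locus.exon(ref.key.donor_exon).interval
                acceptor = locus.exon(ref.key.acceptor_exon).interval
                chrom = genome[donor.chrom]
                expected = (
                    chrom[donor.start : donor.end][-ref.left_flank :]
                    + chrom[acceptor.start : acceptor.end][: ref.right_flank]
                )
                assert ref.sequence == expected

    def test_minus_strand_ref_matches_revcomp_oracle(self):
        plus, length = build_locus("g", "alpha", 2)
        genome = random_genome_for(plus, length, seed=5)
        chrom = genome[plus.interval.chrom]
        # mirror the locus onto the minus strand of the reverse-complemented
        # genome; junction sequences must be identical to the plus version
        rc_genome = {plus.interval.chrom: reverse_complement(chrom)}

        def mirror(iv):
            return GenomicInterval(
                iv.chrom, length - iv.end, length - iv.start, "-"
            )

        from dataclasses import replace

        cassettes = tuple(
            replace(
                c,
                exons=tuple(
                    replace(e, interval=mirror(e.interval)) for e in c.exons
                ),
            )
            for c in plus.cassettes
        )
        constant = tuple(
            replace(e, interval=mirror(e.interval))
            for e in plus.constant_exons
        )
        minus = GeneLocus(
            plus.gene_id,
            plus.family,
            cassettes,
            constant,
            replace(plus.interval, strand="-"),
        )
        key = JunctionKey("g", "e1.1", "e2.1")
        ref_plus = build_junction_ref(key, plus, genome, 125, 10)
        ref_minus = build_junction_ref(key, minus, rc_genome, 125, 10)
        assert ref_plus.sequence == ref_minus.sequence

    def test_invalid_overlap_parameters_rejected(self, micro_locus):
        locus, genome = micro_locus
        key = JunctionKey(locus.gene_id, "e1.1", "e2.1")
        with pytest.raises(ValueError):
            build_junction_ref(key, locus, genome, 125, 125)


class TestExonIntronRefs:
    def test_one_ref_per_variable_exon(self, micro_locus):
        locus, genome = micro_locus
        refs = build_exon_intron_refs(locus, genome, 125, 10)
        assert len(refs) == len(locus.variable_exons)
        assert {r.exon for r in refs} == {
            e.name for e in locus.variable_exons
        }

    def test_short_intron_truncates_right_flank(self):
        locus, length = build_locus("g", "beta", 1, intron_len=30)
        genome = random_genome_for(locus, length)
        refs = build_exon_intron_refs(locus, genome, 125, 10)
        by_exon = {r.exon: r for r in refs}
        assert by_exon["e1.1"].right_flank == 30

    def test_refs_are_genomic_substrings_around_boundaries(self, sim_small):
        loci, genome = sim_small["loci"], sim_small["genome"]
        for locus in loci:
            for ref in build_exon_intron_refs(locus, genome, 125, 10):
                exon = locus.exon(ref.exon).interval
                chrom = genome[exon.chrom]
                start = exon.end - ref.left_flank
                expected = chrom[start : exon.end + ref.right_flank]
                assert ref.sequence == expected

    def test_beta_fixture_has_ref_after_cassette_final_exons(self):
        loci = read_gene_model(fixture_path("beta"), fixture_genome("beta"))
        beta1 = loci[0]
        refs = build_exon_intron_refs(beta1, fixture_genome("beta"), 125, 10)
        names = {r.exon for r in refs}
        assert "e4.5" in names  # boundary into the interval before cassette 6
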