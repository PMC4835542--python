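"""Junction classes, Ig accounting and isoform assembly."""

import pytest

from cassetteseq.classify import (
    IsoformStructure,
    JunctionClass,
    assemble_isoform_from_junction_chain,
    classify_junction,
    ig_domain_count,
    noncanonical_fraction,
)
from cassetteseq.fixtures import fixture_path
from cassetteseq.junctions import JunctionKey, enumerate_candidate_junctions
from cassetteseq.locus import read_gene_model


@pytest.fixture(scope="module")
def beta1():
    return read_gene_model(fixture_path("beta"))[0]


class TestClassifyJunction:
    def test_neighbouring_within_cassette_is_canonical(self, beta1):
        key = JunctionKey(beta1.gene_id, "e1.5", "e2.5")
        assert classify_junction(key, beta1) is JunctionClass.CANONICAL

    def test_within_cassette_skip_is_type_i(self, beta1):
        key = JunctionKey(beta1.gene_id, "e2.7", "e4.7")
        assert classify_junction(key, beta1) is JunctionClass.TYPE_I_SKIP

    def test_cross_cassette_is_type_ii(self, beta1):
        key = JunctionKey(beta1.gene_id, "e2.1", "e3.2")
        assert (
            classify_junction(key, beta1)
            is JunctionClass.TYPE_II_CROSS_CASSETTE
        )

    def test_every_cassette_final_exon_to_constant_is_canonical(self, beta1):
        for cassette in beta1.cassettes:
            key = JunctionKey(
                beta1.gene_id, cassette.last_exon.name, "const1"
            )
            assert classify_junction(key, beta1) is JunctionClass.CANONICAL

    def test_non_final_exon_to_constant_skips_cassette_tail(self, beta1):
        key = JunctionKey(beta1.gene_id, "e3.4", "const1")
        assert classify_junction(key, beta1) is JunctionClass.TYPE_I_SKIP

    def test_total_and_deterministic_over_enumeration(self, beta1):
        keys = enumerate_candidate_junctions(beta1)
        labels = [classify_junction(k, beta1) for k in keys]
        assert len(labels) == len(keys)
        assert set(labels) <= {
            JunctionClass.CANONICAL,
            JunctionClass.TYPE_I_SKIP,
            JunctionClass.TYPE_II_CROSS_CASSETTE,
        }  # type III never assigned from a key
        assert labels == [classify_junction(k, beta1) for k in keys]


class TestIgDomainCount:
    def test_cross_cassette_three_ig_isoform(self):
        s = IsoformStructure(
            "b1", "beta", ("e1.5", "e2.5", "e3.5", "e4.5", "e3.13", "e4.13")
        )
        ig = ig_domain_count(s)
        assert ig.complete_ig == 3
        assert not ig.has_incomplete

    def test_cross_cassette_four_ig_isoform(self):
        s = IsoformStructure(
            "b3",
            "beta",
            ("e1.10", "e2.10", "e3.10", "e4.10", "e2.11", "e3.11", "e4.11"),
        )
        assert ig_domain_count(s).complete_ig == 4

    @pytest.mark.parametrize("cassette", [1, 7, 13])
    def test_canonical_beta_cassette_two_ig(self, cassette):
        s = IsoformStructure(
            "b1",
            "beta",
            tuple(f"e{i}.{cassette}" for i in range(1, 5)) + ("const1",),
        )
        ig = ig_domain_count(s)
        assert ig.complete_ig == 2
        assert not ig.has_incomplete

    @pytest.mark.parametrize("cassette", [1, 4, 40])
    def test_canonical_alpha_cassette_one_ig(self, cassette):
        s = IsoformStructure(
            "a", "alpha", (f"e1.{cassette}", f"e2.{cassette}", "const1")
        )
        ig = ig_domain_count(s)
        assert ig.complete_ig == 1
        assert not ig.has_incomplete

    def test_exon_skip_leaves_incomplete_ig(self):
        s = IsoformStructure("b6", "beta", ("e1.1", "e2.1", "e4.1", "const1"))
        ig = ig_domain_count(s)
        assert ig.complete_ig == 1
        assert ig.has_incomplete

    def test_unknown_exon_name_is_an_error(self):
        s = IsoformStructure("b1", "beta", ("e1.1", "weird", "const1"))
        with pytest.raises(ValueError):
            ig_domain_count(s)


class TestNoncanonicalFraction:
    def test_all_canonical_is_zero(self):
        shares = noncanonical_fraction({JunctionClass.CANONICAL: 42.0})
        assert shares["noncanonical"] == 0.0

    def test_simple_arithmetic(self):
        shares = noncanonical_fraction(
            {
                JunctionClass.CANONICAL: 3.0,
                JunctionClass.TYPE_II_CROSS_CASSETTE: 1.0,
            }
        )
        assert shares["noncanonical"] == pytest.approx(0.25)
        assert shares["type_ii_cross_cassette"] == pytest.approx(0.25)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            noncanonical_fraction({})


class TestAssembleIsoform:
    def test_single_cross_cassette_junction_chain(self, beta1):
        chain = [JunctionKey(beta1.gene_id, "e4.5", "e3.13")]
        structure = assemble_isoform_from_junction_chain(chain, beta1)
        assert structure.parts == (
            "e1.5",
            "e2.5",
            "e3.5",
            "e4.5",
            "e3.13",
            "e4.13",
            "const1",
        )

    def test_empty_chain_gives_canonical_structure(self, beta1):
        structure = assemble_isoform_from_junction_chain(
            [], beta1, start_cassette=7
        )
        assert structure.parts == (
            "e1.7",
            "e2.7",
            "e3.7",
            "e4.7",
            "const1",
        )

    def test_unchainable_keys_raise_with_break_location(self, beta1):
        chain = [
            JunctionKey(beta1.gene_id, "e2.1", "e3.2"),
            JunctionKey(beta1.gene_id, "e2.5", "e3.6"),
        ]
        with pytest.raises(ValueError, match="chain"):
            assemble_isoform_from_junction_chain(chain, beta1)

    def test_round_trip_against_simulated_isoforms(self, sim_small):
        loci = {l.gene_id: l for l in sim_small["loci"]}
        checked = 0
        for iso in sim_small["isoforms"]:
            parts = iso.structure.parts
            if any(p.startswith("intron:") for p in parts):
                continue  # retained-sequence isoforms carry no junction chain
            locus = loci[iso.structure.gene_id]
            chain = []
            for a, b in zip(parts, parts[1:]):
                key = JunctionKey(locus.gene_id, a, b)
                if classify_junction(key, locus) is not JunctionClass.CANONICAL:
                    chain.append(key)
            if chain:
                rebuilt = assemble_isoform_from_junction_chain(chain, locus)
            else:
                start = int(parts[0].split(".")[1])
                rebuilt = assemble_isoform_from_junction_chain(
                    [], locus, start_cassette=start
                )
            assert rebuilt.parts == parts
            checked += 1
        assert checked >= 20
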