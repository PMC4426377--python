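"""Allele nomenclature parsing, consensus expansion and coordinate mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refbias.alleles import (
    AlleleCall,
    AlleleName,
    AlleleNameError,
    CatalogLookupError,
    ConsensusSequence,
    Exon,
    LocusSpec,
    cds_to_genomic,
    deconstruct_genotypes,
    expand_call_to_consensus,
    genomic_to_cds,
    parse_allele_call,
    parse_allele_name,
)


class TestParseAlleleName:
    @pytest.mark.parametrize(
        "raw, locus, fields",
        [
            ("B*35:03", "B", (35, 3)),
            ("A*01:01:01:01", "A", (1, 1, 1, 1)),
            ("B*35", "B", (35,)),
            ("DQB1*06:02", "DQB1", (6, 2)),
        ],
    )
    def test_well_formed(self, raw, locus, fields):
        name = parse_allele_name(raw)
        assert (name.locus, name.fields) == (locus, fields)
        assert name.resolution == len(fields)

    @pytest.mark.parametrize(
        "raw", ["B35:03", "B*", "A*01:02:03:04:05", "", "A*01N", "*01:01"]
    )
    def test_malformed_rejected(self, raw):
        with pytest.raises(AlleleNameError):
            parse_allele_name(raw)

    def test_error_names_offending_token(self):
        with pytest.raises(AlleleNameError, match="B35:03"):
            parse_allele_name("B35:03")

    @given(
        st.sampled_from(["A", "B", "C", "DQB1", "DRB1"]),
        st.lists(st.integers(1, 999), min_size=1, max_size=4),
    )
    @settings(max_examples=100, derandomize=True)
    def test_format_parse_round_trip(self, locus, fields):
        name = AlleleName(locus, tuple(fields))
        assert parse_allele_name(str(name)) == name


class TestParseAlleleCall:
    def test_explicit_ambiguity_list(self):
        call = parse_allele_call("B*35:02/B*35:03/B*35:04")
        assert len(call.candidates) == 3
        assert call.is_ambiguous
        assert call.locus == "B"

    def test_singleton(self):
        call = parse_allele_call("A*02:01")
        assert not call.is_ambiguous

    def test_mixed_loci_rejected(self):
        with pytest.raises(AlleleNameError, match="mixed loci"):
            parse_allele_call("A*02:01/B*07:02")

    def test_empty_rejected(self):
        with pytest.raises(AlleleNameError):
            parse_allele_call("//")


class TestCatalogAndConsensus:
    def test_singleton_expands_to_its_sequence(self, toy_catalog):
        cons = expand_call_to_consensus(parse_allele_call("TOY*01:01"), toy_catalog)
        assert cons.to_string() == "ACGTACGTAC"
        assert len(cons.ambiguous_positions()) == 0

    def test_two_candidates_differing_at_one_position(self, toy_catalog):
        cons = expand_call_to_consensus(
            parse_allele_call("TOY*01:01/TOY*01:02"), toy_catalog
        )
        assert list(cons.ambiguous_positions()) == [5]
        assert cons.base_set(5) == frozenset("AT")
        assert cons.base_set(1) == frozenset("A")

    def test_lower_resolution_name_expands_like_ambiguity(self, toy_catalog):
        # TOY*02:01 matches both third-field entries, which differ at site 9
        cons = expand_call_to_consensus(parse_allele_call("TOY*02:01"), toy_catalog)
        assert list(cons.ambiguous_positions()) == [9]
        assert cons.base_set(9) == frozenset("AG")

    def test_missing_candidate_reported_by_name(self, toy_catalog):
        with pytest.raises(CatalogLookupError, match="TOY\\*99:99"):
            expand_call_to_consensus(parse_allele_call("TOY*99:99"), toy_catalog)

    def test_nonsingleton_positions_match_pairwise_disagreement_oracle(self):
        # oracle: direct position-wise comparison over the candidate set
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(1, 5)
            L = 30
            seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, L))]
            for _ in range(k - 1):
                s = list(seqs[0])
                for pos in rng.choice(L, size=rng.integers(0, 4), replace=False):
                    s[pos] = "ACGT"[rng.integers(0, 4)]
                seqs.append("".join(s))
            cons = ConsensusSequence.from_sequences(seqs)
            expected = {
                p + 1
                for p in range(L)
                if len({s[p] for s in seqs}) > 1
            }
            assert set(cons.ambiguous_positions().tolist()) == expected


class TestDeconstruct:
    def test_heterozygote_and_homozygote(self, toy_catalog):
        c1 = expand_call_to_consensus(parse_allele_call("TOY*01:01"), toy_catalog)
        c2 = expand_call_to_consensus(parse_allele_call("TOY*01:02"), toy_catalog)
        gts = deconstruct_genotypes(c1, c2, [5, 1], sample_id="s1")
        assert gts[0].alleles == (frozenset("A"), frozenset("T"))
        assert gts[1].alleles == (frozenset("A"), frozenset("A"))
        assert gts[0].sample_id == "s1"

    def test_ambiguous_copy_paired_with_unambiguous(self, toy_catalog):
        amb = expand_call_to_consensus(
            parse_allele_call("TOY*01:01/TOY*01:02"), toy_catalog
        )
        other = expand_call_to_consensus(parse_allele_call("TOY*02:01:01"), toy_catalog)
        (gt,) = deconstruct_genotypes(amb, other, [5])
        assert set(gt.alleles) == {frozenset("AT"), frozenset("A")}

    def test_out_of_range_site(self, toy_catalog):
        c = expand_call_to_consensus(parse_allele_call("TOY*01:01"), toy_catalog)
        with pytest.raises(ValueError, match="outside"):
            deconstruct_genotypes(c, c, [11])


class TestCoordinates:
    def test_plus_strand_single_exon(self):
        locus = LocusSpec("X", (Exon("e", 1000, 1009),), "+", "ACGTACGTAC")
        assert cds_to_genomic(locus, 1) == 1000
        assert cds_to_genomic(locus, 10) == 1009

    def test_plus_strand_two_exons(self):
        locus = LocusSpec(
            "X", (Exon("e1", 1000, 1009), Exon("e2", 2000, 2009)), "+", "ACGTACGTAC" * 2
        )
        # enumerate exon offsets: cds 11 is the first base of the second exon
        assert cds_to_genomic(locus, 10) == 1009
        assert cds_to_genomic(locus, 11) == 2000

    def test_minus_strand_reflection(self):
        locus = LocusSpec("X", (Exon("e", 1000, 1050),), "-", "A" * 51)
        assert cds_to_genomic(locus, 1) == 1050
        assert cds_to_genomic(locus, 51) == 1000

    def test_out_of_range(self, toy_locus):
        with pytest.raises(ValueError):
            cds_to_genomic(toy_locus, 0)
        with pytest.raises(ValueError):
            cds_to_genomic(toy_locus, 41)

    def test_outside_exons_maps_to_none(self, toy_locus):
        assert genomic_to_cds(toy_locus, 1500) is None

    @given(st.data())
    @settings(max_examples=60, derandomize=True)
    def test_round_trip_over_random_exon_maps(self, data):
        n_exons = data.draw(st.integers(1, 4))
        strand = data.draw(st.sampled_from("+-"))
        lengths = [data.draw(st.integers(1, 30)) for _ in range(n_exons)]
        starts, g = [], 1
        for ln in lengths:
            g += data.draw(st.integers(1, 50))
            starts.append(g)
            g += ln
        exons = [
            Exon(f"e{i}", s, s + ln - 1) for i, (s, ln) in enumerate(zip(starts, lengths))
        ]
        if strand == "-":
            exons = exons[::-1]  # coding order is genomically descending
        L = sum(lengths)
        locus = LocusSpec("X", tuple(exons), strand, "A" * L)
        for p in range(1, L + 1):
            assert genomic_to_cds(locus, cds_to_genomic(locus, p)) == p
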