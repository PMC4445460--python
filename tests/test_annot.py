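"""Nonsense-mutation calling and tRNA-suppressor detection."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from yeastdmi.annot import (
    STOP_CODONS,
    VariantInputError,
    call_nonsense,
    call_nonsense_genomic,
    count_nonsense_by_class,
    detect_trna_suppressor,
    genomic_to_orf_variant,
    scan_trnas,
    shared_nonsense_genes,
)


def make_orf(codons: dict, n_codons: int = 120) -> str:
    """In-frame ORF: ATG, alanine filler, overrides from ``codons``
    (1-based codon index), terminal TAA."""
    body = ["ATG"] + ["GCT"] * (n_codons - 2) + ["TAA"]
    for idx, codon in codons.items():
        body[idx - 1] = codon
    return "".join(body)


class TestCallNonsense:
    def test_caa_to_taa_at_codon_39(self):
        orf = make_orf({39: "CAA"})
        calls = call_nonsense(orf, [(115, "C", "T")])
        assert len(calls) == 1
        call = calls[0]
        assert call.orf_nt_pos == 115
        assert call.codon_index == 39
        assert (call.ref_codon, call.alt_codon) == ("CAA", "TAA")
        assert call.stop_class == "TAA"

    def test_synonymous_variant_no_call(self):
        orf = make_orf({10: "CTT"})
        assert call_nonsense(orf, [(30, "T", "C")]) == []  # CTT -> CTC

    def test_cga_to_tga_at_codon_5(self):
        orf = make_orf({5: "CGA"})
        calls = call_nonsense(orf, [(13, "C", "T")])
        assert len(calls) == 1
        assert calls[0].stop_class == "TGA"
        assert calls[0].orf_nt_pos == 13  # 3*(5-1)+1

    def test_terminal_stop_codon_never_called(self):
        orf = make_orf({}, n_codons=10)  # ends TAA
        # mutate codon 10's TAA -> TGA: stop-to-stop, also terminal
        assert call_nonsense(orf, [(29, "A", "G")]) == []

    def test_stop_to_stop_not_premature(self):
        orf = make_orf({7: "TAG"})
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert call_nonsense(orf, [(21, "G", "A")]) == []  # TAG -> TAA

    def test_ref_mismatch_reported_with_position(self):
        orf = make_orf({39: "CAA"})
        with pytest.raises(VariantInputError, match="115"):
            call_nonsense(orf, [(115, "G", "T")])

    def test_position_outside_orf_rejected(self):
        with pytest.raises(VariantInputError, match="outside"):
            call_nonsense(make_orf({}), [(5000, "A", "T")])

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(VariantInputError):
            call_nonsense("ATGAA", [])

    def test_nonstandard_ends_warn_but_run(self):
        orf = "CCT" * 20 + "GCT" * 2  # no ATG, no stop
        with pytest.warns(UserWarning):
            call_nonsense(orf, [])

    def test_inverse_variant_round_trip_removes_call(self):
        orf = make_orf({39: "CAA"})
        calls = call_nonsense(orf, [(115, "C", "T")])
        assert calls
        mutated = orf[:114] + "T" + orf[115:]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert call_nonsense(mutated, [(115, "T", "C")]) == []

    def test_every_emitted_call_satisfies_coordinate_identity(self):
        orf = make_orf({5: "CGA", 39: "CAA", 60: "TGG"})
        calls = call_nonsense(
            orf, [(13, "C", "T"), (115, "C", "T"), (179, "G", "A")]
        )
        assert len(calls) == 3
        for call in calls:
            assert call.orf_nt_pos == 3 * (call.codon_index - 1) + 1
            assert call.alt_codon in STOP_CODONS

    def test_phased_mode_compounds_codon_variants(self):
        # CGG needs both hits to reach TAG: C->T alone gives TGG (Trp),
        # G->A alone gives CAG (Gln)
        orf = make_orf({11: "CGG"})
        assert call_nonsense(orf, [(31, "C", "T"), (32, "G", "A")]) == []
        phased = call_nonsense(orf, [(31, "C", "T"), (32, "G", "A")],
                               phased=True)
        assert len(phased) == 1 and phased[0].alt_codon == "TAG"


class TestGenomicCoordinates:
    def test_plus_strand_mapping(self):
        assert genomic_to_orf_variant(1001, 1360, "+", 1115, "C", "T") == \
            (115, "C", "T")

    def test_minus_strand_gene_gives_identical_calls(self):
        orf = make_orf({39: "CAA"}, n_codons=50)
        start, end = 2001, 2000 + len(orf)
        plus_calls = call_nonsense_genomic(
            orf, ("chrII", start, end, "+"),
            [("chrII", start + 114, "C", "T")],
        )
        # same gene annotated on the minus strand: genomic position of ORF
        # base 115 counts from the gene end, alleles complemented
        minus_calls = call_nonsense_genomic(
            orf, ("chrII", start, end, "-"),
            [("chrII", end - 114, "G", "A")],
        )
        assert plus_calls == minus_calls
        assert plus_calls[0].orf_nt_pos == 115

    def test_variants_off_gene_ignored(self):
        orf = make_orf({39: "CAA"}, n_codons=50)
        calls = call_nonsense_genomic(
            orf, ("chrII", 2001, 2000 + len(orf), "+"),
            [("chrIII", 2115, "C", "T"), ("chrII", 99, "C", "T")],
        )
        assert calls == []


class TestCounting:
    def test_empty_calls_all_zero(self):
        table = count_nonsense_by_class({"s1": []})
        assert (table.loc["s1"] == 0).all()

    def test_class_counts_per_strain(self):
        orf_taa = make_orf({39: "CAA"})
        orf_tga = make_orf({5: "CGA"})
        calls = (
            call_nonsense(orf_taa, [(115, "C", "T")], gene_id="g1")
            + call_nonsense(orf_taa, [(115, "C", "T")], gene_id="g2")
            + call_nonsense(orf_taa, [(115, "C", "T")], gene_id="g3")
            + call_nonsense(orf_tga, [(13, "C", "T")], gene_id="g4")
        )
        table = count_nonsense_by_class({"s1": calls})
        assert list(table.loc["s1", ["TAA", "TAG", "TGA"]]) == [3, 0, 1]

    def test_poisson_generator_round_trip_mean_near_10(self):
        # 100 synthetic strains, Poisson(10) calls per stop class
        rng = np.random.default_rng(0)
        template = {
            "TAA": ("CAA", (115, "C", "T"), 39),
            "TAG": ("CAG", (115, "C", "T"), 39),
            "TGA": ("CGA", (115, "C", "T"), 39),
        }
        per_strain = {}
        for s in range(100):
            calls = []
            for stop, (codon, (pos, ref, alt), ci) in template.items():
                orf = make_orf({ci: codon})
                n = rng.poisson(10)
                for j in range(n):
                    calls += call_nonsense(orf, [(pos, ref, alt)],
                                           gene_id=f"{stop}_{s}_{j}")
            per_strain[f"strain{s}"] = calls
        table = count_nonsense_by_class(per_strain)
        assert table.shape == (100, 3)
        for stop in STOP_CODONS:
            assert table[stop].mean() == pytest.approx(10, abs=1.0)

    def test_shared_genes(self):
        orf = make_orf({39: "CAA"})
        call = call_nonsense(orf, [(115, "C", "T")], gene_id="geneA")
        callB = call_nonsense(orf, [(115, "C", "T")], gene_id="geneB")
        assert shared_nonsense_genes({"s1": call}) == (0, 1)
        assert shared_nonsense_genes({"s1": call + callB, "s2": call}) == (1, 2)


class TestSuppressor:
    def test_gta_to_tta_is_taa_suppressor(self):
        call = detect_trna_suppressor("GTA", "TTA")
        assert call is not None
        assert call.suppressed_stop == "TAA"

    def test_unchanged_anticodon_no_call(self):
        assert detect_trna_suppressor("GTA", "GTA") is None

    def test_gta_to_cta_is_tag_suppressor(self):
        call = detect_trna_suppressor("GTA", "CTA")
        assert call.suppressed_stop == "TAG"

    def test_non_dna_rejected(self):
        with pytest.raises(VariantInputError):
            detect_trna_suppressor("GUA", "UUA")  # RNA alphabet

    def test_already_stop_reading_anticodon_not_called(self):
        # TTA reads TAA already; a TTA -> CTA change is not a gain
        assert detect_trna_suppressor("TTA", "CTA") is None

    def test_enumeration_oracle_all_single_base_changes(self):
        """All 64 anticodons x 9 single-base substitutions against the
        brute-force rule revcomp(after) in stops and revcomp(before) not."""
        stops = set(STOP_CODONS)
        n_calls = 0
        for before in map("".join, itertools.product("ACGT", repeat=3)):
            for i, alt in itertools.product(range(3), "ACGT"):
                if before[i] == alt:
                    continue
                after = before[:i] + alt + before[i + 1:]
                expected = (
                    str(Seq(after).reverse_complement()) in stops
                    and str(Seq(before).reverse_complement()) not in stops
                )
                got = detect_trna_suppressor(before, after) is not None
                assert got == expected, (before, after)
                n_calls += got
        assert n_calls > 0

    def test_scan_standard_set_without_variants_is_empty(self):
        trnas = [("tY1", "GTA"), ("tQ1", "TTG"), ("tE1", "TTC"), ("tW1", "CCA")]
        assert scan_trnas(trnas) == []

    def test_scan_finds_the_single_suppressor(self):
        trnas = [("tY(GUA)J1", "GTA"), ("tQ1", "TTG")]
        variants = {"tY(GUA)J1": [(1, "G", "T")]}
        calls = scan_trnas(trnas, variants)
        assert len(calls) == 1
        assert calls[0].trna_id == "tY(GUA)J1"
        assert calls[0].suppressed_stop == "TAA"

    def test_scan_ref_mismatch_rejected(self):
        with pytest.raises(VariantInputError):
            scan_trnas([("t1", "GTA")], {"t1": [(1, "C", "T")]})
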