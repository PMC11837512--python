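"""Codon edit engine and premature-stop classification."""

import itertools

import pytest

from bestop.genome_model import GenomeRecord, revcomp
from bestop.guide_scan import EditWindow, ProtospacerSite, find_pam_sites
from bestop.stop_logic import (
    StopGuide,
    apply_ct_edits,
    classify_site,
    pre_stop_codons,
)
from bestop.synthetic import Plant, make_genome
from bestop import design, DesignConfig, load_annotation, load_genome

ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


class TestApplyCtEdits:
    @pytest.mark.parametrize(
        "codon, offsets, strand, expected",
        [
            ("CGA", {0}, "coding", "TGA"),
            ("CAG", {0}, "coding", "TAG"),
            ("CAA", {0}, "coding", "TAA"),
            ("TGG", {1}, "template", "TAG"),
            ("TGG", {2}, "template", "TGA"),
            ("TGG", {1, 2}, "template", "TAA"),
            ("AAA", set(), "coding", "AAA"),
            ("CCC", {0, 1, 2}, "coding", "TTT"),
        ],
    )
    def test_edit_outcomes(self, codon, offsets, strand, expected):
        assert apply_ct_edits(codon, offsets, strand) == expected

    def test_mismatched_base_rejected(self):
        with pytest.raises(ValueError, match="not 'C'"):
            apply_ct_edits("AGA", {0}, "coding")
        with pytest.raises(ValueError, match="not 'G'"):
            apply_ct_edits("CAA", {1}, "template")

    def test_strand_symmetry_brute_force(self):
        """Editing G->A on the coding strand is C->T on the template read in
        reverse complement, with mirrored offsets."""
        for codon in ALL_CODONS:
            gs = [i for i in range(3) if codon[i] == "G"]
            for r in range(1, len(gs) + 1):
                for offsets in itertools.combinations(gs, r):
                    mirrored = {2 - o for o in offsets}
                    assert apply_ct_edits(codon, offsets, "template") == revcomp(
                        apply_ct_edits(revcomp(codon), mirrored, "coding")
                    )


class TestPreStopCodons:
    def test_closure_is_the_four_codon_rule_set(self):
        assert set(pre_stop_codons()) == {"CGA", "CAG", "CAA", "TGG"}

    def test_cga_single_route(self):
        assert pre_stop_codons()["CGA"] == {("coding", frozenset({0}), "TGA")}

    def test_tgg_three_outcomes(self):
        outcomes = pre_stop_codons()["TGG"]
        assert {stop for _, _, stop in outcomes} == {"TGA", "TAG", "TAA"}
        assert all(strand == "template" for strand, _, _ in outcomes)

    def test_stop_codons_not_counted_as_convertible(self):
        # TAG/TGA can become TAA but are stops already
        assert not {"TAA", "TAG", "TGA"} & set(pre_stop_codons())


def build_case(plant, seed=5):
    fasta, gff, manifest = make_genome(1, seed=seed, plants=[plant])
    genome = load_genome(fasta)
    genes = load_annotation(gff, genome)
    (planted,) = manifest.planted
    (record,) = genome
    (site,) = [
        s
        for s in find_pam_sites(record)
        if s.start == planted.site_start and s.strand == planted.site_strand
    ]
    return genome, genes[0], site, planted


class TestClassifySite:
    def test_planted_cga_found_at_planted_codon(self):
        genome, gene, site, planted = build_case(Plant("CGA", -17, gene=0))
        guide = classify_site(site, gene, genome, EditWindow.canonical())
        assert isinstance(guide, StopGuide)
        assert guide.stop_codon == "TGA"
        assert guide.stop_codon_index == planted.codon_index
        assert guide.relative_position == planted.codon_index / gene.codon_count
        (edit,) = guide.codon_edits
        assert (edit.original_codon, edit.edited_codon) == ("CGA", "TGA")

    def test_tgg_minimal_vs_all_window_policies(self):
        genome, gene, site, planted = build_case(Plant("TGG", -17, gene=0))
        minimal = classify_site(site, gene, genome, EditWindow.canonical(),
                                policy="any-subset")
        both = classify_site(site, gene, genome, EditWindow.canonical(),
                             policy="all-window-cs")
        # single-C subsets give TAG or TGA; co-editing both Cs of the
        # template CCA gives TAA
        assert minimal.stop_codon in ("TAG", "TGA")
        (edit,) = minimal.codon_edits
        assert len(edit.edit_positions) == 1
        assert both.stop_codon == "TAA"
        assert edit.edit_strand == "template"

    def test_site_without_prestop_window_c_is_none(self):
        genome, gene, site, _ = build_case(
            Plant("CGG", -17, gene=0, decoy="non_prestop")
        )
        assert classify_site(site, gene, genome, EditWindow.extended()) is None

    def test_window_position_outside_mode_is_none(self):
        genome, gene, site, _ = build_case(Plant("CAA", -14, gene=0))
        assert classify_site(site, gene, genome, EditWindow.canonical()) is None
        guide = classify_site(site, gene, genome, EditWindow.extended())
        assert guide is not None and guide.stop_codon == "TAA"

    def test_native_stop_codon_is_not_premature(self):
        # gene is exactly ATG AAA CAA TGA; the only NGG site places the CAA
        # cytosine at -17, creating TAA at codon 2, upstream of the native
        # stop at codon 3 -- which itself never counts as a premature stop
        seq = "T" * 30 + "ATGAAACAATGA" + "T" * 12 + "GG" + "T" * 30
        genome = [GenomeRecord("c1", seq)]
        from bestop.genome_model import GeneModel

        gene = GeneModel("g1", "c1", "+", ((30, 42),))
        window = EditWindow.extended()
        hits = [
            classify_site(s, gene, genome, window)
            for s in find_pam_sites(genome[0])
        ]
        guides = [g for g in hits if g is not None]
        assert {g.stop_codon_index for g in guides} == {2}
        assert all(g.stop_codon == "TAA" for g in guides)

    def test_relative_position_is_fraction_of_codons(self):
        genome, gene, site, planted = build_case(Plant("CAG", -19, gene=0))
        guide = classify_site(site, gene, genome, EditWindow.canonical())
        assert 0.0 <= guide.relative_position < 1.0


class TestEquivalenceWithEditAndTranslate:
    def test_catalog_revalidates_through_oracle(self, fixture_genome):
        from bestop.synthetic import brute_force_design

        _fasta, _gff, _manifest, genome, genes = fixture_genome
        catalog = design(genome, genes, DesignConfig(window_mode="extended"))
        oracle = brute_force_design(genome, genes, "extended", "any-subset")
        assert {g.key for g in catalog.guides} == oracle
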