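"""Genome and annotation loading: coordinate conventions, validation, I/O."""

import pytest

from bestop.genome_model import (
    GeneModel,
    GenomeModelError,
    GenomeRecord,
    coding_sequence,
    first_stop_index,
    load_annotation,
    load_genbank,
    load_genome,
    revcomp,
    write_fasta,
    write_gff3,
)


def gff(lines):
    return "##gff-version 3\n" + "\n".join(lines) + "\n"


class TestLoadGenome:
    def test_case_and_u_normalization(self):
        (rec,) = load_genome(">c1\nacgun\n")
        assert rec.sequence == "ACGTN"

    def test_duplicate_contig_ids_rejected(self):
        with pytest.raises(GenomeModelError, match="duplicate"):
            load_genome(">c1\nACGT\n>c1\nACGT\n")

    def test_empty_input_rejected(self):
        with pytest.raises(GenomeModelError):
            load_genome("")

    def test_illegal_characters_strict_vs_lenient(self):
        with pytest.raises(GenomeModelError, match="illegal"):
            load_genome(">c1\nACXGT\n", strict=True)
        (rec,) = load_genome(">c1\nACXGT\n", strict=False)
        assert rec.sequence == "ACNGT"

    def test_record_order_preserved(self):
        recs = load_genome(">b\nAC\n>a\nGT\n")
        assert [r.contig_id for r in recs] == ["b", "a"]


class TestLoadAnnotation:
    GENOME = load_genome(">c1\n" + "ATGGCCTAAACCGGTTACGT" + "\n")

    def test_one_based_to_half_open(self):
        text = gff(["c1\t.\tCDS\t1\t9\t.\t+\t0\tID=g1"])
        (gene,) = load_annotation(text, self.GENOME)
        assert gene.cds_intervals == ((0, 9),)
        assert gene.codon_count == 3
        assert gene.validated

    def test_reverse_strand_coding_sequence(self):
        text = gff(["c1\t.\tCDS\t4\t12\t.\t-\t0\tID=g1"])
        (gene,) = load_annotation(text, self.GENOME)
        seq = self.GENOME[0].sequence
        assert coding_sequence(gene, self.GENOME) == revcomp(seq[3:12])

    def test_multi_segment_cds_joined_in_translation_order(self):
        text = gff(
            [
                "c1\t.\tCDS\t1\t6\t.\t-\t0\tID=g1",
                "c1\t.\tCDS\t10\t12\t.\t-\t0\tID=g1",
            ]
        )
        (gene,) = load_annotation(text, self.GENOME)
        seq = self.GENOME[0].sequence
        assert coding_sequence(gene, self.GENOME) == revcomp(seq[0:6] + seq[9:12])

    def test_length_not_multiple_of_three_flagged(self):
        text = gff(["c1\t.\tCDS\t1\t8\t.\t+\t0\tID=g1"])
        (gene,) = load_annotation(text, self.GENOME)
        assert not gene.validated
        with pytest.raises(GenomeModelError):
            coding_sequence(gene, self.GENOME)

    def test_unknown_contig_rejected(self):
        text = gff(["cX\t.\tCDS\t1\t9\t.\t+\t0\tID=g1"])
        with pytest.raises(GenomeModelError, match="unknown contig"):
            load_annotation(text, self.GENOME)

    def test_out_of_bounds_rejected(self):
        text = gff(["c1\t.\tCDS\t1\t999\t.\t+\t0\tID=g1"])
        with pytest.raises(GenomeModelError, match="outside contig"):
            load_annotation(text, self.GENOME)


class TestCodingOffsets:
    def test_plus_strand_offsets(self):
        gene = GeneModel("g", "c", "+", ((10, 16), (20, 23)))
        assert [gene.coding_offset(c) for c in (10, 15, 20, 22)] == [0, 5, 6, 8]
        assert gene.coding_offset(17) is None

    def test_minus_strand_offsets_reverse(self):
        gene = GeneModel("g", "c", "-", ((10, 16), (20, 23)))
        # translation starts at the genomic 3' end
        assert gene.coding_offset(22) == 0
        assert gene.coding_offset(10) == 8


class TestFixtureRoundTrip:
    def test_three_record_fasta_matches_manifest(self, multi_contig_genome):
        _fasta, _gff, manifest, genome, _genes = multi_contig_genome
        assert len(genome) == 3
        assert {r.contig_id: len(r) for r in genome} == manifest.contig_lengths

    def test_gene_set_matches_manifest(self, fixture_genome):
        _fasta, _gff, manifest, genome, genes = fixture_genome
        by_id = {g.gene_id: g for g in genes}
        assert set(by_id) == {m.gene_id for m in manifest.genes}
        for m in manifest.genes:
            gene = by_id[m.gene_id]
            assert gene.strand == m.strand
            assert gene.cds_intervals == ((m.start, m.end),)
            assert coding_sequence(gene, genome) == m.cds

    def test_round_trip_write_and_reload(self, fixture_genome):
        _fasta, _gff, _manifest, genome, genes = fixture_genome
        genome2 = load_genome(write_fasta(genome))
        genes2 = load_annotation(write_gff3(genes), genome2)
        assert genome2 == genome
        assert sorted(genes2, key=lambda g: g.gene_id) == sorted(
            genes, key=lambda g: g.gene_id
        )

    def test_validated_genes_have_codon_multiple_length(self, fixture_genome):
        _fasta, _gff, _manifest, genome, genes = fixture_genome
        for gene in genes:
            cds = coding_sequence(gene, genome)
            assert len(cds) == 3 * gene.codon_count
            # generator builds internally stop-free CDSs
            assert first_stop_index(cds) == gene.codon_count - 1


class TestGenBank:
    GB = "\n".join(
        [
            "LOCUS       test1                     30 bp    DNA     circular BCT 01-JAN-2000",
            "FEATURES             Location/Qualifiers",
            "     CDS             3..11",
            '                     /locus_tag="t_0001"',
            "     CDS             complement(13..21)",
            '                     /locus_tag="t_0002"',
            "ORIGIN",
            "        1 atatgaaata acccatggga tttaaatata",
            "//",
            "",
        ]
    )

    def test_genbank_cds_mapping(self):
        records, genes = load_genbank(self.GB)
        (rec,) = records
        assert rec.topology == "circular"
        assert len(rec) == 30
        g1, g2 = genes
        assert (g1.gene_id, g1.strand, g1.cds_intervals) == ("t_0001", "+", ((2, 11),))
        assert (g2.gene_id, g2.strand, g2.cds_intervals) == ("t_0002", "-", ((12, 21),))
        assert coding_sequence(g2, records) == revcomp(rec.sequence[12:21])
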