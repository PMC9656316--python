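import logging

import pytest

from scubkit.annotation_io import (
    GenomeSource,
    TranscriptModel,
    assign_codons,
    filter_cds,
    load_codon_records,
    load_transcripts,
    write_filter_report,
)

from _oracle import revcomp, splice_and_scan
from conftest import write_genome


def simple_transcript(cds, exon_lengths=None, gene_id="g1"):
    exon_lengths = exon_lengths or [len(cds)]
    assert sum(exon_lengths) == len(cds)
    exons, pos = [], 0
    for length in exon_lengths:
        exons.append((pos, pos + length))
        pos += length
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chromosome="chr1",
        strand="+",
        coding_exons=tuple(exons),
        cds_sequence=cds,
    )


class TestLoadTranscripts:
    def test_plus_strand_coordinate_convention(self, tmp_path):
        # CDS feature 11..19 (1-based inclusive) -> characters 10..19 half-open
        chrom = "C" * 10 + "ATGAAATAA" + "GGGG"
        gff = (
            "chr1\tsrc\tgene\t11\t19\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t11\t19\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\tCDS\t11\t19\t.\t+\t0\tID=c1;Parent=t1\n"
        )
        (t,) = load_transcripts(write_genome(tmp_path, {"chr1": chrom}, gff))
        assert t.cds_sequence == chrom[10:19] == "ATGAAATAA"
        assert t.exon_count == 1 and t.intron_count == 0

    def test_first_mrna_in_document_order_wins(self, tmp_path):
        chrom = "ATGAAATAA" + "ATGCCCTGA"
        gff = (
            "chr1\tsrc\tgene\t1\t18\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t9\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\tmRNA\t10\t18\t.\t+\t.\tID=t2;Parent=g1\n"
            "chr1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=c1;Parent=t1\n"
            "chr1\tsrc\tCDS\t10\t18\t.\t+\t0\tID=c2;Parent=t2\n"
        )
        (t,) = load_transcripts(write_genome(tmp_path, {"chr1": chrom}, gff))
        assert t.transcript_id == "t1"
        assert t.cds_sequence == "ATGAAATAA"

    def test_minus_strand_two_exons_matches_revcomp_oracle(self, tmp_path):
        # 30-nt CDS split 13 + 17 with a 10-nt intron, placed on minus strand
        cds = "ATGGCTGCAAGCGTATTCACGTCATGGTAA"
        exon1_t, exon2_t = cds[:13], cds[13:]
        intron = "GTAAAAAAAG"  # content irrelevant to splicing
        region = exon1_t + intron + exon2_t
        offset = 5
        genomic = "T" * offset + revcomp(region) + "T" * 3
        L = len(region)
        # exon1 (transcript order) sits at the region's 5' end -> genomic 3' end
        e1 = (offset + L - 13 + 1, offset + L)          # 1-based inclusive
        e2 = (offset + 1, offset + len(exon2_t))
        gff = (
            f"chr1\tsrc\tgene\t{e2[0]}\t{e1[1]}\t.\t-\t.\tID=g1\n"
            f"chr1\tsrc\tmRNA\t{e2[0]}\t{e1[1]}\t.\t-\t.\tID=t1;Parent=g1\n"
            f"chr1\tsrc\tCDS\t{e2[0]}\t{e2[1]}\t.\t-\t2\tID=c;Parent=t1\n"
            f"chr1\tsrc\tCDS\t{e1[0]}\t{e1[1]}\t.\t-\t0\tID=c;Parent=t1\n"
        )
        (t,) = load_transcripts(write_genome(tmp_path, {"chr1": genomic}, gff))
        # oracle: reverse complement of concatenated exon pieces taken in
        # descending genomic coordinate order
        pieces = [genomic[e1[0] - 1 : e1[1]], genomic[e2[0] - 1 : e2[1]]]
        assert t.cds_sequence == "".join(revcomp(p) for p in pieces) == cds
        assert t.strand == "-"
        assert t.coding_exons[0][0] > t.coding_exons[1][0]  # descending order

    def test_gene_without_cds_skipped_with_warning(self, tmp_path, caplog):
        gff = (
            "chr1\tsrc\tgene\t1\t9\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t9\t.\t+\t.\tID=t1;Parent=g1\n"
        )
        with caplog.at_level(logging.WARNING):
            transcripts = load_transcripts(write_genome(tmp_path, {"chr1": "ATGAAATAA"}, gff))
        assert transcripts == []
        assert "no CDS" in caplog.text

    def test_missing_sequence_region_is_hard_error(self, tmp_path):
        gff = (
            "chr9\tsrc\tgene\t1\t9\t.\t+\t.\tID=g1\n"
            "chr9\tsrc\tmRNA\t1\t9\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr9\tsrc\tCDS\t1\t9\t.\t+\t0\tID=c;Parent=t1\n"
        )
        with pytest.raises(ValueError, match="chr9"):
            load_transcripts(write_genome(tmp_path, {"chr1": "ATGAAATAA"}, gff))

    def test_malformed_line_reports_line_number(self, tmp_path):
        gff = "chr1\tsrc\tgene\t1\t9\n"  # five fields only
        with pytest.raises(ValueError, match=":2"):
            load_transcripts(write_genome(tmp_path, {"chr1": "ATGAAATAA"}, gff))

    def test_soft_masked_fasta_is_case_folded(self, tmp_path):
        gff = (
            "chr1\tsrc\tgene\t1\t9\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t9\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=c;Parent=t1\n"
        )
        (t,) = load_transcripts(write_genome(tmp_path, {"chr1": "atgaaataa"}, gff))
        assert t.cds_sequence == "ATGAAATAA"


class TestFilterCds:
    @pytest.mark.parametrize(
        "cds,outcome,reason",
        [
            ("ATGAAATAA", "retained", "none"),
            ("GTGAAATAA", "rejected", "bad_start"),
            ("ATGAANTAA", "rejected", "contains_N"),
            ("ATGAAATTT", "rejected", "bad_stop"),
            ("ATGAAATA", "rejected", "not_multiple_of_three"),
            ("", "rejected", "not_multiple_of_three"),
            ("ATGAAATAG", "retained", "none"),
            ("ATGAAATGA", "retained", "none"),
        ],
    )
    def test_examples(self, cds, outcome, reason):
        t = TranscriptModel(
            gene_id="g", transcript_id="t", chromosome="chr1", strand="+",
            coding_exons=((0, len(cds)),) if cds else ((0, 0),),
            cds_sequence=cds,
        )
        report = filter_cds(t)
        assert (report.outcome, report.reason) == (outcome, reason)

    def test_reason_order_length_beats_n(self):
        # both rules violated; length violation is reported first
        t = simple_transcript("ATGN")
        assert filter_cds(t).reason == "not_multiple_of_three"

    def test_reason_order_n_beats_start(self):
        t = simple_transcript("NTGAAATAA")
        assert filter_cds(t).reason == "contains_N"


class TestAssignCodons:
    def test_single_exon_all_ordinal_one(self):
        records = assign_codons(simple_transcript("ATGGCTGCAAAATAA"))
        assert [r.exon_ordinal for r in records] == [1] * 5

    def test_phase1_split_goes_downstream(self):
        # exons 7 + 8 nt: break between codon 3's 1st and 2nd nucleotide
        records = assign_codons(simple_transcript("ATGGCAAAATGTTAA", [7, 8]))
        assert [r.exon_ordinal for r in records] == [1, 1, 2, 2, 2]

    def test_phase2_split_goes_upstream(self):
        # exons 8 + 7 nt: break between codon 3's 2nd and 3rd nucleotide
        records = assign_codons(simple_transcript("ATGGCAAAATGTTAA", [8, 7]))
        assert [r.exon_ordinal for r in records] == [1, 1, 1, 2, 2]

    def test_boundary_after_first_nt_of_codon_5(self):
        records = assign_codons(simple_transcript("ATGGCAAAATGTTAA", [13, 2]))
        assert records[4].exon_ordinal == 2
        assert [r.exon_ordinal for r in records[:4]] == [1, 1, 1, 1]

    def test_next_first_base_chain(self):
        records = assign_codons(simple_transcript("ATGGCTTAA"))
        assert [r.next_first_base for r in records] == ["G", "T", None]
        assert [r.codon for r in records] == ["ATG", "GCT", "TAA"]
        assert records[-1].is_stop and records[0].is_start

    def test_exon_ordinal_counts_sum_to_codon_count(self):
        records = assign_codons(simple_transcript("ATGGCAAAATGTTAA", [7, 8]))
        assert len(records) == 5

    def test_cumulative_length_oracle(self):
        """Walk the spliced sequence nucleotide by nucleotide and assign each
        codon to the exon of its middle base; compare with assign_codons."""
        cds = "ATGGCAGCTAAAGGGTGTCCCTAA"
        lengths = [5, 7, 4, 8]
        exon_of_nt = []
        for idx, length in enumerate(lengths):
            exon_of_nt.extend([idx + 1] * length)
        expected = [exon_of_nt[3 * i + 1] for i in range(len(cds) // 3)]
        records = assign_codons(simple_transcript(cds, lengths))
        assert [r.exon_ordinal for r in records] == expected


class TestOracleEquivalence:
    def test_cds_and_ordinals_match_naive_splice_scan(self, oracle_genome, oracle_records):
        _, genome, source = oracle_genome
        records, reports = oracle_records
        oracle = splice_and_scan(source.fasta_path, source.gff3_path)
        assert len(oracle) == len(genome.manifest.genes)
        by_gene = {}
        for rec in records:
            by_gene.setdefault(rec.gene_id, []).append(rec)
        for gene in genome.manifest.genes:
            seq, ordinals = oracle[gene["gene_id"]]
            assert seq == gene["cds"]
            recs = sorted(by_gene[gene["gene_id"]], key=lambda r: r.ordinal)
            assert "".join(r.codon for r in recs) == seq
            assert [r.exon_ordinal for r in recs] == ordinals

    def test_no_internal_stop_in_retained_transcripts(self, oracle_genome):
        _, _, source = oracle_genome
        for t in load_transcripts(source):
            if filter_cds(t).outcome == "retained":
                protein = t.cds_sequence
                from scubkit.codon_stats import GENETIC_CODE
                aa = GENETIC_CODE.translate(protein)
                assert "*" not in aa[:-1]
                assert aa[-1] == "*"

    def test_filter_report_roundtrip(self, oracle_records, tmp_path):
        _, reports = oracle_records
        path = tmp_path / "report.tsv"
        write_filter_report(reports, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "gene_id\ttranscript_id\toutcome\treason"
        assert len(lines) == len(reports) + 1
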