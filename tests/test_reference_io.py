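"""Format readers/writers and coordinate conventions."""
import numpy as np
import pytest

from lofkit.models import GenomicInterval, TranscriptModel, VariantRecord
from lofkit.reference_io import (
    ReferenceSequence,
    coding_sequence,
    minimal_representation,
    read_coverage,
    read_methylation,
    read_transcripts,
    read_variants,
    write_coverage,
    write_fasta,
    write_gtf,
    write_methylation,
    write_vcf,
)


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fa"
    write_fasta({"chr_t": "ACGTACGT"}, path)
    return path


class TestReferenceSequence:
    def test_plus_strand_slice(self, toy_fasta):
        ref = ReferenceSequence(toy_fasta)
        assert ref.fetch("chr_t", 2, 5) == "GTA"

    def test_minus_strand_is_reverse_complement(self, toy_fasta):
        ref = ReferenceSequence(toy_fasta)
        assert ref.fetch("chr_t", 2, 5, strand="-") == "TAC"

    def test_out_of_bounds_query_errors(self, toy_fasta):
        ref = ReferenceSequence(toy_fasta)
        with pytest.raises(ValueError):
            ref.fetch("chr_t", 5, 9)

    def test_missing_contig_errors(self, toy_fasta):
        ref = ReferenceSequence(toy_fasta)
        with pytest.raises(KeyError):
            ref.fetch("chr_x", 0, 1)


def _two_exon_transcript(strand="+"):
    exons = [
        GenomicInterval("chr1", 10, 40, strand),
        GenomicInterval("chr1", 60, 90, strand),
    ]
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel(
        transcript_id=f"tx_{strand}",
        gene_id="g1",
        gene_symbol="G1",
        strand=strand,
        exons=tuple(exons),
        cds_intervals=tuple(exons),
        canonical=strand == "+",
    )


class TestGtf:
    def test_round_trip_preserves_models(self, tmp_path):
        """Writing transcripts to GTF and re-reading yields identical models."""
        path = tmp_path / "t.gtf"
        originals = [_two_exon_transcript("+"), _two_exon_transcript("-")]
        write_gtf(originals, path)
        loaded = {t.transcript_id: t for t in read_transcripts(path)}
        assert len(loaded) == 2
        for orig in originals:
            got = loaded[orig.transcript_id]
            assert got.exons == orig.exons
            assert got.cds_intervals == orig.cds_intervals
            assert got.strand == orig.strand
            assert got.gene_id == orig.gene_id

    def test_minus_strand_exons_in_transcript_order(self, tmp_path):
        path = tmp_path / "t.gtf"
        write_gtf([_two_exon_transcript("-")], path)
        (t,) = read_transcripts(path)
        starts = [e.start for e in t.exons]
        assert starts == sorted(starts, reverse=True)

    def test_fallback_canonical_longest_cds(self, tmp_path):
        """Untagged genes designate the longest-CDS transcript canonical."""
        path = tmp_path / "t.gtf"
        a = _two_exon_transcript("-")  # written without canonical tag
        write_gtf([a], path)
        (t,) = read_transcripts(path)
        assert t.canonical

    def test_empty_gtf_errors(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        with pytest.raises(ValueError):
            read_transcripts(path)


def test_incomplete_cds_flagged():
    exon = GenomicInterval("chr1", 0, 10, "+")
    t = TranscriptModel("tx", "g", "G", "+", (exon,), (exon,))
    assert t.cds_length == 10
    assert t.cds_incomplete


class TestVcf:
    def _write(self, tmp_path, body):
        path = tmp_path / "in.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##INFO=<ID=AC,Number=A,Type=Integer,Description="x">\n'
            '##INFO=<ID=AN,Number=1,Type=Integer,Description="x">\n'
            '##INFO=<ID=nhomalt,Number=A,Type=Integer,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        path.write_text(header + body)
        return path

    def test_allele_frequency(self, tmp_path):
        path = self._write(tmp_path, "chr1\t5\t.\tA\tG\t.\tPASS\tAC=1;AN=20000\n")
        (v,) = read_variants(path)
        assert v.allele_frequency == pytest.approx(5e-5)
        assert v.n_homalt == 0

    def test_multiallelic_split(self, tmp_path):
        path = self._write(tmp_path, "chr1\t5\t.\tA\tG,T\t.\tPASS\tAC=3,2;AN=100\n")
        variants = read_variants(path)
        assert [(v.alt, v.allele_count) for v in variants] == [("G", 3), ("T", 2)]

    def test_indel_normalised_to_minimal_representation(self, tmp_path):
        path = self._write(tmp_path, "chr1\t100\t.\tCTT\tCT\t.\tPASS\tAC=1;AN=100\n")
        (v,) = read_variants(path)
        assert (v.pos, v.ref, v.alt) == (100, "CT", "C")

    def test_ac_above_an_rejected(self, tmp_path):
        path = self._write(tmp_path, "chr1\t5\t.\tA\tG\t.\tPASS\tAC=200;AN=100\n")
        assert read_variants(path) == []

    def test_site_filters_propagated(self, tmp_path):
        path = self._write(tmp_path, "chr1\t5\t.\tA\tG\t.\tRF\tAC=1;AN=100\n")
        (v,) = read_variants(path)
        assert v.site_filters == {"RF"}
        assert not v.passes_filters

    def test_write_read_round_trip(self, tmp_path):
        records = [
            VariantRecord("chr1", 5, "A", "G", 3, 100, n_homalt=1),
            VariantRecord("chr1", 9, "AT", "A", 2, 100),
        ]
        out = tmp_path / "out.vcf"
        write_vcf(records, {"chr1": 1000}, out)
        back = read_variants(out)
        assert [v.key for v in back] == [v.key for v in records]
        assert [v.allele_count for v in back] == [3, 2]
        assert back[0].n_homalt == 1


@pytest.mark.parametrize(
    "pos,ref,alt,expected",
    [
        (100, "CTT", "CT", (100, "CT", "C")),
        (100, "C", "T", (100, "C", "T")),
        (100, "ACGT", "AT", (100, "ACG", "A")),
        (100, "TAC", "TGC", (101, "A", "G")),
    ],
)
def test_minimal_representation(pos, ref, alt, expected):
    assert minimal_representation(pos, ref, alt) == expected


class TestCodingSequence:
    def _ref(self, tmp_path, seq):
        path = tmp_path / "r.fa"
        write_fasta({"c": seq}, path)
        return ReferenceSequence(path)

    def test_plus_strand_concatenation(self, tmp_path):
        seq = "ATGAAACCCCTTTTAAGGGG"
        ref = self._ref(tmp_path, seq)
        ivs = (GenomicInterval("c", 0, 6, "+"), GenomicInterval("c", 10, 16, "+"))
        t = TranscriptModel("t", "g", "G", "+", ivs, ivs)
        assert coding_sequence(t, ref) == seq[0:6] + seq[10:16]
        assert len(coding_sequence(t, ref)) == t.cds_length

    def test_minus_strand_is_reverse_complement_of_plus(self, tmp_path):
        from lofkit.models import revcomp

        seq = "ATGAAACCCCTTTTAAGGGG"
        ref = self._ref(tmp_path, seq)
        plus_ivs = (GenomicInterval("c", 0, 6, "+"), GenomicInterval("c", 10, 16, "+"))
        plus = TranscriptModel("t", "g", "G", "+", plus_ivs, plus_ivs)
        minus_ivs = (GenomicInterval("c", 10, 16, "-"), GenomicInterval("c", 0, 6, "-"))
        minus = TranscriptModel("t2", "g", "G", "-", minus_ivs, minus_ivs)
        assert coding_sequence(minus, ref) == revcomp(coding_sequence(plus, ref))

    def test_incomplete_cds_returned_with_flag(self, tmp_path):
        ref = self._ref(tmp_path, "ATGAAACCCC")
        ivs = (GenomicInterval("c", 0, 10, "+"),)
        t = TranscriptModel("t", "g", "G", "+", ivs, ivs)
        assert coding_sequence(t, ref) == "ATGAAACCCC"
        assert t.cds_incomplete


class TestTracks:
    def test_coverage_round_trip_and_uncovered_sentinel(self, tmp_path):
        from lofkit.models import CoverageTrack

        track = CoverageTrack()
        track.set_interval("c1", 0, 50, 35.0)
        track.set_interval("c1", 50, 80, 12.5)
        path = tmp_path / "cov.tsv"
        write_coverage(track, path)
        back = read_coverage(path)
        assert back.get("c1", 10) == 35.0
        assert back.get("c1", 60) == 12.5
        assert np.isnan(back.get("c1", 500))
        assert np.isnan(back.get("c2", 0))

    def test_methylation_round_trip(self, tmp_path):
        from lofkit.models import PositionTrack

        track = PositionTrack()
        track.set("c1", 7, 0.85)
        path = tmp_path / "meth.tsv"
        write_methylation(track, path)
        back = read_methylation(path)
        assert back.get("c1", 7) == pytest.approx(0.85)
        assert back.get("c1", 8) == 0.0
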