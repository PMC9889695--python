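"""Genome/annotation reading and strand-aware promoter extraction."""

import pytest
from Bio.Seq import Seq

from crescan.genome_io import (
    FormatError,
    GeneModel,
    extract_promoter,
    read_fasta,
    read_gene_annotations,
    read_gene_labels,
    attach_labels,
    write_promoters_fasta,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_single_record(self, tmp_path):
        path = _write(tmp_path, "g.fa", ">chr1\nACGT\n")
        assert read_fasta(path) == {"chr1": "ACGT"}

    def test_case_fold_whitespace_and_n_mapping(self, tmp_path):
        path = _write(tmp_path, "g.fa", ">a\nacg t\nn\n")
        assert read_fasta(path) == {"a": "ACGTN"}

    def test_non_acgtn_mapped_to_n_with_warning(self, tmp_path, caplog):
        path = _write(tmp_path, "g.fa", ">a\nACGU\n")
        with caplog.at_level("WARNING"):
            assert read_fasta(path) == {"a": "ACGN"}
        assert "non-ACGTN" in caplog.text

    def test_duplicate_id_error(self, tmp_path):
        path = _write(tmp_path, "g.fa", ">a\nAC\n>a\nGG\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(path)

    def test_empty_file_error(self, tmp_path):
        path = _write(tmp_path, "g.fa", "")
        with pytest.raises(FormatError):
            read_fasta(path)


GFF = (
    "##gff-version 3\n"
    "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
    "chr1\tsrc\tgene\t1001\t2000\t.\t-\t.\tID=g2\n"
)


class TestAnnotations:
    def test_gff3_plus_strand_tss_is_zero_based_start(self, tmp_path):
        genes = read_gene_annotations(_write(tmp_path, "a.gff3", GFF), "gff3")
        g1 = next(g for g in genes if g.gene_id == "g1")
        assert (g1.chrom, g1.strand, g1.tss) == ("chr1", "+", 1000)

    def test_gff3_minus_strand_tss_is_three_prime_end(self, tmp_path):
        genes = read_gene_annotations(_write(tmp_path, "a.gff3", GFF), "gff3")
        g2 = next(g for g in genes if g.gene_id == "g2")
        assert (g2.strand, g2.tss) == ("-", 1999)

    def test_bed_tss_conventions(self, tmp_path):
        bed = "chr1\t100\t200\tgp\t0\t+\nchr1\t100\t200\tgm\t0\t-\n"
        genes = read_gene_annotations(_write(tmp_path, "a.bed", bed), "bed")
        tss = {g.gene_id: g.tss for g in genes}
        assert tss == {"gp": 100, "gm": 199}

    def test_bed_unknown_strand_error(self, tmp_path):
        bed = "chr1\t100\t200\tg1\t0\t.\n"
        with pytest.raises(FormatError, match="strand"):
            read_gene_annotations(_write(tmp_path, "a.bed", bed), "bed")

    def test_bed_missing_columns_error(self, tmp_path):
        with pytest.raises(FormatError, match="columns"):
            read_gene_annotations(_write(tmp_path, "a.bed", "chr1\t100\t200\n"), "bed")

    def test_duplicate_gene_id_error(self, tmp_path):
        gff = GFF + "chr1\tsrc\tgene\t3001\t4000\t.\t+\t.\tID=g1_x\n"
        # gffutils renames true duplicates; force one via two identical IDs
        dup = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=g1\n"
            "chr2\tsrc\tgene\t1\t10\t.\t+\t.\tID=g1\n"
        )
        bed = "chr1\t0\t10\tg1\t0\t+\nchr2\t0\t10\tg1\t0\t+\n"
        with pytest.raises(FormatError, match="duplicate"):
            read_gene_annotations(_write(tmp_path, "dup.bed", bed), "bed")

    def test_labels_roundtrip_and_attach(self, tmp_path):
        labels = read_gene_labels(_write(tmp_path, "l.tsv", "g1\tup\ng2\tdown\n"))
        assert labels == {"g1": "up", "g2": "down"}
        genes = [GeneModel("g1", "chr1", "+", 5), GeneModel("g3", "chr1", "+", 9)]
        labeled = attach_labels(genes, labels)
        assert [g.label for g in labeled] == ["up", "none"]

    def test_bad_label_error(self, tmp_path):
        with pytest.raises(FormatError, match="label"):
            read_gene_labels(_write(tmp_path, "l.tsv", "g1\tsideways\n"))


@pytest.fixture
def genome_10kb():
    # deterministic non-repetitive 10-kb chromosome
    bases = "ACGT"
    seq = "".join(bases[(i * i + i // 7) % 4] for i in range(10000))
    return {"chr1": seq}


class TestExtractPromoter:
    def test_plus_strand_window_arithmetic(self, genome_10kb):
        p = extract_promoter(genome_10kb, GeneModel("g", "chr1", "+", 5000), 3000)
        assert (p.start, p.end) == (2000, 5000)
        assert len(p.sequence) == 3000 and not p.truncated
        assert p.sequence == genome_10kb["chr1"][2000:5000]

    def test_plus_strand_last_base_abuts_tss(self, genome_10kb):
        p = extract_promoter(genome_10kb, GeneModel("g", "chr1", "+", 5000), 3000)
        assert p.sequence[-1] == genome_10kb["chr1"][4999]

    def test_minus_strand_reverse_complement(self, genome_10kb):
        p = extract_promoter(genome_10kb, GeneModel("g", "chr1", "-", 5000), 3000)
        assert (p.start, p.end) == (5001, 8001)
        expected = str(Seq(genome_10kb["chr1"][5001:8001]).reverse_complement())
        assert p.sequence == expected

    def test_plus_strand_clipping(self, genome_10kb):
        p = extract_promoter(genome_10kb, GeneModel("g", "chr1", "+", 1000), 3000)
        assert (p.start, p.end) == (0, 1000)
        assert len(p.sequence) == 1000 and p.truncated

    def test_minus_strand_clipping(self, genome_10kb):
        p = extract_promoter(genome_10kb, GeneModel("g", "chr1", "-", 9000), 3000)
        assert (p.start, p.end) == (9001, 10000)
        assert len(p.sequence) == 999 and p.truncated

    def test_zero_length_promoter_flagged(self, genome_10kb):
        p = extract_promoter(genome_10kb, GeneModel("g", "chr1", "+", 0), 3000)
        assert p.sequence == "" and p.truncated

    def test_missing_chromosome_error(self, genome_10kb):
        with pytest.raises(KeyError, match="chrX"):
            extract_promoter(genome_10kb, GeneModel("g", "chrX", "+", 10), 100)

    def test_default_window_is_3kb(self, genome_10kb):
        p = extract_promoter(genome_10kb, GeneModel("g", "chr1", "+", 9000))
        assert p.requested_length == 3000 and len(p.sequence) == 3000

    @pytest.mark.parametrize("strand,tss", [("+", 4321), ("-", 4321), ("+", 800), ("-", 9500)])
    def test_mirror_roundtrip(self, genome_10kb, strand, tss):
        """Extracting from the reverse-complemented genome with the mirrored
        gene model yields the identical promoter string."""
        n = len(genome_10kb["chr1"])
        mirrored_genome = {"chr1": str(Seq(genome_10kb["chr1"]).reverse_complement())}
        gene = GeneModel("g", "chr1", strand, tss)
        mirror = GeneModel("g", "chr1", "-" if strand == "+" else "+", n - 1 - tss)
        a = extract_promoter(genome_10kb, gene, 500)
        b = extract_promoter(mirrored_genome, mirror, 500)
        assert a.sequence == b.sequence and a.truncated == b.truncated

    @pytest.mark.parametrize("tss,length", [(5000, 3000), (100, 3000), (9999, 50)])
    def test_length_plus_clipped_equals_requested(self, genome_10kb, tss, length):
        for strand in "+-":
            p = extract_promoter(genome_10kb, GeneModel("g", "chr1", strand, tss), length)
            clipped = length - len(p.sequence)
            assert clipped >= 0 and len(p.sequence) + clipped == length


def test_write_promoters_fasta_headers(tmp_path, genome_10kb):
    p = extract_promoter(genome_10kb, GeneModel("g1", "chr1", "+", 1000), 3000)
    out = tmp_path / "prom.fa"
    write_promoters_fasta([p], out)
    header = out.read_text().splitlines()[0]
    assert header == ">g1 window=chr1:1-1000(+) truncated=1"
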