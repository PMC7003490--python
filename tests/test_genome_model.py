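import textwrap

import numpy as np
import pytest

from chromgex import genome_model as gm


def _write(tmp_path, name, content):
    p = tmp_path / name
    p.write_text(textwrap.dedent(content).lstrip())
    return p


class TestGTF:
    GTF = """
    chr1\tsrc\tgene\t101\t2000\t.\t+\t.\tgene_id "G1"; gene_type "protein_coding";
    chr1\tsrc\ttranscript\t101\t2000\t.\t+\t.\tgene_id "G1"; gene_type "protein_coding";
    chr1\tsrc\ttranscript\t301\t2000\t.\t+\t.\tgene_id "G1"; gene_type "protein_coding";
    chr1\tsrc\tgene\t5001\t7000\t.\t-\t.\tgene_id "G2"; gene_type "protein_coding";
    chr1\tsrc\ttranscript\t5001\t6500\t.\t-\t.\tgene_id "G2"; gene_type "protein_coding";
    chr1\tsrc\ttranscript\t5001\t7000\t.\t-\t.\tgene_id "G2"; gene_type "protein_coding";
    chr2\tsrc\tgene\t1001\t3000\t.\t+\t.\tgene_id "G3"; gene_type "lincRNA";
    """

    def test_biotype_filter_and_coordinate_shift(self, tmp_path):
        path = _write(tmp_path, "a.gtf", self.GTF)
        genes = gm.read_gene_annotation(path, "protein_coding")
        assert {g.gene_id for g in genes} == {"G1", "G2"}
        g1 = next(g for g in genes if g.gene_id == "G1")
        assert g1.start == 100  # GTF start 101 -> 0-based 100
        assert g1.end == 2000

    def test_no_filter_keeps_all(self, tmp_path):
        path = _write(tmp_path, "a.gtf", self.GTF)
        assert len(gm.read_gene_annotation(path, None)) == 3

    def test_most_5prime_tss_per_strand(self, tmp_path):
        path = _write(tmp_path, "a.gtf", self.GTF)
        genes = {g.gene_id: g for g in gm.read_gene_annotation(path, None)}
        assert genes["G1"].tss == 100  # min transcript start on +
        assert genes["G2"].tss == 7000  # max transcript end on -

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = _write(tmp_path, "bad.gtf", "chr1\tonly\tthree\n")
        with pytest.raises(gm.ParseError, match="bad.gtf:1"):
            gm.read_gene_annotation(path)

    def test_empty_result_warns(self, tmp_path):
        path = _write(tmp_path, "a.gtf", self.GTF)
        with pytest.warns(UserWarning, match="no genes"):
            gm.read_gene_annotation(path, "snoRNA")


def test_most_5prime_tss_requires_transcripts():
    g = gm.Gene("G", "chr1", "+", 0, 10, transcript_starts=())
    with pytest.raises(ValueError, match="no transcripts"):
        gm.most_5prime_tss(g)


def test_most_5prime_tss_single_transcript_any_strand():
    plus = gm.Gene("a", "chr1", "+", 5, 100, transcript_starts=(5,))
    minus = gm.Gene("b", "chr1", "-", 5, 100, transcript_starts=(100,))
    assert plus.tss == 5 and minus.tss == 100


class TestPeaks:
    def test_narrowpeak_signal_column(self, tmp_path):
        path = _write(tmp_path, "p.narrowPeak",
                      "chr1\t100\t300\tpeak1\t50\t.\t7.5\t-1\t-1\t-1\n")
        (peak,) = gm.read_peaks(path)
        assert peak.signal == 7.5
        assert peak.interval == gm.GenomicInterval("chr1", 100, 300)

    def test_bed3_defaults_signal_zero_with_warning(self, tmp_path):
        path = _write(tmp_path, "p.bed", "chr1\t100\t300\n")
        with pytest.warns(UserWarning, match="signal"):
            (peak,) = gm.read_peaks(path)
        assert peak.signal == 0.0

    def test_inverted_record_rejected_and_counted(self, tmp_path):
        path = _write(tmp_path, "p.bed",
                      "chr1\t300\t100\tx\t0\t.\t1\n" "chr1\t100\t300\ty\t0\t.\t2\n")
        with pytest.warns(UserWarning, match="1 malformed"):
            peaks = gm.read_peaks(path)
        assert len(peaks) == 1

    def test_non_numeric_signal_raises(self, tmp_path):
        path = _write(tmp_path, "p.bed", "chr1\t1\t2\tx\t0\t.\toops\n")
        with pytest.raises(gm.ParseError, match="non-numeric signal"):
            gm.read_peaks(path)


class TestLoops:
    BEDPE = (
        "chr1\t1000\t2000\tchr1\t50000\t51000\t5kb\t5\t0.01\n"
        "chr1\t3000\t4000\tchr2\t50000\t51000\t5kb\t3\t0.01\n"
        "chr2\t1000\t2000\tchr2\t90000\t91000\t10kb\t1\t0.2\n"
        "chr2\t5000\t6000\tchr2\t70000\t71000\t10kb\t2\t0.01\n"
    )

    def test_interchromosomal_excluded(self, tmp_path):
        path = _write(tmp_path, "l.bedpe", self.BEDPE)
        with pytest.warns(UserWarning, match="inter-chromosomal"):
            loops = gm.read_loops(path)
        assert len(loops) == 3
        assert all(l.anchor1.chrom == l.anchor2.chrom for l in loops)

    def test_pet_threshold(self, tmp_path):
        path = _write(tmp_path, "l.bedpe", self.BEDPE)
        with pytest.warns(UserWarning):
            loops = gm.read_loops(path, pet_min=2)
        assert len(loops) == 2
        assert all(l.pet_count >= 2 for l in loops)

    def test_resolution_all_keeps_every_resolution(self, tmp_path):
        path = _write(tmp_path, "l.bedpe", self.BEDPE)
        with pytest.warns(UserWarning):
            every = gm.read_loops(path, resolution_filter="All")
            only5 = gm.read_loops(path, resolution_filter="5kb")
        assert len(every) == 3 and len(only5) == 1

    def test_pet_min_without_pet_column_raises(self, tmp_path):
        path = _write(tmp_path, "l.bedpe", "chr1\t1\t2\tchr1\t10\t20\n")
        with pytest.raises(gm.ParseError, match="PET column"):
            gm.read_loops(path, pet_min=1)

    def test_q_value_filter(self, tmp_path):
        path = _write(tmp_path, "l.bedpe", self.BEDPE)
        with pytest.warns(UserWarning):
            loops = gm.read_loops(path, q_max=0.05)
        assert len(loops) == 2


class TestChromHMM:
    def test_bookended_same_state_merged(self, tmp_path):
        path = _write(tmp_path, "s.bed", "chr1\t0\t200\tEnh\nchr1\t200\t400\tEnh\n")
        (seg,) = gm.read_chromhmm(path)
        assert (seg.interval.start, seg.interval.end) == (0, 400)

    def test_gap_keeps_two_segments(self, tmp_path):
        path = _write(tmp_path, "s.bed", "chr1\t0\t200\tEnh\nchr1\t300\t400\tEnh\n")
        assert len(gm.read_chromhmm(path)) == 2

    def test_state_filter(self, tmp_path):
        path = _write(tmp_path, "s.bed", "chr1\t0\t200\tEnh\nchr1\t300\t400\tTssA\n")
        segs = gm.read_chromhmm(path, kept_states={"TssA"})
        assert [s.state for s in segs] == ["TssA"]

    def test_unknown_states_listed_in_error(self, tmp_path):
        path = _write(tmp_path, "s.bed", "chr1\t0\t200\tEnh\n")
        with pytest.raises(gm.ParseError, match="Enh"):
            gm.read_chromhmm(path, kept_states={"NoSuchState"})


class TestPSEM:
    def test_length_recorded(self, tmp_path):
        rows = "\n".join("0 1 2 3" for _ in range(11))
        path = _write(tmp_path, "m.psem", f">TFX\n{rows}\n")
        (m,) = gm.read_psems(path)
        assert m.length == 11 and m.tf_name == "TFX"

    def test_duplicate_names_disambiguated(self, tmp_path):
        path = _write(tmp_path, "m.psem", ">A\n0 1 1 1\n>A\n1 0 1 1\n")
        with pytest.warns(UserWarning, match="duplicate"):
            psems = gm.read_psems(path)
        assert [m.tf_name for m in psems] == ["A", "A.1"]

    def test_empty_file_warns(self, tmp_path):
        path = _write(tmp_path, "m.psem", "")
        with pytest.warns(UserWarning, match="no PSEMs"):
            assert gm.read_psems(path) == []

    def test_short_row_raises(self, tmp_path):
        path = _write(tmp_path, "m.psem", ">A\n0 1 1\n")
        with pytest.raises(gm.ParseError, match="4 values"):
            gm.read_psems(path)


def test_interval_invariants():
    with pytest.raises(ValueError):
        gm.GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        gm.GenomicInterval("chr1", -1, 10)
    a = gm.GenomicInterval("chr1", 0, 10)
    b = gm.GenomicInterval("chr1", 9, 20)
    assert a.overlaps(b) and b.overlaps(a)
    assert a.length == 10


def test_loop_rejects_interchromosomal_construction():
    with pytest.raises(ValueError):
        gm.ChromatinLoop(gm.GenomicInterval("chr1", 0, 10),
                         gm.GenomicInterval("chr2", 0, 10))


def test_chrom_style_mismatch_detected():
    with pytest.raises(ValueError, match="naming styles differ"):
        gm.check_chrom_consistency(genes=["chr1", "chr2"], peaks=["1", "2"])
    gm.check_chrom_consistency(genes=["chr1"], peaks=["chr2"], loops=[])


def test_normalize_chrom_both_directions():
    assert gm.normalize_chrom("1", "chr") == "chr1"
    assert gm.normalize_chrom("chr1", "plain") == "1"
    assert gm.normalize_chrom("chrX", None) == "chrX"


def test_roundtrip_of_emitted_fixture_files(small_bundle_files):
    """Writing then re-reading every fixture file reproduces the records."""
    b = small_bundle_files
    genes = gm.read_gene_annotation(b.paths["annotation"], "protein_coding")
    assert sorted(g.gene_id for g in genes) == sorted(g.gene_id for g in b.genes)
    by_id = {g.gene_id: g for g in genes}
    for g in b.genes:
        r = by_id[g.gene_id]
        assert (r.chrom, r.strand, r.start, r.end) == (g.chrom, g.strand, g.start, g.end)
        assert r.tss == g.tss

    peaks = gm.read_peaks(b.paths["peaks"])
    got = sorted(peaks, key=lambda p: (p.interval, p.signal))
    want = sorted(b.peaks, key=lambda p: (p.interval, p.signal))
    assert [p.interval for p in got] == [p.interval for p in want]
    assert np.allclose([p.signal for p in got], [p.signal for p in want], rtol=1e-4)

    loops = gm.read_loops(b.paths["loops"])
    assert len(loops) == len(b.loops)
    assert sorted(l.anchor_distance for l in loops) == sorted(
        l.anchor_distance for l in b.loops
    )

    segs = gm.read_chromhmm(b.paths["chromhmm"])
    assert len(segs) == len(b.segments)

    psems = gm.read_psems(b.paths["psems"])
    assert [m.tf_name for m in psems] == [m.tf_name for m in b.psems]
    assert all(abs(a - b_) < 1e-5
               for m1, m2 in zip(psems, b.psems)
               for r1, r2 in zip(m1.matrix, m2.matrix)
               for a, b_ in zip(r1, r2))

    expr = gm.read_expression(b.paths["expression"])
    assert set(expr) == set(b.expression)
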