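import gzip

import pytest

from hybpipe.formats import (AlignmentHit, ChimeraCall, DuplexResult,
                             FormatError, Fragment, SequenceRecord,
                             TranscriptDB, format_evalue,
                             parse_blast_tab, parse_collapse_metadata,
                             read_hyb, read_sequences, read_viennad,
                             write_fasta, write_fastq, write_hyb,
                             write_viennad)


# ---------------------------------------------------------------------------
# sequence records and collapse metadata
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("identifier,rank,n_bar,count", [
    ("44480_39", 44480, None, 39),
    ("1-2_3", 1, 2, 3),
    ("plainread", None, None, None),
    ("7_0x", None, None, None),
])
def test_collapse_metadata_parsing(identifier, rank, n_bar, count):
    assert parse_collapse_metadata(identifier) == (rank, n_bar, count)


def test_collapsed_id_round_trip():
    rec = SequenceRecord(id="", seq="ACGT", rank=44480, count=39)
    assert rec.collapsed_id == "44480_39"
    rec = SequenceRecord(id="", seq="ACGT", rank=1, n_barcodes=2, count=3)
    assert rec.collapsed_id == "1-2_3"


def test_fasta_reading_parses_collapse_metadata(tmp_path):
    p = tmp_path / "reads.fasta"
    p.write_text(">44480_39\nTGAGGTAG\n>1-2_3\nACGT\nACGT\n")
    recs = list(read_sequences(p))
    assert [r.rank for r in recs] == [44480, 1]
    assert [r.count for r in recs] == [39, 3]
    assert recs[0].n_barcodes is None and recs[1].n_barcodes == 2
    assert recs[1].seq == "ACGTACGT"  # multi-line sequences concatenate


def test_empty_file_yields_empty_stream(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    assert list(read_sequences(p)) == []


def test_fastq_round_trip_and_gzip(tmp_path):
    recs = [SequenceRecord(id="a", seq="ACGT", qual=[30, 31, 32, 33]),
            SequenceRecord(id="b", seq="GGTT", qual=[2, 2, 40, 40])]
    p = tmp_path / "r.fastq.gz"
    write_fastq(recs, p)
    with gzip.open(p, "rt") as fh:
        assert fh.readline() == "@a\n"
    back = list(read_sequences(p))
    assert [(r.id, r.seq, r.qual) for r in back] == \
        [(r.id, r.seq, r.qual) for r in recs]


def test_malformed_fastq_errors_name_line_numbers(tmp_path):
    p = tmp_path / "bad.fastq"
    p.write_text("@ok\nACGT\n+\nIIII\nnot_a_header\nACGT\n+\nIIII\n")
    with pytest.raises(FormatError, match="line 5"):
        list(read_sequences(p))
    p.write_text("@r\nACGT\n+\nIII\n")
    with pytest.raises(FormatError, match="quality length"):
        list(read_sequences(p))


def test_non_phred33_quality_rejected(tmp_path):
    p = tmp_path / "bad.fastq"
    p.write_text("@r\nACGT\n+\nII I\n")  # space is below Phred+33 zero
    with pytest.raises(FormatError, match="Phred"):
        list(read_sequences(p))


# ---------------------------------------------------------------------------
# blast tabular
# ---------------------------------------------------------------------------

BLAST_LINE = "r1\ttx1\t100.00\t22\t0\t0\t1\t22\t1\t22\t2e-04\t44.1"


def test_parse_blast_tab(tmp_path):
    p = tmp_path / "h.blast"
    p.write_text(BLAST_LINE + "\n" +
                 "r2\ttx2\t95.00\t20\t1\t0\t1\t20\t100\t80\t1e-05\t37.4\n")
    hits = list(parse_blast_tab(p))
    h = hits[0]
    assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 22, 1, 22)
    assert h.evalue == pytest.approx(2e-4)
    assert h.sense
    assert not hits[1].sense  # s_start > s_end marks antisense


def test_blast_tab_wrong_column_count(tmp_path):
    p = tmp_path / "h.blast"
    p.write_text("\t".join(BLAST_LINE.split("\t")[:11]) + "\n")
    with pytest.raises(FormatError, match="line 1"):
        list(parse_blast_tab(p))


def test_blast_tab_non_numeric_coordinate(tmp_path):
    p = tmp_path / "h.blast"
    fields = BLAST_LINE.split("\t")
    fields[6] = "x"
    p.write_text("\t".join(fields) + "\n")
    with pytest.raises(FormatError, match="line 1"):
        list(parse_blast_tab(p))


# ---------------------------------------------------------------------------
# .hyb
# ---------------------------------------------------------------------------

def _table3_like_call():
    return ChimeraCall(
        read_id="44480_39",
        read_seq="TGAGGTAGTAGGTTGTGTGGTTACCATCCAACGGCGCACGGGGC",
        dG=-12.1,
        frag1=Fragment("let-7b", 1, 22, 1, 22, 2e-4),
        frag2=Fragment("ACTB", 22, 44, 1614, 1636, 4e-5))


def test_hyb_write_matches_column_layout(tmp_path):
    p = tmp_path / "c.hyb"
    write_hyb([_table3_like_call()], p)
    cols = p.read_text().rstrip("\n").split("\t")
    assert len(cols) == 15
    assert cols[0] == "44480_39"
    assert cols[2] == "-12.1"
    assert cols[3:9] == ["let-7b", "1", "22", "1", "22", "2e-04"]
    assert cols[9:15] == ["ACTB", "22", "44", "1614", "1636", "4e-05"]


def test_hyb_round_trip_is_byte_identical(tmp_path):
    calls = [_table3_like_call(),
             ChimeraCall("1-2_3", "ACGTACGT",
                         frag1=Fragment("a_x_mRNA", 1, 4, 10, 13, 0.003),
                         frag2=Fragment("b_y_mRNA", 5, 8, 1, 4, 0.09),
                         annotation="source=test;")]
    p1, p2 = tmp_path / "a.hyb", tmp_path / "b.hyb"
    write_hyb(calls, p1)
    back = list(read_hyb(p1))
    write_hyb(back, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert back[0].dG == pytest.approx(-12.1)
    assert back[1].dG is None  # '.' restored as absent
    assert back[1].annotation == "source=test;"


def test_hyb_rejects_wrong_column_count(tmp_path):
    p = tmp_path / "bad.hyb"
    p.write_text("only\tthree\tcolumns\n")
    with pytest.raises(FormatError, match="line 1"):
        list(read_hyb(p))


def test_call_invariant_fragments_in_read_order():
    with pytest.raises(ValueError, match="read order"):
        ChimeraCall("r", "ACGT",
                    frag1=Fragment("a", 10, 12, 1, 3, 0.01),
                    frag2=Fragment("b", 1, 3, 1, 3, 0.01))


def test_antisense_fragment_round_trips_via_annotation(tmp_path):
    call = ChimeraCall("r1", "ACGTACGT",
                       frag1=Fragment("a_x_mRNA", 1, 4, 10, 13, 1e-3),
                       frag2=Fragment("b_y_mRNA", 5, 8, 1, 4, 1e-3,
                                      strand="-"))
    p = tmp_path / "anti.hyb"
    write_hyb([call], p)
    line = p.read_text()
    assert "strand2=-;" in line
    back = next(read_hyb(p))
    assert back.frag2.strand == "-"
    assert back.frag2.s_start <= back.frag2.s_end


# ---------------------------------------------------------------------------
# viennad
# ---------------------------------------------------------------------------

def test_viennad_block_layout_and_round_trip(tmp_path):
    call = _table3_like_call()
    duplex = DuplexResult(seq1="ACGGG", seq2="CCCGA",
                          structure="(((((&)))))", dG=-12.1)
    call.duplex = duplex
    p = tmp_path / "c.viennad"
    write_viennad([call], p)
    lines = p.read_text().rstrip("\n").split("\n")
    assert len(lines) == 6
    assert lines[0] == "44480_39"
    assert lines[1].split("\t") == ["ACGGG", "let-7b", "1", "22"]
    assert lines[3] == "ACGGG&CCCGA"
    assert lines[5] == "dG = -12.1 kcal/mol"  # same value as .hyb column 3
    block = next(read_viennad(p))
    assert block.duplex.structure == "(((((&)))))"
    assert block.duplex.dG == pytest.approx(-12.1)


def test_viennad_empty_input(tmp_path):
    p = tmp_path / "empty.viennad"
    write_viennad([], p)
    assert p.read_text() == ""
    assert list(read_viennad(p)) == []


def test_viennad_requires_duplex(tmp_path):
    with pytest.raises(ValueError, match="duplex"):
        write_viennad([_table3_like_call()], tmp_path / "x.viennad")


def test_duplex_result_validation():
    with pytest.raises(ValueError, match="structure length"):
        DuplexResult("ACGU", "ACGU", "((&))", -1.0)
    with pytest.raises(ValueError, match="unbalanced"):
        DuplexResult("ACGU", "ACGU", "((..&...)", -1.0)
    with pytest.raises(ValueError, match="dG"):
        DuplexResult("ACGU", "ACGU", "....&....", -1.0)


# ---------------------------------------------------------------------------
# transcript database
# ---------------------------------------------------------------------------

def test_db_header_biotype_convention(tmp_path):
    p = tmp_path / "db.fasta"
    p.write_text(">ENSG0_ENST0_ACTB_mRNA\nACGTACGT\n"
                 ">MIMAT0000062_hsa-let-7a_microRNA\nTGAGGTAG\n")
    db = TranscriptDB.from_fasta(p)
    actb = db["ENSG0_ENST0_ACTB_mRNA"]
    assert (actb.display_name, actb.biotype) == ("ACTB", "mRNA")
    mir = db["MIMAT0000062_hsa-let-7a_microRNA"]
    assert (mir.display_name, mir.biotype) == ("hsa-let-7a", "microRNA")
    assert db.total_length == 16


def test_db_subseq_is_one_based_inclusive(toy_db):
    assert toy_db.subseq("MIMAT0000062_hsa-let-7a_microRNA", 1, 4) == "TGAG"
    with pytest.raises(ValueError, match="out of range"):
        toy_db.subseq("MIMAT0000062_hsa-let-7a_microRNA", 1, 23)


def test_evalue_formatting_matches_blast_style():
    assert format_evalue(2e-4) == "2e-04"
    assert format_evalue(0.003) == "0.003"
    assert format_evalue(0.1) == "0.1"
    assert format_evalue(0) == "0"
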