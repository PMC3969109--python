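import random

import pytest

from hybpipe.align import align_reads, build_index
from hybpipe.chimera import (CallParams, TranscriptRanking, call_chimeras,
                             enumerate_candidates, extend_call,
                             gap_or_overlap, rank_transcripts,
                             record_matches, select_call)
from hybpipe.formats import (AlignmentHit, ChimeraCall, Fragment,
                             SequenceRecord, TranscriptDB, TranscriptEntry)
from hybpipe import synthetic


def _hit(subject="tx", q=(1, 22), s=(1, 22), score=44.0, evalue=1e-4,
         query="r"):
    return AlignmentHit(query_id=query, subject_id=subject,
                        pct_identity=100.0, aln_len=q[1] - q[0] + 1,
                        mismatches=0, gap_openings=0, q_start=q[0],
                        q_end=q[1], s_start=s[0], s_end=s[1],
                        evalue=evalue, bit_score=score)


class TestGapOrOverlap:
    """Signed fragment distances reproduced from printed chimera rows."""

    @pytest.mark.parametrize("q1,q2,expected", [
        ((2, 21), (22, 47), 0),    # adjacent fragments
        ((1, 22), (22, 44), -1),   # 1-nt overlap
        ((1, 22), (20, 40), -3),   # 3-nt overlap
        ((1, 22), (28, 49), 5),    # 5-nt gap
    ])
    def test_signed_distance(self, q1, q2, expected):
        assert gap_or_overlap(_hit(q=q1), _hit(q=q2)) == expected

    def test_requires_read_order(self):
        with pytest.raises(ValueError):
            gap_or_overlap(_hit(q=(30, 40)), _hit(q=(1, 22)))


class TestRecordMatches:
    def test_top_ties_and_adjacent_hits_recorded(self):
        hits = [_hit("a", q=(1, 50), score=50),
                _hit("b", q=(1, 50), s=(100, 149), score=50),  # ties top
                _hit("c", q=(1, 22), score=22),   # overlaps covered area
                _hit("d", q=(51, 70), score=20)]  # adjacent (gap 0)
        recorded = record_matches(hits)
        assert {h.subject_id for h in recorded} == {"a", "b", "d"}

    def test_evalue_threshold_excludes_hit(self):
        hits = [_hit("a", score=40), _hit("b", q=(23, 44), evalue=0.2)]
        recorded = record_matches(hits, CallParams(hval=0.1))
        assert [h.subject_id for h in recorded] == ["a"]

    def test_hmax_excludes_multimapping_fragment(self):
        # a 22-nt fragment aligning to 11 database entries is dropped
        multi = [_hit(f"m{k}", q=(1, 22), score=22) for k in range(11)]
        partner = [_hit("p", q=(23, 44), score=22)]
        recorded = record_matches(multi + partner, CallParams(hmax=10))
        assert [h.subject_id for h in recorded] == ["p"]
        # at exactly 10 locations the fragment survives
        recorded = record_matches(multi[:10] + partner, CallParams(hmax=10))
        assert len(recorded) == 11

    def test_empty_hit_list(self):
        assert record_matches([]) == []


class TestEnumerateCandidates:
    def test_contiguous_full_length_read_yields_no_candidates(self):
        recorded = record_matches([
            _hit("a", q=(1, 50), score=50),
            _hit("b", q=(1, 24), score=24),
            _hit("c", q=(25, 50), score=26)])
        assert enumerate_candidates(recorded, read_len=50) == []

    def test_abutting_halves_form_one_candidate(self):
        recorded = [_hit("a", q=(1, 22), score=22),
                    _hit("b", q=(23, 49), score=27)]
        pairs = enumerate_candidates(recorded, read_len=49)
        assert len(pairs) == 1
        a, b = pairs[0]
        assert (a.subject_id, b.subject_id) == ("a", "b")

    def test_gap_beyond_gmax_is_rejected(self):
        recorded = [_hit("a", q=(1, 22), score=22),
                    _hit("b", q=(28, 49), score=22)]
        assert enumerate_candidates(recorded, read_len=60) == []
        recorded[1] = _hit("b", q=(27, 49), score=23)  # gap 4: allowed
        assert len(enumerate_candidates(recorded, read_len=60)) == 1

    def test_contained_fragment_never_pairs(self):
        recorded = [_hit("a", q=(1, 40), score=40),
                    _hit("b", q=(10, 30), score=21)]
        assert enumerate_candidates(recorded, read_len=60) == []


class TestRanking:
    def test_rank_by_total_mapped_reads(self):
        groups = [("1_10", [_hit("tx1"), _hit("tx2", q=(23, 44))]),
                  ("2_3", [_hit("tx1")])]
        ranking = rank_transcripts(groups)
        assert ranking.rank("tx1") == 1  # 13 reads vs 10
        assert ranking.rank("tx2") == 2
        assert ranking.rank("absent") == 3

    def test_ties_break_lexicographically(self):
        ranking = rank_transcripts([("1_5", [_hit("b")]),
                                    ("2_5", [_hit("a")])])
        assert ranking.rank("a") == 1 and ranking.rank("b") == 2

    def test_save_load_reproduces_ranks(self, tmp_path):
        ranking = rank_transcripts([("1_7", [_hit("x"), _hit("y")])])
        ranking.save(tmp_path / "ref.tsv")
        loaded = TranscriptRanking.load(tmp_path / "ref.tsv")
        assert loaded.rank("x") == ranking.rank("x")
        assert loaded.counts == ranking.counts


def _mim_db():
    return TranscriptDB([
        TranscriptEntry("M1_mir-1_microRNA", "mir-1", "microRNA", "A" * 22),
        TranscriptEntry("G1_geneA_mRNA", "geneA", "mRNA", "C" * 3000),
        TranscriptEntry("G2_geneB_mRNA", "geneB", "mRNA", "G" * 300),
    ])


class TestSelectCall:
    def test_pref_mim_outranks_equal_score_pair(self):
        db = _mim_db()
        read = SequenceRecord("r", "A" * 44)
        mim_pair = (_hit("M1_mir-1_microRNA", q=(1, 22), score=22),
                    _hit("G1_geneA_mRNA", q=(23, 44), score=18))
        mm_pair = (_hit("G1_geneA_mRNA", q=(1, 22), score=22),
                   _hit("G2_geneB_mRNA", q=(23, 44), score=18))
        call = select_call(read, [mm_pair, mim_pair],
                           CallParams(pref="mim"), db=db)
        assert call.frag1.subject_id == "M1_mir-1_microRNA"

    def test_pref_none_falls_back_to_transcript_rank(self):
        db = _mim_db()
        ranking = TranscriptRanking({"G1_geneA_mRNA": 100,
                                     "G2_geneB_mRNA": 90,
                                     "M1_mir-1_microRNA": 1})
        read = SequenceRecord("r", "A" * 44)
        mim_pair = (_hit("M1_mir-1_microRNA", q=(1, 22), score=22),
                    _hit("G2_geneB_mRNA", q=(23, 44), score=18))
        mm_pair = (_hit("G1_geneA_mRNA", q=(1, 22), score=22),
                   _hit("G2_geneB_mRNA", q=(23, 44), score=18))
        call = select_call(read, [mim_pair, mm_pair], CallParams(),
                           ranking=ranking, db=db)
        # G1 (rank 1) + G2 beats M1 (rank 3) + G2
        assert call.frag1.subject_id == "G1_geneA_mRNA"

    def test_higher_score_sum_always_wins(self):
        read = SequenceRecord("r", "A" * 44)
        strong = (_hit("a", q=(1, 22), score=22),
                  _hit("b", q=(23, 44), score=22))
        weak = (_hit("c", q=(1, 22), score=20),
                _hit("d", q=(23, 44), score=20))
        call = select_call(read, [weak, strong])
        assert call.frag1.subject_id == "a"

    def test_antisense_rejected_unless_anti(self):
        read = SequenceRecord("r", "A" * 44)
        pair = (_hit("a", q=(1, 22), s=(44, 23), score=22),
                _hit("b", q=(23, 44), score=22))
        assert select_call(read, [pair]) is None
        call = select_call(read, [pair], CallParams(anti=True))
        assert call is not None
        assert call.frag1.strand == "-"
        assert call.frag1.s_start < call.frag1.s_end  # stored ascending

    def test_type_mim_restricts_eligibility(self):
        db = _mim_db()
        read = SequenceRecord("r", "A" * 44)
        mm_pair = (_hit("G1_geneA_mRNA", q=(1, 22), score=22),
                   _hit("G2_geneB_mRNA", q=(23, 44), score=22))
        assert select_call(read, [mm_pair], CallParams(type="mim"),
                           db=db) is None


class TestExtension:
    def test_mirna_extended_to_full_mature_sequence(self):
        db = _mim_db()
        call = ChimeraCall("r", "A" * 42,
                           frag1=Fragment("M1_mir-1_microRNA", 1, 20, 1, 20,
                                          1e-4),
                           frag2=Fragment("G1_geneA_mRNA", 21, 42, 1614,
                                          1636, 1e-4))
        out = extend_call(call, db, CallParams(type="mim"))
        assert (out.frag1.s_start, out.frag1.s_end) == (1, 22)
        assert (out.frag2.s_start, out.frag2.s_end) == (1589, 1661)
        # read coordinates untouched
        assert (out.frag1.q_start, out.frag1.q_end) == (1, 20)

    def test_target_extension_clamped_at_transcript_edges(self):
        db = _mim_db()
        call = ChimeraCall("r", "A" * 42,
                           frag1=Fragment("M1_mir-1_microRNA", 1, 22, 1, 22,
                                          1e-4),
                           frag2=Fragment("G2_geneB_mRNA", 22, 42, 10, 40,
                                          1e-4))
        out = extend_call(call, db, CallParams(type="mim"))
        assert (out.frag2.s_start, out.frag2.s_end) == (1, 65)

    def test_no_extension_with_type_all(self):
        db = _mim_db()
        call = ChimeraCall("r", "A" * 42,
                           frag1=Fragment("M1_mir-1_microRNA", 1, 20, 1, 20,
                                          1e-4),
                           frag2=Fragment("G1_geneA_mRNA", 21, 42, 1614,
                                          1636, 1e-4))
        out = extend_call(call, db, CallParams(type="all"))
        assert out.frag1.s_end == 20


class TestEndToEndCalling:
    def test_planted_fusions_are_recovered(self, plain_db, plain_index):
        reads, truth = synthetic.make_fusion_reads(40, plain_db, seed=21)
        groups = list(align_reads(reads, plain_index))
        ranking = rank_transcripts((r.id, h) for r, h in groups)
        calls = {c.read_id: c for c in
                 call_chimeras(groups, CallParams(), ranking, plain_db)}
        assert len(calls) >= 38  # redundancy-free db: near-total recovery
        for row in truth.itertuples():
            if row.read_id not in calls:
                continue
            call = calls[row.read_id]
            assert {call.frag1.subject_id, call.frag2.subject_id} == \
                {row.mirna_id, row.mrna_id}
            # breakpoint within gmax of the truth
            assert abs(call.frag1.q_end - row.breakpoint) <= 4

    def test_contiguous_reads_yield_no_calls(self, plain_db, plain_index):
        reads = synthetic.make_contiguous_reads(60, plain_db, seed=22)
        groups = align_reads(reads, plain_index)
        assert list(call_chimeras(groups, CallParams())) == []

    def test_empty_input(self):
        assert list(call_chimeras([], CallParams())) == []

    def test_calls_invariant_under_hit_order_shuffling(self, plain_db,
                                                       plain_index):
        reads, _ = synthetic.make_fusion_reads(15, plain_db, seed=23)
        groups = [(r, h) for r, h in align_reads(reads, plain_index)]
        ranking = rank_transcripts((r.id, h) for r, h in groups)
        baseline = list(call_chimeras(groups, CallParams(), ranking,
                                      plain_db))
        rng = random.Random(0)
        shuffled = [(r, rng.sample(h, len(h))) for r, h in groups]
        repeat = list(call_chimeras(shuffled, CallParams(), ranking,
                                    plain_db))
        assert [c.__dict__ for c in baseline] == \
            [c.__dict__ for c in repeat]
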