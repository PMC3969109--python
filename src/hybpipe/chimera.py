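"""Chimera identification and calling from per-read hit lists.

This is the heart of the pipeline.  For every read we examine its
local matches in descending score order and *record* the top-scoring
match, every match tying the top score, and every match whose gap or
overlap with the already-matched area of the read is at most ``gmax``
nucleotides (default 4).  All pairs of recorded matches separated by
at most ``gmax`` in the read become candidate chimeras; a read whose
best match covers (almost) its full length is non-chimeric and yields
none.  Small gaps tolerate post-transcriptional additions between the
ligated fragments; small overlaps arise when a nucleotide at the
ligation point maps to either fragment.

One call per read is then selected lexicographically by (1) the sum of
the two fragments' mapping scores, (2) optionally the transcript-class
preference for miRNA-mRNA pairs, and (3) the transcript abundance
ranking (total mapped reads across the experiment, shareable across
samples as an alignment reference), with a final deterministic
identifier tie-break.  Antisense fragments are rejected unless
``anti`` is set (genomic databases).  For miRNA-mRNA calls the miRNA
fragment can be extended to the full mature sequence and the target
widened by 25 nt, compensating for reads that do not span the whole
chimeric cDNA.

Per-fragment filters: e-value <= ``hval`` (default 0.1) and at most
``hmax`` (default 10) distinct mapped locations; fragments that map to
more locations -- typically because the database carries several
near-identical transcripts for one gene -- are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .formats import (AlignmentHit, ChimeraCall, Fragment, SequenceRecord,
                      TranscriptDB, read_weight)

__all__ = ["CallParams", "gap_or_overlap", "record_matches",
           "enumerate_candidates", "rank_transcripts", "TranscriptRanking",
           "select_call", "extend_call", "call_chimeras"]

TARGET_EXTENSION = 25  # nt added on both sides of the mRNA fragment

# read-interval overlap fraction above which two hits are treated as
# alternative locations of the same fragment (for the hmax filter)
_SAME_FRAGMENT_OVERLAP = 0.75


@dataclass(frozen=True)
class CallParams:
    """Chimera-calling thresholds and modes.

    hval: per-fragment e-value threshold; hmax: maximum mapped
    locations per fragment; gmax: maximum |gap/overlap| between
    fragments; pref/type select the miRNA-mRNA ("mim") preference and
    restriction; anti accepts antisense fragments.
    """

    hval: float = 0.1
    hmax: int = 10
    gmax: int = 4
    pref: str = "none"
    type: str = "all"
    anti: bool = False

    def __post_init__(self) -> None:
        if self.hval <= 0:
            raise ValueError("hval must be > 0")
        if self.hmax < 1:
            raise ValueError("hmax must be >= 1")
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")
        if self.pref not in ("none", "mim"):
            raise ValueError("pref must be 'none' or 'mim'")
        if self.type not in ("all", "mim"):
            raise ValueError("type must be 'all' or 'mim'")


def gap_or_overlap(frag_a, frag_b) -> int:
    """Signed distance between two read intervals (a before b).

    Positive = gap, negative = overlap, 0 = directly adjacent.
    Accepts anything with ``q_start``/``q_end`` attributes.
    """
    if frag_a.q_start > frag_b.q_start:
        raise ValueError("fragments must be ordered by read start")
    return frag_b.q_start - frag_a.q_end - 1


def _interval_gap(qs: int, qe: int, intervals: list[tuple[int, int]]) -> int:
    """|gap or overlap| between [qs,qe] and the covered read area.

    If the interval overlaps the covered area at all, the (largest)
    overlap length is the distance; otherwise the smallest gap to any
    covered interval.
    """
    max_overlap = 0
    min_gap = None
    for (cs, ce) in intervals:
        if qs > ce:
            d = qs - ce - 1
        elif qe < cs:
            d = cs - qe - 1
        else:
            max_overlap = max(max_overlap,
                              min(qe, ce) - max(qs, cs) + 1)
            continue
        if min_gap is None or d < min_gap:
            min_gap = d
    if max_overlap > 0:
        return max_overlap
    return min_gap if min_gap is not None else 10 ** 9


def _n_locations(hit: AlignmentHit, hits: list[AlignmentHit]) -> int:
    """Distinct (subject, strand, s-interval) locations of hit's fragment.

    Hits whose read intervals overlap ``hit`` by at least 75% of the
    shorter interval count as alternative locations of the same
    fragment.
    """
    locations = set()
    for other in hits:
        lo = max(hit.q_start, other.q_start)
        hi = min(hit.q_end, other.q_end)
        ov = hi - lo + 1
        shorter = min(hit.q_span, other.q_span)
        if ov >= _SAME_FRAGMENT_OVERLAP * shorter:
            locations.add((other.subject_id, other.strand,
                           other.s_interval))
    return len(locations)


def _hit_sort_key(h: AlignmentHit):
    return (-h.score, h.subject_id, min(h.s_start, h.s_end), h.q_start)


def record_matches(hits: Iterable[AlignmentHit],
                   params: CallParams = CallParams()
                   ) -> list[AlignmentHit]:
    """Select the hits worth pairing for one read.

    Processing in descending score order: the top hit, all hits tying
    the top score, and every hit whose gap or overlap with the union of
    previously recorded read intervals is at most ``gmax`` are
    recorded.  Hits above the e-value threshold are never considered;
    fragments mapping to more than ``hmax`` distinct locations are
    excluded.
    """
    pool = [h for h in hits if h.evalue <= params.hval]
    pool.sort(key=_hit_sort_key)
    pool = [h for h in pool if _n_locations(h, pool) <= params.hmax]
    if not pool:
        return []
    top_score = pool[0].score
    recorded: list[AlignmentHit] = []
    covered: list[tuple[int, int]] = []
    for h in pool:
        if h.score == top_score or \
                _interval_gap(h.q_start, h.q_end, covered) <= params.gmax:
            recorded.append(h)
            covered.append((h.q_start, h.q_end))
    return recorded


def _contains(a: AlignmentHit, b: AlignmentHit) -> bool:
    return a.q_start <= b.q_start and a.q_end >= b.q_end


def enumerate_candidates(recorded: list[AlignmentHit],
                         read_len: int,
                         params: CallParams = CallParams()
                         ) -> list[tuple[AlignmentHit, AlignmentHit]]:
    """All ordered fragment pairs within ``gmax`` gap/overlap.

    Pairs are returned with the first fragment earlier in the read.
    Reads whose best match covers at least ``read_len - gmax``
    nucleotides are non-chimeric (contiguous full-length match) and
    yield no candidates; a fragment contained in the other is never a
    partner.
    """
    if not recorded:
        return []
    best = min(recorded, key=_hit_sort_key)
    if best.q_span >= read_len - params.gmax:
        return []
    pairs = []
    for i, a in enumerate(recorded):
        for b in recorded[i + 1:]:
            first, second = (a, b) if (a.q_start, a.q_end) <= \
                (b.q_start, b.q_end) else (b, a)
            if _contains(first, second) or _contains(second, first):
                continue
            if abs(gap_or_overlap(first, second)) <= params.gmax:
                pairs.append((first, second))
    return pairs


# ---------------------------------------------------------------------------
# Transcript ranking (alignment reference)
# ---------------------------------------------------------------------------

class TranscriptRanking:
    """Transcripts ranked by total mapped reads (rank 1 = most).

    Read counts are weighted by the collapse count M encoded in read
    identifiers; ties break lexicographically.  The ranking can be
    saved and reloaded so that several samples share one alignment
    reference and produce consistent calls.
    """

    def __init__(self, counts: dict[str, int]):
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        self.counts = dict(counts)
        self._rank = {tid: r for r, (tid, _) in enumerate(ordered, 1)}

    def rank(self, transcript_id: str) -> int:
        """Rank of a transcript; unranked transcripts sort last."""
        return self._rank.get(transcript_id, len(self._rank) + 1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\ttranscript\tn_reads\n")
            for tid, r in sorted(self._rank.items(), key=lambda kv: kv[1]):
                fh.write(f"{r}\t{tid}\t{self.counts[tid]}\n")

    @classmethod
    def load(cls, path) -> "TranscriptRanking":
        counts = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("rank\t"):
                raise ValueError(f"{path}: not a transcript ranking file")
            for line in fh:
                _, tid, n = line.rstrip("\n").split("\t")
                counts[tid] = int(n)
        return cls(counts)


def rank_transcripts(hit_groups: Iterable[tuple[str, Iterable[AlignmentHit]]]
                     ) -> TranscriptRanking:
    """Build the alignment reference from (read_id, hits) groups.

    A read contributes its collapse weight M once to every transcript
    it maps to (however many individual hits).
    """
    counts: dict[str, int] = {}
    for read_id, hits in hit_groups:
        w = read_weight(read_id)
        for tid in {h.subject_id for h in hits}:
            counts[tid] = counts.get(tid, 0) + w
    return TranscriptRanking(counts)


# ---------------------------------------------------------------------------
# Call selection
# ---------------------------------------------------------------------------

def _is_mim(a: AlignmentHit, b: AlignmentHit, db: TranscriptDB) -> bool:
    """Exactly one microRNA fragment and one mRNA fragment."""
    types = {db[a.subject_id].biotype, db[b.subject_id].biotype}
    return types == {"microRNA", "mRNA"}


def _hit_to_fragment(h: AlignmentHit) -> Fragment:
    s_lo, s_hi = h.s_interval
    return Fragment(subject_id=h.subject_id, q_start=h.q_start,
                    q_end=h.q_end, s_start=s_lo, s_end=s_hi,
                    evalue=h.evalue, strand=h.strand)


def select_call(read: SequenceRecord,
                candidates: list[tuple[AlignmentHit, AlignmentHit]],
                params: CallParams = CallParams(),
                ranking: Optional[TranscriptRanking] = None,
                db: Optional[TranscriptDB] = None
                ) -> Optional[ChimeraCall]:
    """Pick at most one chimera call for a read.

    Eligibility: antisense fragments only with ``anti``; with
    ``type='mim'`` only miRNA+mRNA pairs.  Selection is lexicographic:
    maximum score sum, then (with ``pref='mim'``) miRNA-mRNA pairs
    first, then the better sorted pair of transcript ranks, then the
    transcript-id pair.
    """
    eligible = []
    for a, b in candidates:
        if not params.anti and not (a.sense and b.sense):
            continue
        if params.type == "mim":
            if db is None:
                raise ValueError("type='mim' requires the transcript db")
            if not _is_mim(a, b, db):
                continue
        eligible.append((a, b))
    if not eligible:
        return None

    def key(pair):
        a, b = pair
        score_sum = a.score + b.score
        mim_first = 0
        if params.pref == "mim" and db is not None:
            mim_first = 0 if _is_mim(a, b, db) else 1
        if ranking is not None:
            ranks = sorted((ranking.rank(a.subject_id),
                            ranking.rank(b.subject_id)))
        else:
            ranks = [0, 0]
        return (-score_sum, mim_first, ranks[0], ranks[1],
                a.subject_id, b.subject_id, a.q_start, b.q_start,
                min(a.s_start, a.s_end), min(b.s_start, b.s_end))

    a, b = min(eligible, key=key)
    return ChimeraCall(read_id=read.id, read_seq=read.seq,
                       frag1=_hit_to_fragment(a), frag2=_hit_to_fragment(b))


def extend_call(call: ChimeraCall, db: TranscriptDB,
                params: CallParams = CallParams()) -> ChimeraCall:
    """Bioinformatic extension of miRNA-mRNA calls (type='mim' only).

    The miRNA fragment is widened to the full mature sequence and the
    target fragment by 25 nt on both sides (clamped to the
    transcript); read coordinates are untouched.
    """
    if params.type != "mim":
        return call

    def extend(frag: Fragment) -> Fragment:
        entry = db[frag.subject_id]
        if entry.biotype == "microRNA":
            s_start, s_end = 1, len(entry.seq)
        elif entry.biotype == "mRNA":
            s_start = max(1, frag.s_start - TARGET_EXTENSION)
            s_end = min(len(entry.seq), frag.s_end + TARGET_EXTENSION)
        else:
            return frag
        return Fragment(subject_id=frag.subject_id, q_start=frag.q_start,
                        q_end=frag.q_end, s_start=s_start, s_end=s_end,
                        evalue=frag.evalue, strand=frag.strand)

    return ChimeraCall(read_id=call.read_id, read_seq=call.read_seq,
                       frag1=extend(call.frag1), frag2=extend(call.frag2),
                       dG=call.dG, annotation=call.annotation,
                       duplex=call.duplex)


def call_chimeras(hit_groups: Iterable[tuple[SequenceRecord,
                                             list[AlignmentHit]]],
                  params: CallParams = CallParams(),
                  ranking: Optional[TranscriptRanking] = None,
                  db: Optional[TranscriptDB] = None
                  ) -> Iterator[ChimeraCall]:
    """Run the full per-read calling cascade over a stream of hit groups.

    One pass, constant memory per read group; output order equals input
    read order.
    """
    for read, hits in hit_groups:
        recorded = record_matches(hits, params)
        candidates = enumerate_candidates(recorded, len(read.seq), params)
        call = select_call(read, candidates, params, ranking, db)
        if call is None:
            continue
        if params.type == "mim" and db is not None:
            call = extend_call(call, db, params)
        yield call
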