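"""Built-in seed-and-extend local aligner with blast-tabular semantics.

Reads are aligned against a k-mer-indexed transcript database.  Exact
word matches (default word length 11, the same seed length the common
external aligners use for this task) nominate candidate transcripts on
either strand; each candidate is then scored with a full affine-gap
Smith-Waterman dynamic program over the read x transcript matrix, so
reported scores are exact local-alignment optima, not heuristic
extensions.  Additional non-overlapping alignments per transcript are
found by masking the read positions of earlier alignments and
re-running the DP.

Scoring follows the local-mode short-read convention: match +1,
mismatch -2, gap open 5 and gap extend 1 (a gap of length k costs
5 + k), minimum reported score 15.

E-values for built-in hits use ungapped Karlin-Altschul statistics:
``E = m * n * 2**(-bits)`` with ``bits = (lambda * S - ln K) / ln 2``,
lambda being the unique positive root of
``sum_ij p_i p_j exp(lambda * s(i, j)) = 1`` under uniform base
composition.  External aligner e-values are ingested verbatim through
the same :class:`~hybpipe.formats.AlignmentHit` contract.
"""

from __future__ import annotations

import functools
import math
import pickle
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
from numba import njit

from .formats import AlignmentHit, SequenceRecord, TranscriptDB, \
    reverse_complement

__all__ = ["AlignParams", "KmerIndex", "build_index", "local_align",
           "karlin_lambda", "karlin_k", "bit_score", "evalue",
           "align_reads"]

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_ENCODE[ord("U")] = 3  # U aligns as T


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignParams:
    """Scoring and reporting parameters of the built-in aligner."""

    word: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 1
    min_score: int = 15
    max_hits_reported: int = 20
    max_alignments_per_subject: int = 4

    def __post_init__(self) -> None:
        if self.word < 4:
            raise ValueError("word length must be >= 4")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def karlin_lambda(match: int, mismatch: int, tol: float = 1e-9) -> float:
    """Positive root of sum_ij p_i p_j e^{lambda s(i,j)} = 1 (bisection).

    Uniform base composition: 4/16 letter pairs score ``match``, 12/16
    score ``mismatch``.
    """
    def f(lam: float) -> float:
        return (0.25 * math.exp(lam * match)
                + 0.75 * math.exp(lam * mismatch) - 1.0)

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2
        if hi > 1e3:
            raise ValueError("no positive Karlin-Altschul lambda for this "
                             "score scheme")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# Published ungapped K values (nucleotide schemes, uniform composition).
_K_TABLE = {(1, -2): 0.621, (1, -3): 0.711, (1, -4): 0.747,
            (2, -3): 0.61, (1, -1): 0.2}
_K_DEFAULT = 0.5


def karlin_k(match: int, mismatch: int) -> float:
    return _K_TABLE.get((match, mismatch), _K_DEFAULT)


def bit_score(raw_score: float, params: AlignParams) -> float:
    lam = karlin_lambda(params.match, params.mismatch)
    k = karlin_k(params.match, params.mismatch)
    return (lam * raw_score - math.log(k)) / math.log(2.0)


def evalue(bits: float, read_len: int, db_len: int) -> float:
    """Karlin-Altschul expectation E = m * n * 2^(-bits).

    ``db_len`` is the total nucleotide count of the database; no
    effective-length correction is applied, keeping the statistic
    deterministic and exactly linear in both lengths.
    """
    if read_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return float(read_len) * float(db_len) * 2.0 ** (-bits)


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact-word lookup over a transcript database.

    Maps every word-length substring of every transcript to its
    (transcript, offset) occurrences; O(1) expected lookup.
    """

    def __init__(self, db: TranscriptDB, word: int = 11):
        if len(db) == 0:
            raise ValueError("cannot index an empty database")
        self.word = word
        self.db = db
        self.ids = db.ids
        self._table: dict[str, list[tuple[int, int]]] = {}
        for t, entry in enumerate(db):
            if len(entry.seq) < word:
                warnings.warn(
                    f"transcript {entry.full_id!r} is shorter than the "
                    f"word length {word}; it has no seeds")
                continue
            seq = entry.seq
            for pos in range(len(seq) - word + 1):
                self._table.setdefault(seq[pos:pos + word], []).append(
                    (t, pos))

    def seeds(self, kmer: str) -> list[tuple[int, int]]:
        return self._table.get(kmer, [])

    def candidate_subjects(self, query: str) -> list[int]:
        """Indices of transcripts sharing at least one exact word."""
        found: set[int] = set()
        w = self.word
        for pos in range(len(query) - w + 1):
            for t, _ in self._table.get(query[pos:pos + w], ()):
                found.add(t)
        return sorted(found)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"word": self.word,
                         "entries": [(e.full_id, e.seq) for e in self.db]},
                        fh)

    @classmethod
    def load(cls, path) -> "KmerIndex":
        from .formats import TranscriptDB, TranscriptEntry, _parse_db_header
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        entries = []
        for full_id, seq in payload["entries"]:
            display, biotype = _parse_db_header(full_id)
            entries.append(TranscriptEntry(full_id, display, biotype, seq))
        return cls(TranscriptDB(entries), word=payload["word"])


def build_index(db: TranscriptDB, word: int = 11) -> KmerIndex:
    return KmerIndex(db, word=word)


# ---------------------------------------------------------------------------
# Smith-Waterman kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_fill(q, s, match, mismatch, gap_oe, gap_e, qmask, H, E, F):
    n, m = q.shape[0], s.shape[0]
    best = 0
    bi = -1
    bj = -1
    for i in range(1, n + 1):
        if qmask[i - 1]:
            for j in range(m + 1):
                H[i, j] = 0
                E[i, j] = -10 ** 8
                F[i, j] = -10 ** 8
            continue
        for j in range(1, m + 1):
            e = E[i - 1, j] - gap_e
            t = H[i - 1, j] - gap_oe
            if t > e:
                e = t
            E[i, j] = e
            f = F[i, j - 1] - gap_e
            t = H[i, j - 1] - gap_oe
            if t > f:
                f = t
            F[i, j] = f
            if q[i - 1] < 4 and q[i - 1] == s[j - 1]:
                sub = match
            else:
                sub = mismatch
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@dataclass
class _RawAlignment:
    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    mismatches: int
    gap_openings: int
    aln_len: int


def _traceback(q, s, match, mismatch, gap_oe, gap_e, H, E, F, bi, bj
               ) -> _RawAlignment:
    i, j = bi, bj
    matches = mism = gaps = gap_open = 0
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            sub = match if (q[i - 1] < 4 and q[i - 1] == s[j - 1]) \
                else mismatch
            if h == H[i - 1, j - 1] + sub:
                if sub == match:
                    matches += 1
                else:
                    mism += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            elif h == F[i, j]:
                state = "F"
            else:  # pragma: no cover - DP consistency
                raise AssertionError("inconsistent traceback")
        elif state == "E":
            gaps += 1
            if E[i, j] == H[i - 1, j] - gap_oe:
                gap_open += 1
                state = "H"
            i -= 1
        else:
            gaps += 1
            if F[i, j] == H[i, j - 1] - gap_oe:
                gap_open += 1
                state = "H"
            j -= 1
    return _RawAlignment(
        score=int(H[bi, bj]), q_start=i + 1, q_end=bi,
        s_start=j + 1, s_end=bj, matches=matches, mismatches=mism,
        gap_openings=gap_open, aln_len=matches + mism + gaps)


def _subject_alignments(qarr: np.ndarray, sarr: np.ndarray,
                        params: AlignParams) -> list[_RawAlignment]:
    """All non-overlapping (in the query) local alignments >= min_score."""
    n, m = qarr.shape[0], sarr.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10 ** 8, dtype=np.int32)
    F = np.full((n + 1, m + 1), -10 ** 8, dtype=np.int32)
    E[0, :] = -10 ** 8
    qmask = np.zeros(n, dtype=np.bool_)
    gap_oe = params.gap_open + params.gap_extend
    out: list[_RawAlignment] = []
    for _ in range(params.max_alignments_per_subject):
        best, bi, bj = _sw_fill(qarr, sarr, params.match, params.mismatch,
                                gap_oe, params.gap_extend, qmask, H, E, F)
        if best < params.min_score:
            break
        aln = _traceback(qarr, sarr, params.match, params.mismatch,
                         gap_oe, params.gap_extend, H, E, F, bi, bj)
        out.append(aln)
        qmask[aln.q_start - 1:aln.q_end] = True
    return out


def local_align(read: SequenceRecord, index: KmerIndex,
                params: AlignParams = AlignParams(),
                db_len: Optional[int] = None) -> list[AlignmentHit]:
    """Local alignments of one read against the indexed database.

    Both strands are searched; minus-strand hits carry
    ``s_start > s_end``.  Hits are sorted by score descending with a
    deterministic (subject_id, s_start) tie-break, and capped at
    ``max_hits_reported``.
    """
    seq = read.seq.upper().replace("U", "T")
    if len(seq) < params.word:
        return []
    total_db = db_len if db_len is not None else index.db.total_length
    hits: list[AlignmentHit] = []
    entries = list(index.db)
    for strand in ("+", "-"):
        query = seq if strand == "+" else reverse_complement(seq)
        qarr = _encode(query)
        L = len(query)
        for t in index.candidate_subjects(query):
            entry = entries[t]
            sarr = _encode(entry.seq)
            for aln in _subject_alignments(qarr, sarr, params):
                bits = bit_score(aln.score, params)
                ev = evalue(bits, len(seq), total_db)
                if strand == "+":
                    q_start, q_end = aln.q_start, aln.q_end
                    s_start, s_end = aln.s_start, aln.s_end
                else:
                    q_start = L - aln.q_end + 1
                    q_end = L - aln.q_start + 1
                    s_start, s_end = aln.s_end, aln.s_start
                hits.append(AlignmentHit(
                    query_id=read.id,
                    subject_id=entry.full_id,
                    pct_identity=round(100.0 * aln.matches / aln.aln_len, 2),
                    aln_len=aln.aln_len,
                    mismatches=aln.mismatches,
                    gap_openings=aln.gap_openings,
                    q_start=q_start, q_end=q_end,
                    s_start=s_start, s_end=s_end,
                    evalue=ev, bit_score=round(bits, 1),
                ))
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id,
                             min(h.s_start, h.s_end)))
    return hits[:params.max_hits_reported]


def align_reads(reads: Iterable[SequenceRecord], index: KmerIndex,
                params: AlignParams = AlignParams()
                ) -> Iterator[tuple[SequenceRecord, list[AlignmentHit]]]:
    """Align a stream of reads, yielding (read, hits) groups in order."""
    db_len = index.db.total_length
    for read in reads:
        yield read, local_align(read, index, params, db_len=db_len)
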