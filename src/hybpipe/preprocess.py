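"""Read preprocessing: 3' adapter trimming, quality and length filters,
PCR-duplicate collapsing, and length-distribution reporting.

CLASH inserts are frequently shorter than the read, so part or all of
the 3' sequencing linker ends up inside the read and must be removed
before local alignment (untrimmed linker bases otherwise extend or
break fragment alignments).  After trimming and filtering, identical
reads are collapsed into single records that retain the occurrence
count, and -- when random 5' barcodes were used -- the number of
distinct random tags, so that PCR duplicates can be told apart from
genuinely abundant molecules.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Iterator, Optional

import pandas as pd

from .formats import SequenceRecord

__all__ = ["trim_adapter_3p", "quality_trim", "filter_length",
           "filter_mean_quality", "collapse_reads", "check"]


def _truncate(read: SequenceRecord, length: int) -> SequenceRecord:
    if length >= len(read.seq):
        return read
    return SequenceRecord(
        id=read.id, seq=read.seq[:length],
        qual=read.qual[:length] if read.qual is not None else None,
        random_tag=read.random_tag, rank=read.rank,
        n_barcodes=read.n_barcodes, count=read.count)


def trim_adapter_3p(read: SequenceRecord, adapter: str,
                    min_match: int = 4) -> SequenceRecord:
    """Remove a 3' adapter (linker) remnant from the read end.

    The longest read suffix matching a prefix of the adapter -- with at
    most one mismatch per 10 aligned nucleotides (floor) -- is removed,
    provided the match is at least ``min_match`` nt; a full internal
    adapter occurrence removes the adapter and everything 3' of it.
    ``min_match=0`` disables trimming.  No-op when nothing qualifies.
    """
    if min_match <= 0:
        return read
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    adapter = adapter.upper()
    seq = read.seq
    L, A = len(seq), len(adapter)
    for start in range(0, L - min_match + 1):
        overlap = min(L - start, A)
        if overlap < min_match:
            break
        # only full-suffix matches or full-adapter internal occurrences
        if start + overlap != L and overlap != A:
            continue
        allowed = overlap // 10
        mism = 0
        for a, b in zip(seq[start:start + overlap], adapter):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            return _truncate(read, start)
    return read


def quality_trim(read: SequenceRecord, q_threshold: int = 30
                 ) -> SequenceRecord:
    """Trim low-quality 3' tails (BWA-style running sum).

    Removes the suffix maximizing sum(q_threshold - q) over trailing
    bases; ``q_threshold=0`` is the identity.
    """
    if q_threshold <= 0:
        return read
    if read.qual is None:
        raise ValueError(f"read {read.id!r} has no qualities; cannot "
                         f"quality-trim at threshold {q_threshold}")
    best, running = 0, 0
    cut = len(read.seq)
    for i in range(len(read.seq) - 1, -1, -1):
        running += q_threshold - read.qual[i]
        if running > best:
            best = running
            cut = i
    return _truncate(read, cut)


def filter_length(reads: Iterable[SequenceRecord], min_len: int = 17
                  ) -> Iterator[SequenceRecord]:
    """Keep only reads of at least ``min_len`` nucleotides."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return (r for r in reads if len(r.seq) >= min_len)


def filter_mean_quality(reads: Iterable[SequenceRecord],
                        min_mean: float = 0.0) -> Iterator[SequenceRecord]:
    """Drop reads whose mean Phred quality is below ``min_mean``.

    Default 0 (off), matching the pipeline's default quality-filter
    setting.
    """
    for r in reads:
        if min_mean <= 0:
            yield r
        elif r.qual and sum(r.qual) / len(r.qual) >= min_mean:
            yield r


def collapse_reads(reads: Iterable[SequenceRecord]
                   ) -> list[SequenceRecord]:
    """Collapse identical sequences into single FASTA records.

    Each distinct sequence becomes one record with ``count`` = number
    of occurrences (re-reading counts already encoded in collapsed
    input ids, so collapsing is idempotent), ``n_barcodes`` = number of
    distinct random tags when tags are present, and ``rank`` = 1-based
    position after sorting by count descending (ties broken
    lexicographically by sequence).  Ids are rewritten ``K-L_M`` /
    ``K_M``; the sum of counts equals the input read total.
    """
    counts: Counter[str] = Counter()
    tags: defaultdict[str, set[str]] = defaultdict(set)
    any_tags = False
    for r in reads:
        counts[r.seq] += r.weight
        if r.random_tag is not None:
            tags[r.seq].add(r.random_tag)
            any_tags = True
        elif r.n_barcodes is not None:
            # already-collapsed input: carry the barcode count forward
            tags[r.seq].update(f"{r.seq}:{k}" for k in range(r.n_barcodes))
            any_tags = True
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    for rank, (seq, count) in enumerate(ordered, start=1):
        n_bar = len(tags[seq]) if any_tags and tags[seq] else None
        rec = SequenceRecord(id="", seq=seq, rank=rank,
                             n_barcodes=n_bar, count=count)
        rec.id = rec.collapsed_id
        out.append(rec)
    return out


def check(reads_raw: Iterable[SequenceRecord],
          reads_collapsed: Iterable[SequenceRecord]) -> pd.DataFrame:
    """Length distributions of uncollapsed and collapsed reads.

    Returns a table with one row per observed length: ``n_raw`` counts
    every input read (weighted by collapse count), ``n_unique`` counts
    distinct collapsed records.
    """
    raw: Counter[int] = Counter()
    uniq: Counter[int] = Counter()
    for r in reads_raw:
        raw[len(r.seq)] += r.weight
    for r in reads_collapsed:
        uniq[len(r.seq)] += 1
    lengths = sorted(set(raw) | set(uniq))
    return pd.DataFrame({
        "length": lengths,
        "n_raw": [raw.get(n, 0) for n in lengths],
        "n_unique": [uniq.get(n, 0) for n in lengths],
    })
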