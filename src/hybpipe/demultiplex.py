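"""Splitting multiplexed libraries by 5' barcode.

CLASH 5' linkers may carry a composite barcode: fixed positions (the
multiplex code, identifying the sample) interleaved with random
positions (used downstream to recognize PCR duplicates).  A pattern
like ``NNNACGT`` means three random bases followed by the sample code
``ACGT``.

Demultiplexing precomputes a lookup table of *every* read prefix
compatible with some barcode (optionally allowing one substitution in
the code positions, never in the random positions, never indels).
Splitting a read is then a single substring extraction and one
dictionary lookup -- no per-read string comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .formats import SequenceRecord

__all__ = ["BarcodeSpec", "BarcodeTable", "build_barcode_table",
           "demultiplex", "read_barcode_file", "UNASSIGNED"]

UNASSIGNED = "unassigned"

_BASES = "ACGT"


@dataclass(frozen=True)
class BarcodeSpec:
    """One sample's barcode pattern; N marks random positions."""

    sample: str
    pattern: str

    def __post_init__(self) -> None:
        bad = set(self.pattern) - set("ACGTN")
        if bad:
            raise ValueError(f"barcode pattern {self.pattern!r} contains "
                             f"invalid characters {sorted(bad)}")

    @property
    def code_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c != "N")

    @property
    def random_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c == "N")


@dataclass
class BarcodeTable:
    """Prefix-string lookup: prefix -> (sample, random-position mask)."""

    length: int
    entries: dict[str, tuple[str, tuple[int, ...]]]

    def lookup(self, prefix: str):
        return self.entries.get(prefix)


def read_barcode_file(path) -> list[BarcodeSpec]:
    """Parse a two-column whitespace-separated ``pattern sample`` file.

    Lines starting with '#' are comments.
    """
    specs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}, line {lineno}: expected "
                                 "'pattern sample'")
            specs.append(BarcodeSpec(sample=fields[1],
                                     pattern=fields[0].upper()))
    if not specs:
        raise ValueError(f"{path}: no barcodes found")
    return specs


def _code_variants(code: str, mismatches: int) -> Iterator[str]:
    yield code
    if mismatches >= 1:
        for i, orig in enumerate(code):
            for b in _BASES:
                if b != orig:
                    yield code[:i] + b + code[i + 1:]


def build_barcode_table(specs: Iterable[BarcodeSpec],
                        mismatches: int = 0) -> BarcodeTable:
    """Enumerate every read prefix compatible with some barcode.

    ``mismatches`` (0 or 1) substitutions are tolerated at code
    positions only.  Specs whose codes collide under the allowance
    raise; residual ambiguous prefixes map to the unassigned stream.
    """
    specs = list(specs)
    if mismatches not in (0, 1):
        raise ValueError("mismatches must be 0 or 1 (no indels supported)")
    if not specs:
        raise ValueError("no barcode specs given")
    lengths = {len(s.pattern) for s in specs}
    if len(lengths) != 1:
        raise ValueError(f"barcode patterns differ in length: {lengths}")
    length = lengths.pop()
    if len({s.sample for s in specs}) != len(specs):
        raise ValueError("duplicate sample names in barcode specs")

    # pairwise code distance must exceed twice the mismatch allowance
    for a, b in itertools.combinations(specs, 2):
        dist = 0
        for i in range(length):
            ca, cb = a.pattern[i], b.pattern[i]
            if ca != "N" and cb != "N" and ca != cb:
                dist += 1
        if dist <= 2 * mismatches:
            raise ValueError(
                f"barcodes for samples {a.sample!r} and {b.sample!r} are "
                f"ambiguous at distance {dist} with mismatches={mismatches}")

    entries: dict[str, tuple[str, tuple[int, ...]]] = {}
    ambiguous: set[str] = set()
    for spec in specs:
        rand_pos = spec.random_positions
        code_pos = spec.code_positions
        code = "".join(spec.pattern[i] for i in code_pos)
        for variant in _code_variants(code, mismatches):
            for fill in itertools.product(_BASES, repeat=len(rand_pos)):
                prefix = list(spec.pattern)
                for p, b in zip(code_pos, variant):
                    prefix[p] = b
                for p, b in zip(rand_pos, fill):
                    prefix[p] = b
                key = "".join(prefix)
                prev = entries.get(key)
                if prev is not None and prev[0] != spec.sample:
                    if mismatches == 0:
                        raise ValueError(
                            f"barcode collision on prefix {key!r} between "
                            f"{prev[0]!r} and {spec.sample!r}")
                    ambiguous.add(key)
                else:
                    entries[key] = (spec.sample, rand_pos)
    for key in ambiguous:
        del entries[key]
    return BarcodeTable(length=length, entries=entries)


def demultiplex(reads: Iterable[SequenceRecord], table: BarcodeTable,
                ) -> dict[str, list[SequenceRecord]]:
    """Partition reads by 5' barcode.

    The barcode is removed from sequence and qualities; the random
    substring is stored in ``random_tag`` and appended to the read id
    (``id:TAG``).  Reads with no table entry, and reads shorter than the
    barcode, go to the ``unassigned`` stream; every input read appears
    in exactly one output stream.
    """
    out: dict[str, list[SequenceRecord]] = {UNASSIGNED: []}
    L = table.length
    for rec in reads:
        if len(rec.seq) <= L:
            out[UNASSIGNED].append(rec)
            continue
        found = table.lookup(rec.seq[:L])
        if found is None:
            out[UNASSIGNED].append(rec)
            continue
        sample, rand_pos = found
        tag = "".join(rec.seq[p] for p in rand_pos)
        new = SequenceRecord(
            id=f"{rec.id}:{tag}" if tag else rec.id,
            seq=rec.seq[L:],
            qual=rec.qual[L:] if rec.qual is not None else None,
            random_tag=tag or None,
        )
        out.setdefault(sample, []).append(new)
    return out
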