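"""Domain types and readers/writers for the formats used by the pipeline.

The pipeline moves data through a small set of plain-text formats:

* FASTQ/FASTA sequencing reads (optionally gzip-compressed), whose
  identifiers may carry read-collapsing metadata in the ``K-L_M`` /
  ``K_M`` convention (frequency rank, number of distinct random
  barcodes, number of reads collapsed);
* 12-column blast tabular alignment files ("blast8" / ``-outfmt 6``),
  the lingua franca shared by the built-in aligner and every external
  aligner whose output we ingest;
* the 15-column ``.hyb`` chimera format (one line per called chimera:
  identifier, read sequence, duplex folding energy, and one six-column
  mapping block per fragment, coordinates 1-based inclusive);
* the ``viennad`` annotated dot-bracket format (one six-line block per
  folded chimera);
* transcript databases as FASTA with biotype-encoded headers
  (underscore-delimited, biotype last, display name second to last,
  e.g. ``MIMAT0000062_hsa-let-7a_microRNA``).

Parsers are strict and report the offending line number; writers are
canonical so that write -> read -> write is byte-identical.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

__all__ = [
    "FormatError",
    "SequenceRecord",
    "AlignmentHit",
    "Fragment",
    "ChimeraCall",
    "DuplexResult",
    "Interaction",
    "TranscriptEntry",
    "TranscriptDB",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "parse_blast_tab",
    "write_blast_tab",
    "read_hyb",
    "write_hyb",
    "write_viennad",
    "read_viennad",
    "format_evalue",
    "format_energy",
]

PathLike = Union[str, Path]

COLLAPSED_ID_RE = re.compile(r"^(\d+)(?:-(\d+))?_(\d+)$")
_RANDOM_TAG_RE = re.compile(r"^(.*):([ACGTN]+)$")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed input files; carries the file line number."""

    def __init__(self, message: str, path: Optional[PathLike] = None,
                 line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


def _open_text(path: PathLike, mode: str = "rt",
               gz: Optional[bool] = None) -> IO[str]:
    if gz is None:
        gz = str(path).endswith(".gz")
    if gz:
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# SequenceRecord
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A single sequencing read.

    ``qual`` holds Phred scores (Phred+33 on disk).  After PCR-duplicate
    collapsing, ``rank``/``n_barcodes``/``count`` carry the ``K-L_M``
    metadata and ``collapsed_id`` renders it back.
    """

    id: str
    seq: str
    qual: Optional[list[int]] = None
    random_tag: Optional[str] = None
    rank: Optional[int] = None
    n_barcodes: Optional[int] = None
    count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}")
        if (self.count is not None and self.n_barcodes is not None
                and not self.count >= self.n_barcodes >= 1):
            raise ValueError(
                f"record {self.id!r}: need count >= n_barcodes >= 1, got "
                f"{self.count} / {self.n_barcodes}")

    @property
    def collapsed_id(self) -> str:
        """Identifier in the ``K-L_M`` (with barcodes) or ``K_M`` form."""
        if self.rank is None or self.count is None:
            return self.id
        if self.n_barcodes is not None:
            return f"{self.rank}-{self.n_barcodes}_{self.count}"
        return f"{self.rank}_{self.count}"

    @property
    def weight(self) -> int:
        """Number of raw reads this record stands for (1 if uncollapsed)."""
        return self.count if self.count is not None else 1

    def __len__(self) -> int:
        return len(self.seq)


def parse_collapse_metadata(identifier: str):
    """Parse ``K_M`` / ``K-L_M`` collapse metadata from an identifier.

    Returns (rank, n_barcodes, count); all None when the id does not
    follow the convention.
    """
    m = COLLAPSED_ID_RE.match(identifier)
    if not m:
        return None, None, None
    rank = int(m.group(1))
    n_bar = int(m.group(2)) if m.group(2) is not None else None
    count = int(m.group(3))
    return rank, n_bar, count


def read_weight(identifier: str) -> int:
    """Collapse count M encoded in an identifier, or 1."""
    _, _, count = parse_collapse_metadata(identifier)
    return count if count is not None else 1


def _infer_format(path: PathLike) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fastq", ".fq")):
        return "fastq"
    if name.endswith((".fasta", ".fa", ".fas")):
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path!r}; "
                     "pass format='fastq' or 'fasta'")


def _make_record(identifier: str, seq: str, qual: Optional[list[int]],
                 parse_random_tag: bool) -> SequenceRecord:
    token = identifier.split()[0] if identifier.split() else identifier
    random_tag = None
    if parse_random_tag:
        m = _RANDOM_TAG_RE.match(token)
        if m:
            token_base, random_tag = m.group(1), m.group(2)
        else:
            token_base = token
        rank, n_bar, count = parse_collapse_metadata(token_base)
    else:
        rank, n_bar, count = parse_collapse_metadata(token)
    return SequenceRecord(id=token, seq=seq, qual=qual,
                          random_tag=random_tag, rank=rank,
                          n_barcodes=n_bar, count=count)


def read_sequences(path: PathLike, format: Optional[str] = None,
                   gz: Optional[bool] = None,
                   parse_random_tag: bool = False
                   ) -> Iterator[SequenceRecord]:
    """Stream reads from a FASTA or FASTQ file (gzip transparent).

    Collapse metadata is parsed from identifiers matching ``K_M`` /
    ``K-L_M``.  With ``parse_random_tag=True``, a trailing ``:TAG`` on
    the identifier (as written by the demultiplexer) is split off into
    ``random_tag``.  Malformed records raise :class:`FormatError` naming
    the line number.
    """
    fmt = format or _infer_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown sequence format {fmt!r}")
    with _open_text(path, gz=gz) as fh:
        if fmt == "fastq":
            yield from _read_fastq(fh, path, parse_random_tag)
        else:
            yield from _read_fasta(fh, path, parse_random_tag)


def _read_fastq(fh: IO[str], path: PathLike,
                parse_random_tag: bool) -> Iterator[SequenceRecord]:
    lineno = 0
    while True:
        header = fh.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header:
            continue
        if not header.startswith("@"):
            raise FormatError("expected '@' header", path, lineno)
        seq = fh.readline().rstrip("\n")
        plus = fh.readline().rstrip("\n")
        qual = fh.readline().rstrip("\n")
        if not qual and not plus:
            raise FormatError("truncated FASTQ record", path, lineno)
        lineno += 3
        if not plus.startswith("+"):
            raise FormatError("expected '+' separator", path, lineno - 1)
        if len(qual) != len(seq):
            raise FormatError(
                f"quality length {len(qual)} != sequence length {len(seq)}",
                path, lineno)
        scores = []
        for ch in qual:
            q = ord(ch) - 33
            if q < 0 or q > 93:
                raise FormatError(
                    f"quality character {ch!r} outside Phred+33 range",
                    path, lineno)
            scores.append(q)
        yield _make_record(header[1:], seq.upper(), scores, parse_random_tag)


def _read_fasta(fh: IO[str], path: PathLike,
                parse_random_tag: bool) -> Iterator[SequenceRecord]:
    header = None
    chunks: list[str] = []
    header_line = 0
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield _make_record(header, "".join(chunks).upper(), None,
                                   parse_random_tag)
            header = line[1:]
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FormatError("sequence data before first '>' header",
                                  path, lineno)
            chunks.append(line.strip())
    if header is not None:
        if not "".join(chunks):
            raise FormatError("header with no sequence", path, header_line)
        yield _make_record(header, "".join(chunks).upper(), None,
                           parse_random_tag)


def write_fasta(records: Iterable[SequenceRecord], path: PathLike,
                use_collapsed_id: bool = False) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            name = rec.collapsed_id if use_collapsed_id else rec.id
            fh.write(f">{name}\n{rec.seq}\n")


def write_fastq(records: Iterable[SequenceRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no qualities; "
                                 "cannot write FASTQ")
            quals = "".join(chr(q + 33) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{quals}\n")


# ---------------------------------------------------------------------------
# Blast tabular
# ---------------------------------------------------------------------------

@dataclass
class AlignmentHit:
    """One local alignment in blast-tabular ("blast8") semantics.

    Query coordinates are 1-based inclusive and always ascending;
    subject coordinates with ``s_start > s_end`` denote an antisense
    match.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 1 <= self.q_start <= self.q_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: invalid query "
                f"interval [{self.q_start},{self.q_end}]")
        if self.evalue < 0:
            raise ValueError("negative e-value")

    @property
    def sense(self) -> bool:
        return self.s_start <= self.s_end

    @property
    def strand(self) -> str:
        return "+" if self.sense else "-"

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start + 1

    @property
    def s_interval(self) -> tuple[int, int]:
        """Subject interval with ascending coordinates."""
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))

    @property
    def score(self) -> float:
        """Mapping score used for chimera calling (bit score)."""
        return self.bit_score


def parse_blast_tab(path: PathLike) -> Iterator[AlignmentHit]:
    """Stream :class:`AlignmentHit` from a 12-column blast tabular file."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"expected 12 tab-separated columns, found {len(fields)}",
                    path, lineno)
            try:
                yield AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_openings=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"bad alignment record: {exc}",
                                  path, lineno) from exc


def write_blast_tab(hits: Iterable[AlignmentHit], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                str(h.aln_len), str(h.mismatches), str(h.gap_openings),
                str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                format_evalue(h.evalue), f"{h.bit_score:g}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Transcript database
# ---------------------------------------------------------------------------

@dataclass
class TranscriptEntry:
    full_id: str
    display_name: str
    biotype: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def _parse_db_header(full_id: str) -> tuple[str, str]:
    fields = full_id.split("_")
    if len(fields) < 2:
        raise FormatError(
            f"transcript id {full_id!r} lacks the underscore-delimited "
            "biotype field (expected e.g. NAME_display_biotype)")
    return fields[-2], fields[-1]


class TranscriptDB:
    """Ordered transcript collection keyed by full id.

    Headers encode the biotype as the last underscore-delimited field
    and the display name as the second to last, keeping the database a
    plain FASTA file.
    """

    def __init__(self, entries: Iterable[TranscriptEntry]):
        self._entries: dict[str, TranscriptEntry] = {}
        for e in entries:
            if e.full_id in self._entries:
                raise ValueError(f"duplicate transcript id {e.full_id!r}")
            self._entries[e.full_id] = e

    @classmethod
    def from_fasta(cls, path: PathLike) -> "TranscriptDB":
        entries = []
        for rec in read_sequences(path, format="fasta"):
            display, biotype = _parse_db_header(rec.id)
            entries.append(TranscriptEntry(rec.id, display, biotype,
                                           rec.seq))
        if not entries:
            raise FormatError("empty transcript database", path)
        return cls(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[TranscriptEntry]:
        return iter(self._entries.values())

    def __contains__(self, full_id: str) -> bool:
        return full_id in self._entries

    def __getitem__(self, full_id: str) -> TranscriptEntry:
        return self._entries[full_id]

    @property
    def ids(self) -> list[str]:
        return list(self._entries)

    @property
    def total_length(self) -> int:
        return sum(len(e.seq) for e in self._entries.values())

    def subseq(self, full_id: str, start: int, end: int) -> str:
        """Substring at 1-based inclusive coordinates, bounds-checked."""
        entry = self._entries[full_id]
        if not 1 <= start <= end <= len(entry.seq):
            raise ValueError(
                f"coordinates [{start},{end}] out of range for "
                f"{full_id!r} (length {len(entry.seq)})")
        return entry.seq[start - 1:end]

    def write_fasta(self, path: PathLike) -> None:
        with _open_text(path, "wt") as fh:
            for e in self:
                fh.write(f">{e.full_id}\n{e.seq}\n")


# ---------------------------------------------------------------------------
# Chimera calls and .hyb
# ---------------------------------------------------------------------------

@dataclass
class Fragment:
    """One aligned fragment of a chimera.

    ``q`` coordinates are 1-based in the read, ``s`` coordinates 1-based
    ascending in the transcript; minus-strand fragments (possible only
    with anti=1 against genomic databases) carry ``strand='-'``.
    """

    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 1 <= self.q_start <= self.q_end:
            raise ValueError(f"fragment {self.subject_id}: bad read interval "
                             f"[{self.q_start},{self.q_end}]")
        if not 1 <= self.s_start <= self.s_end:
            raise ValueError(f"fragment {self.subject_id}: bad subject "
                             f"interval [{self.s_start},{self.s_end}]")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class DuplexResult:
    """An intermolecular RNA-RNA duplex prediction.

    ``structure`` is dot-bracket over ``seq1 & seq2`` with '(' in seq1
    and ')' in seq2; ``dG`` is the predicted free energy in kcal/mol
    (0 for the empty structure).
    """

    seq1: str
    seq2: str
    structure: str
    dG: float

    def __post_init__(self) -> None:
        expected = len(self.seq1) + 1 + len(self.seq2)
        if len(self.structure) != expected:
            raise ValueError(
                f"structure length {len(self.structure)} != "
                f"len(seq1)+1+len(seq2) = {expected}")
        part1, sep, part2 = self.structure.partition("&")
        if not sep or len(part1) != len(self.seq1):
            raise ValueError("structure '&' separator misplaced")
        if part1.count(")") or part2.count("("):
            raise ValueError("brackets must open in seq1 and close in seq2")
        if part1.count("(") != part2.count(")"):
            raise ValueError("unbalanced brackets")
        if (part1.count("(") == 0) != (self.dG == 0):
            raise ValueError("dG must be 0 iff the structure is empty")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as 1-based (pos in seq1, pos in seq2) tuples."""
        part1, _, part2 = self.structure.partition("&")
        opens = [i + 1 for i, c in enumerate(part1) if c == "("]
        closes = [j + 1 for j, c in enumerate(part2) if c == ")"]
        # intermolecular nesting: i ascending pairs with j descending
        return list(zip(opens, reversed(closes)))


@dataclass
class ChimeraCall:
    """One called chimera: two annotated fragments plus the read.

    This is the unit of the ``.hyb`` format.  Fragments are stored in
    read order (frag1.q_start <= frag2.q_start).
    """

    read_id: str
    read_seq: str
    frag1: Fragment
    frag2: Fragment
    dG: Optional[float] = None
    annotation: Optional[str] = None
    duplex: Optional[DuplexResult] = None

    def __post_init__(self) -> None:
        if self.frag1.q_start > self.frag2.q_start:
            raise ValueError(
                f"call {self.read_id}: fragments must be in read order")

    @property
    def weight(self) -> int:
        return read_weight(self.read_id)


def format_evalue(e: float) -> str:
    """Blast-style e-value rendering (``0.003`` but ``7e-04``)."""
    if e == 0:
        return "0"
    if e >= 1e-3:
        return f"{e:g}"
    return f"{e:.0e}"


def format_energy(dg: float) -> str:
    return f"{round(dg, 2):g}"


def _frag_columns(frag: Fragment) -> list[str]:
    return [frag.subject_id, str(frag.q_start), str(frag.q_end),
            str(frag.s_start), str(frag.s_end), format_evalue(frag.evalue)]


def _annotation_with_strands(call: ChimeraCall) -> Optional[str]:
    notes = []
    if call.frag1.strand == "-":
        notes.append("strand1=-;")
    if call.frag2.strand == "-":
        notes.append("strand2=-;")
    if call.annotation:
        notes.append(call.annotation)
    return " ".join(notes) if notes else None


def write_hyb(calls: Iterable[ChimeraCall], path: PathLike) -> None:
    """Write calls as 15-column ``.hyb`` (+ optional 16th annotation).

    Column 3 is '.' for calls that have not been folded.  Minus-strand
    fragments are flagged in the annotation column so that the
    coordinate columns always satisfy start <= end.
    """
    with _open_text(path, "wt") as fh:
        for call in calls:
            cols = [call.read_id, call.read_seq,
                    "." if call.dG is None else format_energy(call.dG)]
            cols += _frag_columns(call.frag1)
            cols += _frag_columns(call.frag2)
            ann = _annotation_with_strands(call)
            if ann is not None:
                cols.append(ann)
            fh.write("\t".join(cols) + "\n")


def _parse_frag(fields: list[str], strand: str) -> Fragment:
    return Fragment(subject_id=fields[0], q_start=int(fields[1]),
                    q_end=int(fields[2]), s_start=int(fields[3]),
                    s_end=int(fields[4]), evalue=float(fields[5]),
                    strand=strand)


def read_hyb(path: PathLike) -> Iterator[ChimeraCall]:
    """Stream chimera calls from a ``.hyb`` file (inverse of write_hyb)."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (15, 16):
                raise FormatError(
                    f"expected 15 or 16 columns, found {len(fields)}",
                    path, lineno)
            annotation = fields[15] if len(fields) == 16 else None
            strand1 = strand2 = "+"
            if annotation is not None:
                notes = annotation.split()
                if "strand1=-;" in notes:
                    strand1 = "-"
                    notes.remove("strand1=-;")
                if "strand2=-;" in notes:
                    strand2 = "-"
                    notes.remove("strand2=-;")
                annotation = " ".join(notes) or None
            try:
                yield ChimeraCall(
                    read_id=fields[0],
                    read_seq=fields[1],
                    dG=None if fields[2] == "." else float(fields[2]),
                    frag1=_parse_frag(fields[3:9], strand1),
                    frag2=_parse_frag(fields[9:15], strand2),
                    annotation=annotation,
                )
            except ValueError as exc:
                raise FormatError(f"bad .hyb record: {exc}", path,
                                  lineno) from exc


# ---------------------------------------------------------------------------
# viennad
# ---------------------------------------------------------------------------

def write_viennad(calls: Iterable[ChimeraCall], path: PathLike) -> None:
    """Write one six-line block per folded chimera.

    Block layout: (1) read id; (2) fragment-1 sequence with
    ``id s_start s_end`` suffix; (3) same for fragment 2; (4) the
    concatenated duplex sequences joined by '&'; (5) the dot-bracket
    structure; (6) ``dG = <value> kcal/mol``.
    """
    with _open_text(path, "wt") as fh:
        for call in calls:
            d = call.duplex
            if d is None:
                raise ValueError(f"call {call.read_id} has no duplex result")
            if call.dG is None:
                raise ValueError(f"call {call.read_id} has no dG")
            f1, f2 = call.frag1, call.frag2
            fh.write(f"{call.read_id}\n")
            fh.write(f"{d.seq1}\t{f1.subject_id}\t{f1.s_start}\t{f1.s_end}\n")
            fh.write(f"{d.seq2}\t{f2.subject_id}\t{f2.s_start}\t{f2.s_end}\n")
            fh.write(f"{d.seq1}&{d.seq2}\n")
            fh.write(f"{d.structure}\n")
            fh.write(f"dG = {format_energy(call.dG)} kcal/mol\n")


@dataclass
class ViennadBlock:
    read_id: str
    frag1_id: str
    frag1_interval: tuple[int, int]
    frag2_id: str
    frag2_interval: tuple[int, int]
    duplex: DuplexResult


def read_viennad(path: PathLike) -> Iterator[ViennadBlock]:
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) % 6 != 0:
        raise FormatError(f"viennad file length {len(lines)} is not a "
                          "multiple of 6", path)
    for k in range(0, len(lines), 6):
        block = lines[k:k + 6]
        s1, id1, a1, b1 = block[1].split("\t")
        s2, id2, a2, b2 = block[2].split("\t")
        m = re.match(r"^dG = (\S+) kcal/mol$", block[5])
        if m is None:
            raise FormatError("malformed energy line", path, k + 6)
        duplex = DuplexResult(seq1=s1, seq2=s2, structure=block[4],
                              dG=float(m.group(1)))
        if block[3] != f"{s1}&{s2}":
            raise FormatError("concatenated sequence line disagrees with "
                              "fragment lines", path, k + 4)
        yield ViennadBlock(read_id=block[0], frag1_id=id1,
                           frag1_interval=(int(a1), int(b1)),
                           frag2_id=id2, frag2_interval=(int(a2), int(b2)),
                           duplex=duplex)


# ---------------------------------------------------------------------------
# Interactions (merged chimeras)
# ---------------------------------------------------------------------------

@dataclass
class Interaction:
    """A cluster of merged chimera calls between one transcript pair."""

    id1: str
    id2: str
    span1: tuple[int, int]
    span2: tuple[int, int]
    n_chimeras: int
    n_reads: int
    mean_dG: Optional[float]
    supporting_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.n_reads >= self.n_chimeras >= 1:
            raise ValueError("need n_reads >= n_chimeras >= 1")


INTERACTION_COLUMNS = ["id1", "span1_start", "span1_end", "id2",
                       "span2_start", "span2_end", "n_chimeras", "n_reads",
                       "mean_dG", "supporting_ids"]


def write_interactions(interactions: Iterable[Interaction],
                       path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(INTERACTION_COLUMNS) + "\n")
        for x in interactions:
            fh.write("\t".join([
                x.id1, str(x.span1[0]), str(x.span1[1]),
                x.id2, str(x.span2[0]), str(x.span2[1]),
                str(x.n_chimeras), str(x.n_reads),
                "." if x.mean_dG is None else format_energy(x.mean_dG),
                ",".join(x.supporting_ids),
            ]) + "\n")
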