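"""Format converters: .hyb to GFF3 and transcript-to-genome projection.

``hyb_to_gff`` splits each chimera into two GFF3 features (one per
fragment) on the transcript coordinate system.  ``transcript_to_genome``
projects a transcript interval through an exon map onto genomic
coordinates, splitting spliced intervals into one genomic block per
exon crossed and handling minus-strand transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .formats import ChimeraCall, FormatError, format_energy

__all__ = ["hyb_to_gff", "write_gff", "ExonMap", "transcript_to_genome"]

_GFF_HEADER = "##gff-version 3"


def hyb_to_gff(calls: Iterable[ChimeraCall],
               source: str = "hyb") -> list[str]:
    """GFF3 lines for a stream of chimera calls (2 per chimera).

    seqid is the transcript id; coordinates are the fragment's
    1-based inclusive transcript coordinates; attributes carry the
    read id, the partner transcript, and the folding energy.
    """
    lines = [_GFF_HEADER]
    for call in calls:
        dg = "." if call.dG is None else format_energy(call.dG)
        for frag, partner, idx in ((call.frag1, call.frag2, 1),
                                   (call.frag2, call.frag1, 2)):
            attrs = (f"ID={call.read_id}.{idx};read_id={call.read_id};"
                     f"partner={partner.subject_id};dG={dg}")
            lines.append("\t".join([
                frag.subject_id, source, "chimeric_fragment",
                str(frag.s_start), str(frag.s_end), ".",
                frag.strand, ".", attrs]))
    return lines


def write_gff(calls: Iterable[ChimeraCall], path,
              source: str = "hyb") -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(hyb_to_gff(calls, source=source)) + "\n")


@dataclass
class _Transcript:
    chrom: str
    strand: str
    # exon blocks as 1-based inclusive genomic intervals, ascending
    blocks: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)


class ExonMap:
    """Transcript-to-genome exon structures (BED12 or GFF exon lines).

    Internally each transcript is an ordered list of genomic exon
    blocks (1-based inclusive) on a chromosome and strand; for
    minus-strand transcripts the first transcript base is the *end* of
    the last genomic block.
    """

    def __init__(self, transcripts: dict[str, _Transcript]):
        self._tx = transcripts

    def __contains__(self, tx_id: str) -> bool:
        return tx_id in self._tx

    def __getitem__(self, tx_id: str) -> _Transcript:
        return self._tx[tx_id]

    @classmethod
    def from_bed12(cls, path) -> "ExonMap":
        tx = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 12:
                    raise FormatError("expected 12 BED columns", path,
                                      lineno)
                chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], \
                    f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                    raise FormatError("blockCount disagrees with block "
                                      "lists", path, lineno)
                blocks = [(chrom_start + st + 1, chrom_start + st + sz)
                          for st, sz in zip(starts, sizes)]
                tx[name] = _Transcript(chrom=chrom, strand=strand,
                                       blocks=blocks)
        if not tx:
            raise FormatError("no transcripts in exon map", path)
        return cls(tx)

    @classmethod
    def from_gff(cls, path) -> "ExonMap":
        """Collect ``exon`` features grouped by Parent (or transcript_id)."""
        raw: dict[str, _Transcript] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) != 9:
                    raise FormatError("expected 9 GFF columns", path, lineno)
                if f[2].lower() != "exon":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";")
                             if "=" in kv)
                parent = attrs.get("Parent") or attrs.get("transcript_id")
                if parent is None:
                    raise FormatError("exon without Parent/transcript_id",
                                      path, lineno)
                block = (int(f[3]), int(f[4]))
                if parent in raw:
                    raw[parent].blocks.append(block)
                else:
                    raw[parent] = _Transcript(chrom=f[0], strand=f[6],
                                              blocks=[block])
        if not raw:
            raise FormatError("no exon features in exon map", path)
        for t in raw.values():
            t.blocks.sort()
        return cls(raw)


def transcript_to_genome(tx_id: str, s_start: int, s_end: int,
                         exon_map: ExonMap
                         ) -> list[tuple[str, int, int, str]]:
    """Project a transcript interval onto the genome.

    Returns (chrom, start, end, strand) blocks, 1-based inclusive, in
    transcript order; the projected lengths always sum to
    ``s_end - s_start + 1``.
    """
    if tx_id not in exon_map:
        raise KeyError(f"transcript {tx_id!r} absent from exon map")
    tx = exon_map[tx_id]
    if not 1 <= s_start <= s_end <= tx.length:
        raise ValueError(
            f"interval [{s_start},{s_end}] outside transcript {tx_id!r} "
            f"(length {tx.length})")
    # exon blocks in transcript order
    blocks = tx.blocks if tx.strand == "+" else list(reversed(tx.blocks))
    out = []
    offset = 0  # transcript bases before the current block
    for (gs, ge) in blocks:
        size = ge - gs + 1
        lo = max(s_start, offset + 1)
        hi = min(s_end, offset + size)
        if lo <= hi:
            if tx.strand == "+":
                out.append((tx.chrom, gs + (lo - offset - 1),
                            gs + (hi - offset - 1), "+"))
            else:
                out.append((tx.chrom, ge - (hi - offset - 1),
                            ge - (lo - offset - 1), "-"))
        offset += size
    return out
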