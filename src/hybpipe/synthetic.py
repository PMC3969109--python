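"""Synthetic CLASH libraries with known ground truth.

The generators emulate the structure of a CLASH sequencing experiment
so every pipeline stage can be exercised without external data: a
transcript database of random-composition mRNAs (optionally with
near-identical isoform copies for a fraction of genes, reproducing the
multi-mapping that real databases show when several transcripts per
gene are present) and 22-nt microRNAs; fusion reads formed by
concatenating a mature miRNA with a short mRNA fragment (the
signature of an RNA-RNA ligation event), optionally with a 3' linker
remnant; contiguous mRNA segments as non-chimeric background; and
multiplexed FASTQ with composite 5' barcodes and PCR duplicates.

All generators are pure functions of their parameters and the seed,
and return truth tables sufficient to score recovery, breakpoint
accuracy and demultiplexing without re-deriving anything.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .demultiplex import BarcodeSpec
from .formats import (SequenceRecord, TranscriptDB, TranscriptEntry,
                      reverse_complement)

__all__ = ["make_transcript_db", "make_fusion_reads", "make_seeded_library",
           "make_contiguous_reads", "make_multiplexed_fastq",
           "gene_of", "MIRNA_LENGTH"]

_BASES = np.array(list("ACGT"))
MIRNA_LENGTH = 22
_DEFAULT_QUAL = 40


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def gene_of(full_id: str) -> str:
    """Gene-level name of a synthetic transcript (its display name)."""
    return full_id.split("_")[-2]


def make_transcript_db(n_mrna: int = 60, n_mirna: int = 30,
                       mrna_len_range: tuple[int, int] = (500, 1500),
                       redundancy: int = 1,
                       redundant_fraction: float = 0.1,
                       isoform_divergence: float = 0.01,
                       seed: int = 0) -> TranscriptDB:
    """Random transcript database with biotype-encoded headers.

    ``n_mrna`` genes get one mRNA each; a ``redundant_fraction`` of
    them (the first ones, deterministically) instead get ``redundancy``
    near-identical isoforms diverging by ``isoform_divergence``
    substitutions per site -- the situation that makes fragments
    multi-map past the hmax filter.  ``n_mirna`` microRNAs of 22 nt are
    appended.  Byte-identical output under the same seed.
    """
    if n_mrna < 1 or n_mirna < 0:
        raise ValueError("need at least one mRNA and n_mirna >= 0")
    rng = np.random.default_rng(seed)
    entries = []
    n_redundant = int(round(n_mrna * redundant_fraction)) \
        if redundancy > 1 else 0
    for g in range(n_mrna):
        length = int(rng.integers(mrna_len_range[0],
                                  mrna_len_range[1] + 1))
        base = _random_seq(rng, length)
        n_iso = redundancy if g < n_redundant else 1
        for iso in range(1, n_iso + 1):
            seq = base if iso == 1 else _mutate(rng, base,
                                                isoform_divergence)
            entries.append(TranscriptEntry(
                full_id=f"SYNTG{g:05d}.{iso}_GENE{g:05d}_mRNA",
                display_name=f"GENE{g:05d}", biotype="mRNA", seq=seq))
    for i in range(n_mirna):
        entries.append(TranscriptEntry(
            full_id=f"SYNMIMAT{i:05d}_syn-miR-{i}_microRNA",
            display_name=f"syn-miR-{i}", biotype="microRNA",
            seq=_random_seq(rng, MIRNA_LENGTH)))
    return TranscriptDB(entries)


def _db_split(db: TranscriptDB):
    mirnas = [e for e in db if e.biotype == "microRNA"]
    mrnas = [e for e in db if e.biotype == "mRNA"]
    return mirnas, mrnas


def make_fusion_reads(n: int, db: TranscriptDB, frag_len: int = 30,
                      order: str = "mixed", linker: Optional[str] = None,
                      seed: int = 0
                      ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulated chimeric reads: mature miRNA + mRNA fragment.

    Each read concatenates a (whole) mature miRNA with a ``frag_len``
    mRNA segment -- miRNA first, mRNA first, or mixed per read -- with
    an optional 3' linker suffix.

    Returns FASTQ-ready records and a truth table with the source
    transcripts, fragment coordinates and the breakpoint position
    (last base of the first fragment).
    """
    if order not in ("mirna_first", "mrna_first", "mixed"):
        raise ValueError(f"unknown order {order!r}")
    mirnas, mrnas = _db_split(db)
    if not mirnas or not mrnas:
        raise ValueError("database must contain both microRNAs and mRNAs")
    rng = np.random.default_rng(seed)
    genes = sorted({gene_of(e.full_id) for e in mrnas})
    by_gene: dict[str, list[TranscriptEntry]] = {}
    for e in mrnas:
        by_gene.setdefault(gene_of(e.full_id), []).append(e)
    reads, truth = [], []
    for k in range(n):
        mir = mirnas[rng.integers(0, len(mirnas))]
        gene = genes[rng.integers(0, len(genes))]
        isoforms = by_gene[gene]
        mrna = isoforms[rng.integers(0, len(isoforms))]
        pos = int(rng.integers(0, len(mrna.seq) - frag_len + 1))
        frag = mrna.seq[pos:pos + frag_len]
        this_order = order
        if order == "mixed":
            this_order = "mirna_first" if rng.random() < 0.5 \
                else "mrna_first"
        if this_order == "mirna_first":
            insert = mir.seq + frag
            breakpoint = len(mir.seq)
        else:
            insert = frag + mir.seq
            breakpoint = frag_len
        seq = insert + (linker or "")
        read_id = f"r{k:06d}"
        reads.append(SequenceRecord(id=read_id, seq=seq,
                                    qual=[_DEFAULT_QUAL] * len(seq)))
        truth.append({
            "read_id": read_id, "mirna_id": mir.full_id,
            "mrna_id": mrna.full_id, "gene": gene, "order": this_order,
            "breakpoint": breakpoint, "mrna_start": pos + 1,
            "mrna_end": pos + frag_len,
        })
    return reads, pd.DataFrame(truth)


def make_seeded_library(n: int, db: TranscriptDB, frag_len: int = 30,
                        order: str = "mixed", seed: int = 0
                        ) -> tuple[TranscriptDB, list[SequenceRecord],
                                   pd.DataFrame]:
    """Fusion library whose targets carry cognate seed-match sites.

    Builds a copy of the database in which, for every planned fusion
    read, the reverse complement of the miRNA's nt 2-8 is written into
    the target mRNA at the fragment position; reads are then generated
    from the *seeded* database.  This gives the folding and seed-match
    QC statistics planted true positives: cognate pairs fold more
    stably and contain seed sites, while randomly re-associated pairs
    do not.

    Returns (seeded database, reads, truth table).
    """
    if order not in ("mirna_first", "mrna_first", "mixed"):
        raise ValueError(f"unknown order {order!r}")
    mirnas, mrnas = _db_split(db)
    if not mirnas or not mrnas:
        raise ValueError("database must contain both microRNAs and mRNAs")
    rng = np.random.default_rng(seed)
    seqs = {e.full_id: e.seq for e in db}
    genes = sorted({gene_of(e.full_id) for e in mrnas})
    by_gene: dict[str, list[TranscriptEntry]] = {}
    for e in mrnas:
        by_gene.setdefault(gene_of(e.full_id), []).append(e)
    plan = []
    for k in range(n):
        mir = mirnas[rng.integers(0, len(mirnas))]
        gene = genes[rng.integers(0, len(genes))]
        isoforms = by_gene[gene]
        mrna = isoforms[rng.integers(0, len(isoforms))]
        pos = int(rng.integers(0, len(mrna.seq) - frag_len + 1))
        site = reverse_complement(mir.seq[1:8])
        off = int(rng.integers(0, frag_len - len(site) + 1))
        seq = seqs[mrna.full_id]
        seqs[mrna.full_id] = (seq[:pos + off] + site
                              + seq[pos + off + len(site):])
        plan.append((k, mir, mrna, gene, pos))
    seeded = TranscriptDB([
        TranscriptEntry(e.full_id, e.display_name, e.biotype,
                        seqs[e.full_id]) for e in db])
    reads, truth = [], []
    for k, mir, mrna, gene, pos in plan:
        frag = seeded[mrna.full_id].seq[pos:pos + frag_len]
        this_order = order
        if order == "mixed":
            this_order = "mirna_first" if rng.random() < 0.5 \
                else "mrna_first"
        if this_order == "mirna_first":
            insert = mir.seq + frag
            breakpoint = len(mir.seq)
        else:
            insert = frag + mir.seq
            breakpoint = frag_len
        read_id = f"r{k:06d}"
        reads.append(SequenceRecord(id=read_id, seq=insert,
                                    qual=[_DEFAULT_QUAL] * len(insert)))
        truth.append({
            "read_id": read_id, "mirna_id": mir.full_id,
            "mrna_id": mrna.full_id, "gene": gene, "order": this_order,
            "breakpoint": breakpoint, "mrna_start": pos + 1,
            "mrna_end": pos + frag_len,
        })
    return seeded, reads, pd.DataFrame(truth)


def make_contiguous_reads(n: int, db: TranscriptDB, read_len: int = 50,
                          seed: int = 0) -> list[SequenceRecord]:
    """Non-chimeric background: contiguous mRNA segments."""
    _, mrnas = _db_split(db)
    usable = [e for e in mrnas if len(e.seq) >= read_len]
    if not usable:
        raise ValueError(f"no mRNA of length >= {read_len} in database")
    rng = np.random.default_rng(seed)
    reads = []
    for k in range(n):
        src = usable[rng.integers(0, len(usable))]
        pos = int(rng.integers(0, len(src.seq) - read_len + 1))
        seq = src.seq[pos:pos + read_len]
        reads.append(SequenceRecord(id=f"c{k:06d}", seq=seq,
                                    qual=[_DEFAULT_QUAL] * read_len))
    return reads


def make_multiplexed_fastq(barcode_specs: Sequence[BarcodeSpec],
                           n_inserts_per_sample: int = 50,
                           insert_len: int = 40,
                           pcr_dup_rate: float = 0.3,
                           natural_dup_rate: float = 0.1,
                           seed: int = 0
                           ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Multiplexed raw reads with composite 5' barcodes.

    Each sample receives ``n_inserts_per_sample`` distinct cDNA
    molecules, each prefixed with its sample's barcode pattern (random
    positions drawn fresh per molecule).  PCR duplicates copy a
    molecule *including* its random tag; natural duplicates reuse an
    insert sequence but draw a fresh random tag.  The truth table
    records sample, insert, and random tag for every read.
    """
    rng = np.random.default_rng(seed)
    reads, truth = [], []
    k = 0
    for spec in barcode_specs:
        rand_pos = spec.random_positions
        inserts = {_random_seq(rng, insert_len)
                   for _ in range(n_inserts_per_sample)}
        molecules = []  # (insert, tag)
        for insert in sorted(inserts):
            tag = _random_seq(rng, len(rand_pos))
            molecules.append((insert, tag))
            if rng.random() < natural_dup_rate:
                molecules.append((insert, _random_seq(rng, len(rand_pos))))
        final = []
        for insert, tag in molecules:
            final.append((insert, tag))
            while rng.random() < pcr_dup_rate:
                final.append((insert, tag))  # PCR copy keeps the tag
        for insert, tag in final:
            prefix = list(spec.pattern)
            for p, b in zip(rand_pos, tag):
                prefix[p] = b
            seq = "".join(prefix) + insert
            read_id = f"m{k:06d}"
            k += 1
            reads.append(SequenceRecord(id=read_id, seq=seq,
                                        qual=[_DEFAULT_QUAL] * len(seq)))
            truth.append({"read_id": read_id, "sample": spec.sample,
                          "insert": insert, "random_tag": tag})
    return reads, pd.DataFrame(truth)
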