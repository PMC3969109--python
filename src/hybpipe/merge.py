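"""Merging overlapping chimeras into interactions, plus QC statistics.

Two chimeras support the same RNA-RNA interaction when they join the
same transcript pair and their fragment coordinates overlap on *both*
transcripts (by at least one nucleotide) -- akin to an interval-merge,
but requiring the dual overlap.  Merging takes the transitive closure
of that relation; each resulting interaction reports the coordinate
envelopes, the number of supporting chimeras and raw reads, the mean
folding energy, and the supporting read identifiers.

The QC statistics summarize the properties that separate genuine
interactions from artefacts: mean predicted folding energy, the
fraction of miRNA-mRNA chimeras whose target fragment contains a seed
match, and the fraction of chimeras with zero gap/overlap between the
fragments.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .chimera import gap_or_overlap
from .formats import (ChimeraCall, Fragment, Interaction, TranscriptDB,
                      reverse_complement)

__all__ = ["merge_interactions", "interaction_qc", "seed_match"]


def _canonical(call: ChimeraCall) -> tuple:
    """Transcript-pair key and per-side intervals, order-normalized.

    Fragments are reattached to a canonical side so that the two read
    orientations of the same interaction (miRNA first or target first)
    merge together.
    """
    f1, f2 = call.frag1, call.frag2
    k1 = (f1.subject_id, f1.strand)
    k2 = (f2.subject_id, f2.strand)
    if (k2, (f2.s_start, f2.s_end)) < (k1, (f1.s_start, f1.s_end)):
        f1, f2 = f2, f1
    return ((f1.subject_id, f1.strand, f2.subject_id, f2.strand),
            (f1.s_start, f1.s_end), (f2.s_start, f2.s_end))


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return min(a[1], b[1]) - max(a[0], b[0]) + 1 >= 1


def merge_interactions(calls: Iterable[ChimeraCall]) -> list[Interaction]:
    """Cluster chimera calls into interactions.

    Transitive closure of "same transcript pair and both fragment
    intervals overlap"; idempotent and invariant under permutations of
    the input.  ``n_reads`` sums the collapse counts of the supporting
    reads; ``mean_dG`` averages over members that carry an energy.
    """
    groups: dict[tuple, list[tuple]] = {}
    for call in calls:
        key, iv1, iv2 = _canonical(call)
        groups.setdefault(key, []).append((iv1, iv2, call))

    interactions = []
    for key, members in groups.items():
        members.sort(key=lambda m: (m[0], m[1], m[2].read_id))
        parent = list(range(len(members)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if _overlaps(members[i][0], members[j][0]) and \
                        _overlaps(members[i][1], members[j][1]):
                    parent[find(i)] = find(j)

        clusters: dict[int, list[tuple]] = {}
        for i, member in enumerate(members):
            clusters.setdefault(find(i), []).append(member)

        for cluster in clusters.values():
            iv1s = [m[0] for m in cluster]
            iv2s = [m[1] for m in cluster]
            calls_in = [m[2] for m in cluster]
            energies = [c.dG for c in calls_in if c.dG is not None]
            interactions.append(Interaction(
                id1=key[0], id2=key[2],
                span1=(min(a for a, _ in iv1s), max(b for _, b in iv1s)),
                span2=(min(a for a, _ in iv2s), max(b for _, b in iv2s)),
                n_chimeras=len(calls_in),
                n_reads=sum(c.weight for c in calls_in),
                mean_dG=(sum(energies) / len(energies)) if energies
                else None,
                supporting_ids=sorted(c.read_id for c in calls_in),
            ))
    interactions.sort(key=lambda x: (x.id1, x.id2, x.span1, x.span2))
    return interactions


def seed_match(mirna_seq: str, target_seq: str) -> bool:
    """Canonical 6-mer seed site: reverse complement of miRNA nt 2-7
    occurs in the target sequence."""
    if len(mirna_seq) < 7:
        return False
    seed = mirna_seq.upper().replace("U", "T")[1:7]
    site = reverse_complement(seed)
    return site in target_seq.upper().replace("U", "T")


def _mim_fragments(call: ChimeraCall, db: TranscriptDB
                   ) -> Optional[tuple[Fragment, Fragment]]:
    """(miRNA fragment, target fragment) when the call is miRNA+mRNA."""
    b1 = db[call.frag1.subject_id].biotype
    b2 = db[call.frag2.subject_id].biotype
    if {b1, b2} != {"microRNA", "mRNA"}:
        return None
    return (call.frag1, call.frag2) if b1 == "microRNA" \
        else (call.frag2, call.frag1)


def interaction_qc(calls: Iterable[ChimeraCall],
                   db: Optional[TranscriptDB] = None) -> pd.DataFrame:
    """One-row QC table over a set of calls.

    Columns: n_chimeras; mean_dG over folded calls; zero_gap_fraction
    (fragments directly adjacent in the read); for miRNA-mRNA calls
    (requires ``db``), n_mim and seed_match_fraction.  Empty input
    yields an empty table.
    """
    calls = list(calls)
    if not calls:
        return pd.DataFrame()
    energies = [c.dG for c in calls if c.dG is not None]
    zero_gap = sum(1 for c in calls
                   if gap_or_overlap(c.frag1, c.frag2) == 0)
    row = {
        "n_chimeras": len(calls),
        "mean_dG": (sum(energies) / len(energies)) if energies else None,
        "zero_gap_fraction": zero_gap / len(calls),
    }
    if db is not None:
        n_mim = n_seed = 0
        for c in calls:
            pair = _mim_fragments(c, db)
            if pair is None:
                continue
            mir, tgt = pair
            n_mim += 1
            mir_seq = db[mir.subject_id].seq
            tgt_seq = db.subseq(tgt.subject_id, tgt.s_start, tgt.s_end)
            if seed_match(mir_seq, tgt_seq):
                n_seed += 1
        row["n_mim"] = n_mim
        row["seed_match_fraction"] = (n_seed / n_mim) if n_mim else None
    return pd.DataFrame([row])
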