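"""Intermolecular RNA-RNA duplex folding of called chimeras.

Each chimera's two fragments are folded against each other as an
RNA-RNA duplex: only intermolecular base pairs are considered (no
hairpins within either strand), with Watson-Crick and GU wobble pairs,
nearest-neighbor stacking energies, an affine penalty for interior and
bulge loops, and a duplex-initiation penalty.  The minimum-free-energy
structure is found by the standard two-sequence hybridization dynamic
program with loop sizes bounded at 30 nt per strand.

Folding operates on *database* sequences extracted at the call's
(possibly extended) coordinates, never on the read itself: reads may
carry crosslinking-induced substitutions and deletions that are
irrelevant to in-vivo pairing.

Energies are Turner-style nearest-neighbor stacking free energies for
RNA at 37 degrees C (1 M NaCl convention); see docs/methods.md for the
exact parameterization.  N bases never pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from numba import njit

from .formats import ChimeraCall, DuplexResult, TranscriptDB

__all__ = ["duplex_fold", "score_duplex", "extract_fold_sequences",
           "fold_chimeras", "INIT_PENALTY", "LOOP_OPEN", "LOOP_PER_NT",
           "MAX_LOOP", "pair_index", "stack_energy"]

# duplex initiation penalty, kcal/mol (Turner 2004 intermolecular init)
INIT_PENALTY = 4.09
# affine interior/bulge loop penalty: LOOP_OPEN + LOOP_PER_NT * unpaired nt
LOOP_OPEN = 2.0
LOOP_PER_NT = 0.5
MAX_LOOP = 30  # per strand, nt

# pair codes: AU=0 UA=1 CG=2 GC=3 GU=4 UG=5; -1 = not pairable
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

_PAIR_CODE = -np.ones((5, 5), dtype=np.int64)
_PAIR_CODE[0, 3] = 0   # A-U
_PAIR_CODE[3, 0] = 1   # U-A
_PAIR_CODE[1, 2] = 2   # C-G
_PAIR_CODE[2, 1] = 3   # G-C
_PAIR_CODE[2, 3] = 4   # G-U
_PAIR_CODE[3, 2] = 5   # U-G

# Turner 2004 Watson-Crick stack table (kcal/mol).  STACK[p][q] is the
# free energy of pair q stacked directly 3' of pair p (reading the
# first strand 5'->3').  The ten canonical WC values are laid out via
# the symmetry STACK[p][q] == STACK[rev(q)][rev(p)]; stacks involving
# one or two GU wobbles use representative constants.
_REV = {0: 1, 1: 0, 2: 3, 3: 2, 4: 5, 5: 4}
_GU_ONE = -1.3
_GU_TWO = -0.5

_WC_STACKS = {
    (0, 0): -0.93,  # 5'AA3'/3'UU5'
    (0, 1): -1.10,  # 5'AU3'/3'UA5'
    (1, 0): -1.33,  # 5'UA3'/3'AU5'
    (2, 1): -2.08,  # 5'CU3'/3'GA5'
    (2, 0): -2.11,  # 5'CA3'/3'GU5'
    (3, 1): -2.24,  # 5'GU3'/3'CA5'
    (3, 0): -2.35,  # 5'GA3'/3'CU5'
    (2, 3): -2.36,  # 5'CG3'/3'GC5'
    (3, 3): -3.26,  # 5'GG3'/3'CC5'
    (3, 2): -3.42,  # 5'GC3'/3'CG5'
}


def _build_stack_table() -> np.ndarray:
    table = np.zeros((6, 6), dtype=np.float64)
    for p in range(6):
        for q in range(6):
            n_gu = (p >= 4) + (q >= 4)
            if n_gu == 2:
                table[p, q] = _GU_TWO
            elif n_gu == 1:
                table[p, q] = _GU_ONE
            else:
                val = _WC_STACKS.get((p, q))
                if val is None:
                    val = _WC_STACKS[(_REV[q], _REV[p])]
                table[p, q] = val
    return table


_STACKS = _build_stack_table()


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq.upper()],
                        dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character {exc} in sequence")


def pair_index(b1: str, b2: str) -> int:
    """Pair code of two bases (-1 when they cannot pair)."""
    return int(_PAIR_CODE[_BASE_INDEX[b1.upper()], _BASE_INDEX[b2.upper()]])


def stack_energy(pair_a: int, pair_b: int) -> float:
    """Stacking energy of pair_b directly 3' (strand 1) of pair_a."""
    return float(_STACKS[pair_a, pair_b])


def score_duplex(seq1: str, seq2: str,
                 pairs: list[tuple[int, int]]) -> float:
    """Energy of an explicit duplex structure under the model.

    ``pairs`` are 1-based (i in seq1, j in seq2) with i ascending and j
    descending (anti-parallel nesting).  Returns 0 for the empty
    structure, +inf for structures the model forbids (non-pairable
    bases, crossing pairs, loops beyond the bound).
    """
    if not pairs:
        return 0.0
    s1, s2 = _encode(seq1), _encode(seq2)
    energy = INIT_PENALTY
    prev = None
    for (i, j) in pairs:
        if not (1 <= i <= len(seq1) and 1 <= j <= len(seq2)):
            raise ValueError(f"pair ({i},{j}) out of range")
        code = _PAIR_CODE[s1[i - 1], s2[j - 1]]
        if code < 0:
            return float("inf")
        if prev is not None:
            pi, pj, pcode = prev
            if i <= pi or j >= pj:
                return float("inf")  # crossing / duplicated position
            gap1, gap2 = i - pi - 1, pj - j - 1
            if gap1 == 0 and gap2 == 0:
                energy += _STACKS[pcode, code]
            elif gap1 <= MAX_LOOP and gap2 <= MAX_LOOP:
                energy += LOOP_OPEN + LOOP_PER_NT * (gap1 + gap2)
            else:
                return float("inf")
        prev = (i, j, code)
    return energy


@njit(cache=True)
def _duplex_fill(code, init, stacks, loop_open, loop_per_nt, max_loop,
                 D, PK, PL):
    n, m = code.shape
    best = 0.0
    bi = -1
    bj = -1
    INF = 1e30
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if code[i, j] < 0:
                D[i, j] = INF
                continue
            e = init
            pk = -1
            pl = -1
            kmin = i - max_loop - 1
            if kmin < 0:
                kmin = 0
            lmax = j + max_loop + 1
            if lmax > m - 1:
                lmax = m - 1
            for k in range(kmin, i):
                if code[i, j] < 0:
                    break
                for l in range(j + 1, lmax + 1):
                    if D[k, l] >= INF or code[k, l] < 0:
                        continue
                    gap1 = i - k - 1
                    gap2 = l - j - 1
                    if gap1 == 0 and gap2 == 0:
                        cost = stacks[code[k, l], code[i, j]]
                    elif gap1 <= max_loop and gap2 <= max_loop:
                        cost = loop_open + loop_per_nt * (gap1 + gap2)
                    else:
                        continue
                    cand = D[k, l] + cost
                    if cand < e - 1e-12:
                        e = cand
                        pk = k
                        pl = l
            D[i, j] = e
            PK[i, j] = pk
            PL[i, j] = pl
            if e < best - 1e-12:
                best = e
                bi = i
                bj = j
    return best, bi, bj


def duplex_fold(seq1: str, seq2: str) -> DuplexResult:
    """Minimum-free-energy intermolecular duplex of two sequences.

    Deterministic; symmetric in its arguments (same energy with the
    roles of the strands swapped); N positions never pair.  Returns the
    empty structure with dG = 0 when no negative-energy duplex exists.
    """
    if not seq1 or not seq2:
        raise ValueError("both sequences must be non-empty")
    s1, s2 = _encode(seq1), _encode(seq2)
    n, m = len(s1), len(s2)
    code = _PAIR_CODE[s1[:, None], s2[None, :]]
    D = np.zeros((n, m), dtype=np.float64)
    PK = np.zeros((n, m), dtype=np.int64)
    PL = np.zeros((n, m), dtype=np.int64)
    best, bi, bj = _duplex_fill(code, INIT_PENALTY, _STACKS, LOOP_OPEN,
                                LOOP_PER_NT, MAX_LOOP, D, PK, PL)
    empty = "." * n + "&" + "." * m
    if bi < 0 or best >= -1e-9:
        return DuplexResult(seq1=seq1, seq2=seq2, structure=empty, dG=0.0)
    pairs = []
    i, j = bi, bj
    while i >= 0:
        pairs.append((i + 1, j + 1))
        i, j = int(PK[i, j]), int(PL[i, j])
        if i < 0:
            break
    pairs.reverse()
    part1 = ["."] * n
    part2 = ["."] * m
    for (pi, pj) in pairs:
        part1[pi - 1] = "("
        part2[pj - 1] = ")"
    structure = "".join(part1) + "&" + "".join(part2)
    return DuplexResult(seq1=seq1, seq2=seq2, structure=structure,
                        dG=round(float(best), 6))


def extract_fold_sequences(call: ChimeraCall,
                           db: TranscriptDB) -> tuple[str, str]:
    """Database sequences of the two fragments at the call coordinates.

    Always the database entries, never the read sequence, so that
    crosslinking-induced read errors cannot distort the folding.
    """
    seq1 = db.subseq(call.frag1.subject_id, call.frag1.s_start,
                     call.frag1.s_end)
    seq2 = db.subseq(call.frag2.subject_id, call.frag2.s_start,
                     call.frag2.s_end)
    return seq1, seq2


def fold_chimeras(calls: Iterable[ChimeraCall], db: TranscriptDB,
                  backend: str = "builtin",
                  viennad_path=None) -> list[ChimeraCall]:
    """Attach a duplex prediction (dG + structure) to every call.

    ``backend='builtin'`` runs the nearest-neighbor DP above;
    ``backend='viennad'`` imports externally produced foldings from a
    viennad file (matched by read id).  Calls sharing a transcript pair
    and identical extended coordinates receive identical energies (the
    fold is cached on the sequence pair).
    """
    out = []
    if backend == "builtin":
        cache: dict[tuple[str, str], DuplexResult] = {}
        for call in calls:
            key = extract_fold_sequences(call, db)
            duplex = cache.get(key)
            if duplex is None:
                duplex = duplex_fold(*key)
                cache[key] = duplex
            out.append(ChimeraCall(
                read_id=call.read_id, read_seq=call.read_seq,
                frag1=call.frag1, frag2=call.frag2, dG=duplex.dG,
                annotation=call.annotation, duplex=duplex))
    elif backend == "viennad":
        from .formats import read_viennad
        if viennad_path is None:
            raise ValueError("backend='viennad' requires viennad_path")
        blocks = {b.read_id: b for b in read_viennad(viennad_path)}
        for call in calls:
            block = blocks.get(call.read_id)
            if block is None:
                out.append(call)
                continue
            out.append(ChimeraCall(
                read_id=call.read_id, read_seq=call.read_seq,
                frag1=call.frag1, frag2=call.frag2, dG=block.duplex.dG,
                annotation=call.annotation, duplex=block.duplex))
    else:
        raise ValueError(f"unknown folding backend {backend!r}")
    return out
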