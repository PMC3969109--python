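"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation paths they
check: the alignment oracle is a plain full-matrix affine-gap
Smith-Waterman in pure Python, and the duplex oracle enumerates every
valid intermolecular pairing recursively (scoring each with the energy
model's public structure scorer).
"""

from __future__ import annotations

from hybpipe.fold import pair_index, score_duplex


def sw_best_score(query: str, subject: str, match: int = 1,
                  mismatch: int = -2, gap_open: int = 5,
                  gap_extend: int = 1) -> int:
    """Exhaustive affine-gap local alignment score (full DP, no seeds).

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(query), len(subject)
    NEG = -10 ** 9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    open_cost = gap_open + gap_extend
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - open_cost, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - open_cost, F[i][j - 1] - gap_extend)
            sub = match if (qi == subject[j - 1] and qi in "ACGT") \
                else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def enumerate_duplex_mfe(seq1: str, seq2: str) -> float:
    """Minimum energy over *all* valid intermolecular pairings.

    Pairings are anti-parallel and non-crossing: positions i in seq1
    ascending pair with positions j in seq2 descending.  Each complete
    pairing is scored with :func:`hybpipe.fold.score_duplex`; the
    minimum over every enumerated structure (including the empty one,
    energy 0) is returned.
    """
    n, m = len(seq1), len(seq2)
    allowed = [[pair_index(seq1[i], seq2[j]) >= 0 for j in range(m)]
               for i in range(n)]
    best = [0.0]

    def recurse(i: int, j_hi: int, pairs: list[tuple[int, int]]) -> None:
        if pairs:
            energy = score_duplex(seq1, seq2, pairs)
            if energy < best[0]:
                best[0] = energy
        if i >= n:
            return
        # leave position i unpaired
        recurse(i + 1, j_hi, pairs)
        # or pair it with any j below the previous partner
        for j in range(j_hi - 1, -1, -1):
            if allowed[i][j]:
                pairs.append((i + 1, j + 1))
                recurse(i + 1, j, pairs)
                pairs.pop()

    recurse(0, m, [])
    return best[0]
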