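"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: alignment scores come
from exhaustive enumeration of alignment paths, motif positions from a
sliding-window check. Feasible only for small inputs.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sub_score(a: str, b: str) -> float:
    return float(_B62[a, b])


def bruteforce_global_score(q: str, s: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Max score over every global alignment path. Gap run of length L
    costs open + (L-1)*extend; a gap run in the other sequence re-opens."""
    best = [float("-inf")]

    def rec(i: int, j: int, prev: str, score: float) -> None:
        if i == len(q) and j == len(s):
            if score > best[0]:
                best[0] = score
            return
        if i < len(q) and j < len(s):
            rec(i + 1, j + 1, "M", score + sub_score(q[i], s[j]))
        if i < len(q):
            rec(i + 1, j, "X", score - (gap_extend if prev == "X" else gap_open))
        if j < len(s):
            rec(i, j + 1, "Y", score - (gap_extend if prev == "Y" else gap_open))

    rec(0, 0, "", 0.0)
    return best[0]


def bruteforce_local_score(q: str, s: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Max over all start pairs and paths of any prefix ending on a match
    column, floored at 0 (local alignments never start/end with a gap)."""
    best = [0.0]
    n, m = len(q), len(s)

    def rec(i: int, j: int, prev: str, score: float) -> None:
        if i < n and j < m:
            sc = score + sub_score(q[i], s[j])
            if sc > best[0]:
                best[0] = sc
            rec(i + 1, j + 1, "M", sc)
        if prev:
            if i < n:
                rec(i + 1, j, "X", score - (gap_extend if prev == "X" else gap_open))
            if j < m:
                rec(i, j + 1, "Y", score - (gap_extend if prev == "Y" else gap_open))

    for i0 in range(n):
        for j0 in range(m):
            rec(i0, j0, "", 0.0)
    return best[0]


def window_rxxxr(seq: str) -> list[int]:
    """1-based starts of R-x-x-x-R by direct window check."""
    return [
        i + 1
        for i in range(len(seq) - 4)
        if seq[i] == "R" and seq[i + 4] == "R"
    ]


def window_switch2(seq: str) -> list[int]:
    """1-based starts of [D/N]-z-S-x-x-G by direct window check."""
    return [
        i + 1
        for i in range(len(seq) - 5)
        if seq[i] in "DN" and seq[i + 2] == "S" and seq[i + 5] == "G"
    ]
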