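"""Deterministic pairwise alignment with affine gaps and residue mapping.

The conservation screen anchors every candidate domain to a single reference
sequence by global (Needleman–Wunsch/Gotoh) alignment and then reads the
residues opposite the reference's catalytic positions. Orthology calls use
local (Smith–Waterman) alignment percent identity. Both modes share one
dynamic-programming kernel with a fixed traceback tie order
(diagonal > up > left, i.e. match > gap-in-subject > gap-in-query), so
outputs are bit-reproducible across runs and platforms.

Gap convention: a gap run of length L costs ``gap_open + (L-1)*gap_extend``
in substitution-matrix units (EMBOSS-style; the first gapped residue pays
the opening penalty). Defaults are BLOSUM62, open 10, extend 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

#: Sentinel for a reference position that falls in an alignment gap.
GAP = None


@lru_cache(maxsize=8)
def _load_matrix(name: str) -> tuple[str, np.ndarray]:
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    dense = np.asarray(mat, dtype=np.float64)
    return alphabet, dense


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters: substitution matrix name and affine gap penalties."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes; must be >= 0")


DEFAULT_PARAMS = AlignmentParams()


@dataclass
class AlignmentResult:
    """A pairwise alignment with a subject→query residue position map.

    ``column_map`` maps 1-based subject positions to 1-based query positions,
    or ``None`` where the subject residue is opposite a gap. For local mode
    only the aligned subject stretch is present in the map.
    """

    query_aligned: str
    subject_aligned: str
    score: float
    identity_percent: float
    mode: str
    column_map: dict[int, int | None]
    query_start: int = 1
    subject_start: int = 1

    @property
    def length(self) -> int:
        return len(self.query_aligned)


def _encode(seq: str, alphabet: str) -> np.ndarray:
    idx = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        p = alphabet.find(ch)
        if p < 0:
            raise ValueError(f"residue {ch!r} not in substitution matrix alphabet")
        idx[i] = p
    return idx


# Pointer codes: 0 = start/stop, 1 = from M (diagonal), 2 = from X (up), 3 = from Y (left).
@njit(cache=False)
def _gotoh(qi, si, sub, gap_open, gap_extend, local):  # pragma: no cover - numba
    n = qi.shape[0]
    m = si.shape[0]
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    if not local:
        for i in range(1, n + 1):
            X[i, 0] = -(gap_open + (i - 1) * gap_extend)
            pX[i, 0] = 1 if i == 1 else 2
        for j in range(1, m + 1):
            Y[0, j] = -(gap_open + (j - 1) * gap_extend)
            pY[0, j] = 1 if j == 1 else 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[qi[i - 1], si[j - 1]]
            # M: consume one residue of each; tie order M > X > Y.
            bm = M[i - 1, j - 1]
            pm = 1
            if X[i - 1, j - 1] > bm:
                bm = X[i - 1, j - 1]
                pm = 2
            if Y[i - 1, j - 1] > bm:
                bm = Y[i - 1, j - 1]
                pm = 3
            if local and bm < 0.0:
                bm = 0.0
                pm = 0
            M[i, j] = s + bm
            pM[i, j] = pm
            # X: query residue opposite a gap ("up" move).
            bx = M[i - 1, j] - gap_open
            px = 1
            if X[i - 1, j] - gap_extend > bx:
                bx = X[i - 1, j] - gap_extend
                px = 2
            if Y[i - 1, j] - gap_open > bx:
                bx = Y[i - 1, j] - gap_open
                px = 3
            X[i, j] = bx
            pX[i, j] = px
            # Y: subject residue opposite a gap ("left" move).
            by = M[i, j - 1] - gap_open
            py = 1
            if X[i, j - 1] - gap_open > by:
                by = X[i, j - 1] - gap_open
                py = 2
            if Y[i, j - 1] - gap_extend > by:
                by = Y[i, j - 1] - gap_extend
                py = 3
            Y[i, j] = by
            pY[i, j] = py
    return M, X, Y, pM, pX, pY


def _traceback(q, s, M, X, Y, pM, pX, pY, i, j, state):
    """Walk pointers from (i, j, state) back to the alignment start."""
    q_cols: list[str] = []
    s_cols: list[str] = []
    while True:
        if state == 1:  # M
            prev = pM[i, j]
            q_cols.append(q[i - 1])
            s_cols.append(s[j - 1])
            i -= 1
            j -= 1
        elif state == 2:  # X: gap in subject
            prev = pX[i, j]
            q_cols.append(q[i - 1])
            s_cols.append("-")
            i -= 1
        else:  # Y: gap in query
            prev = pY[i, j]
            q_cols.append("-")
            s_cols.append(s[j - 1])
            j -= 1
        if prev == 0 or (i == 0 and j == 0):
            break
        state = prev
    return "".join(reversed(q_cols)), "".join(reversed(s_cols)), i, j


def _finish(q, s, qa, sa, score, mode, query_start, subject_start) -> AlignmentResult:
    length = len(qa)
    ident = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
    identity = round(100.0 * ident / length, 1) if length else 0.0
    column_map: dict[int, int | None] = {}
    qpos = query_start - 1
    spos = subject_start - 1
    for a, b in zip(qa, sa):
        if a != "-":
            qpos += 1
        if b != "-":
            spos += 1
            column_map[spos] = qpos if a != "-" else None
    return AlignmentResult(
        query_aligned=qa,
        subject_aligned=sa,
        score=float(score),
        identity_percent=identity,
        mode=mode,
        column_map=column_map,
        query_start=query_start,
        subject_start=subject_start,
    )


def global_align(
    query: str, subject: str, params: AlignmentParams = DEFAULT_PARAMS
) -> AlignmentResult:
    """Optimal global alignment of ``query`` against ``subject``.

    Deterministic: on score ties the traceback prefers diagonal over up
    over left moves, so co-optimal alignments always resolve the same way.
    """
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    alphabet, sub = _load_matrix(params.matrix)
    qi = _encode(query, alphabet)
    si = _encode(subject, alphabet)
    M, X, Y, pM, pX, pY = _gotoh(qi, si, sub, params.gap_open, params.gap_extend, False)
    n, m = len(query), len(subject)
    score, state = M[n, m], 1
    if X[n, m] > score:
        score, state = X[n, m], 2
    if Y[n, m] > score:
        score, state = Y[n, m], 3
    qa, sa, _, _ = _traceback(query, subject, M, X, Y, pM, pX, pY, n, m, state)
    return _finish(query, subject, qa, sa, score, "global", 1, 1)


def local_align(
    query: str, subject: str, params: AlignmentParams = DEFAULT_PARAMS
) -> AlignmentResult:
    """Optimal local (Smith–Waterman) alignment with a zero score floor.

    When every pairing scores negative the result is the empty alignment
    with score 0. Identity is identical columns over alignment length
    (gap columns included in the denominator), reported to one decimal.
    """
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    alphabet, sub = _load_matrix(params.matrix)
    qi = _encode(query, alphabet)
    si = _encode(subject, alphabet)
    M, X, Y, pM, pX, pY = _gotoh(qi, si, sub, params.gap_open, params.gap_extend, True)
    n, m = len(query), len(subject)
    # Local alignments end on a match column; first best cell in row-major order.
    best = 0.0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i, j] > best:
                best = M[i, j]
                bi, bj = i, j
    if best <= 0.0:
        return AlignmentResult("", "", 0.0, 0.0, "local", {}, 1, 1)
    qa, sa, i0, j0 = _traceback(query, subject, M, X, Y, pM, pX, pY, bi, bj, 1)
    return _finish(query, subject, qa, sa, best, "local", i0 + 1, j0 + 1)


def map_reference_positions(
    alignment: AlignmentResult, positions: list[int]
) -> dict[int, tuple[int | None, str | None]]:
    """Map 1-based subject (reference) positions through an alignment.

    Returns ``{position: (query_position, query_residue)}`` with
    ``(None, None)`` where the reference residue is aligned to a gap.
    Positions outside the subject raise ``ValueError``.
    """
    # Residue lookup from the aligned strings.
    residues: dict[int, str] = {}
    qpos = alignment.query_start - 1
    spos = alignment.subject_start - 1
    for a, b in zip(alignment.query_aligned, alignment.subject_aligned):
        if a != "-":
            qpos += 1
        if b != "-":
            spos += 1
            if a != "-":
                residues[spos] = a
    out: dict[int, tuple[int | None, str | None]] = {}
    for pos in positions:
        if pos < 1 or pos not in alignment.column_map:
            raise ValueError(f"position {pos} outside the aligned subject range")
        qp = alignment.column_map[pos]
        out[pos] = (qp, residues.get(pos)) if qp is not None else (None, None)
    return out
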