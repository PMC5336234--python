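"""Pairwise and profile alignment primitives (Gotoh affine-gap DP).

Local alignment (Smith–Waterman) backs the PTP-domain similarity matrix;
global alignment (Needleman–Wunsch) backs reference-scaffold anchoring,
guide-tree distances and the progressive aligner's profile steps.

Unknown residues (X) score 0 against everything, so ambiguity is neutral.
Tie-breaking in the traceback prefers diagonal, then gap-in-b, then
gap-in-a, which makes alignments deterministic.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .errors import AlignmentError

NEG = -1e30  # effectively minus infinity for the DP


@lru_cache(maxsize=4)
def scoring_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """Substitution matrix as a symmetric dict; X scores 0 vs everything."""
    m = substitution_matrices.load(name)
    table: dict[tuple[str, str], float] = {}
    letters = m.alphabet
    for a in letters:
        for b in letters:
            table[(a, b)] = float(m[a, b])
    for a in set(letters) | {"X"}:
        table[("X", a)] = 0.0
        table[(a, "X")] = 0.0
    return table


def _score_fn(matrix: str):
    tbl = scoring_matrix(matrix)
    return lambda a, b: tbl.get((a, b), 0.0)


def _gotoh(a: str, b: str, matrix: str, gap_open: float, gap_extend: float,
           local: bool) -> tuple[float, str, str]:
    """Affine-gap DP with pointer-matrix traceback.

    Returns (score, aligned_a, aligned_b).  A gap run of length k costs
    ``gap_open + (k - 1) * gap_extend`` (the first gapped position pays the
    opening penalty).  State M pairs a[i-1] with b[j-1]; X puts a gap in b
    (consumes a); Y puts a gap in a (consumes b).  Pointer code 3 marks a
    fresh local start.
    """
    if not a or not b:
        raise AlignmentError("cannot align empty sequences")
    tbl = scoring_matrix(matrix)
    n, m = len(a), len(b)
    # plain Python lists: elementwise numpy indexing is far slower here
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptrM = [bytearray([3]) * (m + 1) for _ in range(n + 1)]
    ptrX = [bytearray(m + 1) for _ in range(n + 1)]
    ptrY = [bytearray(m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    if not local:
        for i in range(1, n + 1):
            X[i][0] = -gap_open - (i - 1) * gap_extend
            ptrX[i][0] = 0 if i == 1 else 1
        for j in range(1, m + 1):
            Y[0][j] = -gap_open - (j - 1) * gap_extend
            ptrY[0][j] = 0 if j == 1 else 2

    best_score, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        srow = [tbl.get((ai, c), 0.0) for c in b]
        pM, pX, pY = M[i - 1], X[i - 1], Y[i - 1]
        cM, cX, cY = M[i], X[i], Y[i]
        rM, rX, rY = ptrM[i], ptrX[i], ptrY[i]
        for j in range(1, m + 1):
            c0, c1, c2 = pM[j - 1], pX[j - 1], pY[j - 1]
            # best predecessor for a match at (i, j)
            if c0 >= c1 and c0 >= c2:
                prev, k = c0, 0
            elif c1 >= c2:
                prev, k = c1, 1
            else:
                prev, k = c2, 2
            # a local alignment never keeps a non-positive-score prefix
            if local and prev <= 0.0:
                prev, k = 0.0, 3
            v = prev + srow[j - 1]
            cM[j] = v
            rM[j] = k
            c0, c1, c2 = pM[j] - gap_open, pX[j] - gap_extend, pY[j] - gap_open
            if c0 >= c1 and c0 >= c2:
                cX[j], rX[j] = c0, 0
            elif c1 >= c2:
                cX[j], rX[j] = c1, 1
            else:
                cX[j], rX[j] = c2, 2
            c0, c1, c2 = cM[j - 1] - gap_open, cX[j - 1] - gap_open, \
                cY[j - 1] - gap_extend
            if c0 >= c1 and c0 >= c2:
                cY[j], rY[j] = c0, 0
            elif c2 >= c1:
                cY[j], rY[j] = c2, 2
            else:
                cY[j], rY[j] = c1, 1
            if local and v > best_score:
                best_score, bi, bj = v, i, j

    out_a: list[str] = []
    out_b: list[str] = []
    if local:
        if best_score <= 0:
            return 0.0, "", ""
        score, i, j, state = best_score, bi, bj, "M"
        while True:
            if state == "M":
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                k = ptrM[i][j]
                i, j = i - 1, j - 1
                if k == 3:
                    break
                state = "MXY"[k]
            elif state == "X":
                out_a.append(a[i - 1])
                out_b.append("-")
                state = "MXY"[ptrX[i][j]]
                i -= 1
            else:
                out_a.append("-")
                out_b.append(b[j - 1])
                state = "MXY"[ptrY[i][j]]
                j -= 1
    else:
        i, j = n, m
        finals = (M[i][j], X[i][j], Y[i][j])
        k = max(range(3), key=lambda t: finals[t])
        score, state = float(finals[k]), "MXY"[k]
        while i > 0 or j > 0:
            if state == "M":
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                state = "MXY"[min(ptrM[i][j], 2)]
                i, j = i - 1, j - 1
            elif state == "X":
                out_a.append(a[i - 1])
                out_b.append("-")
                state = "MXY"[ptrX[i][j]]
                i -= 1
            else:
                out_a.append("-")
                out_b.append(b[j - 1])
                state = "MXY"[ptrY[i][j]]
                j -= 1
    return float(score), "".join(reversed(out_a)), "".join(reversed(out_b))


def local_affine(a: str, b: str, matrix: str = "BLOSUM62",
                 gap_open: float = 11.0, gap_extend: float = 1.0
                 ) -> tuple[float, str, str]:
    """Smith–Waterman local alignment with affine gaps."""
    return _gotoh(a, b, matrix, gap_open, gap_extend, local=True)


def global_affine(a: str, b: str, matrix: str = "BLOSUM62",
                  gap_open: float = 11.0, gap_extend: float = 1.0
                  ) -> tuple[float, str, str]:
    """Needleman–Wunsch global alignment with affine gaps."""
    return _gotoh(a, b, matrix, gap_open, gap_extend, local=False)


def pairwise_identity(a: str, b: str, matrix: str = "BLOSUM62") -> float:
    """Fraction of identical residues over aligned columns (global alignment,
    gap columns excluded from the denominator)."""
    _, ra, rb = global_affine(a, b, matrix)
    pairs = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(x == y for x, y in pairs) / len(pairs)


# ---------------------------------------------------- profile alignment

def profile_align(rows_a: list[str], rows_b: list[str], matrix: str,
                  gap_open: float, gap_extend: float
                  ) -> tuple[list[str], list[str]]:
    """Global affine alignment of two alignment profiles.

    Column-column score is the mean substitution score over residue pairs;
    residues paired with existing gaps score 0 (gaps already paid for).
    Returns the two input row blocks expanded with new gap columns.
    """
    La, Lb = len(rows_a[0]), len(rows_b[0])
    # column-column scores as a count-matrix product: S = CA @ B62 @ CB.T,
    # normalized by the number of residue pairs per column pair
    letters = sorted({c for r in rows_a + rows_b for c in r} - {"-"})
    lidx = {c: k for k, c in enumerate(letters)}
    tbl = scoring_matrix(matrix)
    B = np.array([[tbl.get((x, y), 0.0) for y in letters] for x in letters])

    def counts(rows: list[str], L: int) -> np.ndarray:
        C = np.zeros((L, len(letters)))
        for r in rows:
            for j, c in enumerate(r):
                if c != "-":
                    C[j, lidx[c]] += 1
        return C

    CA, CB = counts(rows_a, La), counts(rows_b, Lb)
    na, nb = CA.sum(axis=1), CB.sum(axis=1)
    denom = np.outer(na, nb)
    denom[denom == 0] = 1.0
    S = (CA @ B @ CB.T) / denom

    M = [[NEG] * (Lb + 1) for _ in range(La + 1)]
    X = [[NEG] * (Lb + 1) for _ in range(La + 1)]
    Y = [[NEG] * (Lb + 1) for _ in range(La + 1)]
    ptrM = [bytearray(Lb + 1) for _ in range(La + 1)]
    ptrX = [bytearray(Lb + 1) for _ in range(La + 1)]
    ptrY = [bytearray(Lb + 1) for _ in range(La + 1)]
    M[0][0] = 0.0
    for i in range(1, La + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, Lb + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    Slist = S.tolist()
    for i in range(1, La + 1):
        pM, pX, pY = M[i - 1], X[i - 1], Y[i - 1]
        cM, cX, cY = M[i], X[i], Y[i]
        rM, rX, rY = ptrM[i], ptrX[i], ptrY[i]
        srow = Slist[i - 1]
        for j in range(1, Lb + 1):
            c0, c1, c2 = pM[j - 1], pX[j - 1], pY[j - 1]
            if c0 >= c1 and c0 >= c2:
                cM[j], rM[j] = c0 + srow[j - 1], 0
            elif c1 >= c2:
                cM[j], rM[j] = c1 + srow[j - 1], 1
            else:
                cM[j], rM[j] = c2 + srow[j - 1], 2
            c0, c1, c2 = pM[j] - gap_open, pX[j] - gap_extend, pY[j] - gap_open
            if c0 >= c1 and c0 >= c2:
                cX[j], rX[j] = c0, 0
            elif c1 >= c2:
                cX[j], rX[j] = c1, 1
            else:
                cX[j], rX[j] = c2, 2
            c0, c1, c2 = cM[j - 1] - gap_open, cX[j - 1] - gap_open, \
                cY[j - 1] - gap_extend
            if c0 >= c1 and c0 >= c2:
                cY[j], rY[j] = c0, 0
            elif c2 >= c1:
                cY[j], rY[j] = c2, 2
            else:
                cY[j], rY[j] = c1, 1

    i, j = La, Lb
    finals = (M[i][j], X[i][j], Y[i][j])
    state = "MXY"[max(range(3), key=lambda t: finals[t])]
    ops: list[str] = []  # 'D' diag, 'A' consume a, 'B' consume b
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                state = "X" if i > 0 else "Y"
                continue
            ops.append("D")
            state = "MXY"[ptrM[i][j]]
            i, j = i - 1, j - 1
        elif state == "X":
            if i == 0:
                state = "Y"
                continue
            ops.append("A")
            state = "MXY"[ptrX[i][j]]
            i -= 1
        else:
            if j == 0:
                state = "X"
                continue
            ops.append("B")
            state = "MXY"[ptrY[i][j]]
            j -= 1
    ops.reverse()

    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "D":
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ia += 1
            ib += 1
        elif op == "A":
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            for k in range(len(rows_b)):
                out_b[k].append("-")
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]
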