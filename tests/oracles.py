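"""Independent brute-force oracles used to validate the fast paths.

These deliberately re-derive results with naive full-matrix / full-scan
implementations that share only the *stated rules* (scoring scheme,
tie-break order) with the library, never its code.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_MAT = substitution_matrices.load("BLOSUM62")
_ALPHA = str(_MAT.alphabet)
_SUB = np.asarray(_MAT, dtype=int)
_IDX = {c: i for i, c in enumerate(_ALPHA)}


def _enc(seq: str) -> list[int]:
    x = _IDX["X"]
    return [_IDX.get(c, x) for c in seq.upper()]


def oracle_align(a: str, b: str, gap_open: int = 11, gap_extend: int = 1):
    """Naive full-matrix Smith-Waterman-Gotoh with the documented tie rules.

    Returns (score, identities, aln_columns, q_start, q_end, s_start,
    s_end), spans 1-based inclusive.  Gap of length k costs
    ``gap_open + k * gap_extend``.  Traceback starts at the first maximum
    in row-major order; preferences: diagonal, then vertical gap (consuming
    the query), then horizontal; gap extension beats gap opening on ties.
    """
    ea, eb = _enc(a), _enc(b)
    n, m = len(ea), len(eb)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # vertical (gap in subject)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # horizontal (gap in query)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            F[i][j] = max(F[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open - gap_extend)
            d = H[i - 1][j - 1] + _SUB[ea[i - 1]][eb[j - 1]]
            h = max(0, d, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0
    i, j, state = bi, bj, "H"
    ident = cols = 0
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            d = H[i - 1][j - 1] + _SUB[ea[i - 1]][eb[j - 1]]
            if h == d and d >= E[i][j] and d >= F[i][j]:
                cols += 1
                ident += ea[i - 1] == eb[j - 1]
                i, j = i - 1, j - 1
            elif h == E[i][j] and E[i][j] >= F[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            ext = E[i][j] == E[i - 1][j] - gap_extend
            i -= 1
            state = "E" if ext else "H"
        else:
            cols += 1
            ext = F[i][j] == F[i][j - 1] - gap_extend
            j -= 1
            state = "F" if ext else "H"
    return best, ident, cols, i + 1, bi, j + 1, bj


def oracle_identity_short(a: str, b: str) -> float:
    _, ident, cols, *_ = oracle_align(a, b)
    return ident / min(len(a), len(b)) if cols else 0.0


def oracle_greedy(seqs: list[tuple[str, str]], threshold: float):
    """Brute-force replay of the ordered greedy clustering rule.

    Sort by decreasing length then id; each sequence joins the first
    founded cluster whose representative it matches at shorter-sequence
    identity >= threshold, else founds a new cluster.  Returns a list of
    (representative_id, [member ids]) in founding order.
    """
    order = sorted(seqs, key=lambda p: (-len(p[1]), p[0]))
    clusters: list[tuple[str, str, list[str]]] = []  # (rep_id, rep_seq, members)
    for sid, seq in order:
        for rep_id, rep_seq, members in clusters:
            if oracle_identity_short(seq, rep_seq) >= threshold:
                members.append(sid)
                break
        else:
            clusters.append((sid, seq, [sid]))
    return [(rep_id, members) for rep_id, _, members in clusters]


def oracle_window_scan(scores: np.ndarray, seq: str, residues: str) -> float:
    """Best gapless window score by direct summation (X scores 0)."""
    W = scores.shape[0]
    if len(seq) < W:
        return float("-inf")
    idx = {c: i for i, c in enumerate(residues)}
    best = float("-inf")
    for off in range(len(seq) - W + 1):
        s = 0.0
        for k in range(W):
            c = seq[off + k]
            if c in idx:
                s += scores[k, idx[c]]
        best = max(best, s)
    return best
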