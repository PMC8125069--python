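"""Pairwise local protein alignment, identity conventions, greedy clustering
and representative-vs-database homolog search.

This module stands in for the external tools usually chained together in
effector surveys (an aligner for percent identity, CD-HIT for family
clustering, blastp for homolog recovery), with fully deterministic rules so
that every downstream count is reproducible.

Alignment model
---------------
Smith-Waterman local alignment with affine gaps (Gotoh recurrences).  A gap
of length ``k`` costs ``gap_open + k * gap_extend``.  Defaults are BLOSUM62
with gap_open 11 / gap_extend 1.  Traceback tie-breaks are fixed: the start
cell is the first maximum in row-major order, and at each cell the preference
is diagonal (aligned pair), then gap in the subject, then gap in the query;
within a gap run, extension is preferred over opening.  These rules make
identities and spans deterministic, not just the score.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

__all__ = [
    "AlignmentResult",
    "Cluster",
    "HomologMatch",
    "align_local",
    "identity_blast_style",
    "identity_short_style",
    "greedy_cluster",
    "search_homologs",
]

#: residue order of the Biopython BLOSUM62 matrix
_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_CHAR_TO_IDX = np.full(128, _ALPHABET.index("X"), dtype=np.int64)
for _i, _c in enumerate(_ALPHABET):
    _CHAR_TO_IDX[ord(_c)] = _i
    _CHAR_TO_IDX[ord(_c.lower())] = _i


class AlignmentError(ValueError):
    """Raised for invalid alignment inputs (e.g. empty sequences)."""


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment between a query and a subject protein.

    Spans are 1-based inclusive on the respective ungapped sequences.
    ``aln_columns`` counts matches, mismatches and gap columns inside the
    local alignment; ``identities`` counts identical aligned residue pairs.
    """

    query_id: str
    subject_id: str
    identities: int
    aln_columns: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.identities <= self.aln_columns):
            raise AlignmentError(
                f"identities {self.identities} outside [0, {self.aln_columns}]"
            )

    @property
    def q_span(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_span(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    @property
    def q_aln_len(self) -> int:
        return self.q_end - self.q_start + 1 if self.aln_columns else 0

    @property
    def s_aln_len(self) -> int:
        return self.s_end - self.s_start + 1 if self.aln_columns else 0


@dataclass
class Cluster:
    """An identity-threshold protein family with a representative member."""

    cluster_id: str
    member_ids: list[str]
    representative_id: str
    kind: str = "toxin_domain"

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster has no members")
        if self.representative_id not in self.member_ids:
            raise ValueError("representative is not a member")


@dataclass(frozen=True)
class HomologMatch:
    """A representative-vs-database hit that passed all enabled filters."""

    representative_id: str
    subject_id: str
    identity_fraction: float
    aln_len: int
    subject_coverage: float
    representative_coverage: float
    score: float = 0.0


@functools.lru_cache(maxsize=8)
def _load_matrix(name: str) -> np.ndarray:
    mat = substitution_matrices.load(name)
    if str(mat.alphabet) != _ALPHABET:  # pragma: no cover - library invariant
        raise AlignmentError(f"unexpected alphabet for {name}")
    return np.asarray(mat, dtype=np.int32)


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string into BLOSUM row indices (unknown -> X)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _CHAR_TO_IDX[arr]


# traceback codes packed per cell: bits 0-1 source of H (0 stop, 1 diag,
# 2 E = gap in subject/vertical, 3 F = gap in query/horizontal);
# bit 2: E came from an extension; bit 3: F came from an extension
@njit(fastmath=False)
def _sw_fill(a, b, sub, gap_open, gap_extend):
    """Gotoh fill; returns best score, its first row-major cell, traceback."""
    n = a.size
    m = b.size
    NEG = -1_000_000
    tb = np.zeros((n + 1, m + 1), np.uint8)
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full(m + 1, NEG, np.int32)
    best = 0
    bi = 0
    bj = 0
    goe = gap_open + gap_extend
    for i in range(1, n + 1):
        f = NEG
        row = sub[a[i - 1]]
        Hi = H[i]
        Hu = H[i - 1]
        for j in range(1, m + 1):
            code = 0
            e_ext = E[j] - gap_extend
            e_open = Hu[j] - goe
            if e_ext >= e_open:
                e = e_ext
                code |= 4
            else:
                e = e_open
            f_ext = f - gap_extend
            f_open = Hi[j - 1] - goe
            if f_ext >= f_open:
                f = f_ext
                code |= 8
            else:
                f = f_open
            E[j] = e
            d = Hu[j - 1] + row[b[j - 1]]
            if d >= e and d >= f:
                h = d
                src = 1
            elif e >= f:
                h = e
                src = 2
            else:
                h = f
                src = 3
            if h <= 0:
                h = 0
                src = 0
            Hi[j] = h
            tb[i, j] = code | src
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, tb


@njit(fastmath=False)
def _sw_traceback(a, b, tb, bi, bj):
    """Walk the packed traceback; returns identities, columns and spans."""
    i = bi
    j = bj
    identities = 0
    columns = 0
    state = 0  # 0 = in H, 2 = in E, 3 = in F
    qe = bi
    se = bj
    while i > 0 or j > 0:
        cell = tb[i, j]
        if state == 0:
            src = cell & 3
            if src == 0:
                break
            state = src
        if state == 1:
            columns += 1
            if a[i - 1] == b[j - 1]:
                identities += 1
            i -= 1
            j -= 1
            state = 0
        elif state == 2:  # gap in subject: consume query (vertical move)
            columns += 1
            ext = cell & 4
            i -= 1
            state = 2 if ext else 0
        else:  # gap in query: consume subject (horizontal move)
            columns += 1
            ext = cell & 8
            j -= 1
            state = 3 if ext else 0
    return identities, columns, i + 1, qe, j + 1, se


def align_local(
    a: str,
    b: str,
    substitution: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal local alignment of two protein sequences under affine gaps.

    Parameters mirror blastp defaults (BLOSUM62, 11/1).  Raises
    :class:`AlignmentError` on an empty sequence.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    sub = _load_matrix(substitution)
    ea, eb = encode(a), encode(b)
    score, bi, bj, tb = _sw_fill(ea, eb, sub, gap_open, gap_extend)
    if score <= 0:
        return AlignmentResult(query_id, subject_id, 0, 0, 0, 0, 0, 0, 0.0)
    identities, columns, qs, qe, ss, se = _sw_traceback(ea, eb, tb, bi, bj)
    return AlignmentResult(
        query_id, subject_id, int(identities), int(columns),
        int(qs), int(qe), int(ss), int(se), float(score),
    )


def identity_blast_style(r: AlignmentResult) -> float:
    """Identities over alignment columns (blastp 'pident' convention)."""
    if r.aln_columns == 0:
        raise AlignmentError("identity undefined for a zero-length alignment")
    return r.identities / r.aln_columns


def identity_short_style(r: AlignmentResult, len_a: int, len_b: int) -> float:
    """Identities over the shorter full sequence (CD-HIT convention)."""
    shorter = min(len_a, len_b)
    if shorter == 0 or r.aln_columns == 0:
        raise AlignmentError("identity undefined for a zero-length alignment")
    return r.identities / shorter


def _as_pairs(seqs) -> list[tuple[str, str]]:
    out = []
    for s in seqs:
        if hasattr(s, "id") and hasattr(s, "sequence"):
            out.append((s.id, s.sequence))
        else:
            sid, seq = s
            out.append((sid, seq))
    return out


def greedy_cluster(seqs, threshold: float, kind: str = "toxin_domain",
                   prefix: str | None = None) -> list[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are sorted by decreasing length (ties broken by id); the
    longest founds the first cluster as its representative, and each
    subsequent sequence joins the first existing representative (in founding
    order) with shorter-sequence identity >= ``threshold``, otherwise it
    founds a new cluster.  Deterministic by construction.

    ``seqs`` may be ``(id, sequence)`` pairs or objects with ``id`` and
    ``sequence`` attributes.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    pairs = _as_pairs(seqs)
    if len({sid for sid, _ in pairs}) != len(pairs):
        raise ValueError("duplicate sequence ids in clustering input")
    if prefix is None:
        prefix = {"toxin_domain": "T", "core_domain": "C", "vgrg": "V"}.get(
            kind, kind[:1].upper())
    order = sorted(pairs, key=lambda p: (-len(p[1]), p[0]))
    reps: list[tuple[str, str]] = []  # (id, seq) per cluster, founding order
    members: list[list[str]] = []
    for sid, seq in order:
        placed = False
        for ci, (rid, rseq) in enumerate(reps):
            r = align_local(seq, rseq, query_id=sid, subject_id=rid)
            if r.aln_columns == 0:
                continue
            if identity_short_style(r, len(seq), len(rseq)) >= threshold:
                members[ci].append(sid)
                placed = True
                break
        if not placed:
            reps.append((sid, seq))
            members.append([sid])
    return [
        Cluster(f"{prefix}{ci + 1:03d}", mem, reps[ci][0], kind)
        for ci, mem in enumerate(members)
    ]


def search_homologs(
    representatives,
    database,
    min_identity: float = 0.40,
    min_aln_len: int = 0,
    min_subject_coverage: float = 0.0,
    min_representative_coverage: float = 0.0,
) -> list[HomologMatch]:
    """Find database proteins homologous to any representative.

    A (representative, subject) pair is reported when its best local
    alignment passes every enabled filter: blast-style identity >=
    ``min_identity``, alignment columns >= ``min_aln_len``, aligned fraction
    of the subject >= ``min_subject_coverage`` and of the representative >=
    ``min_representative_coverage`` (set a filter to 0 to disable it).
    Self-matches (equal ids) are excluded.  One match per pair.
    """
    reps = _as_pairs(representatives)
    db = _as_pairs(database)
    out: list[HomologMatch] = []
    for rid, rseq in reps:
        for sid, sseq in db:
            if sid == rid:
                continue
            r = align_local(rseq, sseq, query_id=rid, subject_id=sid)
            if r.aln_columns == 0:
                continue
            ident = identity_blast_style(r)
            s_cov = r.s_aln_len / len(sseq)
            r_cov = r.q_aln_len / len(rseq)
            if ident < min_identity:
                continue
            if min_aln_len and r.aln_columns < min_aln_len:
                continue
            if min_subject_coverage and s_cov < min_subject_coverage:
                continue
            if min_representative_coverage and r_cov < min_representative_coverage:
                continue
            out.append(HomologMatch(rid, sid, ident, r.aln_columns,
                                    s_cov, r_cov, r.score))
    return out
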