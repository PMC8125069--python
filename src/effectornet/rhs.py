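"""Rhs core/toxin domain splitting, clustering and orphan recovery.

Rhs polymorphic toxins carry a long conserved core that ends in a DPxG
motif, followed by a hypervariable C-terminal toxin domain.  Because the
toxin-encoding 3' end of an *rhs* gene is exchangeable by recombination
(C-terminal displacement), core and toxin domains are analysed as separate
units: proteins with an Rhs core motif are split at the DPxG anchor, both
domain kinds are clustered at 40 % identity, and the toxin-cluster
representatives are then searched against every proteome to recover
orphaned toxin domains that have no attached core.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from collections import Counter

from .genome_io import ProteinRecord
from .homology import Cluster, HomologMatch, greedy_cluster, search_homologs
from .motifs import DomainHit

logger = logging.getLogger(__name__)

__all__ = [
    "RhsArchitecture",
    "SplitResult",
    "SplitOutcome",
    "locate_dpxg_split",
    "split_all",
    "cluster_domains",
    "recover_orphans",
    "core_toxin_pairs",
]

_DPXG = re.compile("(?=DP.G)")

STATUSES = ("full_length", "orphan_toxin", "core_only", "excluded_no_dpxg")


@dataclass(frozen=True)
class SplitResult:
    """Outcome of the DPxG scan on one protein."""

    split: int | None  # 1-based index of the first toxin residue
    n_occurrences: int


@dataclass
class RhsArchitecture:
    """One protein's decomposition into core and toxin domains."""

    protein_id: str
    genome_id: str
    status: str
    protein_len: int
    core_span: tuple[int, int] | None = None
    toxin_span: tuple[int, int] | None = None
    core_cluster: str | None = None
    toxin_cluster: str | None = None
    n_terminal_class: str = "unknown"
    ambiguous_split: bool = False  # >1 DPxG occurrence existed in the window

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status}")
        if self.status == "full_length":
            if self.core_span is None or self.toxin_span is None:
                raise ValueError(
                    f"{self.protein_id}: full_length needs both spans")
            if self.core_span[1] >= self.toxin_span[0]:
                raise ValueError(
                    f"{self.protein_id}: core must precede toxin")


def locate_dpxg_split(protein: ProteinRecord, core_hit: DomainHit,
                      window: int = 100) -> SplitResult:
    """Find the core/toxin boundary: the DPxG occurrence nearest the end of
    the core-motif hit, scanned over ``[hit.start, hit.end + window]``.

    Returns the 1-based index of the residue after the motif's G (the first
    toxin residue), or ``None`` when no occurrence exists — such proteins
    are excluded from the core/toxin analysis.
    """
    seq = protein.sequence.upper()
    L = len(seq)
    if not (1 <= core_hit.start <= core_hit.end <= L):
        raise ValueError(
            f"core hit {core_hit.start}..{core_hit.end} outside "
            f"protein {protein.id} (length {L})")
    lo = core_hit.start  # 1-based
    hi = min(core_hit.end + window, L)
    region = seq[lo - 1:hi]
    starts = [m.start() + lo for m in _DPXG.finditer(region)
              if m.start() + 3 < len(region)]  # whole 4-mer inside window
    if not starts:
        return SplitResult(None, 0)
    # choose the occurrence whose final G lies nearest the core hit's end;
    # ties break toward the earlier occurrence
    best = min(starts, key=lambda p: (abs((p + 3) - core_hit.end), p))
    return SplitResult(best + 4, len(starts))


@dataclass
class SplitOutcome:
    """Community-wide result of splitting core-motif proteins at DPxG."""

    core_seqs: list[tuple[str, str]]   # (protein_id, core sequence)
    toxin_seqs: list[tuple[str, str]]  # (protein_id, toxin sequence)
    splits: dict[str, int]             # protein_id -> first toxin residue
    statuses: dict[str, str]           # preliminary status per protein
    ambiguous: set[str]                # proteins with >1 DPxG occurrence


def split_all(proteins: list[ProteinRecord],
              core_hits: dict[str, DomainHit],
              window: int = 100,
              min_toxin_len: int = 30) -> SplitOutcome:
    """Split every core-motif protein into core and toxin domains.

    The core runs from the N terminus through the motif's G; the toxin is
    everything after it.  Toxins shorter than ``min_toxin_len`` are dropped
    (the protein is recorded ``core_only``); proteins without a DPxG in the
    scan window are recorded ``excluded_no_dpxg``.
    """
    out = SplitOutcome([], [], {}, {}, set())
    for p in proteins:
        hit = core_hits.get(p.id)
        if hit is None:
            continue
        res = locate_dpxg_split(p, hit, window)
        if res.n_occurrences > 1:
            out.ambiguous.add(p.id)
        if res.split is None:
            out.statuses[p.id] = "excluded_no_dpxg"
            continue
        core = p.sequence[:res.split - 1]
        toxin = p.sequence[res.split - 1:]
        out.splits[p.id] = res.split
        out.core_seqs.append((p.id, core))
        if len(toxin) < min_toxin_len:
            logger.info("protein %s: toxin domain %d aa < %d; core only",
                        p.id, len(toxin), min_toxin_len)
            out.statuses[p.id] = "core_only"
            continue
        out.toxin_seqs.append((p.id, toxin))
        out.statuses[p.id] = "full_length"
    return out


def cluster_domains(
    toxin_seqs: list[tuple[str, str]],
    core_seqs: list[tuple[str, str]],
    threshold: float = 0.40,
    min_core_len: int = 150,
) -> tuple[list[Cluster], list[Cluster], list[str]]:
    """Cluster toxin and core domains at the identity threshold.

    Core fragments shorter than ``min_core_len`` stay unassigned (orphaned
    toxin domains rarely retain enough core to place); their ids are
    returned separately.
    """
    toxin_clusters = greedy_cluster(toxin_seqs, threshold, kind="toxin_domain")
    assignable = [(pid, s) for pid, s in core_seqs if len(s) >= min_core_len]
    unassigned = [pid for pid, s in core_seqs if len(s) < min_core_len]
    core_clusters = (greedy_cluster(assignable, threshold, kind="core_domain")
                     if assignable else [])
    return toxin_clusters, core_clusters, unassigned


def _cluster_of(member_id: str, clusters: list[Cluster]) -> str | None:
    for c in clusters:
        if member_id in c.member_ids:
            return c.cluster_id
    return None


def recover_orphans(
    toxin_clusters: list[Cluster],
    toxin_seq_map: dict[str, str],
    proteomes: list[ProteinRecord],
    split_outcome: SplitOutcome,
    core_clusters: list[Cluster] | None = None,
    min_identity: float = 0.40,
    min_aln_len: int = 90,
) -> tuple[list[HomologMatch], dict[str, RhsArchitecture]]:
    """Search toxin representatives against every proteome protein and
    build the architecture table.

    Every matching protein gains an architecture: ``full_length`` when it
    also carries a core motif with a successful DPxG split, otherwise
    ``orphan_toxin``.  Each protein is assigned to the cluster of its
    best-identity representative (ties: longer alignment, then
    lexicographically smaller cluster id).
    """
    core_clusters = core_clusters or []
    rep_to_cluster = {c.representative_id: c.cluster_id
                      for c in toxin_clusters}
    reps = [(c.representative_id, toxin_seq_map[c.representative_id])
            for c in toxin_clusters]
    # toxin domain ids are "<pid>|toxin"; subjects are whole proteins
    db = [(p.id, p.sequence) for p in proteomes]
    matches = search_homologs(reps, db, min_identity=min_identity,
                              min_aln_len=min_aln_len)
    by_subject: dict[str, list[HomologMatch]] = {}
    for m in matches:
        by_subject.setdefault(m.subject_id, []).append(m)
    genome_of = {p.id: p.genome_id for p in proteomes}
    length_of = {p.id: len(p.sequence) for p in proteomes}

    architectures: dict[str, RhsArchitecture] = {}
    for pid, mlist in sorted(by_subject.items()):
        best = max(mlist, key=lambda m: (
            m.identity_fraction, m.aln_len,
            _neg_lex(rep_to_cluster[m.representative_id])))
        cluster_id = rep_to_cluster[best.representative_id]
        split = split_outcome.splits.get(pid)
        status = split_outcome.statuses.get(pid)
        L = length_of[pid]
        if status == "full_length" and split is not None:
            architectures[pid] = RhsArchitecture(
                pid, genome_of[pid], "full_length", L,
                core_span=(1, split - 1), toxin_span=(split, L),
                core_cluster=_cluster_of(f"{pid}|core", core_clusters),
                toxin_cluster=cluster_id,
                ambiguous_split=pid in split_outcome.ambiguous)
        elif status in {"core_only", "excluded_no_dpxg"}:
            architectures[pid] = RhsArchitecture(
                pid, genome_of[pid], status, L,
                core_span=(1, split - 1) if split else None,
                toxin_cluster=cluster_id,
                ambiguous_split=pid in split_outcome.ambiguous)
        else:
            architectures[pid] = RhsArchitecture(
                pid, genome_of[pid], "orphan_toxin", L,
                toxin_cluster=cluster_id)
    # core-motif proteins that matched no toxin representative keep their
    # preliminary status so that the status partition stays exhaustive
    for pid, status in split_outcome.statuses.items():
        if pid in architectures or pid not in genome_of:
            continue
        split = split_outcome.splits.get(pid)
        architectures[pid] = RhsArchitecture(
            pid, genome_of[pid], status if status != "full_length"
            else "core_only", length_of[pid],
            core_span=(1, split - 1) if split else None,
            ambiguous_split=pid in split_outcome.ambiguous)
    return matches, architectures


class _neg_lex(str):
    """Orders max() toward the lexicographically smaller string."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def core_toxin_pairs(
    architectures: dict[str, RhsArchitecture] | list[RhsArchitecture],
) -> Counter:
    """Multiset of (core_cluster, toxin_cluster) pairs, one per full-length
    protein with both assignments — the edge list of the core-toxin graph."""
    if isinstance(architectures, dict):
        architectures = list(architectures.values())
    pairs = Counter()
    for a in architectures:
        if (a.status == "full_length" and a.core_cluster
                and a.toxin_cluster):
            pairs[(a.core_cluster, a.toxin_cluster)] += 1
    return pairs
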