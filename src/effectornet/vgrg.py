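"""VgrG spike-protein inventory: clustering, length variation, truncations.

VgrG diversifies by C-terminal exchange just like Rhs, so cluster-level
length variation is informative: members far shorter than their cluster's
maximum are candidate pseudogenes (nonsense mutations, mobile-element
insertions), while members whose genes run into a contig end are merely
partial by assembly and are excluded from length statistics rather than
flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genome_io import Genome, feature_at_contig_end
from .homology import Cluster, HomologMatch, greedy_cluster, search_homologs
from .motifs import MotifModel, scan_protein

logger = logging.getLogger(__name__)

__all__ = [
    "VgrgProfileRow",
    "VgrgResult",
    "find_and_cluster_vgrg",
    "vgrg_length_profile",
    "flag_truncations",
    "MOBILE_ELEMENT_KEYWORDS",
]

#: annotation keywords that mark mobile-genetic-element genes
MOBILE_ELEMENT_KEYWORDS = ("transposase", "insertion sequence", "integrase")


@dataclass
class VgrgProfileRow:
    protein_id: str
    genome_id: str
    cluster_id: str
    length: int
    at_contig_end: bool
    is_member: bool            # length > min_cluster_len and homolog match
    identity_to_representative: float
    truncated_flag: bool = False
    length_fraction_of_cluster_max: float = 1.0
    mobile_element_context: bool = False


@dataclass
class VgrgResult:
    clusters: list[Cluster]
    matches: list[HomologMatch]
    rows: list[VgrgProfileRow]

    def rows_by_cluster(self) -> dict[str, list[VgrgProfileRow]]:
        out: dict[str, list[VgrgProfileRow]] = {}
        for r in self.rows:
            out.setdefault(r.cluster_id, []).append(r)
        return out


def _gene_near_mobile_element(genome: Genome, gene_id: str | None,
                              keywords=MOBILE_ELEMENT_KEYWORDS) -> bool:
    if gene_id is None:
        return False
    gene = genome.gene(gene_id)
    neighbors = genome.genes_on(gene.contig_id)
    idx = next(i for i, g in enumerate(neighbors) if g.id == gene_id)
    for j in (idx - 1, idx + 1):
        if 0 <= j < len(neighbors):
            product = (neighbors[j].product or "").lower()
            if any(k in product for k in keywords):
                return True
    return False


def find_and_cluster_vgrg(
    genomes: list[Genome],
    vgrg_model: MotifModel | None = None,
    threshold: float = 0.40,
    min_cluster_len: int = 500,
    min_aln_len: int = 300,
    min_identity: float = 0.40,
    contig_end_margin: int = 0,
    motif_positive_ids: set[str] | None = None,
) -> VgrgResult:
    """Identify, cluster and profile VgrG proteins across a community.

    Motif-positive proteins (found by scanning with ``vgrg_model``, or
    supplied directly as ``motif_positive_ids`` from a previous scan) are
    clustered greedily at ``threshold``; the representatives are then
    searched against every proteome (blast-style identity >=
    ``min_identity`` over >= ``min_aln_len`` aligned columns).  Counted
    cluster members are the matching proteins longer than
    ``min_cluster_len`` aa; shorter matches are retained as fragments.
    """
    proteins = {p.id: p for g in genomes for p in g.proteome}
    genome_of = {p.id: g for g in genomes for p in g.proteome}

    if motif_positive_ids is None:
        if vgrg_model is None:
            raise ValueError("need a vgrg model or precomputed hit ids")
        motif_positive_ids = {p.id for g in genomes for p in g.proteome
                              if scan_protein(vgrg_model, p)}
    motif_positive = [(p.id, p.sequence) for g in genomes
                      for p in g.proteome if p.id in motif_positive_ids]
    if not motif_positive:
        return VgrgResult([], [], [])
    clusters = greedy_cluster(motif_positive, threshold, kind="vgrg")
    rep_to_cluster = {c.representative_id: c.cluster_id for c in clusters}
    member_cluster = {pid: c.cluster_id
                      for c in clusters for pid in c.member_ids}
    reps = [(c.representative_id, proteins[c.representative_id].sequence)
            for c in clusters]
    db = [(pid, p.sequence) for pid, p in sorted(proteins.items())]
    matches = search_homologs(reps, db, min_identity=min_identity,
                              min_aln_len=min_aln_len)
    best_by_subject: dict[str, HomologMatch] = {}
    for m in matches:
        cur = best_by_subject.get(m.subject_id)
        key = (m.identity_fraction, m.aln_len,
               rep_to_cluster[m.representative_id])
        if cur is None or key > (cur.identity_fraction, cur.aln_len,
                                 rep_to_cluster[cur.representative_id]):
            best_by_subject[m.subject_id] = m

    rows: list[VgrgProfileRow] = []
    for pid in sorted(set(best_by_subject) | set(member_cluster)):
        has_match = pid in best_by_subject or pid in rep_to_cluster
        if pid in member_cluster:  # motif-positive: clustering decides
            cluster_id = member_cluster[pid]
            ident = (1.0 if pid in rep_to_cluster
                     else best_by_subject[pid].identity_fraction
                     if pid in best_by_subject else float("nan"))
        else:  # homology-only recovery: best representative decides
            m = best_by_subject[pid]
            cluster_id = rep_to_cluster[m.representative_id]
            ident = m.identity_fraction
        p = proteins[pid]
        genome = genome_of[pid]
        at_end = (p.gene_id is not None
                  and feature_at_contig_end(genome, p.gene_id,
                                            contig_end_margin))
        rows.append(VgrgProfileRow(
            pid, genome.id, cluster_id, len(p.sequence), at_end,
            is_member=len(p.sequence) > min_cluster_len and has_match,
            identity_to_representative=ident,
            mobile_element_context=_gene_near_mobile_element(
                genome, p.gene_id)))
    flag_truncations(rows)
    return VgrgResult(clusters, matches, rows)


def flag_truncations(rows: list[VgrgProfileRow],
                     fraction_cutoff: float = 0.5) -> list[VgrgProfileRow]:
    """Flag cluster members much shorter than their cluster's maximum.

    The reference length per cluster is the maximum among rows not at a
    contig end; rows shorter than ``fraction_cutoff`` times it are flagged.
    Contig-end rows are never flagged (partial by assembly, not decayed).
    """
    by_cluster: dict[str, list[VgrgProfileRow]] = {}
    for r in rows:
        by_cluster.setdefault(r.cluster_id, []).append(r)
    for cluster_id, members in sorted(by_cluster.items()):
        interior = [r.length for r in members if not r.at_contig_end]
        if not interior:
            logger.warning("vgrg cluster %s: all members at contig ends; "
                           "truncation flags undefined", cluster_id)
            for r in members:
                r.truncated_flag = False
                r.length_fraction_of_cluster_max = 1.0
            continue
        ref = max(interior)
        for r in members:
            r.length_fraction_of_cluster_max = r.length / ref
            r.truncated_flag = (not r.at_contig_end
                                and r.length < fraction_cutoff * ref)
    return rows


def vgrg_length_profile(rows: list[VgrgProfileRow],
                        exclude_contig_end: bool = True) -> pd.DataFrame:
    """Per-cluster length summary (n, min, median, max).

    Contig-end rows are excluded from the length statistics when requested
    (they remain in ``n_total``); clusters whose rows are all at contig
    ends produce an empty summary row with a warning.
    """
    records = []
    by_cluster: dict[str, list[VgrgProfileRow]] = {}
    for r in rows:
        by_cluster.setdefault(r.cluster_id, []).append(r)
    for cluster_id, members in sorted(by_cluster.items()):
        usable = [r.length for r in members
                  if not (exclude_contig_end and r.at_contig_end)]
        rec = {"cluster_id": cluster_id, "n_total": len(members),
               "n_length": len(usable)}
        if usable:
            s = pd.Series(usable)
            rec.update(min_len=int(s.min()), median_len=float(s.median()),
                       max_len=int(s.max()))
        else:
            logger.warning("vgrg cluster %s: no non-contig-end members; "
                           "empty length summary", cluster_id)
            rec.update(min_len=pd.NA, median_len=pd.NA, max_len=pd.NA)
        records.append(rec)
    return pd.DataFrame(records,
                        columns=["cluster_id", "n_total", "n_length",
                                 "min_len", "median_len", "max_len"])
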