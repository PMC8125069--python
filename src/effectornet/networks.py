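"""Homology networks, the core-toxin bipartite graph and summary tables.

Two network flavours mirror the two edge rules used in effector surveys:
an alignment-length rule (>= 40 % identity over >= 90 aligned residues,
suited to domain-sized sequences) and a coverage rule (>= 40 % identity
over >= 90 % of the protein length, suited to full-length proteins).  The
coverage denominator is the shorter protein — the permissive, symmetric
reading.  Graphs are networkx objects exportable as GraphML (attributes
preserved) or SIF (viewer-friendly, lossy).
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import networkx as nx
import pandas as pd

from .homology import align_local, identity_blast_style
from .rhs import RhsArchitecture

__all__ = [
    "build_homology_network",
    "build_core_toxin_network",
    "write_graphml",
    "read_graphml",
    "write_sif",
    "per_genome_summary",
]

EDGE_RULES = ("min_aln_len_90", "min_cov_0.9")


def build_homology_network(
    proteins: list[tuple[str, str]] | list,
    rule: str = "min_aln_len_90",
    min_identity: float = 0.40,
    min_aln_len: int = 90,
    min_coverage: float = 0.90,
    node_attrs: dict[str, dict] | None = None,
) -> nx.Graph:
    """All-versus-all homology network under one edge rule.

    ``proteins`` are ``(id, sequence)`` pairs (or objects with ``id`` and
    ``sequence``).  An edge joins two proteins when their best local
    alignment has blast-style identity >= ``min_identity`` and, depending
    on ``rule``, either >= ``min_aln_len`` aligned columns or an aligned
    span covering >= ``min_coverage`` of the shorter protein.
    """
    if rule not in EDGE_RULES:
        raise ValueError(f"unknown edge rule {rule!r}")
    pairs = [(p.id, p.sequence) if hasattr(p, "id") else tuple(p)
             for p in proteins]
    pairs.sort()
    G = nx.Graph(edge_rule=rule)
    for pid, seq in pairs:
        attrs = (node_attrs or {}).get(pid, {})
        G.add_node(pid, length=len(seq), **attrs)
    for i in range(len(pairs)):
        aid, aseq = pairs[i]
        for j in range(i + 1, len(pairs)):
            bid, bseq = pairs[j]
            r = align_local(aseq, bseq, query_id=aid, subject_id=bid)
            if r.aln_columns == 0:
                continue
            ident = identity_blast_style(r)
            if ident < min_identity:
                continue
            if rule == "min_aln_len_90":
                if r.aln_columns < min_aln_len:
                    continue
            else:
                shorter = min(len(aseq), len(bseq))
                span = (r.q_aln_len if len(aseq) <= len(bseq)
                        else r.s_aln_len)
                if span / shorter < min_coverage:
                    continue
            G.add_edge(aid, bid, identity=round(ident, 4),
                       aln_len=r.aln_columns)
    return G


def build_core_toxin_network(
    pairs: Counter,
    core_cluster_sizes: dict[str, int] | None = None,
    toxin_cluster_sizes: dict[str, int] | None = None,
) -> nx.Graph:
    """Bipartite graph of core-domain and toxin-domain clusters.

    One edge per observed (core cluster, toxin cluster) combination, with
    weight = number of full-length proteins exhibiting it.  Node ``size``
    is the cluster's member count when provided.
    """
    G = nx.Graph()
    for (core, toxin), mult in sorted(pairs.items()):
        if not G.has_node(core):
            G.add_node(core, bipartite="core",
                       size=(core_cluster_sizes or {}).get(core, 1))
        if not G.has_node(toxin):
            G.add_node(toxin, bipartite="toxin",
                       size=(toxin_cluster_sizes or {}).get(toxin, 1))
        G.add_edge(core, toxin, weight=mult)
    for cid, size in (toxin_cluster_sizes or {}).items():
        if not G.has_node(cid):  # orphan-only toxin cluster: isolated node
            G.add_node(cid, bipartite="toxin", size=size)
    return G


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_sif(G: nx.Graph, path: str | Path,
              relation: str = "homology") -> None:
    """Simple interaction format: node <relation> node, isolates bare."""
    lines = []
    for a, b in sorted(G.edges()):
        lines.append(f"{a}\t{relation}\t{b}")
    for n in sorted(G.nodes()):
        if G.degree(n) == 0:
            lines.append(str(n))
    Path(path).write_text("\n".join(lines) + "\n")


def per_genome_summary(
    genomes: list,
    architectures: dict[str, RhsArchitecture],
    vgrg_rows: list,
    verdicts: dict[str, str],
) -> pd.DataFrame:
    """One row per genome: toxin-domain counts, full-length/orphan
    breakdown, VgrG member counts and the T6SS verdict.

    Genomes with nothing detected still get an all-zero row, and the
    breakdown columns sum to the toxin-domain count.
    """
    arch_by_genome: dict[str, list[RhsArchitecture]] = {}
    for a in architectures.values():
        arch_by_genome.setdefault(a.genome_id, []).append(a)
    vgrg_by_genome: dict[str, list] = {}
    for r in vgrg_rows:
        vgrg_by_genome.setdefault(r.genome_id, []).append(r)
    records = []
    for g in genomes:
        archs = arch_by_genome.get(g.id, [])
        with_toxin = [a for a in archs if a.toxin_cluster]
        rows = vgrg_by_genome.get(g.id, [])
        records.append({
            "genome_id": g.id,
            "species_label": g.species_label,
            "host_label": g.host_label,
            "n_toxin_domains": len(with_toxin),
            "n_full_length": sum(1 for a in with_toxin
                                 if a.status == "full_length"),
            "n_orphan_toxin": sum(1 for a in with_toxin
                                  if a.status == "orphan_toxin"),
            "n_other_status": sum(1 for a in with_toxin
                                  if a.status not in
                                  {"full_length", "orphan_toxin"}),
            "n_vgrg_members": sum(1 for r in rows if r.is_member),
            "n_vgrg_total": len(rows),
            "t6ss_verdict": verdicts.get(g.id, "absent"),
        })
    return pd.DataFrame(records)


def vgrg_counts_by_cluster(genomes: list, vgrg_rows: list) -> pd.DataFrame:
    """Long-format per-genome, per-cluster VgrG member counts."""
    counts: Counter = Counter()
    meta = {g.id: (g.species_label, g.host_label) for g in genomes}
    for r in vgrg_rows:
        if r.is_member:
            counts[(r.genome_id, r.cluster_id)] += 1
    records = []
    for (gid, cid), n in sorted(counts.items()):
        species, host = meta.get(gid, ("", ""))
        records.append({"genome_id": gid, "species_label": species,
                        "host_label": host, "cluster_id": cid, "count": n})
    return pd.DataFrame(records, columns=["genome_id", "species_label",
                                          "host_label", "cluster_id",
                                          "count"])
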