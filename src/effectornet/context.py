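"""Toxin-immunity pairing, cooccurrence matrices and secretion context.

Immunity genes sit immediately downstream of their cognate toxin gene, so
pairing is positional: the first downstream neighbour on the same strand
within a small intergenic gap.  Pair representatives are then searched
across every genome to build the presence/absence (and copy-number)
cooccurrence matrix.  A toxin found without its immunity partner gets a
caveat: either the toxin gene sits at a contig end (the immunity gene may
simply be unassembled) or homology to the immunity reference was too low.

Separately, each Rhs-related protein is assigned a secretion-system context
from its N-terminal domains and gene neighbourhood: PAAR-led proteins are
T6SS effectors, SpvB/TcdB heads or adjacent type-A sorting-domain genes
point to T9SS, and hemagglutinin repeats plus an extended signal peptide
mark T5SS autotransporters (contact-dependent inhibition systems).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_io import Genome, GeneFeature, ProteinRecord, \
    downstream_neighbors, intergenic_gap
from .homology import Cluster, search_homologs
from .motifs import DomainHit
from .rhs import RhsArchitecture

__all__ = [
    "ToxinImmunityPair",
    "CooccurrenceCell",
    "find_cognate_immunity",
    "derive_pairs",
    "cooccurrence_matrix",
    "classify_secretion_context",
    "CONTEXT_LABELS",
]

CONTEXT_LABELS = ("t6ss_effector", "t9ss_associated", "t5ss_autotransporter",
                  "orphan_domain", "unknown")


@dataclass(frozen=True)
class ToxinImmunityPair:
    pair_id: str
    toxin_representative: str  # domain or protein sequence
    immunity_representative: str
    source_genome: str = ""
    source_toxin_gene: str = ""
    source_immunity_gene: str = ""

    def __post_init__(self) -> None:
        if not self.toxin_representative or not self.immunity_representative:
            raise ValueError(f"pair {self.pair_id}: empty representative")


@dataclass
class CooccurrenceCell:
    genome_id: str
    pair_id: str
    toxin_copy_count: int
    immunity_copy_count: int
    caveat: str = "none"  # none | toxin_at_contig_end | low_homology

    @property
    def toxin_present(self) -> bool:
        return self.toxin_copy_count >= 1

    @property
    def immunity_present(self) -> bool:
        return self.immunity_copy_count >= 1


def find_cognate_immunity(
    genome: Genome,
    toxin_gene: GeneFeature | str,
    max_intergenic: int = 200,
    require_same_strand: bool = True,
) -> tuple[GeneFeature | None, str]:
    """Locate the putative immunity gene downstream of a toxin gene.

    Returns ``(gene, "found")``, ``(None, "contig_end")`` when nothing lies
    downstream on the contig, or ``(None, "no_candidate")`` when the next
    downstream gene is too far or on the wrong strand.
    """
    if isinstance(toxin_gene, str):
        toxin_gene = genome.gene(toxin_gene)
    neighbors = downstream_neighbors(genome, toxin_gene, k=1)
    if not neighbors:
        return None, "contig_end"
    cand = neighbors[0]
    if intergenic_gap(toxin_gene, cand) > max_intergenic:
        return None, "no_candidate"
    if require_same_strand and cand.strand != toxin_gene.strand:
        return None, "no_candidate"
    return cand, "found"


def derive_pairs(
    toxin_clusters: list[Cluster],
    toxin_seq_map: dict[str, str],
    genomes: list[Genome],
    top_k: int | None = None,
    max_intergenic: int = 200,
    require_same_strand: bool = True,
) -> list[ToxinImmunityPair]:
    """Auto-derive toxin/immunity reference pairs from clusters.

    Clusters are visited from largest to smallest (ties by id); for each,
    the first member (by id) whose gene has a cognate immunity neighbour
    donates the pair: the cluster's representative toxin-domain sequence
    plus that immunity protein.  Clusters with no pairable member are
    skipped.  ``top_k`` limits the number of pairs.
    """
    by_genome = {g.id: g for g in genomes}
    gene_to_protein = {
        (g.id, p.gene_id): p for g in genomes for p in g.proteome
        if p.gene_id is not None}
    protein_index = {p.id: (g, p) for g in genomes for p in g.proteome}
    pairs: list[ToxinImmunityPair] = []
    ordered = sorted(toxin_clusters,
                     key=lambda c: (-len(c.member_ids), c.cluster_id))
    for cluster in ordered:
        if top_k is not None and len(pairs) >= top_k:
            break
        found = None
        for domain_id in sorted(cluster.member_ids):
            pid = domain_id.rsplit("|", 1)[0]
            entry = protein_index.get(pid)
            if entry is None:
                continue
            genome, protein = entry
            if protein.gene_id is None:
                continue
            gene = genome.gene(protein.gene_id)
            imm_gene, reason = find_cognate_immunity(
                genome, gene, max_intergenic, require_same_strand)
            if imm_gene is None:
                continue
            imm_protein = gene_to_protein.get((genome.id, imm_gene.id))
            if imm_protein is None:
                continue
            found = (genome, gene, imm_gene, imm_protein)
            break
        if found is None:
            continue
        genome, gene, imm_gene, imm_protein = found
        pairs.append(ToxinImmunityPair(
            pair_id=f"P_{cluster.cluster_id}",
            toxin_representative=toxin_seq_map[cluster.representative_id],
            immunity_representative=imm_protein.sequence,
            source_genome=genome.id,
            source_toxin_gene=gene.id,
            source_immunity_gene=imm_gene.id))
    return pairs


def cooccurrence_matrix(
    pairs: list[ToxinImmunityPair],
    genomes: list[Genome],
    min_identity: float = 0.40,
    min_reference_coverage: float = 0.90,
    max_intergenic: int = 200,
) -> list[CooccurrenceCell]:
    """Count toxin and immunity homologs per genome per reference pair.

    A proteome protein counts when its best alignment to the reference
    reaches ``min_identity`` over at least ``min_reference_coverage`` of
    the reference's length.  When a toxin is present without its immunity
    partner, the caveat records whether any counted toxin gene lacks a
    downstream neighbour on its contig (``toxin_at_contig_end``) or the
    immunity homology simply fell short (``low_homology``).
    """
    cells: list[CooccurrenceCell] = []
    for genome in genomes:
        db = [(p.id, p.sequence) for p in genome.proteome]
        for pair in pairs:
            tox = search_homologs(
                [(f"{pair.pair_id}|toxin", pair.toxin_representative)],
                db, min_identity=min_identity,
                min_representative_coverage=min_reference_coverage)
            imm = search_homologs(
                [(f"{pair.pair_id}|immunity", pair.immunity_representative)],
                db, min_identity=min_identity,
                min_representative_coverage=min_reference_coverage)
            caveat = "none"
            if tox and not imm:
                caveat = "low_homology"
                protein_gene = {p.id: p.gene_id for p in genome.proteome}
                for m in tox:
                    gid = protein_gene.get(m.subject_id)
                    if gid is None:
                        continue
                    _, reason = find_cognate_immunity(
                        genome, gid, max_intergenic)
                    if reason == "contig_end":
                        caveat = "toxin_at_contig_end"
                        break
            cells.append(CooccurrenceCell(genome.id, pair.pair_id,
                                          len(tox), len(imm), caveat))
    return cells


def cooccurrence_frame(cells: list[CooccurrenceCell]) -> pd.DataFrame:
    """Long-format table of the cooccurrence matrix."""
    return pd.DataFrame([{
        "genome_id": c.genome_id, "pair_id": c.pair_id,
        "toxin_n": c.toxin_copy_count, "immunity_n": c.immunity_copy_count,
        "toxin_present": c.toxin_present,
        "immunity_present": c.immunity_present, "caveat": c.caveat,
    } for c in cells])


def classify_secretion_context(
    protein: ProteinRecord,
    hits_by_protein: dict[str, list[DomainHit]],
    genome: Genome,
    architecture: RhsArchitecture | None = None,
    signal_window: int = 100,
) -> str:
    """Assign one secretion-system context label to a protein.

    Precedence: (1) hemagglutinin repeats plus a signal peptide starting in
    the first ``signal_window`` aa -> t5ss_autotransporter; (2) an
    SpvB/TcdB hit in the N-terminal half, or a type-A sorting-domain hit on
    a gene within one neighbour -> t9ss_associated; (3) a PAAR hit, or a
    full-length architecture with an Rhs core -> t6ss_effector; (4) orphan
    toxin status -> orphan_domain; (5) unknown.  Missing motifs simply
    never fire, so a minimal motif library degrades toward ``unknown``.
    """
    hits = hits_by_protein.get(protein.id, [])
    motifs_here = {h.motif_name for h in hits}
    half = len(protein.sequence) / 2

    if "hemagglutinin" in motifs_here and any(
            h.motif_name == "signal_peptide" and h.start <= signal_window
            for h in hits):
        return "t5ss_autotransporter"

    spvb_n_terminal = any(h.motif_name == "spvb_tcdb" and h.start <= half
                          for h in hits)
    sorting_neighbor = False
    if protein.gene_id is not None:
        gene = genome.gene(protein.gene_id)
        on_contig = genome.genes_on(gene.contig_id)
        idx = next(i for i, g in enumerate(on_contig) if g.id == gene.id)
        gene_to_protein = {p.gene_id: p.id for p in genome.proteome
                           if p.gene_id is not None}
        for j in (idx - 1, idx + 1):
            if 0 <= j < len(on_contig):
                npid = gene_to_protein.get(on_contig[j].id)
                if npid and any(h.motif_name == "t9ss_sorting"
                                for h in hits_by_protein.get(npid, [])):
                    sorting_neighbor = True
    if spvb_n_terminal or sorting_neighbor:
        return "t9ss_associated"

    if "paar" in motifs_here or (
            architecture is not None
            and architecture.status == "full_length"
            and "rhs_core" in motifs_here):
        return "t6ss_effector"
    if architecture is not None and architecture.status == "orphan_toxin":
        return "orphan_domain"
    return "unknown"
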