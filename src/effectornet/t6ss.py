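"""T6SS structural-locus detection and completeness classification.

A canonical type VI secretion system is encoded by 13 structural genes
(tssA through tssM, including the Hcp tube tssD and the VgrG spike tssI).
A genome is credited with a T6SS when all 13 are present, with two
relaxations: a single missing gene is forgiven when the locus is truncated
by a contig end (assembly artifact, not biology), and subtype-iii systems
(Bacteroidetes lineage) are complete despite lacking tssQ/tssR homologs.
Detection is homology-based against a reference protein set per subtype;
lone vgrG satellites never count as a system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import Genome, feature_at_contig_end
from .homology import align_local, identity_blast_style

__all__ = [
    "CANONICAL_GENES",
    "StructuralReferenceSet",
    "StructuralHit",
    "LocusSpan",
    "T6SSLocusCall",
    "detect_structural_hits",
    "call_loci",
    "classify_completeness",
    "inventory_genome",
    "VERDICT_ORDER",
]

#: the 13 canonical structural components, in conventional order
CANONICAL_GENES = ("tssA", "tssB", "tssC", "tssD", "tssE", "tssF", "tssG",
                   "tssH", "tssI", "tssJ", "tssK", "tssL", "tssM")

#: verdicts from best to worst, for per-genome aggregation
VERDICT_ORDER = ("complete", "complete_contig_end_exception",
                 "incomplete", "absent")


@dataclass
class StructuralReferenceSet:
    """Named set of reference structural proteins defining one T6SS subtype.

    ``optional_absent`` lists accessory genes whose absence never counts
    against completeness (tssQ/tssR for subtype iii); it is disjoint from
    ``required_genes``.
    """

    name: str
    required_genes: tuple[str, ...] = CANONICAL_GENES
    optional_absent: tuple[str, ...] = ()
    reference_proteins: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.required_genes:
            raise ValueError(f"reference set {self.name}: no required genes")
        overlap = set(self.required_genes) & set(self.optional_absent)
        if overlap:
            raise ValueError(
                f"reference set {self.name}: {sorted(overlap)} both "
                "required and optional")


@dataclass(frozen=True)
class StructuralHit:
    protein_id: str
    gene_id: str | None
    structural_gene: str
    identity: float
    coverage: float  # aligned fraction of the reference protein


@dataclass
class LocusSpan:
    contig_id: str
    start: int
    end: int
    gene_ids: list[str]
    structural_genes: list[str]
    satellite: bool = False


@dataclass
class T6SSLocusCall:
    genome_id: str
    reference_set: str
    gene_hits: dict[str, list[StructuralHit]]
    locus_spans: list[LocusSpan]
    verdict: str
    missing_genes: list[str]

    def __post_init__(self) -> None:
        if self.verdict == "complete" and self.missing_genes:
            raise ValueError("complete verdict with missing genes")


def detect_structural_hits(
    genome: Genome,
    reference_set: StructuralReferenceSet,
    min_identity: float = 0.40,
    min_coverage: float = 0.70,
) -> dict[str, list[StructuralHit]]:
    """Assign proteome proteins to structural genes by best local alignment.

    Each protein is compared with every reference protein; among qualifying
    assignments (blast-style identity >= ``min_identity`` and aligned
    reference fraction >= ``min_coverage``) the protein maps to the single
    highest-identity structural gene.  The permissive outgroup-style setting
    is ``min_identity=0.20, min_coverage=0.20``.
    """
    hits: dict[str, list[StructuralHit]] = {}
    all_refs = [(gname, ref) for gname, refs in
                sorted(reference_set.reference_proteins.items())
                for ref in refs]
    for protein in genome.proteome:
        best: StructuralHit | None = None
        for gname, ref in all_refs:
            # a protein shorter than the required aligned fraction of the
            # reference can never reach min_coverage: skip (exact pruning)
            if len(protein.sequence) < min_coverage * len(ref):
                continue
            r = align_local(ref, protein.sequence,
                            query_id=gname, subject_id=protein.id)
            if r.aln_columns == 0:
                continue
            ident = identity_blast_style(r)
            cov = r.q_aln_len / len(ref)
            if ident < min_identity or cov < min_coverage:
                continue
            if best is None or ident > best.identity:
                best = StructuralHit(protein.id, protein.gene_id, gname,
                                     ident, cov)
        if best is not None:
            hits.setdefault(best.structural_gene, []).append(best)
    return hits


def call_loci(gene_hits: dict[str, list[StructuralHit]], genome: Genome,
              max_gap: int = 10_000) -> list[LocusSpan]:
    """Merge structural-gene features into genomic loci.

    Features on one contig whose consecutive spacing is <= ``max_gap`` form
    one locus.  Loci whose only structural gene is tssI (the VgrG spike) are
    flagged as satellites and excluded from completeness evidence.
    """
    located = []
    for gname, hlist in gene_hits.items():
        for h in hlist:
            if h.gene_id is None:
                continue
            g = genome.gene(h.gene_id)
            located.append((g.contig_id, g.start, g.end, g.id, gname))
    located.sort()
    loci: list[LocusSpan] = []
    for contig_id, start, end, gid, gname in located:
        cur = loci[-1] if loci else None
        if (cur is not None and cur.contig_id == contig_id
                and start - cur.end <= max_gap):
            cur.end = max(cur.end, end)
            cur.gene_ids.append(gid)
            cur.structural_genes.append(gname)
        else:
            loci.append(LocusSpan(contig_id, start, end, [gid], [gname]))
    for locus in loci:
        locus.satellite = set(locus.structural_genes) == {"tssI"}
    return loci


def _locus_abuts_contig_end(locus: LocusSpan, genome: Genome,
                            margin: int) -> bool:
    contig = genome.contig(locus.contig_id)
    return locus.start <= margin + 1 or (contig.length - locus.end) <= margin


def classify_completeness(
    genome: Genome,
    reference_set: StructuralReferenceSet,
    gene_hits: dict[str, list[StructuralHit]],
    locus_spans: list[LocusSpan],
    contig_end_margin: int = 0,
) -> T6SSLocusCall:
    """Apply the completeness rules to one genome under one reference set.

    complete: every required gene (tssQ/tssR-style optional genes aside)
    has a hit.  complete_contig_end_exception: exactly one required gene is
    missing and a non-satellite locus terminates at a contig boundary
    (within ``contig_end_margin`` bp).  incomplete: some structural evidence
    but neither rule holds.  absent: no structural hits, where vgrG-only
    satellite loci do not count as evidence.
    """
    required = [g for g in reference_set.required_genes
                if g not in reference_set.optional_absent]
    present = {g for g, hl in gene_hits.items() if hl}
    missing = [g for g in required if g not in present]
    non_satellite = [l for l in locus_spans if not l.satellite]
    structural_evidence = {g for locus in non_satellite
                           for g in locus.structural_genes}
    if not structural_evidence:
        verdict = "absent"
        missing = list(required)
    elif not missing:
        verdict = "complete"
    elif len(missing) == 1 and any(
            _locus_abuts_contig_end(l, genome, contig_end_margin)
            for l in non_satellite):
        verdict = "complete_contig_end_exception"
    else:
        verdict = "incomplete"
    return T6SSLocusCall(genome.id, reference_set.name, gene_hits,
                         locus_spans, verdict, missing)


def inventory_genome(
    genome: Genome,
    reference_sets: list[StructuralReferenceSet],
    min_identity: float = 0.40,
    min_coverage: float = 0.70,
    max_gap: int = 10_000,
    contig_end_margin: int = 0,
) -> tuple[T6SSLocusCall, dict[str, T6SSLocusCall]]:
    """Classify a genome under every reference set; return the best call.

    The per-genome verdict is the best verdict across subtype reference
    sets (complete beats the contig-end exception, which beats incomplete,
    which beats absent); ties go to the first set in the given order.
    """
    calls: dict[str, T6SSLocusCall] = {}
    for ref_set in reference_sets:
        hits = detect_structural_hits(genome, ref_set, min_identity,
                                      min_coverage)
        loci = call_loci(hits, genome, max_gap)
        calls[ref_set.name] = classify_completeness(
            genome, ref_set, hits, loci, contig_end_margin)
    rank = {v: i for i, v in enumerate(VERDICT_ORDER)}
    best_name = min(calls, key=lambda n: (rank[calls[n].verdict],
                                          [r.name for r in reference_sets].index(n)))
    return calls[best_name], calls
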