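"""Synthetic genome communities with planted effector biology.

The generator emulates a panel of gut-symbiont isolate genomes: multi-contig
assemblies carrying T6SS structural loci (complete, truncated at a contig
end, subtype-iii, partially deleted or absent), full-length *rhs* genes
(N-terminal secretion stub with a PAAR block, a conserved core ending in a
DPxG motif, a divergent C-terminal toxin domain, and a cognate immunity gene
immediately downstream), arrays of orphaned toxin domains, satellite and
pseudogenized *vgrG* genes, and unrelated decoy proteins.

Sequence families are built from fixed-seed random proteins: each family has
a seed sequence, and members are derived by substitution-only mutation to a
controlled positional identity, so family structure is known exactly.
Conserved motif blocks (Rhs core, VgrG, PAAR, ...) are shared across
families at low divergence, which is what makes one scoring model per motif
sufficient.  Every planted element is recorded in a ground-truth ledger so
recovery can be scored precisely.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .genome_io import (ContigRecord, GeneFeature, Genome, ProteinRecord,
                        write_genome_manifest, write_gff3_fasta,
                        write_proteome_fasta)
from .homology import align_local, identity_short_style
from .t6ss import CANONICAL_GENES, StructuralReferenceSet

__all__ = [
    "GenomePlan",
    "CommunitySpec",
    "Community",
    "mutate_to_identity",
    "random_protein",
    "generate_community",
    "default_community_spec",
    "immunity_demo_spec",
    "write_community",
    "verify_separation",
]

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: widths of the conserved motif blocks planted across families
BLOCK_WIDTHS = {
    "rhs_core": 100,
    "vgrg": 120,
    "paar": 60,
    "spvb_tcdb": 80,
    "t9ss_sorting": 60,
    "hemagglutinin": 80,
    "signal_peptide": 18,
}

_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(unambiguous_dna_by_id[11].forward_table.items()):
    _CODONS.setdefault(_aa, []).append(_codon)

_DNA = "ACGT"


class GenerationError(RuntimeError):
    """Raised when a community plan cannot be realized."""


class MutationParameterError(ValueError):
    """Raised when a mutation target is unreachable given masked positions."""


# ---------------------------------------------------------------------------
# sequence-level primitives

def random_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein with uniform residue composition (the scan background)."""
    return "".join(rng.choice(list(RESIDUES), size=length))


def mutate_to_identity(seq: str, target: float,
                       rng: np.random.Generator | int,
                       mask: frozenset[int] | set[int] = frozenset(),
                       tol: float = 0.03) -> str:
    """Substitution-only mutant at a controlled positional identity.

    Exactly ``round((1 - target) * len(seq))`` positions, sampled without
    replacement outside ``mask`` (0-based indices), are replaced with a
    different residue.  Length is preserved and the achieved identity is
    within ``tol`` of the target by construction; an unreachable target
    (too many masked positions) raises :class:`MutationParameterError`.
    """
    if not 0 < target <= 1:
        raise MutationParameterError(f"target {target} outside (0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = len(seq)
    n_mut = round((1 - target) * n)
    available = [i for i in range(n) if i not in mask]
    if n_mut > len(available):
        raise MutationParameterError(
            f"cannot reach identity {target}: only {len(available)} "
            f"mutable positions for {n_mut} substitutions")
    achieved = 1 - n_mut / n
    if abs(achieved - target) > tol:
        raise MutationParameterError(
            f"achievable identity {achieved:.3f} misses target {target} "
            f"by more than {tol}")
    positions = rng.choice(len(available), size=n_mut, replace=False)
    chars = list(seq)
    for k in sorted(positions):
        i = available[k]
        alternatives = RESIDUES.replace(chars[i], "")
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def reverse_translate(aa: str, rng: np.random.Generator) -> str:
    """Codon sequence (table 11) encoding ``aa``, with a TAA stop."""
    codons = [_CODONS[c][rng.integers(len(_CODONS[c]))] for c in aa]
    return "".join(codons) + "TAA"


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_DNA), size=length))


# ---------------------------------------------------------------------------
# community specification

@dataclass
class GenomePlan:
    """Planted content for one synthetic genome."""

    genome_id: str
    species_label: str = "S. alvi"
    host_label: str = "A. mellifera"
    t6ss_verdict: str = "complete"   # planted verdict
    t6ss_set: str = "canonical_i"    # which reference set is planted
    full_length: list[tuple[str, str]] = field(default_factory=list)
    #: (core_family, toxin_family) pairs, one full-length rhs gene each
    orphans: list[tuple[str, bool]] = field(default_factory=list)
    #: (toxin_family, with_core_fragment)
    immunity_only: list[str] = field(default_factory=list)
    toxin_at_contig_end: str | None = None  # (core, toxin) planted bare
    vgrg: list[str] = field(default_factory=list)
    vgrg_pseudo: list[str] = field(default_factory=list)
    vgrg_at_contig_end: str | None = None
    t9ss_rhs: list[str] = field(default_factory=list)
    t5ss_rhs: list[str] = field(default_factory=list)
    n_decoys: int = 3


@dataclass
class CommunitySpec:
    """Study conditions for one synthetic community."""

    seed: int = 0
    n_toxin_families: int = 6
    n_core_families: int = 3
    n_vgrg_families: int = 3
    within_identity: float = 0.60   # pairwise floor within a family
    between_identity: float = 0.25  # ceiling between family seeds
    decoy_identity: float = 0.30    # ceiling decoy vs any family seed
    member_seed_identity: float = 0.85  # member-to-family-seed target
    block_seed_identity: float = 0.90   # motif-seed-to-global-block
    #: VgrG family head vs the global spike block.  More diverged than the
    #: Rhs core block: a pseudogene truncated down to little beyond the
    #: conserved spike region must still fall below the 40 % clustering
    #: threshold against *other* families, which bounds how similar the
    #: family-level spike copies may be.
    vgrg_block_identity: float = 0.75
    plant_t6ss: bool = True
    plans: list[GenomePlan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.within_identity <= 1:
            raise ValueError("within_identity outside (0, 1]")
        if self.within_identity <= self.between_identity:
            raise ValueError("within-family floor must exceed the "
                             "between-family ceiling")
        for plan in self.plans:
            for count in (len(plan.full_length), len(plan.orphans),
                          len(plan.vgrg), len(plan.vgrg_pseudo),
                          plan.n_decoys):
                if count < 0:
                    raise ValueError("negative plant count")


@dataclass
class CommunityAssets:
    """Family seeds and reference material shared by a community."""

    blocks: dict[str, str]
    motif_seed_alignments: dict[str, list[tuple[str, str]]]
    toxin_seeds: dict[str, str]
    core_seeds: dict[str, str]       # stub + body + rhs_core block (DPxG end)
    immunity_seeds: dict[str, str]
    vgrg_seeds: dict[str, str]
    reference_sets: list[StructuralReferenceSet]

    def family_representatives(self) -> list[tuple[str, str]]:
        reps = []
        for fam, seq in sorted({**self.toxin_seeds, **self.core_seeds,
                                **self.immunity_seeds,
                                **self.vgrg_seeds}.items()):
            reps.append((fam, seq))
        for ref_set in self.reference_sets:
            for gname, seqs in sorted(ref_set.reference_proteins.items()):
                for k, s in enumerate(seqs):
                    reps.append((f"{ref_set.name}:{gname}:{k}", s))
        return reps


@dataclass
class Community:
    genomes: list[Genome]
    truth: pd.DataFrame
    genome_truth: pd.DataFrame
    assets: CommunityAssets
    spec: CommunitySpec


# ---------------------------------------------------------------------------
# assets

def _rng_for(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *stream]))


def _make_block(rng: np.random.Generator, name: str, width: int) -> str:
    block = random_protein(rng, width)
    if name == "rhs_core":
        # the block ends with the DPxG anchor (x drawn at random)
        block = block[:-4] + "DP" + block[-2] + "G"
    return block


def _dpxg_mask(length: int) -> frozenset[int]:
    """Positions of D, P and G of the terminal DPxG (0-based; x mutable)."""
    return frozenset({length - 4, length - 3, length - 1})


def build_assets(spec: CommunitySpec) -> CommunityAssets:
    rng = _rng_for(spec.seed, 1)
    blocks = {name: _make_block(rng, name, w)
              for name, w in BLOCK_WIDTHS.items()}

    seed_alignments: dict[str, list[tuple[str, str]]] = {}
    for name, block in blocks.items():
        mask = _dpxg_mask(len(block)) if name == "rhs_core" else frozenset()
        seed_alignments[name] = [
            (f"{name}_seed{k + 1}",
             mutate_to_identity(block, spec.block_seed_identity, rng, mask))
            for k in range(8)]

    toxin_seeds = {
        f"T{k + 1}": random_protein(rng, int(rng.integers(300, 361)))
        for k in range(spec.n_toxin_families)}
    immunity_seeds = {
        f"T{k + 1}": random_protein(rng, int(rng.integers(130, 171)))
        for k in range(spec.n_toxin_families)}

    core_seeds = {}
    for k in range(spec.n_core_families):
        stub = (random_protein(rng, 20)
                + mutate_to_identity(blocks["paar"],
                                     spec.block_seed_identity, rng)
                + random_protein(rng, 40))
        body = random_protein(rng, int(rng.integers(780, 921)))
        core_block = mutate_to_identity(
            blocks["rhs_core"], spec.block_seed_identity, rng,
            _dpxg_mask(len(blocks["rhs_core"])))
        core_seeds[f"C{k + 1}"] = stub + body + core_block

    vgrg_seeds = {}
    for k in range(spec.n_vgrg_families):
        head = random_protein(rng, 10) + mutate_to_identity(
            blocks["vgrg"], spec.vgrg_block_identity, rng)
        body = random_protein(rng, int(rng.integers(520, 621)))
        vgrg_seeds[f"V{k + 1}"] = head + body

    canonical_refs: dict[str, list[str]] = {}
    subtype_refs: dict[str, list[str]] = {}
    for gname in CANONICAL_GENES:
        length = 650 if gname == "tssI" else int(rng.integers(250, 551))
        canonical_refs[gname] = [random_protein(rng, length)]
        subtype_refs[gname] = [random_protein(rng, length)]
    for gname in ("tssQ", "tssR"):
        subtype_refs[gname] = [random_protein(rng, int(rng.integers(200, 401)))]

    reference_sets = [
        StructuralReferenceSet("canonical_i", CANONICAL_GENES, (),
                               canonical_refs),
        StructuralReferenceSet("subtype_iii", CANONICAL_GENES,
                               ("tssQ", "tssR"), subtype_refs),
    ]
    return CommunityAssets(blocks, seed_alignments, toxin_seeds, core_seeds,
                           immunity_seeds, vgrg_seeds, reference_sets)


# ---------------------------------------------------------------------------
# genome assembly

@dataclass
class _PlannedGene:
    protein: str | None  # None: pseudo feature without a proteome entry
    kind: str
    family: str | None = None
    product: str | None = None
    split_pos: int | None = None  # intended first toxin residue (rhs_full)
    t6ss_gene: str | None = None
    gap_before: tuple[int, int] = (250, 600)
    strand: str = "+"
    flush_contig_end: bool = False  # contig must end exactly at this gene


def _member(seq: str, spec: CommunitySpec, rng: np.random.Generator,
            mask: frozenset[int] = frozenset()) -> str:
    return mutate_to_identity(seq, spec.member_seed_identity, rng, mask)


def _rhs_cassette(core_fam: str, toxin_fam: str, assets: CommunityAssets,
                  spec: CommunitySpec, rng: np.random.Generator,
                  with_immunity: bool = True, strand: str = "+",
                  flush_end: bool = False) -> list[_PlannedGene]:
    core_seed = assets.core_seeds[core_fam]
    core = _member(core_seed, spec, rng, _dpxg_mask(len(core_seed)))
    toxin = _member(assets.toxin_seeds[toxin_fam], spec, rng)
    protein = core + toxin
    genes = [_PlannedGene(protein, "rhs_full", f"{core_fam}/{toxin_fam}",
                          "RHS repeat protein",
                          split_pos=len(core) + 1, strand=strand,
                          flush_contig_end=flush_end)]
    if with_immunity:
        imm = _member(assets.immunity_seeds[toxin_fam], spec, rng)
        genes.append(_PlannedGene(imm, "immunity", toxin_fam,
                                  "immunity protein", gap_before=(40, 150),
                                  strand=strand))
    if strand == "-" and len(genes) == 2:
        # immunity 3' of a minus-strand toxin means lower coordinates, so
        # the immunity gene is placed first; the short operonic spacer must
        # still sit BETWEEN the two genes, so the gaps swap too
        genes.reverse()
        genes[0].gap_before, genes[1].gap_before = \
            genes[1].gap_before, genes[0].gap_before
    return genes


def _orphan_cassette(toxin_fam: str, with_fragment: bool,
                     assets: CommunityAssets, spec: CommunitySpec,
                     rng: np.random.Generator) -> list[_PlannedGene]:
    toxin = _member(assets.toxin_seeds[toxin_fam], spec, rng)
    if with_fragment:
        # a short degenerate core remnant, far too little to scan
        # positive or to assign to a core cluster; drawn independently
        # per orphan (decayed remnants diverge fast) so that remnants
        # never create homology edges between unrelated orphans
        toxin = random_protein(rng, 60) + toxin
    imm = _member(assets.immunity_seeds[toxin_fam], spec, rng)
    return [
        _PlannedGene(toxin, "rhs_orphan", toxin_fam, "RHS toxin fragment"),
        _PlannedGene(imm, "immunity", toxin_fam, "immunity protein",
                     gap_before=(40, 150)),
    ]


def _vgrg_cassette(fam: str, mode: str, assets: CommunityAssets,
                   spec: CommunitySpec,
                   rng: np.random.Generator) -> list[_PlannedGene]:
    full = _member(assets.vgrg_seeds[fam], spec, rng)
    if mode == "intact":
        return [_PlannedGene(full, "vgrg", fam, "VgrG protein")]
    if mode == "pseudo":
        frac = rng.uniform(0.30, 0.45)
        truncated = full[:max(BLOCK_WIDTHS["vgrg"] + 20,
                              int(frac * len(full)))]
        return [
            _PlannedGene(truncated, "vgrg_pseudo", fam,
                         "VgrG protein, truncated"),
            _PlannedGene(random_protein(rng, 280), "transposase", None,
                         "IS66 family transposase", gap_before=(80, 150)),
        ]
    if mode == "contig_end":
        truncated = full[:int(rng.uniform(0.55, 0.65) * len(full))]
        return [_PlannedGene(truncated, "vgrg_fragment", fam,
                             "VgrG protein", flush_contig_end=True)]
    raise GenerationError(f"unknown vgrg mode {mode}")


def _t9ss_cassette(toxin_fam: str, assets: CommunityAssets,
                   spec: CommunitySpec,
                   rng: np.random.Generator) -> list[_PlannedGene]:
    head = (mutate_to_identity(assets.blocks["spvb_tcdb"],
                               spec.block_seed_identity, rng)
            + random_protein(rng, 120))
    toxin = _member(assets.toxin_seeds[toxin_fam], spec, rng)
    sorting = (random_protein(rng, 20)
               + mutate_to_identity(assets.blocks["t9ss_sorting"],
                                    spec.block_seed_identity, rng)
               + random_protein(rng, 40))
    imm = _member(assets.immunity_seeds[toxin_fam], spec, rng)
    return [
        _PlannedGene(head + toxin, "t9ss_rhs", toxin_fam,
                     "SpvB-family toxin"),
        _PlannedGene(imm, "immunity", toxin_fam, "immunity protein",
                     gap_before=(40, 150)),
        _PlannedGene(sorting, "t9ss_sorting", None,
                     "type A sorting domain protein", gap_before=(60, 180)),
    ]


def _t5ss_cassette(toxin_fam: str, assets: CommunityAssets,
                   spec: CommunitySpec,
                   rng: np.random.Generator) -> list[_PlannedGene]:
    protein = (mutate_to_identity(assets.blocks["signal_peptide"],
                                  spec.block_seed_identity, rng)
               + random_protein(rng, 10)
               + mutate_to_identity(assets.blocks["hemagglutinin"],
                                    spec.block_seed_identity, rng)
               + random_protein(rng, 150)
               + _member(assets.toxin_seeds[toxin_fam], spec, rng))
    return [_PlannedGene(protein, "t5ss_rhs", toxin_fam,
                         "hemagglutinin repeat protein")]


def _t6ss_cassettes(plan: GenomePlan, assets: CommunityAssets,
                    spec: CommunitySpec,
                    rng: np.random.Generator) -> list[_PlannedGene]:
    ref_set = next(r for r in assets.reference_sets
                   if r.name == plan.t6ss_set)
    genes = []
    names = list(CANONICAL_GENES)
    if plan.t6ss_verdict == "absent":
        return []
    if plan.t6ss_verdict == "incomplete":
        names = [n for n in names if n not in {"tssF", "tssK"}]
    flush_last = plan.t6ss_verdict == "complete_contig_end_exception"
    if flush_last:
        names = names[:-1]  # tssM fell beyond the contig break
    for idx, gname in enumerate(names):
        ref = ref_set.reference_proteins[gname][0]
        protein = mutate_to_identity(ref, 0.75, rng)
        genes.append(_PlannedGene(
            protein, "t6ss_gene", None, f"type VI secretion protein {gname}",
            t6ss_gene=gname, gap_before=(60, 200),
            flush_contig_end=flush_last and idx == len(names) - 1))
    return genes


def _decoy(assets: CommunityAssets, spec: CommunitySpec,
           rng: np.random.Generator,
           representatives: list[tuple[str, str]]) -> str:
    for _ in range(30):
        decoy = random_protein(rng, int(rng.integers(200, 501)))
        ok = True
        for _, rep in representatives:
            r = align_local(decoy, rep)
            if r.aln_columns and identity_short_style(
                    r, len(decoy), len(rep)) > spec.decoy_identity:
                ok = False
                break
        if ok:
            return decoy
    raise GenerationError("could not draw a decoy below the identity ceiling")


def generate_genome(plan: GenomePlan, assets: CommunityAssets,
                    spec: CommunitySpec,
                    rng: np.random.Generator) -> tuple[Genome, list[dict]]:
    """Realize one genome plan as contigs, genes, proteome and truth rows."""
    representatives = assets.family_representatives()

    t6ss_genes = _t6ss_cassettes(plan, assets, spec, rng)
    rhs_cassettes: list[list[_PlannedGene]] = []
    for idx, (core_fam, toxin_fam) in enumerate(plan.full_length):
        rhs_cassettes.append(_rhs_cassette(
            core_fam, toxin_fam, assets, spec, rng,
            strand="-" if idx % 2 else "+"))
    orphan_cassettes = [
        _orphan_cassette(fam, frag, assets, spec, rng)
        for fam, frag in plan.orphans]
    other: list[list[_PlannedGene]] = []
    for fam in plan.immunity_only:
        imm = _member(assets.immunity_seeds[fam], spec, rng)
        other.append([_PlannedGene(imm, "immunity_only", fam,
                                   "immunity protein")])
    for fam in plan.vgrg:
        other.append(_vgrg_cassette(fam, "intact", assets, spec, rng))
    for fam in plan.vgrg_pseudo:
        other.append(_vgrg_cassette(fam, "pseudo", assets, spec, rng))
    for fam in plan.t9ss_rhs:
        other.append(_t9ss_cassette(fam, assets, spec, rng))
    for fam in plan.t5ss_rhs:
        other.append(_t5ss_cassette(fam, assets, spec, rng))
    for _ in range(plan.n_decoys):
        other.append([_PlannedGene(_decoy(assets, spec, rng, representatives),
                                   "decoy", None, "hypothetical protein")])

    # contig 1: general cassettes then the structural locus (so that the
    # contig-end variant can truncate flush with the locus)
    contig1: list[_PlannedGene] = []
    contig2: list[_PlannedGene] = []
    for k, cassette in enumerate(rhs_cassettes):
        contig1.extend(cassette)
        if k < len(orphan_cassettes):
            contig1.extend(orphan_cassettes[k])
    for cassette in orphan_cassettes[len(rhs_cassettes):]:
        contig1.extend(cassette)
    for k, cassette in enumerate(other):
        (contig2 if k % 2 else contig1).extend(cassette)
    contig1.extend(t6ss_genes)

    if plan.vgrg_at_contig_end is not None:
        contig2.extend(_vgrg_cassette(plan.vgrg_at_contig_end, "contig_end",
                                      assets, spec, rng))
    if plan.toxin_at_contig_end is not None:
        core_fam = sorted(assets.core_seeds)[0]
        contig2.extend(_rhs_cassette(core_fam, plan.toxin_at_contig_end,
                                     assets, spec, rng, with_immunity=False,
                                     flush_end=True))

    contigs_plan = [c for c in (contig1, contig2) if c]
    if not contigs_plan:
        contigs_plan = [[_PlannedGene(
            _decoy(assets, spec, rng, representatives), "decoy", None,
            "hypothetical protein")]]

    contig_records: list[ContigRecord] = []
    gene_features: list[GeneFeature] = []
    proteome: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    gene_counter = 0
    for cidx, planned in enumerate(contigs_plan):
        contig_id = f"{plan.genome_id}_c{cidx + 1}"
        pieces: list[str] = []
        cursor = 0
        flush = False
        for pg in planned:
            lo, hi = pg.gap_before
            spacer = int(rng.integers(lo, hi + 1))
            pieces.append(_random_dna(rng, spacer))
            cursor += spacer
            nt = reverse_translate(pg.protein, rng)
            if pg.strand == "-":
                nt = str(Seq(nt).reverse_complement())
            start = cursor + 1
            end = cursor + len(nt)
            pieces.append(nt)
            cursor = end
            gene_counter += 1
            gid = f"{plan.genome_id}_g{gene_counter:04d}"
            pid = f"{plan.genome_id}_p{gene_counter:04d}"
            gene_features.append(GeneFeature(gid, contig_id, start, end,
                                             pg.strand, pg.product, pid))
            proteome.append(ProteinRecord(pid, plan.genome_id, pg.protein,
                                          gid))
            truth_rows.append({
                "genome_id": plan.genome_id, "contig_id": contig_id,
                "gene_id": gid, "protein_id": pid, "kind": pg.kind,
                "family": pg.family, "split_pos": pg.split_pos,
                "t6ss_gene": pg.t6ss_gene,
                "at_contig_end": pg.flush_contig_end,
            })
            flush = pg.flush_contig_end
        if not flush:
            tail = _random_dna(rng, int(rng.integers(100, 301)))
            pieces.append(tail)
            cursor += len(tail)
        contig_records.append(ContigRecord(contig_id, cursor,
                                           "".join(pieces)))

    genome = Genome(plan.genome_id, contig_records, gene_features, proteome,
                    plan.species_label, plan.host_label)
    return genome, truth_rows


# ---------------------------------------------------------------------------
# community-level entry points

_SPECIES = ("S. alvi", "G. apicola", "G. apis", "F. perrara")
_HOSTS = ("A. mellifera", "B. impatiens")


def default_community_spec(seed: int = 0, n_genomes: int = 20,
                           n_toxin_families: int = 6,
                           n_core_families: int = 3,
                           n_vgrg_families: int = 3) -> CommunitySpec:
    """The default study conditions: a 20-genome community with planted
    T6SS verdicts of every class, 6 toxin families, 3 VgrG families,
    displacement signatures, orphan arrays, pseudogenes and decoys."""
    spec = CommunitySpec(seed=seed, n_toxin_families=n_toxin_families,
                         n_core_families=n_core_families,
                         n_vgrg_families=n_vgrg_families)
    T = lambda k: f"T{k % n_toxin_families + 1}"
    C = lambda k: f"C{k % n_core_families + 1}"
    V = lambda k: f"V{k % n_vgrg_families + 1}"
    for i in range(n_genomes):
        if i < max(1, n_genomes - 8):
            verdict, ref = "complete", "canonical_i"
        elif i < n_genomes - 6:
            verdict, ref = "complete_contig_end_exception", "canonical_i"
        elif i < n_genomes - 4:
            verdict, ref = "complete", "subtype_iii"
        elif i < n_genomes - 2:
            verdict, ref = "incomplete", "canonical_i"
        else:
            verdict, ref = "absent", "canonical_i"
        species = ("Apibacter sp." if ref == "subtype_iii"
                   else _SPECIES[i % len(_SPECIES)])
        plan = GenomePlan(
            genome_id=f"sim{i + 1:03d}",
            species_label=species,
            host_label=_HOSTS[i % len(_HOSTS)],
            t6ss_verdict=verdict, t6ss_set=ref,
            full_length=[(C(i), T(i))] + ([(C(i), T(i + 3))]
                                          if i % 2 == 0 else []),
            orphans=[(T(i + 1), False)] + ([(T(i + 4), True)]
                                           if i % 3 == 0 else []),
            immunity_only=[T(i + 2)] if i % 5 == 2 else [],
            toxin_at_contig_end=T(i) if i == 7 else None,
            vgrg=[V(i)] + ([V(i + 1)] if i % 2 else []),
            vgrg_pseudo=[V(i + 2)] if i % 4 == 1 else [],
            vgrg_at_contig_end=V(i) if i in (3, 9) else None,
            n_decoys=3,
        )
        if verdict == "absent" and i == n_genomes - 1:
            plan.vgrg = [V(i)]          # lone satellite, still no T6SS
            plan.full_length = []
            plan.orphans = [(T(i), False), (T(i + 1), False)]
        spec.plans.append(plan)
    return spec


def immunity_demo_spec(seed: int = 0) -> CommunitySpec:
    """A 5-genome, 4-family community for cooccurrence-matrix checks,
    with one orphaned-immunity genome and one toxin-at-contig-end genome."""
    spec = CommunitySpec(seed=seed, n_toxin_families=4, n_core_families=2,
                         n_vgrg_families=1)
    mk = lambda i, **kw: GenomePlan(genome_id=f"imm{i + 1:02d}",
                                    t6ss_verdict="absent", n_decoys=2, **kw)
    spec.plans = [
        mk(0, full_length=[("C1", "T1"), ("C2", "T2")]),
        mk(1, full_length=[("C1", "T3"), ("C2", "T4")]),
        mk(2, immunity_only=["T1"]),                      # orphaned immunity
        mk(3, toxin_at_contig_end="T2"),                  # no immunity gene
        mk(4, full_length=[("C1", "T3"), ("C2", "T3")]),  # two copies
    ]
    return spec


def generate_community(spec: CommunitySpec,
                       verify: bool = True) -> Community:
    """Generate every planned genome plus the ground-truth ledger.

    Fully deterministic for a given spec (the per-genome random stream is
    derived from the spec seed and the genome's index).  With ``verify``,
    the family-separation assumptions are re-measured with the alignment
    oracle and a violation raises :class:`GenerationError`.
    """
    assets = build_assets(spec)
    genomes: list[Genome] = []
    rows: list[dict] = []
    verdict_rows: list[dict] = []
    for idx, plan in enumerate(spec.plans):
        rng = _rng_for(spec.seed, 1000 + idx)
        genome, truth_rows = generate_genome(plan, assets, spec, rng)
        genomes.append(genome)
        rows.extend(truth_rows)
        verdict_rows.append({
            "genome_id": plan.genome_id,
            "intended_verdict": plan.t6ss_verdict,
            "reference_set": plan.t6ss_set,
        })
    truth = pd.DataFrame(rows, columns=[
        "genome_id", "contig_id", "gene_id", "protein_id", "kind", "family",
        "split_pos", "t6ss_gene", "at_contig_end"])
    truth["split_pos"] = truth["split_pos"].astype("Int64")
    community = Community(genomes, truth, pd.DataFrame(verdict_rows),
                          assets, spec)
    if verify:
        verify_separation(community)
    return community


def verify_separation(community: Community) -> dict:
    """Re-measure the planted identity structure with the alignment oracle.

    Checks that pairwise within-family identity (shorter-sequence
    convention) stays at or above the spec floor for toxin and VgrG
    families, that family seeds stay below the between-family ceiling, and
    that decoys stay below their ceiling against every family seed.
    """
    spec = community.spec
    truth = community.truth
    proteins = {p.id: p.sequence for g in community.genomes
                for p in g.proteome}

    def pairwise_floor(seqs: list[str]) -> float:
        worst = 1.0
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                r = align_local(seqs[i], seqs[j])
                ident = (identity_short_style(r, len(seqs[i]), len(seqs[j]))
                         if r.aln_columns else 0.0)
                worst = min(worst, ident)
        return worst

    report = {"within_min": 1.0, "between_max": 0.0, "decoy_max": 0.0}
    # toxin-domain members (extract the planted toxin segment)
    fams: dict[str, list[str]] = {}
    for _, row in truth.iterrows():
        if row["kind"] == "rhs_full":
            fam = row["family"].split("/")[1]
            fams.setdefault(fam, []).append(
                proteins[row["protein_id"]][int(row["split_pos"]) - 1:])
        elif row["kind"] == "rhs_orphan":
            seq = proteins[row["protein_id"]]
            tox_len = len(community.assets.toxin_seeds[row["family"]])
            fams.setdefault(row["family"], []).append(seq[-tox_len:])
        elif row["kind"] in {"vgrg", "vgrg_pseudo", "vgrg_fragment"}:
            fams.setdefault(row["family"], []).append(
                proteins[row["protein_id"]])
    for fam, seqs in sorted(fams.items()):
        report["within_min"] = min(report["within_min"],
                                   pairwise_floor(seqs))
    seeds = {**community.assets.toxin_seeds}
    vseeds = {**community.assets.vgrg_seeds}
    for group in (seeds, vseeds):
        names = sorted(group)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = group[names[i]], group[names[j]]
                r = align_local(a, b)
                ident = (identity_short_style(r, len(a), len(b))
                         if r.aln_columns else 0.0)
                report["between_max"] = max(report["between_max"], ident)
    reps = community.assets.family_representatives()
    decoys = truth[truth["kind"] == "decoy"]["protein_id"]
    for pid in decoys:
        seq = proteins[pid]
        for _, rep in reps:
            r = align_local(seq, rep)
            ident = (identity_short_style(r, len(seq), len(rep))
                     if r.aln_columns else 0.0)
            report["decoy_max"] = max(report["decoy_max"], ident)
    if report["within_min"] < spec.within_identity:
        raise GenerationError(
            f"within-family identity fell to {report['within_min']:.3f}, "
            f"below the {spec.within_identity} floor")
    if report["between_max"] > spec.between_identity:
        raise GenerationError(
            f"between-family identity reached {report['between_max']:.3f}, "
            f"above the {spec.between_identity} ceiling")
    if report["decoy_max"] > spec.decoy_identity:
        raise GenerationError(
            f"decoy identity reached {report['decoy_max']:.3f}, above "
            f"the {spec.decoy_identity} ceiling")
    return report


# ---------------------------------------------------------------------------
# serialization

def write_community(community: Community, outdir: str | Path) -> None:
    """Emit GFF3 + FASTA + protein FASTA per genome, the truth ledger,
    motif seed alignments, structural references and the community spec."""
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "motif_seeds").mkdir(exist_ok=True)
    (outdir / "references").mkdir(exist_ok=True)
    for genome in community.genomes:
        base = outdir / "genomes" / genome.id
        write_gff3_fasta(genome, base.with_suffix(".gff3"),
                         base.with_suffix(".fna"))
        write_proteome_fasta(genome, base.with_suffix(".faa"))
    write_genome_manifest(community.genomes, outdir / "genomes_manifest.tsv")
    community.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    community.genome_truth.to_csv(outdir / "genome_truth.tsv", sep="\t",
                                  index=False)
    motif_config = {}
    for name, seeds in community.assets.motif_seed_alignments.items():
        path = outdir / "motif_seeds" / f"{name}.afa"
        with open(path, "w") as fh:
            for sid, seq in seeds:
                fh.write(f">{sid}\n{seq}\n")
        motif_config[name] = {"path": str(Path("motif_seeds") / f"{name}.afa"),
                              "fpr": 0.001, "n_decoys": 1000}
    with open(outdir / "motif_library.yaml", "w") as fh:
        yaml.safe_dump(motif_config, fh, sort_keys=True)
    sets_meta = []
    for ref_set in community.assets.reference_sets:
        path = outdir / "references" / f"{ref_set.name}.faa"
        with open(path, "w") as fh:
            for gname, seqs in sorted(ref_set.reference_proteins.items()):
                for k, seq in enumerate(seqs):
                    fh.write(f">{gname}|{k}\n{seq}\n")
        sets_meta.append({
            "name": ref_set.name,
            "fasta": str(Path("references") / f"{ref_set.name}.faa"),
            "required_genes": list(ref_set.required_genes),
            "optional_absent": list(ref_set.optional_absent),
        })
    with open(outdir / "references" / "reference_sets.yaml", "w") as fh:
        yaml.safe_dump(sets_meta, fh, sort_keys=False)
    spec_dict = dataclasses.asdict(community.spec)
    with open(outdir / "community.yaml", "w") as fh:
        yaml.safe_dump(spec_dict, fh, sort_keys=False)
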