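"""File-based pipeline stages and the run manifest.

Every stage reads its inputs from, and writes its outputs to, a single run
directory, so stages can be re-run independently and no stage mutates
another stage's files.  The layout is::

    outdir/
      community/           genomes (GFF3+FASTA+protein FASTA), motif seed
                           alignments, structural references, ground truth
      hits.tsv             motif scan results
      motif_thresholds.tsv calibrated bit thresholds
      architectures.tsv    Rhs core/toxin decomposition per protein
      toxin_clusters.tsv / core_clusters.tsv / vgrg_clusters.tsv
      toxin_domains.faa / core_domains.faa
      toxin_homologs.tsv   representative-vs-proteome matches
      vgrg_rows.tsv / vgrg_length_profile.tsv
      t6ss_status.tsv / t6ss_loci.tsv
      pairs.tsv / cooccurrence.tsv
      *.graphml / *.sif    homology and core-toxin networks
      summary.tsv / vgrg_counts.tsv / evaluation.json
      manifest.json        config, seed, versions, file checksums

A rerun with the same seed and config produces byte-identical tables and
manifest (paths in the manifest are relative to the run directory).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .context import (cooccurrence_frame, cooccurrence_matrix, derive_pairs,
                      classify_secretion_context)
from .evaluate import evaluate_recovery
from .genome_io import Genome, read_genome
from .homology import Cluster
from .motifs import DomainHit, load_motif_library
from .networks import (build_core_toxin_network, build_homology_network,
                       per_genome_summary, vgrg_counts_by_cluster,
                       write_graphml, write_sif)
from .rhs import (RhsArchitecture, cluster_domains, core_toxin_pairs,
                  recover_orphans, split_all)
from .simulate import (Community, CommunitySpec, default_community_spec,
                       generate_community, write_community)
from .t6ss import StructuralReferenceSet, inventory_genome
from .vgrg import VgrgProfileRow, find_and_cluster_vgrg, vgrg_length_profile
from .context import ToxinImmunityPair

logger = logging.getLogger(__name__)

__all__ = ["run_all", "stage_simulate", "stage_scan", "stage_cluster",
           "stage_t6ss", "stage_immunity", "stage_network", "stage_report",
           "write_manifest", "load_community_genomes"]

STAGES = ("simulate", "scan", "cluster", "t6ss", "immunity", "network",
          "report")


class StageError(RuntimeError):
    """A stage's declared inputs are missing."""


def _require(outdir: Path, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise StageError(f"missing input {name}; run the earlier "
                             "stage first")


# ---------------------------------------------------------------------------
# shared loaders

def load_community_genomes(community_dir: str | Path) -> list[Genome]:
    """Read every genome in a community directory (GFF3 + FASTA + proteins)."""
    community_dir = Path(community_dir)
    labels: dict[str, tuple[str, str]] = {}
    manifest = community_dir / "genomes_manifest.tsv"
    if manifest.exists():
        df = pd.read_csv(manifest, sep="\t",
                         dtype=str, keep_default_na=False)
        labels = {r["genome_id"]: (r["species_label"], r["host_label"])
                  for _, r in df.iterrows()}
    genomes = []
    for gff in sorted((community_dir / "genomes").glob("*.gff3")):
        gid = gff.stem
        species, host = labels.get(gid, ("", ""))
        genomes.append(read_genome(
            gff, "gff3", fasta=gff.with_suffix(".fna"),
            protein_fasta=gff.with_suffix(".faa"), genome_id=gid,
            species_label=species, host_label=host))
    if not genomes:
        raise StageError(f"no genomes under {community_dir}")
    return genomes


def _load_hits(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "hits.tsv", sep="\t")


def _load_fasta_pairs(path: Path) -> dict[str, str]:
    from Bio import SeqIO
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def _load_clusters(path: Path, kind: str) -> list[Cluster]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for cid, group in df.groupby("cluster_id", sort=True):
        members = sorted(group["member_id"])
        rep = group["representative_id"].iloc[0]
        out.append(Cluster(cid, members, rep, kind))
    return out


def _load_architectures(outdir: Path) -> dict[str, RhsArchitecture]:
    df = pd.read_csv(outdir / "architectures.tsv", sep="\t")
    out = {}
    for _, r in df.iterrows():
        def span(a, b):
            return ((int(r[a]), int(r[b]))
                    if pd.notna(r[a]) and pd.notna(r[b]) else None)
        out[r["protein_id"]] = RhsArchitecture(
            r["protein_id"], r["genome_id"], r["status"],
            int(r["protein_len"]), span("core_start", "core_end"),
            span("toxin_start", "toxin_end"),
            r["core_cluster"] if pd.notna(r["core_cluster"]) else None,
            r["toxin_cluster"] if pd.notna(r["toxin_cluster"]) else None,
            r["n_terminal_class"], bool(r["ambiguous_split"]))
    return out


def _load_vgrg_rows(outdir: Path) -> list[VgrgProfileRow]:
    df = pd.read_csv(outdir / "vgrg_rows.tsv", sep="\t")
    return [VgrgProfileRow(
        r["protein_id"], r["genome_id"], r["cluster_id"], int(r["length"]),
        bool(r["at_contig_end"]), bool(r["is_member"]),
        float(r["identity_to_representative"]), bool(r["truncated_flag"]),
        float(r["length_fraction_of_cluster_max"]),
        bool(r["mobile_element_context"])) for _, r in df.iterrows()]


def _load_reference_sets(community_dir: Path) -> list[StructuralReferenceSet]:
    meta_path = community_dir / "references" / "reference_sets.yaml"
    if not meta_path.exists():
        raise StageError(f"missing {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    sets = []
    for entry in meta:
        seqs = _load_fasta_pairs(community_dir / entry["fasta"])
        refs: dict[str, list[str]] = {}
        for header, seq in sorted(seqs.items()):
            gname = header.split("|")[0]
            refs.setdefault(gname, []).append(seq)
        sets.append(StructuralReferenceSet(
            entry["name"], tuple(entry["required_genes"]),
            tuple(entry["optional_absent"]), refs))
    return sets


# ---------------------------------------------------------------------------
# stages

def stage_simulate(outdir: str | Path, cfg: RunConfig,
                   spec: CommunitySpec | None = None) -> Community:
    """Generate the synthetic community into ``outdir/community``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = default_community_spec(seed=cfg.seed)
    community = generate_community(spec)
    write_community(community, outdir / "community")
    return community


def stage_scan(outdir: str | Path, cfg: RunConfig) -> pd.DataFrame:
    """Scan every protein with every calibrated motif model."""
    outdir = Path(outdir)
    cdir = outdir / "community"
    _require(outdir, "community/motif_library.yaml")
    genomes = load_community_genomes(cdir)
    with open(cdir / "motif_library.yaml") as fh:
        motif_cfg = yaml.safe_load(fh)
    for entry in motif_cfg.values():
        entry.setdefault("fpr", cfg.motif_fpr)
        entry.setdefault("n_decoys", cfg.motif_n_decoys)
    library = load_motif_library(motif_cfg, base_dir=cdir, seed=cfg.seed)
    records = []
    for g in genomes:
        for p in g.proteome:
            for name in sorted(library):
                from .motifs import scan_protein
                for h in scan_protein(library[name], p):
                    records.append({
                        "protein_id": p.id, "genome_id": g.id,
                        "motif": name, "start": h.start, "end": h.end,
                        "bits": round(h.score, 3)})
    hits = pd.DataFrame(records, columns=["protein_id", "genome_id",
                                          "motif", "start", "end", "bits"])
    hits = hits.sort_values(["genome_id", "protein_id", "motif",
                             "start"]).reset_index(drop=True)
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    thr = pd.DataFrame([{
        "motif": name, "width": m.width,
        "bit_threshold": round(m.bit_threshold, 3),
        "calibration": (m.calibration or {}).get("method", "none"),
        "n_decoys": (m.calibration or {}).get("n_decoys", 0),
        "decoy_firing": (m.calibration or {}).get("decoy_firing", 0),
    } for name, m in sorted(library.items())])
    thr.to_csv(outdir / "motif_thresholds.tsv", sep="\t", index=False)
    return hits


def _write_clusters(clusters: list[Cluster], path: Path) -> None:
    rows = [{"cluster_id": c.cluster_id, "kind": c.kind,
             "representative_id": c.representative_id, "member_id": m}
            for c in clusters for m in sorted(c.member_ids)]
    pd.DataFrame(rows, columns=["cluster_id", "kind", "representative_id",
                                "member_id"]).to_csv(path, sep="\t",
                                                     index=False)


def _write_fasta(pairs: list[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in sorted(pairs):
            fh.write(f">{pid}\n{seq}\n")


def stage_cluster(outdir: str | Path, cfg: RunConfig) -> None:
    """Split Rhs proteins, cluster domains, recover orphans, profile VgrG."""
    outdir = Path(outdir)
    _require(outdir, "hits.tsv")
    genomes = load_community_genomes(outdir / "community")
    proteins = [p for g in genomes for p in g.proteome]
    by_id = {p.id: p for p in proteins}
    hits = _load_hits(outdir)

    core_hits: dict[str, DomainHit] = {}
    for _, r in hits[hits["motif"] == "rhs_core"].iterrows():
        h = DomainHit(r["protein_id"], "rhs_core", int(r["start"]),
                      int(r["end"]), float(r["bits"]))
        cur = core_hits.get(h.protein_id)
        if cur is None or h.score > cur.score:
            core_hits[h.protein_id] = h

    split = split_all(proteins, core_hits, window=cfg.dpxg_window,
                      min_toxin_len=cfg.min_toxin_len)
    toxin_seqs = [(f"{pid}|toxin", s) for pid, s in split.toxin_seqs]
    core_seqs = [(f"{pid}|core", s) for pid, s in split.core_seqs]
    toxin_clusters, core_clusters, unassigned = cluster_domains(
        toxin_seqs, core_seqs, threshold=cfg.cluster_identity,
        min_core_len=cfg.core_min_len)
    toxin_seq_map = dict(toxin_seqs)
    matches, architectures = recover_orphans(
        toxin_clusters, toxin_seq_map, proteins, split, core_clusters,
        min_identity=cfg.toxin_min_identity,
        min_aln_len=cfg.toxin_min_aln_len)

    # secretion context from N-terminal motifs and gene neighbourhood
    hits_by_protein: dict[str, list[DomainHit]] = {}
    for _, r in hits.iterrows():
        hits_by_protein.setdefault(r["protein_id"], []).append(
            DomainHit(r["protein_id"], r["motif"], int(r["start"]),
                      int(r["end"]), float(r["bits"])))
    genome_by_id = {g.id: g for g in genomes}
    for pid, arch in architectures.items():
        arch.n_terminal_class = classify_secretion_context(
            by_id[pid], hits_by_protein, genome_by_id[arch.genome_id], arch)

    _write_clusters(toxin_clusters, outdir / "toxin_clusters.tsv")
    _write_clusters(core_clusters, outdir / "core_clusters.tsv")
    _write_fasta(toxin_seqs, outdir / "toxin_domains.faa")
    _write_fasta(core_seqs, outdir / "core_domains.faa")
    homolog_cols = ["representative_id", "subject_id", "pct_identity",
                    "aln_len", "subject_cov"]
    pd.DataFrame([{
        "representative_id": m.representative_id,
        "subject_id": m.subject_id,
        "pct_identity": round(100 * m.identity_fraction, 2),
        "aln_len": m.aln_len,
        "subject_cov": round(m.subject_coverage, 4),
    } for m in matches], columns=homolog_cols).sort_values(
        ["representative_id", "subject_id"]).to_csv(
        outdir / "toxin_homologs.tsv", sep="\t", index=False)

    arch_rows = []
    for pid, a in sorted(architectures.items()):
        arch_rows.append({
            "protein_id": pid, "genome_id": a.genome_id,
            "status": a.status, "protein_len": a.protein_len,
            "core_start": a.core_span[0] if a.core_span else pd.NA,
            "core_end": a.core_span[1] if a.core_span else pd.NA,
            "toxin_start": a.toxin_span[0] if a.toxin_span else pd.NA,
            "toxin_end": a.toxin_span[1] if a.toxin_span else pd.NA,
            "core_cluster": a.core_cluster or pd.NA,
            "toxin_cluster": a.toxin_cluster or pd.NA,
            "n_terminal_class": a.n_terminal_class,
            "ambiguous_split": a.ambiguous_split,
        })
    pd.DataFrame(arch_rows, columns=[
        "protein_id", "genome_id", "status", "protein_len", "core_start",
        "core_end", "toxin_start", "toxin_end", "core_cluster",
        "toxin_cluster", "n_terminal_class", "ambiguous_split",
    ]).to_csv(outdir / "architectures.tsv", sep="\t", index=False)

    # VgrG: reuse the scan's motif-positive set
    vgrg_ids = set(hits.loc[hits["motif"] == "vgrg", "protein_id"])
    result = find_and_cluster_vgrg(
        genomes, motif_positive_ids=vgrg_ids,
        threshold=cfg.cluster_identity,
        min_cluster_len=cfg.vgrg_min_member_len,
        min_aln_len=cfg.vgrg_min_aln_len,
        min_identity=cfg.toxin_min_identity,
        contig_end_margin=cfg.contig_end_margin)
    from .vgrg import flag_truncations
    flag_truncations(result.rows, cfg.truncation_fraction)
    _write_clusters(result.clusters, outdir / "vgrg_clusters.tsv")
    pd.DataFrame([{
        "protein_id": r.protein_id, "genome_id": r.genome_id,
        "cluster_id": r.cluster_id, "length": r.length,
        "at_contig_end": r.at_contig_end, "is_member": r.is_member,
        "identity_to_representative":
            round(r.identity_to_representative, 4),
        "truncated_flag": r.truncated_flag,
        "length_fraction_of_cluster_max":
            round(r.length_fraction_of_cluster_max, 4),
        "mobile_element_context": r.mobile_element_context,
    } for r in sorted(result.rows, key=lambda r: r.protein_id)],
        columns=["protein_id", "genome_id", "cluster_id", "length",
                 "at_contig_end", "is_member", "identity_to_representative",
                 "truncated_flag", "length_fraction_of_cluster_max",
                 "mobile_element_context"]).to_csv(
        outdir / "vgrg_rows.tsv", sep="\t", index=False)
    vgrg_length_profile(result.rows).to_csv(
        outdir / "vgrg_length_profile.tsv", sep="\t", index=False)


def stage_t6ss(outdir: str | Path, cfg: RunConfig) -> None:
    """Classify T6SS completeness per genome under every reference set."""
    outdir = Path(outdir)
    genomes = load_community_genomes(outdir / "community")
    ref_sets = _load_reference_sets(outdir / "community")
    status_rows, locus_rows = [], []
    for g in genomes:
        best, calls = inventory_genome(
            g, ref_sets, cfg.t6ss_min_identity, cfg.t6ss_min_coverage,
            cfg.locus_max_gap, cfg.contig_end_margin)
        for name, call in sorted(calls.items()):
            status_rows.append({
                "genome_id": g.id, "reference_set": name,
                "verdict": call.verdict,
                "missing_genes": ",".join(call.missing_genes),
                "n_structural_hits": sum(len(v)
                                         for v in call.gene_hits.values()),
                "best": name == best.reference_set,
            })
            for locus in call.locus_spans:
                locus_rows.append({
                    "genome_id": g.id, "reference_set": name,
                    "contig_id": locus.contig_id, "start": locus.start,
                    "end": locus.end, "n_genes": len(locus.gene_ids),
                    "satellite": locus.satellite,
                    "genes": ",".join(locus.structural_genes),
                })
    pd.DataFrame(status_rows).to_csv(outdir / "t6ss_status.tsv", sep="\t",
                                     index=False)
    pd.DataFrame(locus_rows, columns=[
        "genome_id", "reference_set", "contig_id", "start", "end",
        "n_genes", "satellite", "genes"]).to_csv(
        outdir / "t6ss_loci.tsv", sep="\t", index=False)


def stage_immunity(outdir: str | Path, cfg: RunConfig) -> None:
    """Derive toxin/immunity pairs and the cooccurrence matrix."""
    outdir = Path(outdir)
    _require(outdir, "toxin_clusters.tsv", "toxin_domains.faa")
    genomes = load_community_genomes(outdir / "community")
    toxin_clusters = _load_clusters(outdir / "toxin_clusters.tsv",
                                    "toxin_domain")
    toxin_seq_map = _load_fasta_pairs(outdir / "toxin_domains.faa")
    pairs = derive_pairs(toxin_clusters, toxin_seq_map, genomes,
                         max_intergenic=cfg.max_intergenic,
                         require_same_strand=cfg.require_same_strand)
    pd.DataFrame([{
        "pair_id": p.pair_id, "source_genome": p.source_genome,
        "source_toxin_gene": p.source_toxin_gene,
        "source_immunity_gene": p.source_immunity_gene,
        "toxin_representative": p.toxin_representative,
        "immunity_representative": p.immunity_representative,
    } for p in pairs], columns=[
        "pair_id", "source_genome", "source_toxin_gene",
        "source_immunity_gene", "toxin_representative",
        "immunity_representative"]).to_csv(outdir / "pairs.tsv", sep="\t",
                                           index=False)
    cells = cooccurrence_matrix(pairs, genomes,
                                min_identity=cfg.immunity_min_identity,
                                min_reference_coverage=
                                cfg.immunity_min_ref_coverage,
                                max_intergenic=cfg.max_intergenic)
    cooccurrence_frame(cells).to_csv(outdir / "cooccurrence.tsv", sep="\t",
                                     index=False)


def stage_network(outdir: str | Path, cfg: RunConfig) -> None:
    """Export homology networks and the core-toxin bipartite graph."""
    outdir = Path(outdir)
    _require(outdir, "architectures.tsv", "vgrg_rows.tsv",
             "toxin_clusters.tsv", "core_clusters.tsv")
    genomes = load_community_genomes(outdir / "community")
    by_id = {p.id: p for g in genomes for p in g.proteome}
    meta = {p.id: g for g in genomes for p in g.proteome}
    architectures = _load_architectures(outdir)
    vgrg_rows = _load_vgrg_rows(outdir)

    # nodes carry the extracted toxin-domain sequence where a split
    # exists; whole proteins would edge through shared core domains and
    # blur family structure, which is why toxin domains are analysed
    # separately in the first place
    def toxin_node_seq(pid: str) -> str:
        a = architectures[pid]
        if a.toxin_span is not None:
            return by_id[pid].sequence[a.toxin_span[0] - 1:a.toxin_span[1]]
        return by_id[pid].sequence

    toxin_nodes = [(pid, toxin_node_seq(pid))
                   for pid, a in sorted(architectures.items())
                   if a.toxin_cluster is not None]
    attrs = {pid: {"species_label": meta[pid].species_label,
                   "host_label": meta[pid].host_label,
                   "cluster_id": architectures[pid].toxin_cluster or ""}
             for pid, _ in toxin_nodes}
    toxin_net = build_homology_network(
        toxin_nodes, rule="min_aln_len_90",
        min_identity=cfg.toxin_min_identity,
        min_aln_len=cfg.toxin_min_aln_len, node_attrs=attrs)
    write_graphml(toxin_net, outdir / "toxin_network.graphml")
    write_sif(toxin_net, outdir / "toxin_network.sif")

    member_rows = [r for r in vgrg_rows if r.is_member]
    vgrg_nodes = [(r.protein_id, by_id[r.protein_id].sequence)
                  for r in sorted(member_rows, key=lambda r: r.protein_id)]
    vattrs = {r.protein_id: {"species_label": meta[r.protein_id].species_label,
                             "host_label": meta[r.protein_id].host_label,
                             "cluster_id": r.cluster_id}
              for r in member_rows}
    vgrg_net = build_homology_network(
        vgrg_nodes, rule="min_cov_0.9",
        min_identity=cfg.toxin_min_identity,
        min_coverage=0.90, node_attrs=vattrs)
    write_graphml(vgrg_net, outdir / "vgrg_network.graphml")
    write_sif(vgrg_net, outdir / "vgrg_network.sif")

    toxin_clusters = _load_clusters(outdir / "toxin_clusters.tsv",
                                    "toxin_domain")
    core_clusters = _load_clusters(outdir / "core_clusters.tsv",
                                   "core_domain")
    toxin_sizes = {c.cluster_id: sum(
        1 for a in architectures.values() if a.toxin_cluster == c.cluster_id)
        for c in toxin_clusters}
    core_sizes = {c.cluster_id: len(c.member_ids) for c in core_clusters}
    pairs = core_toxin_pairs(architectures)
    ct = build_core_toxin_network(pairs, core_sizes, toxin_sizes)
    write_graphml(ct, outdir / "core_toxin_network.graphml")


def stage_report(outdir: str | Path, cfg: RunConfig) -> pd.DataFrame:
    """Per-genome summary tables and, when ground truth exists, recovery
    metrics."""
    outdir = Path(outdir)
    _require(outdir, "architectures.tsv", "vgrg_rows.tsv", "t6ss_status.tsv")
    genomes = load_community_genomes(outdir / "community")
    architectures = _load_architectures(outdir)
    vgrg_rows = _load_vgrg_rows(outdir)
    status = pd.read_csv(outdir / "t6ss_status.tsv", sep="\t")
    best = status[status["best"]]
    verdicts = dict(zip(best["genome_id"], best["verdict"]))
    summary = per_genome_summary(genomes, architectures, vgrg_rows, verdicts)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    vgrg_counts_by_cluster(genomes, vgrg_rows).to_csv(
        outdir / "vgrg_counts.tsv", sep="\t", index=False)

    truth_path = outdir / "community" / "truth.tsv"
    gt_path = outdir / "community" / "genome_truth.tsv"
    if truth_path.exists() and gt_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        genome_truth = pd.read_csv(gt_path, sep="\t")
        metrics = evaluate_recovery(truth, genome_truth, architectures,
                                    vgrg_rows, verdicts)
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# manifest and the full run

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, cfg: RunConfig) -> dict:
    """Checksums of every run file, plus config, seed and versions."""
    import Bio
    import networkx
    import numpy
    outdir = Path(outdir)
    files = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            files[path.relative_to(outdir).as_posix()] = _sha256(path)
    manifest = {
        "config": cfg.as_dict(),
        "seed": cfg.seed,
        "versions": {
            "effectornet": __version__,
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
            "biopython": Bio.__version__,
        },
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_all(outdir: str | Path, cfg: RunConfig | None = None,
            spec: CommunitySpec | None = None,
            simulate: bool = True) -> dict:
    """Run every stage in dependency order and write the manifest.

    With ``simulate`` false, ``outdir/community`` must already hold a
    community (genomes, motif seeds, references).
    """
    cfg = cfg or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if simulate:
        stage_simulate(outdir, cfg, spec)
    stage_scan(outdir, cfg)
    stage_cluster(outdir, cfg)
    stage_t6ss(outdir, cfg)
    stage_immunity(outdir, cfg)
    stage_network(outdir, cfg)
    stage_report(outdir, cfg)
    return write_manifest(outdir, cfg)
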