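"""Uniform in-memory genome model and positional queries.

Annotated genomes come in as GenBank flat files or paired GFF3 + nucleotide
FASTA; both are normalized into :class:`Genome`, which holds contigs, ordered
gene features and the translated proteome.  Coordinates are 1-based inclusive
throughout (GenBank convention); GFF3 input/output needs no conversion since
GFF3 prints the same convention.

Positional helpers answer the two questions the downstream analyses keep
asking: is a gene close enough to a contig end that absence of its neighbour
may be an assembly artifact, and what lies immediately downstream of a gene's
3' end (where cognate immunity genes live).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "ContigRecord",
    "GeneFeature",
    "ProteinRecord",
    "Genome",
    "read_genome",
    "write_gff3_fasta",
    "write_proteome_fasta",
    "write_genome_manifest",
    "feature_at_contig_end",
    "downstream_neighbors",
    "intergenic_gap",
]

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class GenomeInputError(OSError):
    """Unreadable or malformed genome input."""


class EmptyGenomeError(ValueError):
    """A genome with zero contigs."""


class GenomeValidationError(ValueError):
    """A feature violates the genome's coordinate invariants."""


class UnknownGeneError(KeyError):
    """A gene id that does not resolve within the genome."""


@dataclass
class ContigRecord:
    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise GenomeValidationError(f"contig {self.id}: length < 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise GenomeValidationError(
                f"contig {self.id}: length {self.length} != sequence "
                f"length {len(self.sequence)}")


@dataclass
class GeneFeature:
    id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    product: str | None = None
    protein_id: str | None = None
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise GenomeValidationError(
                f"gene {self.id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in {"+", "-"}:
            raise GenomeValidationError(
                f"gene {self.id}: strand must be '+' or '-'")


@dataclass
class ProteinRecord:
    id: str
    genome_id: str
    sequence: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeValidationError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence.upper()) - _VALID_AA
        if bad:
            raise GenomeValidationError(
                f"protein {self.id}: invalid residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    id: str
    contigs: list[ContigRecord]
    genes: list[GeneFeature]
    proteome: list[ProteinRecord]
    species_label: str = ""
    host_label: str = ""
    _gene_index: dict[str, GeneFeature] = field(
        init=False, repr=False, default_factory=dict)
    _contig_index: dict[str, ContigRecord] = field(
        init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise EmptyGenomeError(f"genome {self.id} has zero contigs")
        self._contig_index = {c.id: c for c in self.contigs}
        order = {c.id: i for i, c in enumerate(self.contigs)}
        self.genes = sorted(
            self.genes, key=lambda g: (order[g.contig_id], g.start)
            if g.contig_id in order else (len(order), g.start))
        for g in self.genes:
            contig = self._contig_index.get(g.contig_id)
            if contig is None:
                raise GenomeValidationError(
                    f"gene {g.id}: unknown contig {g.contig_id}")
            if g.end > contig.length:
                raise GenomeValidationError(
                    f"gene {g.id}: end {g.end} beyond contig "
                    f"{contig.id} length {contig.length}")
        self._gene_index = {g.id: g for g in self.genes}
        gene_ids = set(self._gene_index)
        for p in self.proteome:
            if p.gene_id is not None and p.gene_id not in gene_ids:
                raise GenomeValidationError(
                    f"protein {p.id}: unknown gene {p.gene_id}")

    def contig(self, contig_id: str) -> ContigRecord:
        try:
            return self._contig_index[contig_id]
        except KeyError:
            raise UnknownGeneError(f"unknown contig {contig_id}") from None

    def gene(self, gene_id: str) -> GeneFeature:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise UnknownGeneError(f"unknown gene {gene_id}") from None

    def genes_on(self, contig_id: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.contig_id == contig_id]

    def protein_for_gene(self, gene_id: str) -> ProteinRecord | None:
        for p in self.proteome:
            if p.gene_id == gene_id:
                return p
        return None


def _translate_cds(nt: str, gene_id: str) -> str | None:
    """Translate a CDS (table 11); returns None on internal stops/partials."""
    seq = Seq(nt)
    if len(seq) % 3:
        logger.warning("gene %s: CDS length not a multiple of 3; skipped",
                       gene_id)
        return None
    aa = str(seq.translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        logger.warning("gene %s: internal stop in translation; skipped",
                       gene_id)
        return None
    if not aa:
        return None
    return aa.replace("J", "X").replace("B", "X").replace("Z", "X")


def _clean_protein(aa: str, source: str) -> str | None:
    aa = aa.upper().rstrip("*")
    if "*" in aa:
        logger.warning("%s: internal stop in translation; skipped", source)
        return None
    if not aa:
        return None
    return "".join(c if c in _VALID_AA else "X" for c in aa)


def _read_genbank(path: Path, genome_id: str, species_label: str,
                  host_label: str) -> Genome:
    contigs: list[ContigRecord] = []
    genes: list[GeneFeature] = []
    proteome: list[ProteinRecord] = []
    seen_proteins: set[str] = set()
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq)
        contigs.append(ContigRecord(rec.id, len(seq), seq))
        n_cds = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n_cds += 1
            q = feat.qualifiers
            gid = q.get("locus_tag", q.get("gene", [f"cds{n_cds}"]))[0]
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            pseudo = "pseudo" in q or "pseudogene" in q
            product = q.get("product", [None])[0]
            protein_id = q.get("protein_id", [None])[0]
            genes.append(GeneFeature(gid, rec.id, start, end, strand,
                                     product, protein_id, pseudo))
            if pseudo:
                continue
            if "translation" in q:
                aa = _clean_protein(q["translation"][0], f"gene {gid}")
            else:
                aa = _translate_cds(str(feat.extract(rec.seq)), gid)
            if aa is None:
                continue
            pid = protein_id or gid
            if pid in seen_proteins:
                continue
            seen_proteins.add(pid)
            proteome.append(ProteinRecord(pid, genome_id, aa, gid))
    if not contigs:
        raise EmptyGenomeError(f"no contigs parsed from {path}")
    return Genome(genome_id, contigs, genes, proteome,
                  species_label, host_label)


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        out[key.strip()] = val.strip()
    return out


def _read_gff3_fasta(gff_path: Path, fasta_path: Path,
                     protein_fasta: Path | None, genome_id: str,
                     species_label: str, host_label: str) -> Genome:
    import gffutils

    contigs: list[ContigRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        contigs.append(ContigRecord(rec.id, len(seq), seq))
    if not contigs:
        raise EmptyGenomeError(f"no contigs parsed from {fasta_path}")
    contig_seq = {c.id: c.sequence for c in contigs}

    external: dict[str, str] = {}
    if protein_fasta is not None:
        for rec in SeqIO.parse(str(protein_fasta), "fasta"):
            external[rec.id] = str(rec.seq).upper()

    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneFeature] = []
    proteome: list[ProteinRecord] = []
    seen_proteins: set[str] = set()
    for i, feat in enumerate(db.features_of_type("CDS", order_by=("seqid", "start"))):
        gid = feat.attributes.get("ID", [f"cds{i + 1}"])[0]
        product = feat.attributes.get("product", [None])[0]
        protein_id = feat.attributes.get("protein_id", [None])[0]
        pseudo = feat.attributes.get("pseudo", ["false"])[0].lower() == "true"
        strand = "-" if feat.strand == "-" else "+"
        genes.append(GeneFeature(gid, feat.seqid, feat.start, feat.end,
                                 strand, product, protein_id, pseudo))
        if pseudo:
            continue
        pid = protein_id or gid
        if pid in external:
            aa = _clean_protein(external[pid], f"gene {gid}")
        else:
            if feat.seqid not in contig_seq:
                raise GenomeValidationError(
                    f"gene {gid}: unknown contig {feat.seqid}")
            nt = contig_seq[feat.seqid][feat.start - 1:feat.end]
            if strand == "-":
                nt = str(Seq(nt).reverse_complement())
            aa = _translate_cds(nt, gid)
        if aa is None or pid in seen_proteins:
            continue
        seen_proteins.add(pid)
        proteome.append(ProteinRecord(pid, genome_id, aa, gid))
    return Genome(genome_id, contigs, genes, proteome,
                  species_label, host_label)


def read_genome(path: str | Path, format: str = "auto",
                fasta: str | Path | None = None,
                protein_fasta: str | Path | None = None,
                genome_id: str | None = None,
                species_label: str = "", host_label: str = "") -> Genome:
    """Parse one annotated genome into the uniform model.

    ``format`` is ``genbank``, ``gff3`` (requires ``fasta``) or ``auto``
    (by extension).  CDS features without a usable translation are skipped
    with a logged warning; proteins are deduplicated by id.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeInputError(f"no such file: {path}")
    if format == "auto":
        format = ("gff3" if path.suffix.lower() in {".gff", ".gff3"}
                  else "genbank")
    if genome_id is None:
        genome_id = path.stem
    if format == "genbank":
        return _read_genbank(path, genome_id, species_label, host_label)
    if format == "gff3":
        if fasta is None:
            for ext in (".fna", ".fa", ".fasta"):
                cand = path.with_suffix(ext)
                if cand.exists():
                    fasta = cand
                    break
        if fasta is None or not Path(fasta).exists():
            raise GenomeInputError(
                f"gff3 input {path} needs a nucleotide FASTA")
        return _read_gff3_fasta(path, Path(fasta),
                                Path(protein_fasta) if protein_fasta else None,
                                genome_id, species_label, host_label)
    raise GenomeInputError(f"unknown format {format!r}")


def write_gff3_fasta(genome: Genome, gff_path: str | Path,
                     fasta_path: str | Path) -> None:
    """Serialize a genome as GFF3 (CDS features) plus nucleotide FASTA."""
    lines = ["##gff-version 3"]
    for c in genome.contigs:
        lines.append(f"##sequence-region {c.id} 1 {c.length}")
    for g in genome.genes:
        attrs = [f"ID={g.id}"]
        if g.product:
            attrs.append(f"product={g.product}")
        if g.protein_id:
            attrs.append(f"protein_id={g.protein_id}")
        if g.pseudo:
            attrs.append("pseudo=true")
        lines.append("\t".join([
            g.contig_id, "effectornet", "CDS", str(g.start), str(g.end),
            ".", g.strand, "0", ";".join(attrs)]))
    Path(gff_path).write_text("\n".join(lines) + "\n")
    with open(fasta_path, "w") as fh:
        for c in genome.contigs:
            if c.sequence is None:
                raise GenomeValidationError(
                    f"contig {c.id} has no sequence to write")
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i:i + 70] + "\n")


def write_proteome_fasta(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in genome.proteome:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i:i + 70] + "\n")


def write_genome_manifest(genomes: list[Genome], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tspecies_label\thost_label\tn_contigs\tn_genes\n")
        for g in genomes:
            fh.write(f"{g.id}\t{g.species_label}\t{g.host_label}\t"
                     f"{len(g.contigs)}\t{len(g.genes)}\n")


def feature_at_contig_end(genome: Genome, gene: GeneFeature | str,
                          margin: int = 0) -> bool:
    """True when the gene starts within ``margin`` bp of the contig start or
    ends within ``margin`` bp of the contig end."""
    if isinstance(gene, str):
        gene = genome.gene(gene)
    elif gene.id not in genome._gene_index:
        raise UnknownGeneError(f"unknown gene {gene.id}")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    contig = genome.contig(gene.contig_id)
    return gene.start <= margin or (contig.length - gene.end) <= margin


def downstream_neighbors(genome: Genome, gene: GeneFeature | str,
                         k: int = 1) -> list[GeneFeature]:
    """Up to ``k`` genes 3' of ``gene`` on its contig, nearest first.

    Downstream follows the coding strand: increasing coordinates for '+'
    genes, decreasing for '-' genes.  Fewer than ``k`` genes are returned
    at contig ends.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(gene, str):
        gene = genome.gene(gene)
    elif gene.id not in genome._gene_index:
        raise UnknownGeneError(f"unknown gene {gene.id}")
    on_contig = genome.genes_on(gene.contig_id)
    if gene.strand == "+":
        later = [g for g in on_contig if g.start > gene.end]
        later.sort(key=lambda g: g.start)
        return later[:k]
    earlier = [g for g in on_contig if g.end < gene.start]
    earlier.sort(key=lambda g: -g.end)
    return earlier[:k]


def intergenic_gap(a: GeneFeature, b: GeneFeature) -> int:
    """Number of bases strictly between two non-overlapping genes."""
    if a.end < b.start:
        return b.start - a.end - 1
    if b.end < a.start:
        return a.start - b.end - 1
    return 0
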