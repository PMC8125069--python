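"""T6SS structural detection and the completeness rules."""

import numpy as np
import pytest

from effectornet.genome_io import ContigRecord, GeneFeature, Genome, \
    ProteinRecord
from effectornet.simulate import mutate_to_identity, random_protein
from effectornet.t6ss import (CANONICAL_GENES, LocusSpan,
                              StructuralReferenceSet, StructuralHit,
                              call_loci, classify_completeness,
                              detect_structural_hits, inventory_genome)


@pytest.fixture(scope="module")
def reference_set():
    rng = np.random.default_rng(0)
    refs = {g: [random_protein(rng, int(rng.integers(250, 450)))]
            for g in CANONICAL_GENES}
    return StructuralReferenceSet("canonical_i", CANONICAL_GENES, (), refs)


def _locus_genome(reference_set, genes_present, flush_end=False,
                  rng_seed=1, extra=()):
    """A one-contig genome carrying mutated copies of the given structural
    genes in order, optionally truncated flush with the contig end."""
    rng = np.random.default_rng(rng_seed)
    feats, prots = [], []
    cursor = 0
    for i, gname in enumerate(genes_present):
        protein = mutate_to_identity(
            reference_set.reference_proteins[gname][0], 0.75, rng)
        nt_len = 3 * (len(protein) + 1)
        start = cursor + 151
        end = start + nt_len - 1
        cursor = end
        feats.append(GeneFeature(f"g{i + 1}", "c1", start, end, "+"))
        prots.append(ProteinRecord(f"p{i + 1}", "G", protein, f"g{i + 1}"))
    for j, protein in enumerate(extra):
        start = cursor + 20_001
        end = start + 3 * (len(protein) + 1) - 1
        cursor = end
        feats.append(GeneFeature(f"x{j + 1}", "c1", start, end, "+"))
        prots.append(ProteinRecord(f"px{j + 1}", "G", protein, f"x{j + 1}"))
    length = cursor if flush_end and not extra else cursor + 500
    contig = ContigRecord("c1", length)
    return Genome("G", [contig], feats, prots)


class TestReferenceSet:
    def test_required_and_optional_must_be_disjoint(self):
        with pytest.raises(ValueError):
            StructuralReferenceSet("bad", ("tssA",), ("tssA",), {})

    def test_empty_required_rejected(self):
        with pytest.raises(ValueError):
            StructuralReferenceSet("bad", (), (), {})


class TestDetection:
    def test_planted_locus_hits_all_thirteen(self, reference_set):
        genome = _locus_genome(reference_set, CANONICAL_GENES)
        hits = detect_structural_hits(genome, reference_set)
        assert set(hits) == set(CANONICAL_GENES)
        assert all(len(v) == 1 for v in hits.values())

    def test_decoy_only_genome_has_no_hits(self, reference_set):
        rng = np.random.default_rng(9)
        genome = _locus_genome(reference_set, [],
                               extra=[random_protein(rng, 300)])
        assert detect_structural_hits(genome, reference_set) == {}

    def test_protein_assigned_to_single_best_gene(self, reference_set):
        # a protein equally similar to two references maps to exactly one
        genome = _locus_genome(reference_set, ["tssB"])
        hits = detect_structural_hits(genome, reference_set)
        assigned = [g for g, v in hits.items() for _ in v]
        assert assigned == ["tssB"]


class TestLoci:
    def test_contiguous_genes_merge_into_one_locus(self, reference_set):
        genome = _locus_genome(reference_set, CANONICAL_GENES)
        hits = detect_structural_hits(genome, reference_set)
        loci = call_loci(hits, genome)
        assert len(loci) == 1
        assert len(loci[0].gene_ids) == 13

    def test_distant_vgrg_is_satellite(self, reference_set):
        rng = np.random.default_rng(3)
        satellite = mutate_to_identity(
            reference_set.reference_proteins["tssI"][0], 0.75, rng)
        genome = _locus_genome(reference_set, CANONICAL_GENES,
                               extra=[satellite])
        hits = detect_structural_hits(genome, reference_set)
        loci = call_loci(hits, genome)
        assert [l.satellite for l in loci] == [False, True]

    def test_locus_split_across_contigs_gives_two_spans(self):
        genome = Genome("G", [ContigRecord("c1", 10_000),
                              ContigRecord("c2", 10_000)],
                        [GeneFeature("g1", "c1", 100, 1000, "+"),
                         GeneFeature("g2", "c2", 100, 1000, "+")], [])
        hits = {"tssB": [StructuralHit("p1", "g1", "tssB", 0.8, 0.9)],
                "tssC": [StructuralHit("p2", "g2", "tssC", 0.8, 0.9)]}
        loci = call_loci(hits, genome)
        assert len(loci) == 2
        assert {l.contig_id for l in loci} == {"c1", "c2"}


class TestCompleteness:
    def test_all_thirteen_present_is_complete(self, reference_set):
        genome = _locus_genome(reference_set, CANONICAL_GENES)
        hits = detect_structural_hits(genome, reference_set)
        call = classify_completeness(genome, reference_set, hits,
                                     call_loci(hits, genome))
        assert call.verdict == "complete"
        assert call.missing_genes == []

    def test_one_missing_at_contig_end_is_forgiven(self, reference_set):
        genome = _locus_genome(reference_set, CANONICAL_GENES[:-1],
                               flush_end=True)
        hits = detect_structural_hits(genome, reference_set)
        call = classify_completeness(genome, reference_set, hits,
                                     call_loci(hits, genome))
        assert call.verdict == "complete_contig_end_exception"
        assert call.missing_genes == ["tssM"]

    def test_two_missing_interior_is_incomplete(self, reference_set):
        present = [g for g in CANONICAL_GENES if g not in {"tssF", "tssK"}]
        genome = _locus_genome(reference_set, present)
        hits = detect_structural_hits(genome, reference_set)
        call = classify_completeness(genome, reference_set, hits,
                                     call_loci(hits, genome))
        assert call.verdict == "incomplete"
        assert set(call.missing_genes) == {"tssF", "tssK"}

    def test_subtype_iii_complete_without_tssq_tssr(self):
        rng = np.random.default_rng(4)
        refs = {g: [random_protein(rng, 300)]
                for g in CANONICAL_GENES + ("tssQ", "tssR")}
        subtype = StructuralReferenceSet("subtype_iii", CANONICAL_GENES,
                                         ("tssQ", "tssR"), refs)
        genome = _locus_genome(subtype, CANONICAL_GENES, rng_seed=5)
        hits = detect_structural_hits(genome, subtype)
        call = classify_completeness(genome, subtype, hits,
                                     call_loci(hits, genome))
        assert call.verdict == "complete"

    def test_lone_satellite_vgrg_is_absent(self, reference_set):
        rng = np.random.default_rng(6)
        satellite = mutate_to_identity(
            reference_set.reference_proteins["tssI"][0], 0.75, rng)
        genome = _locus_genome(reference_set, [], extra=[satellite])
        hits = detect_structural_hits(genome, reference_set)
        call = classify_completeness(genome, reference_set, hits,
                                     call_loci(hits, genome))
        assert call.verdict == "absent"

    def test_verdicts_exhaustive_and_exclusive(self, reference_set):
        for present, expect in [
            (CANONICAL_GENES, "complete"),
            (CANONICAL_GENES[:11], "incomplete"),
            ([], "absent"),
        ]:
            genome = _locus_genome(reference_set, present)
            hits = detect_structural_hits(genome, reference_set)
            call = classify_completeness(genome, reference_set, hits,
                                         call_loci(hits, genome))
            assert call.verdict == expect
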