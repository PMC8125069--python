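"""Immunity pairing, cooccurrence counting and secretion-context labels."""

import numpy as np
import pytest

from effectornet.context import (CONTEXT_LABELS, ToxinImmunityPair,
                                 classify_secretion_context,
                                 cooccurrence_matrix, derive_pairs,
                                 find_cognate_immunity)
from effectornet.genome_io import ContigRecord, GeneFeature, Genome, \
    ProteinRecord
from effectornet.motifs import DomainHit
from effectornet.rhs import RhsArchitecture


def _genome(genes, proteome=()):
    return Genome("G", [ContigRecord("c1", 100_000)], list(genes),
                  list(proteome))


class TestFindCognateImmunity:
    def test_close_same_strand_neighbor_found(self):
        g = _genome([GeneFeature("tox", "c1", 1000, 5200, "+"),
                     GeneFeature("imm", "c1", 5300, 5700, "+")])
        gene, reason = find_cognate_immunity(g, "tox")
        assert reason == "found" and gene.id == "imm"

    def test_wrong_strand_neighbor_is_no_candidate(self):
        g = _genome([GeneFeature("tox", "c1", 1000, 5200, "+"),
                     GeneFeature("imm", "c1", 5300, 5700, "-")])
        gene, reason = find_cognate_immunity(g, "tox")
        assert gene is None and reason == "no_candidate"

    def test_distant_neighbor_is_no_candidate(self):
        g = _genome([GeneFeature("tox", "c1", 1000, 5200, "+"),
                     GeneFeature("far", "c1", 9000, 9700, "+")])
        gene, reason = find_cognate_immunity(g, "tox", max_intergenic=200)
        assert gene is None and reason == "no_candidate"

    def test_last_gene_on_contig_is_contig_end(self):
        g = _genome([GeneFeature("tox", "c1", 90_000, 99_000, "+")])
        gene, reason = find_cognate_immunity(g, "tox")
        assert gene is None and reason == "contig_end"

    def test_minus_strand_looks_upstream_in_coordinates(self):
        g = _genome([GeneFeature("imm", "c1", 4000, 4400, "-"),
                     GeneFeature("tox", "c1", 4500, 8000, "-")])
        gene, reason = find_cognate_immunity(g, "tox")
        assert reason == "found" and gene.id == "imm"


class TestCooccurrence:
    def test_demo_matrix_equals_ground_truth(self, demo_community):
        """Counts and caveats over the 5-genome, 4-pair plant match the
        planted composition exactly."""
        com = demo_community
        from effectornet.homology import greedy_cluster
        from effectornet.rhs import split_all, cluster_domains
        truth = com.truth

        # build pairs from the planted families directly: representative
        # toxin domain = the family seed's planted member domain
        pairs = []
        for fam in sorted(com.assets.toxin_seeds):
            pairs.append(ToxinImmunityPair(
                f"P_{fam}", com.assets.toxin_seeds[fam],
                com.assets.immunity_seeds[fam]))
        cells = cooccurrence_matrix(pairs, com.genomes)
        by_key = {(c.genome_id, c.pair_id): c for c in cells}

        def expected_counts(gid, fam):
            rows = truth[truth["genome_id"] == gid]
            tox = sum((rows["kind"] == "rhs_full")
                      & rows["family"].str.endswith("/" + fam))
            tox += sum((rows["kind"] == "rhs_orphan")
                       & (rows["family"] == fam))
            imm = sum(rows["kind"].isin(["immunity", "immunity_only"])
                      & (rows["family"] == fam))
            return tox, imm

        for g in com.genomes:
            for fam in sorted(com.assets.toxin_seeds):
                cell = by_key[(g.id, f"P_{fam}")]
                assert (cell.toxin_copy_count,
                        cell.immunity_copy_count) == \
                    expected_counts(g.id, fam), (g.id, fam)

        # caveat flags: the contig-end toxin genome is marked as such
        end_gid = truth.loc[(truth["kind"] == "rhs_full")
                            & truth["at_contig_end"], "genome_id"].iloc[0]
        fam = truth.loc[(truth["kind"] == "rhs_full")
                        & truth["at_contig_end"], "family"].iloc[0]
        fam = fam.split("/")[1]
        assert by_key[(end_gid, f"P_{fam}")].caveat == "toxin_at_contig_end"
        # orphaned-immunity genome: immunity present, toxin absent, no caveat
        imm_gid = truth.loc[truth["kind"] == "immunity_only",
                            "genome_id"].iloc[0]
        imm_fam = truth.loc[truth["kind"] == "immunity_only",
                            "family"].iloc[0]
        cell = by_key[(imm_gid, f"P_{imm_fam}")]
        assert cell.immunity_present and not cell.toxin_present
        assert cell.caveat == "none"

    def test_empty_pair_representative_rejected(self):
        with pytest.raises(ValueError):
            ToxinImmunityPair("P1", "", "MKT")


class TestSecretionContext:
    def _protein(self, pid="p1", length=400):
        return ProteinRecord(pid, "G", "A" * length, "g1")

    def _genome_with(self, *genes):
        return _genome(genes or [GeneFeature("g1", "c1", 100, 1300, "+")])

    def test_paar_hit_is_t6ss_effector(self):
        p = self._protein()
        hits = {"p1": [DomainHit("p1", "paar", 10, 60, 50.0)]}
        assert classify_secretion_context(p, hits, self._genome_with()) \
            == "t6ss_effector"

    def test_full_length_rhs_core_is_t6ss_effector(self):
        p = self._protein()
        hits = {"p1": [DomainHit("p1", "rhs_core", 100, 200, 90.0)]}
        arch = RhsArchitecture("p1", "G", "full_length", 400,
                               core_span=(1, 250), toxin_span=(251, 400))
        assert classify_secretion_context(p, hits, self._genome_with(),
                                          arch) == "t6ss_effector"

    def test_spvb_head_is_t9ss(self):
        p = self._protein()
        hits = {"p1": [DomainHit("p1", "spvb_tcdb", 5, 85, 60.0)]}
        assert classify_secretion_context(p, hits, self._genome_with()) \
            == "t9ss_associated"

    def test_sorting_domain_neighbor_is_t9ss(self):
        genes = [GeneFeature("g1", "c1", 100, 1300, "+"),
                 GeneFeature("g2", "c1", 1400, 1900, "+")]
        genome = Genome("G", [ContigRecord("c1", 100_000)], genes,
                        [ProteinRecord("p1", "G", "A" * 400, "g1"),
                         ProteinRecord("p2", "G", "A" * 120, "g2")])
        p = genome.proteome[0]
        hits = {"p2": [DomainHit("p2", "t9ss_sorting", 10, 60, 40.0)]}
        assert classify_secretion_context(p, hits, genome) \
            == "t9ss_associated"

    def test_hemagglutinin_with_signal_is_t5ss_and_wins_precedence(self):
        p = self._protein()
        hits = {"p1": [DomainHit("p1", "hemagglutinin", 40, 120, 70.0),
                       DomainHit("p1", "signal_peptide", 1, 18, 20.0),
                       DomainHit("p1", "paar", 150, 210, 50.0)]}
        assert classify_secretion_context(p, hits, self._genome_with()) \
            == "t5ss_autotransporter"

    def test_signal_beyond_window_does_not_make_t5ss(self):
        p = self._protein()
        hits = {"p1": [DomainHit("p1", "hemagglutinin", 40, 120, 70.0),
                       DomainHit("p1", "signal_peptide", 150, 168, 20.0)]}
        assert classify_secretion_context(p, hits, self._genome_with()) \
            == "unknown"

    def test_orphan_without_motifs_is_orphan_domain(self):
        p = self._protein()
        arch = RhsArchitecture("p1", "G", "orphan_toxin", 400,
                               toxin_cluster="T001")
        assert classify_secretion_context(p, {}, self._genome_with(),
                                          arch) == "orphan_domain"

    def test_no_signal_at_all_is_unknown(self):
        p = self._protein()
        assert classify_secretion_context(p, {}, self._genome_with()) \
            == "unknown"

    def test_every_label_is_in_the_taxonomy(self):
        p = self._protein()
        label = classify_secretion_context(p, {}, self._genome_with())
        assert label in CONTEXT_LABELS


class TestDerivePairs:
    def test_pairs_derived_from_planted_clusters(self, demo_community):
        from effectornet.homology import greedy_cluster
        com = demo_community
        truth = com.truth
        fulls = truth[truth["kind"] == "rhs_full"]
        proteins = {p.id: p for g in com.genomes for p in g.proteome}
        toxin_seqs = []
        for _, row in fulls.iterrows():
            seq = proteins[row["protein_id"]].sequence
            toxin_seqs.append((f"{row['protein_id']}|toxin",
                               seq[int(row["split_pos"]) - 1:]))
        clusters = greedy_cluster(toxin_seqs, 0.40)
        pairs = derive_pairs(clusters, dict(toxin_seqs), com.genomes)
        # every planted family with a pairable member donates one pair
        assert len(pairs) >= 3
        for p in pairs:
            assert p.toxin_representative and p.immunity_representative
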