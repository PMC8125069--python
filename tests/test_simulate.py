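"""The community generator: mutation control, determinism, ground truth."""

import numpy as np
import pytest

from effectornet.rhs import RhsArchitecture
from effectornet.simulate import (CommunitySpec, GenomePlan,
                                  MutationParameterError,
                                  default_community_spec, generate_community,
                                  immunity_demo_spec, mutate_to_identity,
                                  random_protein, verify_separation)
from effectornet.evaluate import evaluate_recovery


def _positional_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestMutateToIdentity:
    def test_target_one_is_identical_copy(self):
        rng = np.random.default_rng(0)
        seq = random_protein(rng, 50)
        assert mutate_to_identity(seq, 1.0, rng) == seq

    def test_achieved_identity_within_tolerance(self):
        rng = np.random.default_rng(1)
        seq = random_protein(rng, 300)
        mut = mutate_to_identity(seq, 0.60, rng)
        assert len(mut) == 300
        assert 0.57 <= _positional_identity(seq, mut) <= 0.63

    def test_masked_positions_never_mutate(self):
        rng = np.random.default_rng(2)
        seq = random_protein(rng, 100)
        mask = {10, 11, 12, 13}
        for target in (0.9, 0.5, 0.1):
            mut = mutate_to_identity(seq, target, rng, mask)
            assert mut[10:14] == seq[10:14]

    def test_unreachable_target_rejected(self):
        rng = np.random.default_rng(3)
        seq = random_protein(rng, 20)
        with pytest.raises(MutationParameterError):
            mutate_to_identity(seq, 0.05, rng, mask=set(range(15)))

    def test_deterministic_given_seed(self):
        seq = random_protein(np.random.default_rng(4), 80)
        assert mutate_to_identity(seq, 0.7, 42) \
            == mutate_to_identity(seq, 0.7, 42)


class TestGeneration:
    def test_same_seed_gives_byte_identical_genomes(self):
        spec_a = immunity_demo_spec(seed=5)
        spec_b = immunity_demo_spec(seed=5)
        com_a = generate_community(spec_a, verify=False)
        com_b = generate_community(spec_b, verify=False)
        for ga, gb in zip(com_a.genomes, com_b.genomes):
            assert [c.sequence for c in ga.contigs] \
                == [c.sequence for c in gb.contigs]
        assert com_a.truth.equals(com_b.truth)

    def test_plan_arithmetic_matches_ledger(self, demo_community):
        """Every planted gene appears exactly once in the truth ledger."""
        truth = demo_community.truth
        assert truth["gene_id"].is_unique
        for genome in demo_community.genomes:
            n_planted = (truth["genome_id"] == genome.id).sum()
            assert n_planted == len(genome.genes)

    def test_full_length_plants_record_their_split(self, demo_community):
        truth = demo_community.truth
        proteins = {p.id: p.sequence for g in demo_community.genomes
                    for p in g.proteome}
        fulls = truth[truth["kind"] == "rhs_full"]
        assert len(fulls) > 0
        for _, row in fulls.iterrows():
            split = int(row["split_pos"])
            seq = proteins[row["protein_id"]]
            # the core ends with the DPxG anchor right before the split
            motif = seq[split - 5:split - 1]
            assert motif[0] == "D" and motif[1] == "P" and motif[3] == "G"

    def test_separation_assumptions_hold(self, demo_community):
        report = verify_separation(demo_community)
        spec = demo_community.spec
        assert report["within_min"] >= spec.within_identity
        assert report["between_max"] <= spec.between_identity
        assert report["decoy_max"] <= spec.decoy_identity

    def test_default_spec_covers_every_family_and_verdict(self):
        spec = default_community_spec(seed=0)
        fams = {t for p in spec.plans for _, t in p.full_length}
        assert fams == {f"T{k}" for k in range(1, 7)}
        verdicts = {p.t6ss_verdict for p in spec.plans}
        assert verdicts == {"complete", "complete_contig_end_exception",
                            "incomplete", "absent"}
        vfams = {v for p in spec.plans for v in p.vgrg}
        assert vfams == {"V1", "V2", "V3"}

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CommunitySpec(within_identity=0.2, between_identity=0.25)


class TestEvaluateRecovery:
    def _perfect_outputs(self, community):
        truth = community.truth
        proteins = {p.id: len(p.sequence) for g in community.genomes
                    for p in g.proteome}
        archs = {}
        for _, row in truth.iterrows():
            pid = row["protein_id"]
            if row["kind"] == "rhs_full":
                fam = row["family"].split("/")[1]
                split = int(row["split_pos"])
                archs[pid] = RhsArchitecture(
                    pid, row["genome_id"], "full_length", proteins[pid],
                    core_span=(1, split - 1),
                    toxin_span=(split, proteins[pid]),
                    core_cluster=row["family"].split("/")[0],
                    toxin_cluster=fam)
            elif row["kind"] == "rhs_orphan":
                archs[pid] = RhsArchitecture(
                    pid, row["genome_id"], "orphan_toxin", proteins[pid],
                    toxin_cluster=row["family"])
        verdicts = dict(zip(community.genome_truth["genome_id"],
                            community.genome_truth["intended_verdict"]))
        return archs, verdicts

    def test_perfect_run_scores_unity(self, demo_community):
        archs, verdicts = self._perfect_outputs(demo_community)
        m = evaluate_recovery(demo_community.truth,
                              demo_community.genome_truth, archs, [],
                              verdicts)
        assert m["full_length_precision"] == m["full_length_recall"] == 1.0
        assert m["orphan_precision"] == m["orphan_recall"] == 1.0
        assert m["toxin_cluster_ari"] == 1.0
        assert m["split_match_rate"] == 1.0
        assert m["t6ss_verdict_accuracy"] == 1.0

    def test_one_dropped_element_lowers_recall_proportionally(
            self, demo_community):
        archs, verdicts = self._perfect_outputs(demo_community)
        fulls = [pid for pid, a in archs.items()
                 if a.status == "full_length"]
        n = len(fulls)
        del archs[fulls[0]]
        m = evaluate_recovery(demo_community.truth,
                              demo_community.genome_truth, archs, [],
                              verdicts)
        assert m["full_length_recall"] == pytest.approx((n - 1) / n)
        assert m["full_length_precision"] == 1.0

    def test_ari_invariant_under_label_permutation(self, demo_community):
        archs, verdicts = self._perfect_outputs(demo_community)
        renamed = {}
        for pid, a in archs.items():
            if a.toxin_cluster:
                a.toxin_cluster = "X_" + a.toxin_cluster
            renamed[pid] = a
        m = evaluate_recovery(demo_community.truth,
                              demo_community.genome_truth, renamed, [],
                              verdicts)
        assert m["toxin_cluster_ari"] == 1.0

    def test_unknown_protein_id_is_join_error(self, demo_community):
        archs, verdicts = self._perfect_outputs(demo_community)
        archs["ghost"] = RhsArchitecture("ghost", "nowhere", "orphan_toxin",
                                         100, toxin_cluster="T1")
        with pytest.raises(KeyError):
            evaluate_recovery(demo_community.truth,
                              demo_community.genome_truth, archs, [],
                              verdicts)
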