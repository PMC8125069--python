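"""PSSM construction, scanning and decoy-based threshold calibration."""

import math

import numpy as np
import pytest

from effectornet.motifs import (CalibrationError, MotifBuildError,
                                MotifConfigError, RESIDUES, best_window_score,
                                build_pssm, calibrate_threshold,
                                load_motif_library, make_decoy, scan_protein,
                                shuffle_sequence)
from effectornet.simulate import random_protein

from oracles import oracle_window_scan


def _uniform_bg():
    return np.full(20, 1 / 20)


class TestBuildPssm:
    def test_identical_seed_copies_score_formula(self):
        # 4 identical copies, uniform background, pseudocount 1:
        # consensus column score = log2((4 + 0.05) / (5 * 0.05))
        seq = "ACDEFGHIKL"
        model = build_pssm([seq] * 4, pseudocount=1.0,
                           background=_uniform_bg())
        assert model.width == 10
        expected = math.log2((4 + 0.05) / (5 * 0.05))
        for c, residue in enumerate(seq):
            assert model.scores[c, RESIDUES.index(residue)] \
                == pytest.approx(expected, abs=1e-9)

    def test_split_column_scores_residues_equally(self):
        model = build_pssm(["AWWWW", "AWWWW", "CWWWW", "CWWWW"])
        a = model.scores[0, RESIDUES.index("A")]
        c = model.scores[0, RESIDUES.index("C")]
        assert a == pytest.approx(c)

    def test_majority_gap_column_dropped(self):
        seqs = ["AC-DEF", "AC-DEF", "AC-DEF", "ACWDEF"]
        model = build_pssm(seqs)
        assert model.width == 5

    def test_ragged_alignment_rejected(self):
        with pytest.raises(MotifBuildError):
            build_pssm(["ACDEF", "ACDE"])

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(MotifBuildError):
            build_pssm(["-----", "-----"])


class TestScanProtein:
    def test_consensus_self_match_is_single_maximal_hit(self):
        rng = np.random.default_rng(0)
        seed = random_protein(rng, 30)
        model = build_pssm([seed] * 4)
        hits = scan_protein(model, seed, threshold=0.0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (1, 30)
        assert h.score == pytest.approx(model.max_score)

    def test_unrelated_residues_yield_no_hit(self):
        model = build_pssm(["AAAAAAAAAA"] * 4)
        assert scan_protein(model, "W" * 40, threshold=0.0) == []

    def test_translation_invariance_of_scores(self):
        rng = np.random.default_rng(1)
        seed = random_protein(rng, 25)
        model = build_pssm([seed] * 3)
        prefix = "W" * 17
        base = scan_protein(model, seed, threshold=0.0)[0]
        shifted = scan_protein(model, prefix + seed + "W" * 9,
                               threshold=base.score - 1e-6)[0]
        assert shifted.score == pytest.approx(base.score)
        assert shifted.start == base.start + len(prefix)

    def test_protein_shorter_than_motif_scans_empty(self):
        model = build_pssm(["ACDEFGHIKL"] * 2)
        assert scan_protein(model, "ACDEF") == []

    def test_window_scores_match_direct_summation(self):
        rng = np.random.default_rng(2)
        seed = random_protein(rng, 12)
        model = build_pssm([seed, shuffle_sequence(seed, rng),
                            seed])
        protein = random_protein(rng, 50) + seed + "X" * 5
        got = max(h.score for h in scan_protein(model, protein,
                                                threshold=-1e9))
        want = oracle_window_scan(model.scores, protein, RESIDUES)
        assert got == pytest.approx(want)


class TestCalibration:
    @pytest.fixture()
    def model_and_decoys(self):
        rng = np.random.default_rng(3)
        seed = random_protein(rng, 20)
        model = build_pssm([seed] * 4)
        decoys = [shuffle_sequence(seed, rng) for _ in range(1000)]
        return model, decoys

    def test_decoy_firing_bounded_by_target(self, model_and_decoys):
        model, decoys = model_and_decoys
        t = calibrate_threshold(model, decoys, target_fpr=0.001)
        firing = sum(best_window_score(model, d) >= t for d in decoys)
        assert firing <= 1  # floor(0.001 * 1000)

    def test_unit_fpr_returns_minimum_decoy_score(self, model_and_decoys):
        model, decoys = model_and_decoys
        t = calibrate_threshold(model, decoys, target_fpr=1.0)
        assert t == pytest.approx(min(best_window_score(model, d)
                                      for d in decoys))

    def test_threshold_monotone_in_target_fpr(self, model_and_decoys):
        model, decoys = model_and_decoys
        strict = calibrate_threshold(model, list(decoys), 0.001)
        loose = calibrate_threshold(model, list(decoys), 0.01)
        assert strict >= loose

    def test_too_few_decoys_rejected(self, model_and_decoys):
        model, decoys = model_and_decoys
        with pytest.raises(CalibrationError):
            calibrate_threshold(model, decoys[:50], 0.01)


class TestMotifLibrary:
    def _write_seeds(self, tmp_path, name, seed, n=4, rng=None):
        rng = rng or np.random.default_rng(0)
        path = tmp_path / f"{name}.afa"
        from effectornet.simulate import mutate_to_identity
        with open(path, "w") as fh:
            for k in range(n):
                fh.write(f">{name}{k}\n"
                         f"{mutate_to_identity(seed, 0.9, rng)}\n")
        return path

    def test_minimal_library_builds_and_calibrates(self, tmp_path):
        rng = np.random.default_rng(4)
        cfg = {}
        for name in ("rhs_core", "vgrg"):
            p = self._write_seeds(tmp_path, name, random_protein(rng, 30),
                                  rng=rng)
            cfg[name] = {"path": str(p), "fpr": 0.01, "n_decoys": 120,
                         "decoy_length": 120}
        lib = load_motif_library(cfg, seed=0)
        assert set(lib) == {"rhs_core", "vgrg"}
        for m in lib.values():
            assert m.calibration["method"] == "decoy_fpr"
            assert m.bit_threshold > m.calibration["noise_bits"] - 1e-9

    def test_seeds_detected_at_calibrated_threshold(self, tmp_path):
        """Sensitivity-on-training: each seed hits its own model."""
        rng = np.random.default_rng(5)
        from effectornet.simulate import mutate_to_identity
        block = random_protein(rng, 40)
        seeds = [mutate_to_identity(block, 0.9, rng) for _ in range(6)]
        p = tmp_path / "rhs_core.afa"
        p.write_text("".join(f">s{k}\n{s}\n" for k, s in enumerate(seeds)))
        cfg = {"rhs_core": {"path": str(p), "fpr": 0.01, "n_decoys": 150,
                            "decoy_length": 150},
               "vgrg": {"path": str(p), "fpr": 0.01, "n_decoys": 150,
                        "decoy_length": 150}}
        lib = load_motif_library(cfg, seed=0)
        for s in seeds:
            assert scan_protein(lib["rhs_core"], s)

    def test_missing_mandatory_motif_rejected(self, tmp_path):
        rng = np.random.default_rng(6)
        p = self._write_seeds(tmp_path, "vgrg", random_protein(rng, 30))
        with pytest.raises(MotifConfigError):
            load_motif_library({"vgrg": {"path": str(p), "fpr": 0.01,
                                         "n_decoys": 120}})

    def test_missing_optional_motif_skipped(self, tmp_path):
        rng = np.random.default_rng(7)
        cfg = {}
        for name in ("rhs_core", "vgrg"):
            p = self._write_seeds(tmp_path, name, random_protein(rng, 30),
                                  rng=rng)
            cfg[name] = {"path": str(p), "fpr": 0.01, "n_decoys": 120,
                         "decoy_length": 120}
        cfg["paar"] = {"path": str(tmp_path / "nope.afa"), "fpr": 0.01}
        lib = load_motif_library(cfg, seed=0)
        assert "paar" not in lib

    def test_duplicate_motif_name_rejected(self, tmp_path):
        rng = np.random.default_rng(8)
        p = self._write_seeds(tmp_path, "rhs_core", random_protein(rng, 30))
        entries = [("rhs_core", {"path": str(p)}),
                   ("rhs_core", {"path": str(p)})]
        with pytest.raises(MotifConfigError):
            load_motif_library(entries)


def test_decoy_embedding_preserves_length_and_composition():
    from collections import Counter
    rng = np.random.default_rng(9)
    seed = random_protein(rng, 50)
    decoy = make_decoy(seed, rng, decoy_length=300)
    assert len(decoy) == 300
    # every residue of the shuffled seed is present in the decoy
    assert not (Counter(seed) - Counter(decoy))
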