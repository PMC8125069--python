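"""Alignment, identity conventions, clustering and homolog search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from effectornet.homology import (AlignmentError, align_local, greedy_cluster,
                                  identity_blast_style, identity_short_style,
                                  search_homologs)
from effectornet.simulate import mutate_to_identity, random_protein

from oracles import oracle_align, oracle_greedy, oracle_identity_short

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, lo, hi):
    return "".join(rng.choice(list(AA), size=rng.integers(lo, hi)))


class TestAlignLocal:
    def test_self_alignment_is_full_identity(self):
        r = align_local("ACDEFGHIKL", "ACDEFGHIKL")
        assert (r.identities, r.aln_columns) == (10, 10)
        assert r.q_span == (1, 10) and r.s_span == (1, 10)
        assert identity_blast_style(r) == 1.0

    def test_single_substitution_gives_ninety_percent(self):
        r = align_local("ACDEFGHIKL", "ACDEFGHIKV")
        assert (r.identities, r.aln_columns) == (9, 10)
        assert identity_blast_style(r) == pytest.approx(0.9)

    def test_gap_columns_counted_in_alignment_length(self):
        # one residue deleted: 12 identities across 13 columns
        r = align_local("ACDEFGHIKLMNP", "ACDEFHIKLMNP")
        assert (r.identities, r.aln_columns) == (12, 13)

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            align_local("", "ACD")

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            a, b = _random_seq(rng, 10, 61), _random_seq(rng, 10, 61)
            r = align_local(a, b)
            o = oracle_align(a, b)
            got = (r.score, r.identities, r.aln_columns, r.q_start,
                   r.q_end, r.s_start, r.s_end)
            assert tuple(map(int, got)) == o


class TestIdentityConventions:
    def test_blast_style_is_identities_over_columns(self):
        r = align_local("A" * 10, "A" * 10)
        assert identity_blast_style(r) == 1.0

    def test_short_style_uses_shorter_full_length(self):
        # 50 identities against a 100-aa shorter sequence -> 0.50
        rng = np.random.default_rng(0)
        short = random_protein(rng, 100)
        long = short[:50] + random_protein(rng, 200)
        r = align_local(long, short)
        assert identity_short_style(r, len(long), len(short)) \
            == pytest.approx(r.identities / 100)

    def test_conventions_agree_for_identical_sequences(self):
        s = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        r = align_local(s, s)
        assert identity_blast_style(r) == 1.0
        assert identity_short_style(r, len(s), len(s)) == 1.0

    def test_zero_length_alignment_is_undefined(self):
        r = align_local("AAAA", "WWWW")  # no positive-scoring window
        assert r.aln_columns == 0
        with pytest.raises(AlignmentError):
            identity_blast_style(r)


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self):
        seqs = [(f"s{i}", "MKTAYIAKQRQISFVKSHFSRQ") for i in range(5)]
        clusters = greedy_cluster(seqs, 0.4)
        assert len(clusters) == 1
        assert clusters[0].representative_id == "s0"  # lowest id on ties
        assert sorted(clusters[0].member_ids) == [f"s{i}" for i in range(5)]

    def test_two_planted_families_separate_at_forty_percent(self):
        rng = np.random.default_rng(5)
        fam_a, fam_b = random_protein(rng, 120), random_protein(rng, 120)
        seqs = []
        for k in range(4):
            seqs.append((f"a{k}", mutate_to_identity(fam_a, 0.85, rng)))
            seqs.append((f"b{k}", mutate_to_identity(fam_b, 0.85, rng)))
        # pre-verify the plant with the oracle before asserting clustering
        assert oracle_identity_short(seqs[0][1], seqs[2][1]) >= 0.6
        assert oracle_identity_short(seqs[0][1], seqs[1][1]) <= 0.25
        clusters = greedy_cluster(seqs, 0.40)
        assert len(clusters) == 2
        families = [{m[0] for m in c.member_ids} for c in clusters]
        assert {frozenset(f) for f in families} == {frozenset("a"),
                                                    frozenset("b")}

    def test_equals_bruteforce_greedy_on_small_sets(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            base = [random_protein(rng, 45) for _ in range(3)]
            seqs = []
            for i in range(int(rng.integers(6, 15))):
                fam = base[int(rng.integers(3))]
                seqs.append((f"q{trial}_{i:02d}",
                             mutate_to_identity(fam, float(rng.uniform(0.5, 1.0)), rng)))
            got = [(c.representative_id, c.member_ids)
                   for c in greedy_cluster(seqs, 0.4)]
            assert got == oracle_greedy(seqs, 0.4)

    def test_clusters_partition_input(self):
        rng = np.random.default_rng(3)
        seqs = [(f"p{i}", _random_seq(rng, 30, 80)) for i in range(12)]
        clusters = greedy_cluster(seqs, 0.4)
        seen = [m for c in clusters for m in c.member_ids]
        assert sorted(seen) == sorted(s for s, _ in seqs)

    def test_members_reach_threshold_identity_to_representative(self):
        rng = np.random.default_rng(4)
        fam = random_protein(rng, 100)
        seqs = [(f"m{i}", mutate_to_identity(fam, 0.8, rng))
                for i in range(6)]
        for c in greedy_cluster(seqs, 0.4):
            rep = dict(seqs)[c.representative_id]
            for m in c.member_ids:
                r = align_local(dict(seqs)[m], rep)
                assert identity_short_style(
                    r, len(dict(seqs)[m]), len(rep)) >= 0.4


class TestSearchHomologs:
    def test_exact_copy_matches_fully(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
        out = search_homologs([("rep", seq)], [("copy", seq)],
                              min_identity=0.4)
        assert len(out) == 1
        m = out[0]
        assert m.identity_fraction == 1.0
        assert m.subject_coverage == 1.0

    def test_planted_homolog_passes_then_fails_higher_cutoff(self):
        rng = np.random.default_rng(7)
        rep = random_protein(rng, 200)
        homolog = mutate_to_identity(rep, 0.5, rng)
        o = oracle_align(rep, homolog)
        assert 0.40 <= o[1] / o[2] < 0.60  # oracle-verified blast identity
        db = [("h", homolog)]
        assert search_homologs([("rep", rep)], db, 0.40, 90)
        assert not search_homologs([("rep", rep)], db, 0.60, 90)

    def test_short_shared_segment_fails_length_filter(self):
        rng = np.random.default_rng(8)
        shared = random_protein(rng, 30)
        rep = shared + random_protein(rng, 150)
        subject = random_protein(rng, 120) + shared
        out = search_homologs([("rep", rep)], [("s", subject)],
                              min_identity=0.4, min_aln_len=90)
        assert out == []

    def test_self_matches_excluded(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLG"
        assert search_homologs([("x", seq)], [("x", seq)]) == []

    def test_pass_fail_symmetric_under_swap(self):
        rng = np.random.default_rng(12)
        a = random_protein(rng, 150)
        b = mutate_to_identity(a, 0.55, rng)
        fwd = search_homologs([("a", a)], [("b", b)], 0.4, 90)
        rev = search_homologs([("b", b)], [("a", a)], 0.4, 90)
        assert bool(fwd) == bool(rev)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.text(alphabet=AA, min_size=1, max_size=40),
       st.text(alphabet=AA, min_size=1, max_size=40))
def test_identity_conventions_bounded(a, b):
    """Both identity conventions stay within [0, 1] and blast-style is
    never below short-style times min_len/aln_columns trivia aside."""
    r = align_local(a, b)
    if r.aln_columns == 0:
        return
    assert 0 <= identity_blast_style(r) <= 1
    assert 0 <= identity_short_style(r, len(a), len(b)) <= 1
    assert r.identities <= min(len(a), len(b))
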