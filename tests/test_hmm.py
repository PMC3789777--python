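"""HMM decoders against enumeration oracles; Baum-Welch; profile and pair HMMs."""

import itertools
import math

import numpy as np
import pytest

import probseq as ps
from probseq import DNA, Sequence, encode
from probseq.hmm import Hmm, PairHmm, baum_welch, build_profile_hmm

from conftest import random_distribution, random_hmm, random_sequence
import oracles


def one_state_hmm():
    return Hmm(DNA, ["only"], [1.0], [[1.0]], [[0.4, 0.3, 0.2, 0.1]])


class TestForwardBackward:
    def test_one_state_closed_form(self):
        h = one_state_hmm()
        seq = encode(list("ACGGT"), DNA)
        expected = sum(math.log(h.emissions[0, v]) for v in seq.values)
        assert h.forward(seq)[0] == pytest.approx(expected)
        assert h.backward(seq)[0] == pytest.approx(expected)

    def test_forward_equals_backward_random(self, rng):
        for _ in range(30):
            h = random_hmm(rng, int(rng.integers(1, 4)))
            seq = random_sequence(rng, int(rng.integers(1, 12)))
            f = h.forward(seq)[0]
            b = h.backward(seq)[0]
            assert f == pytest.approx(b, rel=1e-8)

    def test_matches_enumeration(self, rng):
        for _ in range(10):
            h = random_hmm(rng, int(rng.integers(2, 4)))
            seq = random_sequence(rng, int(rng.integers(2, 7)))
            assert h.forward(seq)[0] == pytest.approx(
                oracles.enumerate_forward(h, seq), abs=1e-9)


class TestViterbi:
    def test_forced_chain(self):
        # left-to-right chain with deterministic emissions
        A = [[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, 1.0]]
        E = [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]]
        h = Hmm(DNA, ["a", "b", "c"], [1, 0, 0], A, E)
        path, ll = h.viterbi(encode(list("ACGG"), DNA))
        assert path == ["a", "b", "c", "c"]
        assert ll == pytest.approx(0.0)

    def test_matches_enumeration(self, rng):
        for _ in range(10):
            h = random_hmm(rng, int(rng.integers(2, 4)))
            seq = random_sequence(rng, int(rng.integers(2, 7)))
            path, ll = h.viterbi(seq)
            assert ll == pytest.approx(oracles.enumerate_viterbi(h, seq)[1], abs=1e-9)
            assert oracles.hmm_path_score(h, seq, path) == pytest.approx(ll, abs=1e-9)

    def test_never_exceeds_forward(self, rng):
        for _ in range(20):
            h = random_hmm(rng, int(rng.integers(1, 4)))
            seq = random_sequence(rng, int(rng.integers(1, 15)))
            assert h.viterbi(seq)[1] <= h.forward(seq)[0] + 1e-12

    def test_impossible_sequence(self):
        h = Hmm(DNA, ["a"], [1.0], [[1.0]], [[1, 0, 0, 0]])
        path, ll = h.viterbi(encode(list("AC"), DNA))
        assert path == [] and ll == ps.NEG_INF


class TestPosterior:
    def test_one_state_all_ones(self):
        post, path = one_state_hmm().posterior_decode(encode(list("ACG"), DNA))
        assert np.allclose(post, 1.0) and path == ["only"] * 3

    def test_symmetric_states_give_half(self):
        h = Hmm(DNA, ["a", "b"], [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
                [[0.25] * 4, [0.25] * 4])
        post, _ = h.posterior_decode(encode(list("ACGT"), DNA))
        assert np.allclose(post, 0.5)

    def test_columns_sum_to_one_and_match_enumeration(self, rng):
        for _ in range(8):
            h = random_hmm(rng, int(rng.integers(2, 4)))
            seq = random_sequence(rng, int(rng.integers(2, 6)))
            post, _ = h.posterior_decode(seq)
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
            assert np.abs(post - oracles.enumerate_posterior(h, seq)).max() < 1e-9

    def test_zero_probability_sequence_raises(self):
        h = Hmm(DNA, ["a"], [1.0], [[1.0]], [[1, 0, 0, 0]])
        with pytest.raises(ValueError):
            h.posterior_decode(encode(list("C"), DNA))


def separated_two_state():
    return Hmm(DNA, ["gc", "at"], [0.5, 0.5],
               [[0.9, 0.1], [0.15, 0.85]],
               [[0.05, 0.45, 0.45, 0.05], [0.45, 0.05, 0.05, 0.45]])


class TestBaumWelch:
    def test_fixed_point_at_truth(self, rng):
        truth = separated_two_state()
        seqs = [truth.simulate(300, rng) for _ in range(20)]
        _, trace = baum_welch(truth, seqs, max_iter=2, tol=1e-12)
        assert trace[1] - trace[0] < 0.01 * abs(trace[0])

    def test_monotone_trace_random_inits(self, rng):
        truth = separated_two_state()
        seqs = [truth.simulate(100, rng) for _ in range(5)]
        for _ in range(3):
            init = random_hmm(rng, 2)
            _, trace = baum_welch(init, seqs, max_iter=15, tol=1e-9)
            assert all(b - a > -1e-10 for a, b in zip(trace, trace[1:]))

    def test_parameter_recovery_up_to_relabeling(self, rng):
        truth = separated_two_state()
        seqs = [truth.simulate(200, rng) for _ in range(50)]
        init = Hmm(DNA, ["gc", "at"], [0.5, 0.5],
                   [[0.7, 0.3], [0.3, 0.7]],
                   [[0.15, 0.35, 0.35, 0.15], [0.35, 0.15, 0.15, 0.35]])
        fitted, _ = baum_welch(init, seqs, max_iter=60, tol=1e-6)
        best = np.inf
        for perm in itertools.permutations(range(2)):
            p = list(perm)
            err = max(np.abs(fitted.transitions[p][:, p] - truth.transitions).max(),
                      np.abs(fitted.emissions[p] - truth.emissions).max())
            best = min(best, err)
        assert best < 0.05

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            baum_welch(separated_two_state(), [])


class TestProfileHmm:
    def test_gap_free_alignment_width(self):
        ph = build_profile_hmm([list("ACGT"), list("ACGT"), list("TCGA")], DNA)
        assert ph.M == 4

    def test_majority_gap_column_becomes_insert(self):
        aln = [list("A-T"), list("A-T"), list("A-T"), list("ACT")]
        ph = build_profile_hmm(aln, DNA, match_threshold=0.5)
        assert ph.M == 2

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile_hmm([list("ACG"), list("AC")], DNA)

    def test_family_scores_beat_shuffled(self, rng):
        # simulate a family from a known profile, compare mean log-odds
        cons = "ACGTACGTAC"
        rows = []
        for _ in range(30):
            toks = [c if rng.random() < 0.85 else "ACGT"[rng.integers(4)]
                    for c in cons]
            rows.append(toks)
        ph = build_profile_hmm(rows, DNA)
        null = ps.DiscreteIid(DNA, [0.25] * 4)
        fam, shuf = [], []
        for _ in range(30):
            seq = ph.simulate(rng=rng)
            if len(seq) == 0:
                continue
            fam.append(ph.log_probability(seq) - null.log_probability(seq))
            perm = rng.permutation(len(seq))
            sh = Sequence("sh", seq.values[perm], DNA)
            shuf.append(ph.log_probability(sh) - null.log_probability(sh))
        assert np.mean(fam) > np.mean(shuf)


def simple_pair_hmm(match_bonus=0.7):
    e_match = np.full((4, 4), (1 - match_bonus) / 12.0)
    np.fill_diagonal(e_match, match_bonus / 4.0)
    gap = np.full(4, 0.25)
    return PairHmm(
        DNA, ["M", "X", "Y"], ["match", "x", "y"],
        [0.9, 0.05, 0.05],
        [[0.79, 0.05, 0.06], [0.6, 0.25, 0.05], [0.6, 0.05, 0.25]],
        [0.10, 0.10, 0.10],
        [e_match, gap, gap])


class TestPairHmm:
    def test_identical_sequences_align_all_match(self):
        pair = simple_pair_hmm()
        s = encode(list("ACGT"), DNA)
        r1, r2, states, _ = pair.pair_viterbi(s, s)
        assert states == ["M"] * 4
        assert "".join(r1) == "ACGT" and "".join(r2) == "ACGT"

    def test_forward_and_viterbi_match_enumeration(self, rng):
        pair = simple_pair_hmm()
        for _ in range(6):
            s1 = random_sequence(rng, int(rng.integers(1, 5)))
            s2 = random_sequence(rng, int(rng.integers(1, 5)))
            assert pair.pair_forward(s1, s2) == pytest.approx(
                oracles.enumerate_pair_forward(pair, s1, s2), abs=1e-9)
            _, _, _, vll = pair.pair_viterbi(s1, s2)
            assert vll == pytest.approx(
                oracles.enumerate_pair_viterbi(pair, s1, s2), abs=1e-9)

    def test_forward_at_least_viterbi(self, rng):
        pair = simple_pair_hmm()
        for _ in range(10):
            s1 = random_sequence(rng, int(rng.integers(1, 6)))
            s2 = random_sequence(rng, int(rng.integers(1, 6)))
            assert pair.pair_forward(s1, s2) >= pair.pair_viterbi(s1, s2)[3] - 1e-12

    def test_empty_sequence_pure_gap_path(self):
        pair = simple_pair_hmm()
        s1 = encode(list("AC"), DNA)
        empty = encode((), DNA)
        r1, r2, states, ll = pair.pair_viterbi(s1, empty)
        assert states == ["X", "X"] and "".join(r2) == "--"
        assert ll > ps.NEG_INF

    def test_alignment_consumes_both_sequences(self, rng):
        pair = simple_pair_hmm()
        s1 = random_sequence(rng, 5)
        s2 = random_sequence(rng, 3)
        r1, r2, _, _ = pair.pair_viterbi(s1, s2)
        assert [c for c in r1 if c != "-"] == s1.tokens()
        assert [c for c in r2 if c != "-"] == s2.tokens()
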