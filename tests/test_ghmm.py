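"""Duration models, prefix sum arrays, and GHMM decoding against oracles."""

import math

import numpy as np
import pytest

import probseq as ps
from probseq import DNA, Sequence
from probseq.ghmm import (
    CompositeEmission,
    FixedDuration,
    GeometricDuration,
    Ghmm,
    GhmmState,
    HistogramDuration,
    ReverseComplementModel,
    SmoothedHistogram,
    ghmm_simulate,
    ghmm_viterbi,
    ghmm_viterbi_naive,
    path_log_likelihood,
    plan_decoding,
    train_smoothed_histogram,
)

from conftest import random_distribution, random_iid, random_markov, random_sequence
import oracles


class TestSmoothedHistogram:
    def test_tiny_bandwidth_concentrates(self):
        hist = train_smoothed_histogram([100] * 20, bandwidth=0.05)
        assert hist.probs[99] == pytest.approx(1.0, abs=1e-9)
        assert hist.max_duration == 150

    def test_sums_to_one(self, rng):
        lengths = rng.integers(5, 60, size=200)
        hist = train_smoothed_histogram(lengths)
        assert hist.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mean_recovery_from_discretised_normal(self, rng):
        lengths = np.clip(np.round(rng.normal(300, 50, size=500)), 1, None).astype(int)
        hist = train_smoothed_histogram(lengths)
        assert abs(hist.mean() - 300) / 300 < 0.05

    def test_empty_input(self):
        with pytest.raises(ValueError):
            train_smoothed_histogram([])


class TestDurationModels:
    def test_fixed_is_singleton_histogram(self):
        fd = FixedDuration(27)
        assert fd.support().tolist() == [27]
        assert fd.log_pmf().tolist() == [0.0]

    def test_phase_restriction_filters_support(self):
        probs = np.ones(30) / 30
        dur = HistogramDuration(SmoothedHistogram(probs)).restrict_phase(1, 0)
        assert all(d % 3 == 2 for d in dur.support())
        assert math.exp(
            float(np.logaddexp.reduce(dur.log_pmf()))) == pytest.approx(1.0, abs=1e-9)

    def test_geometric_sampling_mean(self, rng):
        q = 0.9
        dur = GeometricDuration(q)
        samples = [dur.sample(rng) for _ in range(10_000)]
        assert abs(np.mean(samples) - 1 / (1 - q)) / (1 / (1 - q)) < 0.05


class TestBuildValidation:
    def test_two_state_cpg_is_geometric(self, rng):
        g = ps.build_cpg_ghmm(random_iid(rng), random_iid(rng), 0.01, 100)
        assert g.n_states == 2
        assert g.is_geometric.all()

    def test_unnormalised_row_rejected(self, rng):
        states = [GhmmState("A", random_iid(rng), None, {"A": 0.9})]
        with pytest.raises(ValueError, match="sums to 0.9"):
            Ghmm(states, {"A": 1.0})

    def test_unknown_destination_rejected(self, rng):
        states = [GhmmState("A", random_iid(rng), None, {"A": 0.5, "Z": 0.5})]
        with pytest.raises(ValueError, match="unknown state 'Z'"):
            Ghmm(states, {"A": 1.0})

    def test_geometric_needs_factorable_emission(self, rng):
        wam = ps.train_wam([random_sequence(rng, 3) for _ in range(4)], 3, 0)
        states = [GhmmState("A", wam, None, {"A": 0.5, "B": 0.5}),
                  GhmmState("B", random_iid(rng), None, {"B": 1.0})]
        with pytest.raises(ValueError, match="factorable"):
            Ghmm(states, {"A": 1.0})

    def test_composite_length_mismatch_rejected(self, rng):
        parts = [ps.train_wam([random_sequence(rng, w) for _ in range(4)], w, 0)
                 for w in (20, 3, 4)]
        comp = CompositeEmission(parts)
        st = [GhmmState("S", comp, FixedDuration(26), {"T": 1.0}),
              GhmmState("T", random_iid(rng), None, {"T": 1.0})]
        with pytest.raises(ValueError, match="26"):
            Ghmm(st, {"S": 1.0})
        st[0].duration = FixedDuration(27)
        assert Ghmm(st, {"S": 1.0}).n_states == 2

    def test_explicit_state_forbids_self_transition(self, rng):
        st = [GhmmState("A", random_iid(rng), FixedDuration(2),
                        {"A": 0.5, "B": 0.5}),
              GhmmState("B", random_iid(rng), None, {"B": 1.0})]
        with pytest.raises(ValueError, match="self-transition"):
            Ghmm(st, {"A": 1.0})


class TestDecodingPlan:
    def test_plan_classifies_states(self, rng):
        hist = HistogramDuration(SmoothedHistogram(np.ones(50) / 50))
        states = [
            GhmmState("geo", random_iid(rng), None, {"geo": 0.8, "fix": 0.2}),
            GhmmState("fix", random_iid(rng), FixedDuration(27), {"geo": 1.0}),
            GhmmState("his", random_iid(rng), hist, {"geo": 1.0}),
        ]
        g = Ghmm(states, {"geo": 1.0})
        plan = plan_decoding(g)
        by_name = {sp.name: sp for sp in plan.states}
        assert by_name["geo"].geometric and by_name["geo"].support is None
        assert by_name["fix"].support.tolist() == [27]
        assert by_name["his"].max_duration == 50
        assert plan.max_duration == 50


class TestPrefixSumArray:
    def test_iid_lookup_closed_form(self, rng):
        model = ps.DiscreteIid(DNA, [0.4, 0.3, 0.2, 0.1])
        seq = random_sequence(rng, 20)
        psa = ps.build_psa(model, seq)
        expected = sum(math.log(model.probs[v]) for v in seq.values[4:10])
        assert psa.lookup(4, 9) == pytest.approx(expected, abs=1e-9)

    def test_exhaustive_windows_order2(self, rng):
        model = random_markov(rng, 2)
        seq = model.simulate(50, rng)
        psa = ps.build_psa(model, seq)
        for i in range(50):
            for j in range(i, 50):
                assert psa.lookup(i, j) == pytest.approx(
                    model.log_probability(seq, i + 1, j + 1), abs=1e-9)

    def test_three_periodic_phases(self, rng):
        imm = ps.train_imm([random_iid(rng).simulate(2000, rng)], 2, periodicity=3)
        seq = random_sequence(rng, 40)
        psa = ps.build_psa(imm, seq)
        for i in range(0, 40, 3):
            for j in range(i, min(i + 12, 40)):
                for ph in range(3):
                    assert psa.lookup(i, j, ph) == pytest.approx(
                        imm.log_probability(seq, i + 1, j + 1, phase=ph), abs=1e-9)
        # frame-shifted lookups differ
        assert psa.lookup(3, 20, 0) != psa.lookup(3, 20, 1)

    def test_zero_probability_windows(self, rng):
        model = ps.DiscreteIid(DNA, [0.5, 0.5, 0.0, 0.0])
        seq = ps.encode(list("ACGCA"), DNA)
        psa = ps.build_psa(model, seq)
        assert psa.lookup(0, 1) > ps.NEG_INF
        assert psa.lookup(1, 3) == ps.NEG_INF

    def test_reverse_complement_delegation(self, rng):
        model = random_markov(rng, 1)
        rc = ReverseComplementModel(model)
        seq = random_sequence(rng, 25)
        psa = ps.build_psa(rc, seq)
        for i in range(0, 25, 2):
            for j in range(i, 25, 3):
                assert psa.lookup(i, j) == pytest.approx(
                    rc.log_probability(seq, i + 1, j + 1), abs=1e-9)

    def test_non_factorable_rejected(self, rng):
        wam = ps.train_wam([random_sequence(rng, 3) for _ in range(4)], 3, 0)
        with pytest.raises(ValueError, match="factorable"):
            ps.build_psa(wam, random_sequence(rng, 10))


def random_small_ghmm(rng):
    """Random 3-state GHMM mixing geometric / fixed / histogram durations."""
    iid = random_iid(rng)
    mc = random_markov(rng, 1)
    wam = ps.PositionalChain(
        DNA, [random_distribution(rng, 4).reshape(1, 4),
              np.vstack([random_distribution(rng, 4) for _ in range(4)])])
    hist = HistogramDuration(SmoothedHistogram(random_distribution(rng, 5)))
    q = 0.3 + 0.5 * rng.random()
    states = [
        GhmmState("A", iid, None, {"A": q, "B": (1 - q) / 2, "C": (1 - q) / 2}),
        GhmmState("B", wam, FixedDuration(2), {"A": 0.6, "C": 0.4}),
        GhmmState("C", mc if rng.random() < 0.5 else ReverseComplementModel(mc),
                  hist, {"A": 0.5, "B": 0.5}),
    ]
    return Ghmm(states, {"A": 0.4, "B": 0.3, "C": 0.3})


class TestGhmmViterbi:
    def test_single_geometric_state(self, rng):
        iid = random_iid(rng)
        g = Ghmm([GhmmState("only", iid, None, {"only": 1.0})], {"only": 1.0})
        seq = random_sequence(rng, 12)
        seg = ghmm_viterbi(g, seq)
        assert seg.segments == [("only", 1, 12)]
        expected = iid.log_probability(seq)  # self-transitions have prob 1
        assert seg.log_likelihood == pytest.approx(expected, abs=1e-9)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(8):
            g = random_small_ghmm(rng)
            seq = random_sequence(rng, int(rng.integers(4, 11)))
            seg = ghmm_viterbi(g, seq)
            best = oracles.best_segmentation_score(g, seq)
            assert seg.log_likelihood == pytest.approx(best, abs=1e-9)
            assert path_log_likelihood(g, seq, seg) == pytest.approx(
                seg.log_likelihood, abs=1e-9)

    def test_optimized_equals_naive_on_random_instances(self, rng):
        for _ in range(40):
            g = random_small_ghmm(rng)
            seq, _ = ghmm_simulate(g, int(rng.integers(8, 25)), rng)
            opt = ghmm_viterbi(g, seq)
            naive = ghmm_viterbi_naive(g, seq)
            assert opt.log_likelihood == pytest.approx(naive.log_likelihood, abs=1e-9)
            assert opt.segments == naive.segments

    def test_plan_does_not_change_result(self, rng):
        g = random_small_ghmm(rng)
        seq, _ = ghmm_simulate(g, 20, rng)
        assert ghmm_viterbi(g, seq, plan_decoding(g)).segments == \
            ghmm_viterbi(g, seq, None).segments

    def test_impossible_sequence(self):
        iid = ps.DiscreteIid(DNA, [1.0, 0.0, 0.0, 0.0])
        g = Ghmm([GhmmState("a", iid, None, {"a": 1.0})], {"a": 1.0})
        seg = ghmm_viterbi(g, ps.encode(list("AC"), DNA))
        assert seg.segments == [] and seg.log_likelihood == ps.NEG_INF

    def test_all_geometric_equals_classical_hmm(self, rng):
        from probseq.hmm import Hmm

        K = 3
        pi = random_distribution(rng, K)
        A = np.vstack([random_distribution(rng, K) for _ in range(K)])
        E = np.vstack([random_distribution(rng, 4) for _ in range(K)])
        names = ["s%d" % i for i in range(K)]
        h = Hmm(DNA, names, pi, A, E)
        states = [GhmmState(names[i], ps.DiscreteIid(DNA, E[i]), None,
                            {names[j]: A[i, j] for j in range(K)})
                  for i in range(K)]
        g = Ghmm(states, {names[i]: pi[i] for i in range(K)})
        for _ in range(10):
            seq = random_sequence(rng, int(rng.integers(5, 30)))
            hpath, hll = h.viterbi(seq)
            seg = ghmm_viterbi(g, seq)
            assert seg.log_likelihood == pytest.approx(hll, abs=1e-9)
            flat = seg.state_per_position()
            assert flat == hpath

    def test_cpg_recovery_from_own_simulation(self, rng):
        # strongly separated order-1 interpolated chains
        cpg_train = [ps.encode(list("CG" * 400), DNA)]
        bg_train = [ps.encode(list("AT" * 300 + "AATT" * 100), DNA)]
        cpg = ps.train_imm(cpg_train, 1)
        bg = ps.train_imm(bg_train, 1)
        g = ps.build_cpg_ghmm(cpg, bg, p_exit_noncpg=0.01, mean_cpg_len=100)
        seq, true_seg = ghmm_simulate(g, 4000, rng)
        decoded = ghmm_viterbi(g, seq)
        assert ps.position_accuracy(true_seg, decoded) >= 0.95


class TestGhmmSimulate:
    def test_fixed_duration_chain_exact_lengths(self, rng):
        iid = random_iid(rng)
        states = [
            GhmmState("a", iid, FixedDuration(4), {"b": 1.0}),
            GhmmState("b", iid, FixedDuration(3), {"a": 1.0}),
        ]
        g = Ghmm(states, {"a": 1.0})
        _, seg = ghmm_simulate(g, 14, rng)
        assert seg.segments == [("a", 1, 4), ("b", 5, 7), ("a", 8, 11), ("b", 12, 14)]

    def test_geometric_mean_duration(self, rng):
        q = 0.8
        iid = random_iid(rng)
        states = [GhmmState("a", iid, None, {"a": q, "b": 1 - q}),
                  GhmmState("b", iid, None, {"b": q, "a": 1 - q})]
        g = Ghmm(states, {"a": 1.0})
        durs = []
        _, seg = ghmm_simulate(g, 50_000, rng)
        durs = [e - b + 1 for _n, b, e in list(seg)[:-1]]  # last is truncated
        assert abs(np.mean(durs) - 1 / (1 - q)) / (1 / (1 - q)) < 0.05

    def test_seed_reproducibility(self, rng):
        g = random_small_ghmm(rng)
        s1, seg1 = ghmm_simulate(g, 50, np.random.default_rng(42))
        s2, seg2 = ghmm_simulate(g, 50, np.random.default_rng(42))
        assert s1 == s2 and seg1.segments == seg2.segments
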