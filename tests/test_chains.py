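"""Training and scoring of the factorable and signal emission families."""

import itertools
import math

import numpy as np
import pytest

import probseq as ps
from probseq import DNA, Sequence, encode
from probseq.chains import IMM_COUNT_THRESHOLD

from conftest import random_iid, random_markov


def seqs_from(*texts):
    return [encode(list(t), DNA, name="t%d" % i) for i, t in enumerate(texts)]


class TestIid:
    def test_counting(self):
        model = ps.train_iid(seqs_from("AACG"), pseudocount=0.0)
        assert model.probs.tolist() == [0.5, 0.25, 0.25, 0.0]

    def test_pseudocount_only_gives_uniform(self):
        model = ps.train_iid([Sequence("e", [], DNA)], pseudocount=1.0)
        assert np.allclose(model.probs, 0.25)

    def test_empty_with_zero_pseudocount_errors(self):
        with pytest.raises(ValueError):
            ps.train_iid([Sequence("e", [], DNA)], pseudocount=0.0)

    def test_recovery(self, rng):
        p = np.array([0.7, 0.1, 0.1, 0.1])
        seq = ps.DiscreteIid(DNA, p).simulate(10_000, rng)
        est = ps.train_iid([seq])
        assert np.abs(est.probs - p).max() < 0.02


class TestMarkov:
    def test_order0_equals_iid(self, rng):
        train = [random_iid(rng).simulate(500, rng)]
        mc = ps.train_markov(train, 0)
        iid = ps.train_iid(train)
        assert np.allclose(mc.tables[0][0], iid.probs)

    def test_deterministic_alternation(self):
        mc = ps.train_markov(seqs_from("AC" * 50), 1, pseudocount=0.0)
        assert mc.tables[1][DNA.index("A"), DNA.index("C")] == pytest.approx(1.0)
        assert mc.tables[1][DNA.index("C"), DNA.index("A")] == pytest.approx(1.0)

    def test_order2_recovery(self, rng):
        truth = random_markov(rng, 2)
        seq = truth.simulate(100_000, rng)
        est = ps.train_markov([seq], 2)
        assert np.abs(est.tables[2] - truth.tables[2]).max() < 0.02

    def test_rows_normalised(self, rng):
        mc = ps.train_markov([random_iid(rng).simulate(200, rng)], 2)
        for tab in mc.tables:
            assert np.allclose(tab.sum(axis=1), 1.0, atol=1e-9)


class TestVlmc:
    def test_infinite_cut_prunes_to_root(self, rng):
        train = [random_iid(rng).simulate(400, rng)]
        tree = ps.train_vlmc(train, 3, math.inf)
        assert set(tree.nodes) == {()}
        iid = ps.train_iid(train)
        assert np.allclose(tree.nodes[()], iid.probs)

    def test_zero_cut_keeps_full_tree(self, rng):
        train = [random_iid(rng).simulate(400, rng)]
        tree = ps.train_vlmc(train, 2, 0.0)
        assert len(tree.nodes) == 1 + 4 + 16

    def test_zero_cut_equals_fixed_order_likelihood(self, rng):
        train = [random_markov(rng, 2).simulate(5_000, rng)]
        held = [random_markov(rng, 2).simulate(300, rng) for _ in range(3)]
        tree = ps.train_vlmc(train, 2, 0.0)
        chain = ps.train_markov(train, 2)
        for s in held:
            assert tree.log_probability(s) == pytest.approx(
                chain.log_probability(s), abs=1e-9)

    def test_recovers_true_contexts(self, rng):
        # VLMC with contexts {A, C<-A (written 'CA' most-recent-first), rest}:
        # next-symbol law depends on the previous symbol, and for a previous A
        # also on the symbol before it.
        pA_after = {0: [0.9, 0.05, 0.03, 0.02], 1: [0.05, 0.9, 0.03, 0.02]}
        other = [0.25, 0.25, 0.25, 0.25]
        deep = [0.02, 0.03, 0.05, 0.9]
        vals = [0, 1]
        g = np.random.default_rng(4)
        for _ in range(100_000):
            prev, prev2 = vals[-1], vals[-2]
            if prev == 0:  # previous symbol A: depends on prev2
                probs = pA_after[0] if prev2 == 1 else deep
            elif prev == 1:
                probs = other
            else:
                probs = pA_after[1]
            vals.append(int(g.choice(4, p=np.array(probs) / np.sum(probs))))
        train = [Sequence("x", vals, DNA)]
        grid = [0.5, 2.0, 8.0, 32.0, 128.0]
        res = ps.select_model(
            lambda cut, seqs: ps.train_vlmc(seqs, 2, cut), grid, train, "bic")
        tree = res.model
        # depth-2 contexts must survive only under the A branch
        depth2 = {c for c in tree.nodes if len(c) == 2}
        assert depth2 and all(c[0] == 0 for c in depth2)
        assert (1,) in tree.nodes and len([c for c in tree.nodes if len(c) == 1]) == 4


class TestWam:
    def test_manual_start_codon(self):
        wam = ps.train_wam(seqs_from("ATG", "ATG", "ATG"), 3, 0, pseudocount=0.0)
        assert wam.log_probability(encode(list("ATG"), DNA)) == pytest.approx(0.0)
        assert wam.log_probability(encode(list("ATC"), DNA)) == ps.NEG_INF

    def test_positionwise_split(self):
        wam = ps.train_wam(seqs_from("AA", "AC"), 2, 0, pseudocount=0.0)
        assert wam.tables[1][0, DNA.index("A")] == pytest.approx(0.5)
        assert wam.tables[1][0, DNA.index("C")] == pytest.approx(0.5)

    def test_length_mismatch_names_record(self):
        bad = seqs_from("ATG", "ATGA")
        with pytest.raises(ValueError, match="t1"):
            ps.train_wam(bad, 3, 0)

    def test_windowed_recovery(self, rng):
        # branch-point-like data: one position with a strong bias, neighbours
        # share statistics through the pooling window
        W = 9
        rows = [np.full(4, 0.25) for _ in range(W)]
        for u in (3, 4, 5):
            rows[u] = np.array([0.05, 0.8, 0.1, 0.05])
        pats = []
        for i in range(4000):
            vals = [int(rng.choice(4, p=r)) for r in rows]
            pats.append(Sequence("p%d" % i, vals, DNA))
        wam = ps.train_windowed_wam(pats, W, order=0, window=1)
        assert abs(wam.tables[4][0, 1] - 0.8) < 0.03


class TestImm:
    def test_order0_equals_iid(self, rng):
        train = [random_iid(rng).simulate(300, rng)]
        imm = ps.train_imm(train, 0)
        iid = ps.train_iid(train)
        assert np.allclose(imm.phase_tables[0][0], iid.probs[None, :])

    def test_rich_context_gets_full_weight(self, rng):
        seq = random_markov(rng, 1).simulate(30_000, rng)
        imm = ps.train_imm([seq], 1)
        counts = np.bincount(seq.values[:-1], minlength=4)
        lam = imm.lambdas[0][1]
        for ctx in range(4):
            if counts[ctx] >= IMM_COUNT_THRESHOLD:
                assert lam[ctx] == 1.0

    def test_full_weight_reduces_to_markov(self, rng):
        seq = random_markov(rng, 1).simulate(200_000, rng)
        imm = ps.train_imm([seq], 1)
        mc = ps.train_markov([seq], 1)
        if np.all(imm.lambdas[0][1] == 1.0):
            assert np.allclose(imm.phase_tables[0][1], mc.tables[1])

    def test_three_periodic_frame_discrimination(self, rng):
        phase_probs = [np.array([0.1, 0.2, 0.6, 0.1]),
                       np.array([0.5, 0.2, 0.2, 0.1]),
                       np.array([0.1, 0.5, 0.2, 0.2])]
        def sample_cds(n):
            return Sequence("cds", [int(rng.choice(4, p=phase_probs[t % 3]))
                                    for t in range(n)], DNA)
        imm = ps.train_imm([sample_cds(30_000)], 2, periodicity=3)
        test = sample_cds(3_000)
        lls = [imm.log_probability(test, phase=ph) for ph in range(3)]
        assert int(np.argmax(lls)) == 0

    def test_interpolated_rows_normalised(self, rng):
        imm = ps.train_imm([random_iid(rng).simulate(2_000, rng)], 2, 3)
        for tabs in imm.phase_tables:
            for tab in tabs:
                assert np.allclose(tab.sum(axis=1), 1.0, atol=1e-9)


class TestSbsw:
    def make(self, epsilon=1e-3):
        pats = seqs_from("AAGTC", "ACGTC", "AAGTG")
        return ps.train_sbsw(pats, skip_offset=2, skip_sequence=("G", "T"),
                             epsilon=epsilon)

    def test_training_pattern_scores_highest(self):
        model = self.make()
        best = model.log_probability(encode(list("AAGTC"), DNA))
        for tup in itertools.product("ACGT", repeat=3):
            q = tup[0] + tup[1] + "GT" + tup[2]
            assert model.log_probability(encode(list(q), DNA)) <= best + 1e-12

    def test_missing_skip_sequence_is_impossible(self):
        model = self.make()
        assert model.log_probability(encode(list("AACTC"), DNA)) == ps.NEG_INF

    def test_training_pattern_without_skip_rejected(self):
        with pytest.raises(ValueError, match="t1"):
            ps.train_sbsw(seqs_from("AAGTC", "AACTC"), 2, ("G", "T"))

    def test_scores_match_bruteforce_enumeration(self):
        model = self.make(epsilon=0.001)
        counts = {("A", "A", "C"): 1, ("A", "C", "C"): 1, ("A", "A", "G"): 1}
        eps = 0.001
        total_check = 0.0
        for tup in itertools.product("ACGT", repeat=3):
            numer = counts.get(tup, 0)
            for pos in range(3):
                for sym in "ACGT":
                    if sym == tup[pos]:
                        continue
                    neigh = tup[:pos] + (sym,) + tup[pos + 1:]
                    numer += eps * counts.get(neigh, 0)
            expected = numer / (3 * (1 + eps * 3 * 3))
            q = tup[0] + tup[1] + "GT" + tup[2]
            got = model.log_probability(encode(list(q), DNA))
            if expected == 0:
                assert got == ps.NEG_INF
            else:
                assert got == pytest.approx(math.log(expected), abs=1e-12)
            total_check += expected
        assert total_check == pytest.approx(1.0, abs=1e-9)

    def test_distribution_sums_to_one_w8(self, rng):
        pats = []
        for i in range(5):
            left = rng.integers(0, 4, size=3).tolist()
            right = rng.integers(0, 4, size=3).tolist()
            pats.append(Sequence("p%d" % i, left + [2, 3] + right, DNA))
        model = ps.train_sbsw(pats, 3, ("G", "T"), epsilon=0.01)
        total = 0.0
        for tup in itertools.product(range(4), repeat=6):
            window = list(tup[:3]) + [2, 3] + list(tup[3:])
            ll = model.log_probability(Sequence("q", window, DNA))
            if ll > ps.NEG_INF:
                total += math.exp(ll)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_simulation_matches_scores(self, rng):
        model = self.make(epsilon=0.05)
        draws = {}
        for _ in range(20_000):
            s = str(model.simulate(rng=rng))
            draws[s] = draws.get(s, 0) + 1
        for s, c in sorted(draws.items(), key=lambda kv: -kv[1])[:3]:
            p = math.exp(model.log_probability(encode(list(s), DNA)))
            assert abs(c / 20_000 - p) < 0.02
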