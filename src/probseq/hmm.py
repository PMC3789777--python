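"""Hidden Markov models: forward/backward/Viterbi/posterior decoding and
Baum-Welch training, profile-HMM construction from multiple alignments, and
pair-HMMs for two-sequence alignment.

All dynamic programming is done in natural-log space with log-sum-exp, so no
scaling vectors are needed and zero probabilities are exact (-inf).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from scipy.special import logsumexp

from .core import (
    NEG_INF,
    Alphabet,
    Sequence,
    SequenceModel,
    as_rng,
    log_array,
)
from .chains import sample_categorical

__all__ = [
    "Hmm",
    "ProfileHmm",
    "PairHmm",
    "baum_welch",
    "build_profile_hmm",
]


def _lse(x: np.ndarray, axis: int) -> np.ndarray:
    """Log-sum-exp along an axis, -inf-safe and cheaper than the scipy call
    inside the per-position recursions."""
    m = x.max(axis=axis)
    safe = np.where(np.isfinite(m), m, 0.0)
    out = safe + np.log(np.exp(x - np.expand_dims(safe, axis)).sum(axis=axis))
    return np.where(np.isfinite(m), out, NEG_INF)


def _check_dist(name: str, p: np.ndarray, tol: float = 1e-6) -> None:
    if np.any(np.asarray(p) < -tol) or abs(float(np.sum(p)) - 1.0) > tol:
        raise ValueError("%s must be a probability distribution (sum %.6f)"
                         % (name, float(np.sum(p))))


class Hmm(SequenceModel):
    """Classical discrete-emission hidden Markov model.

    Parameters are the initial distribution pi, the K x K transition matrix A
    and the K x |Σ| emission table E; all rows must be normalised.
    """

    family = "hmm"

    def __init__(self, alphabet: Alphabet, state_names, initial, transitions, emissions):
        self.alphabet = alphabet
        self.state_names = list(state_names)
        K, a = len(self.state_names), len(alphabet)
        self.initial = np.asarray(initial, dtype=float)
        self.transitions = np.asarray(transitions, dtype=float)
        self.emissions = np.asarray(emissions, dtype=float)
        if self.initial.shape != (K,) or self.transitions.shape != (K, K) \
                or self.emissions.shape != (K, a):
            raise ValueError("parameter shapes inconsistent with %d states / %d symbols"
                             % (K, a))
        _check_dist("initial distribution", self.initial)
        for i in range(K):
            _check_dist("transition row %r" % self.state_names[i], self.transitions[i])
            _check_dist("emission row %r" % self.state_names[i], self.emissions[i])
        self.log_pi = log_array(self.initial)
        self.log_A = log_array(self.transitions)
        self.log_E = log_array(self.emissions)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    # -- decoding -----------------------------------------------------------

    def forward(self, seq: Sequence):
        """Return (total log-likelihood, alpha table of shape (L, K))."""
        v = seq.values
        L, K = len(v), self.n_states
        alpha = np.full((L, K), NEG_INF)
        alpha[0] = self.log_pi + self.log_E[:, v[0]]
        for t in range(1, L):
            alpha[t] = _lse(alpha[t - 1][:, None] + self.log_A, axis=0) \
                + self.log_E[:, v[t]]
        return float(logsumexp(alpha[-1])), alpha

    def backward(self, seq: Sequence):
        """Return (total log-likelihood, beta table of shape (L, K))."""
        v = seq.values
        L, K = len(v), self.n_states
        beta = np.full((L, K), NEG_INF)
        beta[-1] = 0.0
        for t in range(L - 2, -1, -1):
            beta[t] = _lse(self.log_A + (self.log_E[:, v[t + 1]] + beta[t + 1])[None, :],
                           axis=1)
        total = float(logsumexp(self.log_pi + self.log_E[:, v[0]] + beta[0]))
        return total, beta

    def viterbi(self, seq: Sequence):
        """Return (best state-name path, best joint log-likelihood).

        Ties are broken towards the lowest state index at every argmax, which
        makes the decoded path deterministic.  An impossible sequence yields
        ([], -inf).
        """
        v = seq.values
        L, K = len(v), self.n_states
        V = np.full((L, K), NEG_INF)
        ptr = np.zeros((L, K), dtype=np.int64)
        V[0] = self.log_pi + self.log_E[:, v[0]]
        for t in range(1, L):
            scores = V[t - 1][:, None] + self.log_A  # (from, to)
            ptr[t] = np.argmax(scores, axis=0)
            V[t] = scores[ptr[t], np.arange(K)] + self.log_E[:, v[t]]
        best = int(np.argmax(V[-1]))
        loglik = float(V[-1, best])
        if loglik == NEG_INF:
            return [], NEG_INF
        path = [best]
        for t in range(L - 1, 0, -1):
            path.append(int(ptr[t, path[-1]]))
        path.reverse()
        return [self.state_names[k] for k in path], loglik

    def posterior_decode(self, seq: Sequence):
        """Per-position state posteriors (L, K) and the per-position argmax path."""
        total_f, alpha = self.forward(seq)
        if total_f == NEG_INF:
            raise ValueError("sequence has probability zero under the model")
        _, beta = self.backward(seq)
        post = np.exp(alpha + beta - total_f)
        post /= post.sum(axis=1, keepdims=True)
        path = [self.state_names[int(k)] for k in np.argmax(post, axis=1)]
        return post, path

    # -- model contract -----------------------------------------------------

    def log_probability(self, seq: Sequence, begin: int = 1, end: int | None = None) -> float:
        begin, end = self._check_window(seq, begin, end)
        window = Sequence(seq.name, seq.values[begin - 1:end], seq.alphabet)
        return self.forward(window)[0]

    def simulate_with_path(self, length: int, rng=None, name: str = "sim"):
        if length < 1:
            raise ValueError("simulation length must be >= 1")
        rng = as_rng(rng)
        states, symbols = [], []
        k = sample_categorical(self.initial, rng)
        for t in range(length):
            if t:
                k = sample_categorical(self.transitions[k], rng)
            states.append(k)
            symbols.append(sample_categorical(self.emissions[k], rng))
        return (Sequence(name, symbols, self.alphabet),
                [self.state_names[k] for k in states])

    def simulate(self, length: int, rng=None, name: str = "sim") -> Sequence:
        return self.simulate_with_path(length, rng, name)[0]

    def parameter_count(self) -> int:
        K, a = self.n_states, len(self.alphabet)
        return K * (K - 1) + K * (a - 1) + (K - 1)


def baum_welch(hmm0: Hmm, seqs: Iterable[Sequence], max_iter: int = 100,
               tol: float = 1e-6, pseudocount: float = 0.0):
    """Expectation-maximisation training of an HMM.

    Returns ``(trained Hmm, log-likelihood trace)``; the trace is
    non-decreasing (up to 1e-10) and iteration stops when the improvement
    drops below ``tol`` or after ``max_iter`` rounds.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty training set")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    hmm = hmm0
    trace: list[float] = []
    K, a = hmm0.n_states, len(hmm0.alphabet)
    for _ in range(max_iter):
        pi_acc = np.zeros(K)
        A_acc = np.zeros((K, K))
        E_acc = np.zeros((K, a))
        total = 0.0
        for s in seqs:
            v = s.values
            ll, alpha = hmm.forward(s)
            if ll == NEG_INF:
                raise ValueError("training sequence %r has probability zero" % s.name)
            _, beta = hmm.backward(s)
            total += ll
            gamma = np.exp(alpha + beta - ll)  # (L, K)
            pi_acc += gamma[0]
            np.add.at(E_acc.T, v, gamma)
            if len(v) > 1:
                emit_next = hmm.log_E[:, v[1:]].T + beta[1:]  # (L-1, K)
                xi = np.exp(alpha[:-1, :, None] + hmm.log_A[None, :, :]
                            + emit_next[:, None, :] - ll)
                A_acc += xi.sum(axis=0)
        trace.append(total)
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            break
        pi_new = (pi_acc + pseudocount) / (pi_acc + pseudocount).sum()
        A_new = (A_acc + pseudocount) / (A_acc + pseudocount).sum(axis=1, keepdims=True)
        E_new = (E_acc + pseudocount) / (E_acc + pseudocount).sum(axis=1, keepdims=True)
        hmm = Hmm(hmm.alphabet, hmm.state_names, pi_new, A_new, E_new)
    return hmm, trace


# ---------------------------------------------------------------------------
# profile HMMs
# ---------------------------------------------------------------------------

GAP = "-"


class ProfileHmm(SequenceModel):
    """Profile HMM with match/insert/delete layers and begin/end states.

    Full match/insert/delete connectivity (including I->D and D->I) in the
    style of Durbin et al.; delete states are silent.  Scoring is global:
    :meth:`log_probability` is the forward total over all begin-to-end paths.
    """

    family = "profile-hmm"

    def __init__(self, alphabet: Alphabet, M: int, match_emissions, insert_emissions,
                 trans: dict[str, np.ndarray]):
        # trans keys "MM","MI","MD","IM","II","ID","DM","DD","DI"; index i is
        # the source layer index (M_i/I_i at i = 0..M, D_i at i = 1..M).
        self.alphabet = alphabet
        self.M = M
        self.match_emissions = np.asarray(match_emissions, dtype=float)   # (M+1, A), row 0 unused
        self.insert_emissions = np.asarray(insert_emissions, dtype=float)  # (M+1, A)
        self.trans = {k: np.asarray(v, dtype=float) for k, v in trans.items()}
        self._lmE = log_array(self.match_emissions)
        self._liE = log_array(self.insert_emissions)
        self._lt = {k: log_array(v) for k, v in self.trans.items()}

    def _forward(self, seq: Sequence) -> float:
        v = seq.values
        L, M = len(v), self.M
        lt = self._lt
        # column j = number of symbols consumed; layers M 0..M, I 0..M, D 1..M
        vM = np.full(M + 1, NEG_INF)
        vI = np.full(M + 1, NEG_INF)
        vD = np.full(M + 1, NEG_INF)
        vM[0] = 0.0
        for i in range(1, M + 1):
            parts = [vM[i - 1] + lt["MD"][i - 1]]
            if i >= 2:
                parts.append(vD[i - 1] + lt["DD"][i - 1])
            parts.append(vI[i - 1] + lt["ID"][i - 1])
            vD[i] = logsumexp(parts)
        for j in range(1, L + 1):
            s = v[j - 1]
            nM = np.full(M + 1, NEG_INF)
            nI = np.full(M + 1, NEG_INF)
            nD = np.full(M + 1, NEG_INF)
            for i in range(1, M + 1):
                parts = [vM[i - 1] + lt["MM"][i - 1], vI[i - 1] + lt["IM"][i - 1]]
                if i >= 2:
                    parts.append(vD[i - 1] + lt["DM"][i - 1])
                nM[i] = logsumexp(parts) + self._lmE[i, s]
            for i in range(0, M + 1):
                parts = [vM[i] + lt["MI"][i], vI[i] + lt["II"][i]]
                if i >= 1:
                    parts.append(vD[i] + lt["DI"][i])
                nI[i] = logsumexp(parts) + self._liE[i, s]
            for i in range(1, M + 1):
                parts = [nM[i - 1] + lt["MD"][i - 1], nI[i - 1] + lt["ID"][i - 1]]
                if i >= 2:
                    parts.append(nD[i - 1] + lt["DD"][i - 1])
                nD[i] = logsumexp(parts)
            vM, vI, vD = nM, nI, nD
        end_parts = [vM[M] + lt["MM"][M], vI[M] + lt["IM"][M], vD[M] + lt["DM"][M]]
        return float(logsumexp(end_parts))

    def log_probability(self, seq: Sequence, begin: int = 1, end: int | None = None) -> float:
        begin, end = self._check_window(seq, begin, end)
        window = Sequence(seq.name, seq.values[begin - 1:end], seq.alphabet)
        return self._forward(window)

    def simulate(self, length: int | None = None, rng=None, name: str = "sim") -> Sequence:
        """Sample one begin-to-end traversal (the emitted length is random;
        ``length`` is ignored for this family)."""
        rng = as_rng(rng)
        out: list[int] = []
        layer, i = "M", 0  # begin
        while True:
            if layer == "M" and i == self.M + 1:
                break
            if layer == "M" and i >= 1:
                out.append(sample_categorical(self.match_emissions[i], rng))
            elif layer == "I":
                out.append(sample_categorical(self.insert_emissions[i], rng))
            choices, probs = self._out_edges(layer, i)
            layer, i = choices[sample_categorical(np.array(probs), rng)]
        return Sequence(name, out, self.alphabet)

    def _out_edges(self, layer: str, i: int):
        t = self.trans
        choices: list[tuple[str, int]] = []
        probs: list[float] = []
        if layer in ("M", "I"):
            key = layer
            choices.append(("M", i + 1)); probs.append(t[key + "M"][i])
            choices.append(("I", i)); probs.append(t[key + "I"][i])
            if i < self.M:
                choices.append(("D", i + 1)); probs.append(t[key + "D"][i])
        else:
            choices.append(("M", i + 1)); probs.append(t["DM"][i])
            choices.append(("I", i)); probs.append(t["DI"][i])
            if i < self.M:
                choices.append(("D", i + 1)); probs.append(t["DD"][i])
        return choices, probs

    def parameter_count(self) -> int:
        a = len(self.alphabet)
        k = self.M * (a - 1) + (self.M + 1) * (a - 1)  # match + insert emissions
        # transition distributions: M_i and I_i (i=0..M), D_i (i=1..M), each
        # with out-degree 3 (2 at the right edge)
        for i in range(self.M + 1):
            deg = 3 if i < self.M else 2
            k += 2 * (deg - 1)
        for i in range(1, self.M + 1):
            deg = 3 if i < self.M else 2
            k += deg - 1
        return k


def build_profile_hmm(alignment, alphabet: Alphabet, match_threshold: float = 0.5,
                      pseudocount: float = 1.0) -> ProfileHmm:
    """Construct a profile HMM from a multiple alignment.

    ``alignment`` is a list of equal-length token lists (or Sequences over an
    alphabet that includes "-").  Columns whose gap fraction is below
    ``match_threshold`` become match states; the rest are insert columns.
    Emissions and transitions are Laplace-smoothed counts.
    """
    rows = []
    for r in alignment:
        rows.append(r.tokens() if isinstance(r, Sequence) else list(r))
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    for r in rows:
        if len(r) != width:
            raise ValueError("ragged alignment: row lengths differ")
    n = len(rows)
    a = len(alphabet)
    gap_frac = [sum(1 for r in rows if r[c] == GAP) / n for c in range(width)]
    is_match = [f < match_threshold for f in gap_frac]
    match_cols = [c for c in range(width) if is_match[c]]
    M = len(match_cols)
    col_to_node = {}
    node = 0
    for c in range(width):
        if is_match[c]:
            node += 1
        col_to_node[c] = node  # insert columns attach to the preceding match node

    mE = np.zeros((M + 1, a))
    iE = np.zeros((M + 1, a))
    tcounts = {k: np.zeros(M + 1) for k in
               ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DD", "DI")}

    for r in rows:
        path: list[tuple[str, int]] = [("M", 0)]  # begin
        for c in range(width):
            tok = r[c]
            if is_match[c]:
                i = col_to_node[c]
                if tok == GAP:
                    path.append(("D", i))
                else:
                    path.append(("M", i))
                    mE[i, alphabet.index(tok)] += 1
            elif tok != GAP:
                i = col_to_node[c]
                path.append(("I", i))
                iE[i, alphabet.index(tok)] += 1
        path.append(("M", M + 1))  # end
        for (l1, i1), (l2, i2) in zip(path, path[1:]):
            tcounts[l1 + l2][i1] += 1

    def norm_rows(counts: np.ndarray) -> np.ndarray:
        c = counts + pseudocount
        return c / c.sum(axis=1, keepdims=True)

    trans = {k: np.zeros(M + 1) for k in tcounts}
    for i in range(M + 1):
        last = i == M
        for layer in ("M", "I"):
            keys = [layer + "M", layer + "I"] + ([] if last else [layer + "D"])
            tot = sum(tcounts[k][i] + pseudocount for k in keys)
            for k in keys:
                trans[k][i] = (tcounts[k][i] + pseudocount) / tot
        if i >= 1:
            keys = ["DM", "DI"] + ([] if last else ["DD"])
            tot = sum(tcounts[k][i] + pseudocount for k in keys)
            for k in keys:
                trans[k][i] = (tcounts[k][i] + pseudocount) / tot
    return ProfileHmm(alphabet, M, norm_rows(mE), norm_rows(iE), trans)


# ---------------------------------------------------------------------------
# pair HMMs
# ---------------------------------------------------------------------------


class PairHmm:
    """Pair hidden Markov model over two sequences on a shared alphabet.

    States are tagged by emission arity: "match" states emit an aligned symbol
    pair, "x" states a symbol of the first sequence only, "y" states of the
    second only.  ``end_probs`` terminates a path; each transition row plus
    its end probability sums to 1.
    """

    def __init__(self, alphabet: Alphabet, state_names, arities, initial,
                 transitions, end_probs, emissions):
        self.alphabet = alphabet
        self.state_names = list(state_names)
        self.arities = list(arities)
        K, a = len(self.state_names), len(alphabet)
        if set(self.arities) - {"match", "x", "y"}:
            raise ValueError("arities must be 'match', 'x' or 'y'")
        self.initial = np.asarray(initial, dtype=float)
        self.transitions = np.asarray(transitions, dtype=float)
        self.end_probs = np.asarray(end_probs, dtype=float)
        _check_dist("initial distribution", self.initial)
        for i in range(K):
            _check_dist("transition row %r (incl. end)" % self.state_names[i],
                        np.concatenate([self.transitions[i], [self.end_probs[i]]]))
        self.emissions = []
        for k, (ar, e) in enumerate(zip(self.arities, emissions)):
            e = np.asarray(e, dtype=float)
            want = (a, a) if ar == "match" else (a,)
            if e.shape != want:
                raise ValueError("emission table for state %r has shape %r, want %r"
                                 % (self.state_names[k], e.shape, want))
            _check_dist("emission table %r" % self.state_names[k], e.ravel())
            self.emissions.append(e)
        self.log_pi = log_array(self.initial)
        self.log_A = log_array(self.transitions)
        self.log_end = log_array(self.end_probs)
        self.log_emissions = [log_array(e) for e in self.emissions]

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def _deltas(self, k: int) -> tuple[int, int]:
        return {"match": (1, 1), "x": (1, 0), "y": (0, 1)}[self.arities[k]]

    def _emit(self, k: int, s1v, s2v, i: int, j: int) -> float:
        ar = self.arities[k]
        if ar == "match":
            return float(self.log_emissions[k][s1v[i - 1], s2v[j - 1]])
        if ar == "x":
            return float(self.log_emissions[k][s1v[i - 1]])
        return float(self.log_emissions[k][s2v[j - 1]])

    def _dp(self, seq1: Sequence, seq2: Sequence, viterbi: bool):
        v1, v2 = seq1.values, seq2.values
        n1, n2 = len(v1), len(v2)
        K = self.n_states
        F = np.full((K, n1 + 1, n2 + 1), NEG_INF)
        ptr = np.full((K, n1 + 1, n2 + 1), -1, dtype=np.int64) if viterbi else None
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                if i == 0 and j == 0:
                    continue
                for k in range(K):
                    di, dj = self._deltas(k)
                    pi_, pj = i - di, j - dj
                    if pi_ < 0 or pj < 0:
                        continue
                    em = self._emit(k, v1, v2, i, j)
                    if em == NEG_INF:
                        continue
                    if viterbi:
                        scores = F[:, pi_, pj] + self.log_A[:, k]
                        best_prev = int(np.argmax(scores))
                        val = float(scores[best_prev])
                        entry = float(self.log_pi[k]) if (pi_ == 0 and pj == 0) else NEG_INF
                        if entry > val:
                            F[k, i, j] = entry + em
                            ptr[k, i, j] = -1
                        else:
                            F[k, i, j] = val + em
                            ptr[k, i, j] = best_prev
                    else:
                        parts = F[:, pi_, pj] + self.log_A[:, k]
                        if pi_ == 0 and pj == 0:
                            parts = np.concatenate([parts, [self.log_pi[k]]])
                        F[k, i, j] = float(logsumexp(parts)) + em
        return F, ptr

    def pair_forward(self, seq1: Sequence, seq2: Sequence) -> float:
        """Total log-likelihood summed over all monotone alignment paths."""
        n1, n2 = len(seq1), len(seq2)
        if n1 == 0 and n2 == 0:
            return 0.0
        F, _ = self._dp(seq1, seq2, viterbi=False)
        return float(logsumexp(F[:, n1, n2] + self.log_end))

    def pair_viterbi(self, seq1: Sequence, seq2: Sequence):
        """Best alignment as two gapped token rows, plus its log-likelihood.

        Returns ``(row1, row2, state_path, log-lik)``; ties break towards the
        lowest state index.
        """
        n1, n2 = len(seq1), len(seq2)
        if n1 == 0 and n2 == 0:
            return [], [], [], 0.0
        F, ptr = self._dp(seq1, seq2, viterbi=True)
        finals = F[:, n1, n2] + self.log_end
        k = int(np.argmax(finals))
        loglik = float(finals[k])
        if loglik == NEG_INF:
            return [], [], [], NEG_INF
        row1: list[str] = []
        row2: list[str] = []
        states: list[str] = []
        i, j = n1, n2
        while True:
            di, dj = self._deltas(k)
            states.append(self.state_names[k])
            row1.append(seq1.alphabet.symbol(int(seq1.values[i - 1])) if di else GAP)
            row2.append(seq2.alphabet.symbol(int(seq2.values[j - 1])) if dj else GAP)
            prev = int(ptr[k, i, j])
            i, j = i - di, j - dj
            if prev < 0:
                break
            k = prev
        row1.reverse(); row2.reverse(); states.reverse()
        return row1, row2, states, loglik
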