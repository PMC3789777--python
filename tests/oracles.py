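"""Independent brute-force oracles used to cross-check the dynamic programs.

Everything here enumerates explicitly (paths, segmentations, alignment paths,
pattern spaces) and stays deliberately independent of the implementations it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

NEG_INF = float("-inf")


def _logsum(values):
    finite = [v for v in values if v > NEG_INF]
    if not finite:
        return NEG_INF
    m = max(finite)
    return m + math.log(sum(math.exp(v - m) for v in finite))


def hmm_path_score(hmm, seq, path) -> float:
    v = seq.values
    idx = [hmm.state_names.index(p) if isinstance(p, str) else p for p in path]
    score = hmm.log_pi[idx[0]] + hmm.log_E[idx[0], v[0]]
    for t in range(1, len(v)):
        score += hmm.log_A[idx[t - 1], idx[t]] + hmm.log_E[idx[t], v[t]]
    return float(score)


def enumerate_forward(hmm, seq) -> float:
    K, L = hmm.n_states, len(seq)
    return _logsum(hmm_path_score(hmm, seq, path)
                   for path in itertools.product(range(K), repeat=L))


def enumerate_viterbi(hmm, seq):
    K, L = hmm.n_states, len(seq)
    best, best_path = NEG_INF, []
    for path in itertools.product(range(K), repeat=L):
        s = hmm_path_score(hmm, seq, path)
        if s > best:
            best, best_path = s, list(path)
    return best_path, best


def enumerate_posterior(hmm, seq) -> np.ndarray:
    K, L = hmm.n_states, len(seq)
    total = NEG_INF
    acc = [[[] for _ in range(K)] for _ in range(L)]
    for path in itertools.product(range(K), repeat=L):
        s = hmm_path_score(hmm, seq, path)
        total = _logsum([total, s])
        for t, k in enumerate(path):
            acc[t][k].append(s)
    post = np.zeros((L, K))
    for t in range(L):
        for k in range(K):
            post[t, k] = math.exp(_logsum(acc[t][k]) - total) if acc[t][k] else 0.0
    return post


def enumerate_pair_paths(pair, seq1, seq2):
    """All monotone state paths consuming both sequences; yields scores."""
    deltas = {"match": (1, 1), "x": (1, 0), "y": (0, 1)}
    n1, n2 = len(seq1), len(seq2)
    v1, v2 = seq1.values, seq2.values

    def emit(k, i, j):
        ar = pair.arities[k]
        if ar == "match":
            return float(pair.log_emissions[k][v1[i - 1], v2[j - 1]])
        if ar == "x":
            return float(pair.log_emissions[k][v1[i - 1]])
        return float(pair.log_emissions[k][v2[j - 1]])

    def rec(i, j, k, score):
        if i == n1 and j == n2:
            yield score + float(pair.log_end[k])
            return
        for k2 in range(pair.n_states):
            di, dj = deltas[pair.arities[k2]]
            if i + di > n1 or j + dj > n2:
                continue
            yield from rec(i + di, j + dj, k2,
                           score + float(pair.log_A[k, k2]) + emit(k2, i + di, j + dj))

    for k in range(pair.n_states):
        di, dj = deltas[pair.arities[k]]
        if di > n1 or dj > n2:
            continue
        yield from rec(di, dj, k, float(pair.log_pi[k]) + emit(k, di, dj))


def enumerate_pair_forward(pair, seq1, seq2) -> float:
    return _logsum(enumerate_pair_paths(pair, seq1, seq2))


def enumerate_pair_viterbi(pair, seq1, seq2) -> float:
    return max(enumerate_pair_paths(pair, seq1, seq2), default=NEG_INF)


def enumerate_segmentations(ghmm, seq):
    """All (state, duration) tilings of the sequence with their joint scores.

    Mirrors the decoder's semantics from first principles: initial probability,
    per-segment duration weight (a_kk^(d-1) for geometric states, the explicit
    pmf otherwise), direct emission-model calls, raw inter-segment transition
    probabilities, no exit term after the last segment.
    """
    from probseq.ghmm import _duration_weight, _segment_emission

    L = len(seq)
    K = ghmm.n_states
    results = []

    def durations(k, max_d):
        if ghmm.is_geometric[k]:
            return range(1, max_d + 1)
        return [int(d) for d in ghmm.states[k].duration.support() if d <= max_d]

    def rec(pos, prev, score, segs):
        if pos == L:
            results.append((list(segs), score))
            return
        for k in range(K):
            if prev is None:
                entry = float(ghmm.log_pi[k])
            elif k == prev:
                continue
            else:
                entry = float(ghmm.log_trans.get((prev, k), NEG_INF))
            if entry == NEG_INF:
                continue
            for d in durations(k, L - pos):
                dw = _duration_weight(ghmm, k, d)
                if dw == NEG_INF:
                    continue
                em = _segment_emission(ghmm.states[k], seq, pos, pos + d - 1)
                if em == NEG_INF:
                    continue
                segs.append((ghmm.state_names[k], pos + 1, pos + d))
                rec(pos + d, k, score + entry + dw + em, segs)
                segs.pop()

    rec(0, None, 0.0, [])
    return results


def best_segmentation_score(ghmm, seq) -> float:
    results = enumerate_segmentations(ghmm, seq)
    return max((s for _seg, s in results), default=NEG_INF)
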