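"""Emission model families whose likelihoods factor over positions.

Implemented families:

* discrete i.i.d. distributions,
* fixed-order Markov chains (with lower-order tables for initial positions),
* variable-length Markov chains stored as pruned probabilistic suffix trees,
* inhomogeneous Markov chains over fixed-width windows (weight array models,
  WAMs, including a windowed variant that pools counts over nearby positions),
* interpolated Markov models (IMMs) with Glimmer-style order interpolation,
  optionally three-periodic for codon structure,
* similarity-based sequence weighting (SBSW) signal models with a mandatory
  consensus subsequence that is skipped when scoring.

Contexts are encoded as base-``|Σ|`` integers with the most recent symbol in
the least significant digit, so the parent (one-symbol-shorter) context of
``c`` at order ``m`` is simply ``c mod |Σ|^(m-1)``.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from scipy import stats

from .core import (
    NEG_INF,
    Alphabet,
    FactorableModel,
    Sequence,
    SequenceModel,
    as_rng,
    log_array,
)

__all__ = [
    "DiscreteIid",
    "MarkovChain",
    "Vlmc",
    "PositionalChain",
    "InterpolatedChain",
    "SbswModel",
    "train_iid",
    "train_markov",
    "train_vlmc",
    "train_wam",
    "train_windowed_wam",
    "train_imm",
    "train_sbsw",
    "DEFAULT_PSEUDOCOUNT",
    "IMM_COUNT_THRESHOLD",
]

#: Default pseudocount added wherever observed counts may be zero.  Small
#: enough to barely perturb estimates while avoiding spurious -inf.
DEFAULT_PSEUDOCOUNT = 1e-4

#: Context count at (and above) which an IMM fully trusts the higher-order
#: estimate (interpolation weight 1).
IMM_COUNT_THRESHOLD = 400


def sample_categorical(probs: np.ndarray, rng) -> int:
    """Sample an index from a probability vector using one uniform draw."""
    u = rng.random()
    return int(np.searchsorted(np.cumsum(probs), u, side="right").clip(0, len(probs) - 1))


def _normalize_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    c = np.atleast_2d(np.asarray(counts, dtype=float) + pseudocount)
    s = c.sum(axis=-1, keepdims=True)
    zero = (s <= 0).ravel()
    c[zero] = 1.0  # unseen context with zero pseudocount: uniform fallback
    s[zero] = c.shape[-1]
    return (c / s).reshape(np.shape(counts))


def _context_index(values, t: int, m: int, n_symbols: int) -> int:
    """Base-|Σ| index of the m-symbol context preceding position t."""
    ctx = 0
    for d in range(1, m + 1):
        ctx += int(values[t - d]) * n_symbols**(d - 1)
    return ctx


# ---------------------------------------------------------------------------
# i.i.d.
# ---------------------------------------------------------------------------


class DiscreteIid(FactorableModel):
    """Independent, identically distributed symbols."""

    family = "iid"

    def __init__(self, alphabet: Alphabet, probs):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (len(alphabet),):
            raise ValueError("probability vector length must match alphabet size")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        self.alphabet = alphabet
        self.probs = probs
        self._log_probs = log_array(probs)

    def position_log_prob(self, values, t, phase=0):
        return float(self._log_probs[values[t]])

    def sample_next(self, history, rng, phase=0):
        return sample_categorical(self.probs, rng)

    def parameter_count(self) -> int:
        return len(self.alphabet) - 1


def train_iid(seqs: Iterable[Sequence], pseudocount: float = DEFAULT_PSEUDOCOUNT) -> DiscreteIid:
    """Maximum-likelihood i.i.d. estimate: probs ∝ symbol counts + pseudocount."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty training set")
    alphabet = seqs[0].alphabet
    counts = np.zeros(len(alphabet))
    for s in seqs:
        counts += np.bincount(s.values, minlength=len(alphabet))
    if counts.sum() == 0 and pseudocount == 0:
        raise ValueError("no observed symbols and pseudocount is zero")
    return DiscreteIid(alphabet, _normalize_counts(counts, pseudocount))


# ---------------------------------------------------------------------------
# fixed-order Markov chains
# ---------------------------------------------------------------------------


def _ngram_counts(seqs, max_order: int, n_symbols: int,
                  phase: int | None = None, period: int = 1) -> list[np.ndarray]:
    """counts[m][ctx, sym] over all positions t >= m, for m = 0..max_order.

    With ``phase``/``period`` set, only positions t with t % period == phase
    contribute (used by periodic models).
    """
    counts = [np.zeros((n_symbols**m, n_symbols)) for m in range(max_order + 1)]
    for s in seqs:
        v = s.values
        L = len(v)
        for m in range(max_order + 1):
            if L <= m:
                continue
            t = np.arange(m, L)
            ctx = np.zeros(L - m, dtype=np.int64)
            for d in range(1, m + 1):
                ctx += v[t - d] * n_symbols**(d - 1)
            sym = v[t]
            if phase is not None:
                keep = (t % period) == phase
                ctx, sym = ctx[keep], sym[keep]
            np.add.at(counts[m], (ctx, sym), 1)
    return counts


class MarkovChain(FactorableModel):
    """Homogeneous Markov chain of fixed order.

    Positions with fewer than ``order`` predecessors use the lower-order
    tables, so the model defines a proper distribution from the first symbol.
    """

    family = "markov"

    def __init__(self, alphabet: Alphabet, tables: list[np.ndarray]):
        # tables[m]: (|Σ|^m, |Σ|) conditional probabilities, m = 0..order
        self.alphabet = alphabet
        self.order = len(tables) - 1
        self.tables = [np.asarray(t, dtype=float) for t in tables]
        a = len(alphabet)
        for m, tab in enumerate(self.tables):
            if tab.shape != (a**m, a):
                raise ValueError("order-%d table has wrong shape %r" % (m, tab.shape))
        self._log_tables = [log_array(t) for t in self.tables]

    def position_log_prob(self, values, t, phase=0):
        m = min(self.order, t)
        ctx = _context_index(values, t, m, len(self.alphabet))
        return float(self._log_tables[m][ctx, values[t]])

    def sample_next(self, history, rng, phase=0):
        m = min(self.order, len(history))
        ctx = _context_index(history, len(history), m, len(self.alphabet))
        return sample_categorical(self.tables[m][ctx], rng)

    def parameter_count(self) -> int:
        a = len(self.alphabet)
        return a**self.order * (a - 1)


def train_markov(seqs: Iterable[Sequence], order: int,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> MarkovChain:
    """Fit a fixed-order chain from (order+1)-gram counts; initial positions
    from lower-order marginal counts over all eligible positions."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty training set")
    if order < 0:
        raise ValueError("order must be >= 0")
    alphabet = seqs[0].alphabet
    counts = _ngram_counts(seqs, order, len(alphabet))
    return MarkovChain(alphabet, [_normalize_counts(c, pseudocount) for c in counts])


# ---------------------------------------------------------------------------
# variable-length Markov chains (probabilistic suffix trees)
# ---------------------------------------------------------------------------


class Vlmc(FactorableModel):
    """Variable-length Markov chain stored as a context tree.

    ``nodes`` maps context tuples (most recent symbol first; root = empty
    tuple) to conditional probability vectors.  Every non-root context's
    one-symbol-shorter suffix is also present.  Scoring a position walks the
    tree as deep as the available history and the tree allow.
    """

    family = "vlmc"

    def __init__(self, alphabet: Alphabet, nodes: dict[tuple, np.ndarray],
                 counts: dict[tuple, float] | None = None):
        if () not in nodes:
            raise ValueError("context tree must contain the root context")
        for ctx in nodes:
            if ctx and ctx[:-1] not in nodes:
                raise ValueError("context %r lacks its parent suffix" % (ctx,))
        self.alphabet = alphabet
        self.nodes = {c: np.asarray(p, dtype=float) for c, p in nodes.items()}
        self.counts = dict(counts) if counts else {}
        self._log_nodes = {c: log_array(p) for c, p in self.nodes.items()}

    def _deepest(self, values, t: int) -> tuple:
        ctx = ()
        d = 1
        while t - d >= 0:
            cand = ctx + (int(values[t - d]),)
            if cand not in self.nodes:
                break
            ctx = cand
            d += 1
        return ctx

    def position_log_prob(self, values, t, phase=0):
        return float(self._log_nodes[self._deepest(values, t)][values[t]])

    def sample_next(self, history, rng, phase=0):
        ctx = self._deepest(history, len(history))
        return sample_categorical(self.nodes[ctx], rng)

    def leaf_contexts(self) -> list[tuple]:
        has_child = set(ctx[:-1] for ctx in self.nodes if ctx)
        return [c for c in self.nodes if c not in has_child]

    def depth(self) -> int:
        return max(len(c) for c in self.nodes)

    def parameter_count(self) -> int:
        return len(self.leaf_contexts()) * (len(self.alphabet) - 1)


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask]))))


def train_vlmc(seqs: Iterable[Sequence], max_depth: int, cut: float,
               pseudocount: float = DEFAULT_PSEUDOCOUNT,
               enumerate_limit: int = 4096) -> Vlmc:
    """Grow the full suffix tree to ``max_depth``, then prune bottom-up.

    A childless node ``w`` is removed when ``2 * n_w * KL(P(.|w) || P(.|parent))``
    falls below ``cut`` (natural logs).  ``cut = 0`` keeps the full tree
    (equivalent to the order-``max_depth`` chain); ``cut = inf`` prunes to the
    root (i.i.d.).

    When ``|Σ|^max_depth <= enumerate_limit`` all contexts are materialised
    (unseen ones get the pseudocount-uniform distribution, matching the
    fixed-order chain's treatment of unseen contexts); beyond that only
    observed contexts are kept.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty training set")
    if max_depth < 0 or cut < 0:
        raise ValueError("max_depth and cut must be >= 0")
    alphabet = seqs[0].alphabet
    a = len(alphabet)

    counts: dict[tuple, np.ndarray] = {}
    for s in seqs:
        v = s.values
        for t in range(len(v)):
            ctx = ()
            for d in range(0, min(max_depth, t) + 1):
                if d:
                    ctx = ctx + (int(v[t - d]),)
                row = counts.get(ctx)
                if row is None:
                    row = counts[ctx] = np.zeros(a)
                row[v[t]] += 1

    if a**max_depth <= enumerate_limit:
        # materialise every context so unseen ones fall back to uniform
        frontier = [()]
        for _ in range(max_depth):
            frontier = [c + (s,) for c in frontier for s in range(a)]
            for c in frontier:
                counts.setdefault(c, np.zeros(a))
    counts.setdefault((), np.zeros(a))

    probs = {c: _normalize_counts(row, pseudocount) for c, row in counts.items()}
    totals = {c: float(row.sum()) for c, row in counts.items()}

    # bottom-up pruning of childless nodes
    for depth in range(max_depth, 0, -1):
        layer = [c for c in list(probs) if len(c) == depth]
        has_child = set(c[:-1] for c in probs if len(c) > depth)
        for ctx in layer:
            if ctx in has_child:
                continue
            stat = 2.0 * totals[ctx] * _kl(probs[ctx], probs[ctx[:-1]])
            if stat < cut:
                del probs[ctx]
                del totals[ctx]

    return Vlmc(alphabet, probs, totals)


# ---------------------------------------------------------------------------
# weight array models (inhomogeneous Markov chains over fixed windows)
# ---------------------------------------------------------------------------


class PositionalChain(SequenceModel):
    """Inhomogeneous Markov chain with position-specific conditional tables.

    In the default (non-phased) form the model emits fixed-width patterns:
    scoring requires a window of exactly ``length`` positions, and position
    ``u`` (0-based within the window) conditions on ``min(order_u, u)``
    predecessors *inside* the window.
    """

    family = "wam"
    is_inhomogeneous = True

    def __init__(self, alphabet: Alphabet, tables: list[np.ndarray]):
        # tables[u]: (|Σ|^m_u, |Σ|) with m_u implied by the row count
        self.alphabet = alphabet
        self.tables = [np.asarray(t, dtype=float) for t in tables]
        a = len(alphabet)
        self.orders = []
        for u, tab in enumerate(self.tables):
            m = round(math.log(tab.shape[0], a)) if tab.shape[0] > 1 else 0
            if tab.shape != (a**m, a) or m > u:
                raise ValueError("position %d table has invalid shape %r" % (u, tab.shape))
            self.orders.append(m)
        self._log_tables = [log_array(t) for t in self.tables]

    @property
    def length(self) -> int:
        return len(self.tables)

    emission_length = length

    def log_probability(self, seq: Sequence, begin: int = 1, end: int | None = None) -> float:
        begin, end = self._check_window(seq, begin, end)
        if end - begin + 1 != self.length:
            raise ValueError(
                "window length %d does not match pattern length %d"
                % (end - begin + 1, self.length)
            )
        total = 0.0
        v = seq.values
        for u in range(self.length):
            t = begin - 1 + u
            ctx = _context_index(v, t, self.orders[u], len(self.alphabet))
            term = float(self._log_tables[u][ctx, v[t]])
            if term == NEG_INF:
                return NEG_INF
            total += term
        return total

    def simulate(self, length: int | None = None, rng=None, name: str = "sim") -> Sequence:
        if length is None:
            length = self.length
        if length != self.length:
            raise ValueError("a WAM emits patterns of exactly length %d" % self.length)
        rng = as_rng(rng)
        out: list[int] = []
        for u in range(self.length):
            ctx = _context_index(out, u, self.orders[u], len(self.alphabet))
            out.append(sample_categorical(self.tables[u][ctx], rng))
        return Sequence(name, out, self.alphabet)

    def parameter_count(self) -> int:
        a = len(self.alphabet)
        return sum(a**m * (a - 1) for m in self.orders)


def _check_pattern_lengths(seqs, pattern_length):
    for s in seqs:
        if len(s) != pattern_length:
            raise ValueError(
                "training record %r has length %d, expected %d"
                % (s.name, len(s), pattern_length)
            )


def train_wam(seqs: Iterable[Sequence], pattern_length: int, order: int,
              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PositionalChain:
    """Per-position order-k tables from aligned fixed-length patterns."""
    return train_windowed_wam(seqs, pattern_length, order, window=0,
                              pseudocount=pseudocount)


def train_windowed_wam(seqs: Iterable[Sequence], pattern_length: int, order: int,
                       window: int, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PositionalChain:
    """WAM whose position-``u`` table pools counts from positions ``u ± window``.

    ``window = 0`` is the plain WAM.  Pooling shares statistics across nearby
    positions, which stabilises estimates for diffuse signals such as branch
    points.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty training set")
    alphabet = seqs[0].alphabet
    a = len(alphabet)
    _check_pattern_lengths(seqs, pattern_length)
    tables = []
    for u in range(pattern_length):
        m = min(order, u)
        counts = np.zeros((a**m, a))
        lo, hi = max(m, u - window), min(pattern_length - 1, u + window)
        for s in seqs:
            v = s.values
            for w in range(lo, hi + 1):
                counts[_context_index(v, w, m, a), v[w]] += 1
        tables.append(_normalize_counts(counts, pseudocount))
    return PositionalChain(alphabet, tables)


# ---------------------------------------------------------------------------
# interpolated Markov models
# ---------------------------------------------------------------------------


class InterpolatedChain(FactorableModel):
    """Interpolated Markov model (IMM), optionally three-periodic.

    Stores the *interpolated* conditional tables for every order 0..k (and
    every phase); a position with ``t`` available predecessors is scored from
    the order-``min(k, t)`` interpolated table of its phase.  The interpolation
    weights used during training are kept for introspection but are not needed
    for scoring.
    """

    family = "imm"

    def __init__(self, alphabet: Alphabet, phase_tables: list[list[np.ndarray]],
                 lambdas: list[list[np.ndarray]] | None = None):
        # phase_tables[phase][m]: (|Σ|^m, |Σ|) interpolated conditionals
        self.alphabet = alphabet
        self.period = len(phase_tables)
        if self.period < 1:
            raise ValueError("at least one phase table set required")
        orders = {len(tabs) - 1 for tabs in phase_tables}
        if len(orders) != 1:
            raise ValueError("all phases must share the same max order")
        self.max_order = orders.pop()
        a = len(alphabet)
        self.phase_tables = [[np.asarray(t, dtype=float) for t in tabs]
                             for tabs in phase_tables]
        for tabs in self.phase_tables:
            for m, tab in enumerate(tabs):
                if tab.shape != (a**m, a):
                    raise ValueError("order-%d table has wrong shape" % m)
        self.lambdas = lambdas
        self._log_tables = [[log_array(t) for t in tabs] for tabs in self.phase_tables]

    def position_log_prob(self, values, t, phase=0):
        m = min(self.max_order, t)
        ctx = _context_index(values, t, m, len(self.alphabet))
        return float(self._log_tables[phase % self.period][m][ctx, values[t]])

    def sample_next(self, history, rng, phase=0):
        m = min(self.max_order, len(history))
        ctx = _context_index(history, len(history), m, len(self.alphabet))
        return sample_categorical(self.phase_tables[phase % self.period][m][ctx], rng)

    def parameter_count(self) -> int:
        a = len(self.alphabet)
        return self.period * a**self.max_order * (a - 1)


def train_imm(seqs: Iterable[Sequence], max_order: int, periodicity: int = 1,
              pseudocount: float = DEFAULT_PSEUDOCOUNT,
              count_threshold: int = IMM_COUNT_THRESHOLD) -> InterpolatedChain:
    """Fit an IMM with Glimmer-style interpolation.

    For each context ``w`` at order ``m`` with ``n_w`` observations, the
    interpolation weight is λ = 1 when ``n_w >= count_threshold``; otherwise
    λ = c · n_w / count_threshold (floored at 0, capped at 1) where ``c`` is
    the χ² confidence that the context's next-symbol counts differ from the
    interpolated order-(m-1) prediction.  The interpolated conditional is the
    convex combination λ·P_m + (1-λ)·P̃_{m-1}.

    ``periodicity`` 3 keeps three phase-indexed table sets (phase of position
    ``t``, 0-based, is ``t mod 3`` in the training sequences, i.e. training
    sequences are assumed to start on a period boundary).
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty training set")
    if periodicity not in (1, 3):
        raise ValueError("periodicity must be 1 or 3")
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    alphabet = seqs[0].alphabet
    a = len(alphabet)

    counts = [_ngram_counts(seqs, max_order, a,
                            phase=(ph if periodicity > 1 else None),
                            period=periodicity)
              for ph in range(periodicity)]

    phase_tables = []
    all_lambdas = []
    for ph in range(periodicity):
        raw = [_normalize_counts(c, pseudocount) for c in counts[ph]]
        interp = [raw[0]]
        lambdas = [np.ones(1)]
        for m in range(1, max_order + 1):
            tab = np.empty_like(raw[m])
            lam_m = np.empty(a**m)
            parent = interp[m - 1]
            for ctx in range(a**m):
                row_counts = counts[ph][m][ctx]
                n = float(row_counts.sum())
                pctx = ctx % (a**(m - 1)) if m > 1 else 0
                if n >= count_threshold:
                    lam = 1.0
                elif n == 0:
                    lam = 0.0
                else:
                    expected = parent[pctx] * n
                    chi2 = float(np.sum((row_counts - expected)**2 / expected))
                    confidence = float(stats.chi2.cdf(chi2, df=a - 1))
                    lam = min(1.0, max(0.0, confidence * n / count_threshold))
                lam_m[ctx] = lam
                tab[ctx] = lam * raw[m][ctx] + (1.0 - lam) * parent[pctx]
            interp.append(tab)
            lambdas.append(lam_m)
        phase_tables.append(interp)
        all_lambdas.append(lambdas)
    return InterpolatedChain(alphabet, phase_tables, all_lambdas)


# ---------------------------------------------------------------------------
# similarity-based sequence weighting
# ---------------------------------------------------------------------------


class SbswModel(SequenceModel):
    """Signal model scoring by weighted similarity to stored training patterns.

    Patterns have fixed width ``length`` and must carry the mandatory
    ``skip_sequence`` (a consensus such as "GT") starting at ``skip_offset``
    (0-based); those positions are excluded from scoring.  A query's score is

        [count(q) + ε · Σ_{t : Hamming(q,t)=1 off-skip} count(t)] / Z,

    with Z chosen so that the scores over all ``|Σ|^(W-|skip|)`` off-skip
    patterns sum to 1.  Queries lacking the skip sequence score -inf.
    """

    family = "sbsw"
    is_inhomogeneous = True

    def __init__(self, alphabet: Alphabet, length: int, skip_offset: int,
                 skip_values: tuple[int, ...], epsilon: float,
                 pattern_counts: dict[tuple, float]):
        if not (0 <= skip_offset and skip_offset + len(skip_values) <= length):
            raise ValueError("skip sequence does not fit inside the pattern")
        self.alphabet = alphabet
        self.length = length
        self.skip_offset = skip_offset
        self.skip_values = tuple(int(x) for x in skip_values)
        self.epsilon = float(epsilon)
        self.pattern_counts = {tuple(int(x) for x in k): float(v)
                               for k, v in pattern_counts.items()}
        self.n_free = length - len(skip_values)
        for pat in self.pattern_counts:
            if len(pat) != self.n_free:
                raise ValueError("stored pattern has wrong off-skip length")
        self.n_total = float(sum(self.pattern_counts.values()))
        if self.n_total <= 0:
            raise ValueError("SBSW needs at least one training pattern")
        a = len(alphabet)
        # every pattern contributes 1 to itself and ε to each of its
        # n_free·(|Σ|-1) single-mismatch neighbours, hence the closed form
        self.normalizer = self.n_total * (1.0 + self.epsilon * self.n_free * (a - 1))

    @property
    def emission_length(self) -> int:
        return self.length

    def _strip_skip(self, window: list[int]) -> tuple | None:
        lo, hi = self.skip_offset, self.skip_offset + len(self.skip_values)
        if tuple(window[lo:hi]) != self.skip_values:
            return None
        return tuple(window[:lo]) + tuple(window[hi:])

    def _numerator(self, pat: tuple) -> float:
        total = self.pattern_counts.get(pat, 0.0)
        if self.epsilon > 0:
            a = len(self.alphabet)
            for pos in range(self.n_free):
                for sym in range(a):
                    if sym == pat[pos]:
                        continue
                    neigh = pat[:pos] + (sym,) + pat[pos + 1:]
                    c = self.pattern_counts.get(neigh)
                    if c:
                        total += self.epsilon * c
        return total

    def log_probability(self, seq: Sequence, begin: int = 1, end: int | None = None) -> float:
        begin, end = self._check_window(seq, begin, end)
        if end - begin + 1 != self.length:
            raise ValueError(
                "window length %d does not match pattern length %d"
                % (end - begin + 1, self.length)
            )
        window = [int(x) for x in seq.values[begin - 1:end]]
        pat = self._strip_skip(window)
        if pat is None:
            return NEG_INF
        numer = self._numerator(pat)
        if numer <= 0:
            return NEG_INF
        return math.log(numer) - math.log(self.normalizer)

    def simulate(self, length: int | None = None, rng=None, name: str = "sim") -> Sequence:
        """Exact sampling: pick a training pattern by count, then emit it as-is
        or mutate one uniformly chosen off-skip position (mixture weights match
        the score normalisation)."""
        if length is None:
            length = self.length
        if length != self.length:
            raise ValueError("an SBSW model emits patterns of exactly length %d" % self.length)
        rng = as_rng(rng)
        a = len(self.alphabet)
        pats = list(self.pattern_counts)
        weights = np.array([self.pattern_counts[p] for p in pats])
        base = pats[sample_categorical(weights / weights.sum(), rng)]
        p_mut = self.epsilon * self.n_free * (a - 1) / (1.0 + self.epsilon * self.n_free * (a - 1))
        pat = list(base)
        if rng.random() < p_mut:
            pos = int(rng.integers(self.n_free))
            alternatives = [s for s in range(a) if s != pat[pos]]
            pat[pos] = alternatives[int(rng.integers(a - 1))]
        lo = self.skip_offset
        full = pat[:lo] + list(self.skip_values) + pat[lo:]
        return Sequence(name, full, self.alphabet)

    def parameter_count(self) -> int:
        # convention: one weight per distinct stored pattern
        return len(self.pattern_counts)


def train_sbsw(seqs: Iterable[Sequence], skip_offset: int, skip_sequence,
               epsilon: float = 1e-3) -> SbswModel:
    """Store off-skip pattern counts from uniform-length training patterns.

    Every training pattern must carry ``skip_sequence`` (tokens) starting at
    ``skip_offset`` (0-based); violations raise with the offending record.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty training set")
    alphabet = seqs[0].alphabet
    length = len(seqs[0])
    _check_pattern_lengths(seqs, length)
    skip_values = tuple(alphabet.index(t) for t in skip_sequence)
    counts: dict[tuple, float] = {}
    model = None
    for s in seqs:
        window = [int(x) for x in s.values]
        lo, hi = skip_offset, skip_offset + len(skip_values)
        if tuple(window[lo:hi]) != skip_values:
            raise ValueError(
                "training record %r lacks mandatory %r at offset %d"
                % (s.name, "".join(skip_sequence), skip_offset)
            )
        pat = tuple(window[:lo]) + tuple(window[hi:])
        counts[pat] = counts.get(pat, 0.0) + 1.0
    return SbswModel(alphabet, length, skip_offset, skip_values, epsilon, counts)
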