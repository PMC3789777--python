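"""Generalized hidden Markov models.

A GHMM state emits a variable-length word from an arbitrary emission
sub-model under an explicit duration law.  Three duration kinds exist:

* ``geometric`` — realised exactly as a self-transition (the state behaves
  like a classical HMM state, one symbol per step);
* ``fixed`` — a single length, typical of signal states;
* ``histogram`` — an explicit (smoothed) length distribution with finite
  support, typical of exon states.

Decoding follows the segment formulation of the Viterbi algorithm.  A naive
reference decoder scores every candidate segment by calling the emission
model directly (O(K^2 L D) with per-segment emission cost on top); the
optimized decoder exploits three architecture properties when present —
sparse transitions, bounded duration supports, and factorable emissions that
admit constant-time window scoring through prefix sum arrays — and skips
candidates whose emission probability is exactly zero.  Both decoders share
the same joint-probability semantics and tie rule (shorter duration, then
lower state index), so their results agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .core import (
    NEG_INF,
    Alphabet,
    FactorableModel,
    Sequence,
    SequenceModel,
    as_rng,
    log_safe,
    reverse_complement,
)
from .chains import sample_categorical

__all__ = [
    "SmoothedHistogram",
    "train_smoothed_histogram",
    "GeometricDuration",
    "FixedDuration",
    "HistogramDuration",
    "CompositeEmission",
    "ReverseComplementModel",
    "GhmmState",
    "Ghmm",
    "build_ghmm",
    "PrefixSumArray",
    "build_psa",
    "DecodingPlan",
    "plan_decoding",
    "ghmm_viterbi",
    "ghmm_viterbi_naive",
    "ghmm_simulate",
    "Segmentation",
    "path_log_likelihood",
]


# ---------------------------------------------------------------------------
# duration models
# ---------------------------------------------------------------------------


class SmoothedHistogram:
    """Discrete length distribution on support 1..D."""

    def __init__(self, probs):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise ValueError("histogram needs a 1-d probability vector over 1..D")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("histogram probabilities must be >= 0 and sum to 1")
        self.probs = probs  # probs[d-1] = P(duration = d)

    @property
    def max_duration(self) -> int:
        return len(self.probs)

    def mean(self) -> float:
        return float(np.sum(np.arange(1, len(self.probs) + 1) * self.probs))


def train_smoothed_histogram(lengths, bandwidth: float | None = None,
                             tail_factor: float = 1.5,
                             trim: float = 1e-12) -> SmoothedHistogram:
    """Gaussian-kernel density estimate of a length distribution on integers.

    The bandwidth defaults to the normal-reference rule 1.06·σ·n^(-1/5)
    (floored at 1); the support is 1..D with D = ceil(max length ·
    ``tail_factor``) and the density is renormalised over that support.
    Probabilities below ``trim`` times the mode are zeroed (and the rest
    renormalised) so decoding loops only over lengths that carry real mass.
    """
    lengths = np.asarray(list(lengths), dtype=float)
    if lengths.size == 0:
        raise ValueError("empty length sample")
    if np.any(lengths < 1):
        raise ValueError("lengths must be positive integers")
    if bandwidth is None:
        sd = float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0
        bandwidth = max(1.0, 1.06 * sd * lengths.size ** (-0.2))
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    D = int(math.ceil(lengths.max() * tail_factor))
    grid = np.arange(1, D + 1, dtype=float)
    dens = np.exp(-0.5 * ((grid[:, None] - lengths[None, :]) / bandwidth) ** 2).sum(axis=1)
    dens[dens < trim * dens.max()] = 0.0
    return SmoothedHistogram(dens / dens.sum())


class GeometricDuration:
    """Geometric run length realised as a self-transition with continuation
    probability ``q`` (mean 1/(1-q))."""

    kind = "geometric"

    def __init__(self, continuation: float):
        # continuation 1 is allowed for an absorbing final state
        if not (0.0 <= continuation <= 1.0):
            raise ValueError("continuation probability must be in [0, 1]")
        self.continuation = float(continuation)

    @property
    def mean(self) -> float:
        return 1.0 / (1.0 - self.continuation) if self.continuation < 1 else math.inf

    def sample(self, rng) -> int:
        if self.continuation >= 1.0:
            return 2**31  # absorbing; always truncated by the requested length
        return int(rng.geometric(1.0 - self.continuation)) if self.continuation > 0 else 1


class FixedDuration:
    kind = "fixed"

    def __init__(self, length: int):
        if length < 1:
            raise ValueError("fixed duration must be >= 1")
        self.length = int(length)

    def support(self) -> np.ndarray:
        return np.array([self.length])

    def log_pmf(self) -> np.ndarray:
        return np.array([0.0])

    def sample(self, rng) -> int:
        return self.length


class HistogramDuration:
    kind = "histogram"

    def __init__(self, histogram: SmoothedHistogram):
        self.histogram = histogram
        mask = histogram.probs > 0
        self._support = np.nonzero(mask)[0] + 1
        self._log_pmf = np.log(histogram.probs[mask])

    def support(self) -> np.ndarray:
        return self._support

    def log_pmf(self) -> np.ndarray:
        return self._log_pmf

    def sample(self, rng) -> int:
        idx = sample_categorical(np.exp(self._log_pmf), rng)
        return int(self._support[idx])

    def restrict_phase(self, phase_in: int, phase_out: int) -> "HistogramDuration":
        """Keep only lengths d with d ≡ phase_out - phase_in (mod 3), renormalised."""
        want = (phase_out - phase_in) % 3
        probs = self.histogram.probs.copy()
        lengths = np.arange(1, len(probs) + 1)
        probs[lengths % 3 != want] = 0.0
        if probs.sum() <= 0:
            raise ValueError("phase constraint leaves no admissible duration")
        return HistogramDuration(SmoothedHistogram(probs / probs.sum()))


# ---------------------------------------------------------------------------
# emission wrappers
# ---------------------------------------------------------------------------


class CompositeEmission(SequenceModel):
    """Concatenation of fixed-width sub-models emitted as one word.

    Used for composite signal states (e.g. a start-codon state made of an
    upstream motif, the codon itself, and a downstream pattern).  Each part
    scores its own sub-window independently.
    """

    family = "composite"
    is_inhomogeneous = True

    def __init__(self, parts: list[SequenceModel]):
        if not parts:
            raise ValueError("composite emission needs at least one part")
        self.parts = list(parts)
        self.alphabet = parts[0].alphabet
        self.part_lengths = []
        for p in self.parts:
            w = getattr(p, "emission_length", None)
            if w is None:
                raise ValueError("composite parts must have fixed emission length")
            self.part_lengths.append(int(w))
        self.emission_length = sum(self.part_lengths)

    def log_probability(self, seq: Sequence, begin: int = 1, end: int | None = None) -> float:
        begin, end = self._check_window(seq, begin, end)
        if end - begin + 1 != self.emission_length:
            raise ValueError("window length %d does not match composite length %d"
                             % (end - begin + 1, self.emission_length))
        total = 0.0
        pos = begin
        for part, w in zip(self.parts, self.part_lengths):
            term = part.log_probability(seq, pos, pos + w - 1)
            if term == NEG_INF:
                return NEG_INF
            total += term
            pos += w
        return total

    def simulate(self, length: int | None = None, rng=None, name: str = "sim") -> Sequence:
        if length is not None and length != self.emission_length:
            raise ValueError("composite emission has fixed length %d" % self.emission_length)
        rng = as_rng(rng)
        values = np.concatenate([p.simulate(w, rng).values
                                 for p, w in zip(self.parts, self.part_lengths)])
        return Sequence(name, values, self.alphabet)

    def parameter_count(self) -> int:
        return sum(p.parameter_count() for p in self.parts)


class ReverseComplementModel(SequenceModel):
    """Score the reverse complement: P(s) = P_inner(revcomp(s)).

    The exact mirror of a forward-strand model; reverse-strand states built
    with this wrapper emit pattern p with the probability the forward model
    assigns to revcomp(p).  For factorable inner models the factorisation
    survives (terms become anti-causal), so prefix-sum scoring still applies
    via the reverse-complemented sequence.
    """

    def __init__(self, inner: SequenceModel):
        self.inner = inner
        self.alphabet = inner.alphabet
        if tuple(self.alphabet.symbols) != ("A", "C", "G", "T"):
            raise ValueError("reverse-complement wrapper requires the DNA alphabet")
        self.family = inner.family
        self.is_factorable = inner.is_factorable
        self.is_inhomogeneous = inner.is_inhomogeneous
        w = getattr(inner, "emission_length", None)
        if w is not None:
            self.emission_length = int(w)

    @property
    def period(self) -> int:
        return getattr(self.inner, "period", 1)

    def _max_context(self) -> int:
        inner = self.inner
        if hasattr(inner, "max_order"):
            return int(inner.max_order)
        if hasattr(inner, "order"):
            return int(inner.order)
        if hasattr(inner, "depth"):
            return int(inner.depth())
        return 0

    def log_probability(self, seq: Sequence, begin: int = 1, end: int | None = None,
                        phase: int = 0) -> float:
        begin, end = self._check_window(seq, begin, end)
        if not self.is_factorable:
            window = Sequence(seq.name, seq.values[begin - 1:end], seq.alphabet)
            return self.inner.log_probability(reverse_complement(window))
        # include downstream context: it precedes the window on the reverse strand
        c = min(self._max_context(), len(seq) - end)
        chunk = Sequence(seq.name, seq.values[begin - 1:end + c], seq.alphabet)
        rc = reverse_complement(chunk)
        return self.inner.log_probability(rc, c + 1, len(rc), phase=phase) \
            if isinstance(self.inner, FactorableModel) \
            else self.inner.log_probability(rc, c + 1, len(rc))

    def simulate(self, length: int, rng=None, name: str = "sim") -> Sequence:
        return reverse_complement(self.inner.simulate(length, rng, name))

    def parameter_count(self) -> int:
        return self.inner.parameter_count()


# ---------------------------------------------------------------------------
# states and model
# ---------------------------------------------------------------------------


@dataclass
class GhmmState:
    """One GHMM state: emission sub-model, duration law and out-transitions.

    ``phase_in``/``phase_out`` (codon positions, mod 3) constrain exon-like
    states: the duration support is filtered at build time so segment lengths
    keep the coding frame consistent, and ``phase_in`` anchors the reading
    frame of a periodic emission model at the segment start.
    """

    name: str
    emission: SequenceModel
    duration: object
    transitions: dict[str, float] = field(default_factory=dict)
    phase_in: int | None = None
    phase_out: int | None = None

    @property
    def emission_phase(self) -> int:
        return self.phase_in or 0


class Segmentation:
    """Ordered (state, begin, end) segments, 1-based inclusive, tiling 1..L."""

    def __init__(self, segments: list[tuple[str, int, int]], log_likelihood: float):
        self.segments = list(segments)
        self.log_likelihood = float(log_likelihood)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def __eq__(self, other):
        return isinstance(other, Segmentation) and self.segments == other.segments

    def state_per_position(self, length: int | None = None) -> list[str]:
        out: list[str] = []
        for name, b, e in self.segments:
            out.extend([name] * (e - b + 1))
        return out

    def to_tsv(self) -> str:
        lines = ["%s\t%d\t%d" % seg for seg in self.segments]
        lines.append("# log-likelihood\t%r" % self.log_likelihood)
        return "\n".join(lines) + "\n"

    def to_gff(self, seqname: str = "seq", source: str = "probseq") -> str:
        lines = []
        for name, b, e in self.segments:
            lines.append("%s\t%s\t%s\t%d\t%d\t.\t+\t.\t." % (seqname, source, name, b, e))
        return "\n".join(lines) + "\n"

    def __repr__(self):
        return "Segmentation(%r, log_likelihood=%.6g)" % (self.segments, self.log_likelihood)


class Ghmm(SequenceModel):
    """Generalized HMM over named states with sparse transitions.

    Build-time validation classifies every state as geometric (self-transition
    present; requires a factorable emission) or explicit-duration (fixed or
    histogram; self-transitions forbidden), checks that transition rows and
    the initial distribution are normalised, that fixed durations match the
    emission's declared width, and applies phase constraints to exon-like
    states.
    """

    family = "ghmm"

    def __init__(self, states: list[GhmmState], initial: dict[str, float], tol: float = 1e-6):
        self.states = list(states)
        self.alphabet = states[0].emission.alphabet
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError("duplicate state names")
        self.index = {n: i for i, n in enumerate(names)}
        self.state_names = names
        K = len(names)

        pi = np.zeros(K)
        for name, p in initial.items():
            if name not in self.index:
                raise ValueError("initial distribution references unknown state %r" % name)
            pi[self.index[name]] = p
        if abs(pi.sum() - 1.0) > tol or np.any(pi < 0):
            raise ValueError("initial distribution must sum to 1 (got %.6f)" % pi.sum())
        self.initial = pi
        self.log_pi = np.array([log_safe(p) for p in pi])

        self.log_trans: dict[tuple[int, int], float] = {}
        for s in self.states:
            total = 0.0
            for dest, p in s.transitions.items():
                if dest not in self.index:
                    raise ValueError("state %r has transition to unknown state %r"
                                     % (s.name, dest))
                if p < 0:
                    raise ValueError("negative transition probability from %r" % s.name)
                total += p
                if p > 0:
                    self.log_trans[(self.index[s.name], self.index[dest])] = math.log(p)
            if abs(total - 1.0) > tol:
                raise ValueError("transition row of state %r sums to %.6f, expected 1"
                                 % (s.name, total))

        self.is_geometric = np.zeros(K, dtype=bool)
        self.self_log = np.full(K, NEG_INF)
        for i, s in enumerate(self.states):
            self_p = s.transitions.get(s.name, 0.0)
            if isinstance(s.duration, GeometricDuration) or (
                    s.duration is None and self_p > 0):
                if s.duration is None:
                    s.duration = GeometricDuration(self_p)
                elif abs(s.duration.continuation - self_p) > tol:
                    raise ValueError(
                        "state %r: geometric continuation %.6f differs from "
                        "self-transition %.6f" % (s.name, s.duration.continuation, self_p))
                if not getattr(s.emission, "is_factorable", False):
                    raise ValueError("geometric state %r needs a factorable emission"
                                     % s.name)
                if getattr(s.emission, "period", 1) != 1:
                    raise ValueError("geometric state %r cannot use a periodic emission"
                                     % s.name)
                self.is_geometric[i] = True
                self.self_log[i] = log_safe(self_p)
            else:
                if self_p > 0:
                    raise ValueError("explicit-duration state %r may not have a "
                                     "self-transition" % s.name)
                if s.duration is None:
                    raise ValueError("state %r has neither a duration model nor a "
                                     "self-transition" % s.name)
                width = getattr(s.emission, "emission_length", None)
                if isinstance(s.duration, FixedDuration) and width is not None \
                        and width != s.duration.length:
                    raise ValueError(
                        "state %r: declared duration %d does not match emission "
                        "length %d" % (s.name, s.duration.length, width))
                if s.phase_in is not None and s.phase_out is not None \
                        and isinstance(s.duration, HistogramDuration):
                    s.duration = s.duration.restrict_phase(s.phase_in, s.phase_out)

        # sparse predecessor lists (excluding self-loops)
        self.predecessors: list[list[tuple[int, float]]] = [[] for _ in range(K)]
        for (j, k), la in self.log_trans.items():
            if j != k:
                self.predecessors[k].append((j, la))
        for preds in self.predecessors:
            preds.sort()
        self.max_out_degree = max(
            (sum(1 for (j2, _k) in self.log_trans if j2 == j) for j in range(K)),
            default=0)

    @property
    def n_states(self) -> int:
        return len(self.states)

    # decoding / simulation entry points defined below as module functions;
    # thin method aliases for convenience:
    def viterbi(self, seq: Sequence, plan=None) -> Segmentation:
        return ghmm_viterbi(self, seq, plan)

    def simulate_with_path(self, length: int, rng=None, name: str = "sim"):
        return ghmm_simulate(self, length, rng, name)

    def simulate(self, length: int, rng=None, name: str = "sim") -> Sequence:
        return ghmm_simulate(self, length, rng, name)[0]

    def log_probability(self, seq: Sequence, begin: int = 1, end: int | None = None) -> float:
        """Joint log-likelihood of the best segmentation (Viterbi score)."""
        begin, end = self._check_window(seq, begin, end)
        window = Sequence(seq.name, seq.values[begin - 1:end], seq.alphabet)
        return ghmm_viterbi(self, window).log_likelihood

    def parameter_count(self) -> int:
        k = sum(1 for _ in self.log_trans) - self.n_states  # free transition probs
        k += self.n_states - 1  # initial distribution
        seen = set()
        for s in self.states:
            if id(s.emission) not in seen:
                seen.add(id(s.emission))
                k += s.emission.parameter_count()
            if isinstance(s.duration, HistogramDuration):
                k += len(s.duration.support()) - 1
        return max(k, 1)


def build_ghmm(states: list[GhmmState], initial: dict[str, float],
               transitions: dict[str, dict[str, float]] | None = None) -> Ghmm:
    """Validate and assemble a GHMM.

    ``transitions``, if given, overrides the per-state transition maps
    (keyed by source state name).
    """
    if transitions is not None:
        for s in states:
            s.transitions = dict(transitions.get(s.name, {}))
    return Ghmm(states, initial)


# ---------------------------------------------------------------------------
# prefix sum arrays
# ---------------------------------------------------------------------------


class PrefixSumArray:
    """Cumulative per-position log-scores giving O(1) window likelihoods.

    For a periodic model with period p, p arrays are kept, one per phase
    offset; zero-probability positions are tracked in a separate counter so
    that windows containing one score exactly -inf (and are skippable).
    """

    def __init__(self, model: SequenceModel, seq: Sequence):
        self.model = model
        self.L = len(seq)
        if isinstance(model, ReverseComplementModel):
            self._rc_inner = PrefixSumArray._build_direct(model.inner,
                                                          reverse_complement(seq))
            self.period = model.period
            return
        self._rc_inner = None
        self.period, self.cum, self.zeros = PrefixSumArray._build_arrays(model, seq)

    @staticmethod
    def _build_direct(model, seq):
        psa = object.__new__(PrefixSumArray)
        psa.model = model
        psa.L = len(seq)
        psa._rc_inner = None
        psa.period, psa.cum, psa.zeros = PrefixSumArray._build_arrays(model, seq)
        return psa

    @staticmethod
    def _build_arrays(model: FactorableModel, seq: Sequence):
        if not getattr(model, "is_factorable", False):
            raise ValueError("prefix sum arrays require a factorable model")
        p = getattr(model, "period", 1)
        L = len(seq)
        cum = np.zeros((p, L + 1))
        zeros = np.zeros((p, L + 1), dtype=np.int64)
        v = seq.values
        for r in range(p):
            acc = 0.0
            nz = 0
            for t in range(L):
                term = model.position_log_prob(v, t, (t + r) % p)
                if term == NEG_INF:
                    nz += 1
                else:
                    acc += term
                cum[r, t + 1] = acc
                zeros[r, t + 1] = nz
        return p, cum, zeros

    def lookup(self, i0: int, j0: int, phase: int = 0) -> float:
        """Log-likelihood of the window [i0, j0] (0-based inclusive), the
        window's first position having model phase ``phase``."""
        if self._rc_inner is not None:
            return self._rc_inner.lookup(self.L - 1 - j0, self.L - 1 - i0, phase)
        r = (phase - i0) % self.period
        if self.zeros[r, j0 + 1] - self.zeros[r, i0]:
            return NEG_INF
        return float(self.cum[r, j0 + 1] - self.cum[r, i0])

    def lookup_ends(self, starts: np.ndarray, j0: int, phase: int = 0) -> np.ndarray:
        """Vectorised lookup for many window starts sharing one end."""
        if self._rc_inner is not None:
            inner = self._rc_inner
            i0 = self.L - 1 - j0
            ends = self.L - 1 - starts
            r = (phase - i0) % inner.period * np.ones(len(starts), dtype=np.int64)
            vals = inner.cum[r, ends + 1] - inner.cum[r, i0]
            bad = (inner.zeros[r, ends + 1] - inner.zeros[r, i0]) > 0
            vals[bad] = NEG_INF
            return vals
        r = (phase - starts) % self.period
        vals = self.cum[r, j0 + 1] - self.cum[r, starts]
        bad = (self.zeros[r, j0 + 1] - self.zeros[r, starts]) > 0
        vals[bad] = NEG_INF
        return vals

    def position_terms(self) -> np.ndarray:
        """Per-position log scores (period-1 models only)."""
        if self._rc_inner is not None:
            inner = self._rc_inner
            terms = np.diff(inner.cum[0])
            terms[np.diff(inner.zeros[0]) > 0] = NEG_INF
            return terms[::-1].copy()
        if self.period != 1:
            raise ValueError("per-position terms are only defined for period-1 models")
        terms = np.diff(self.cum[0])
        terms[np.diff(self.zeros[0]) > 0] = NEG_INF
        return terms


def build_psa(sub_model: SequenceModel, seq: Sequence) -> PrefixSumArray:
    return PrefixSumArray(sub_model, seq)


# ---------------------------------------------------------------------------
# decoding plan
# ---------------------------------------------------------------------------


@dataclass
class StatePlan:
    name: str
    geometric: bool
    support: np.ndarray | None  # None for geometric (d = 1 recursion)
    max_duration: int | None
    factorable: bool
    predecessors: list[tuple[int, float]]


@dataclass
class DecodingPlan:
    """Pure optimisation descriptor: duration supports, PSA eligibility and
    sparse predecessor lists per state.  Decoding results never depend on it."""

    states: list[StatePlan]
    max_out_degree: int

    @property
    def max_duration(self) -> int | None:
        ds = [sp.max_duration for sp in self.states if not sp.geometric]
        if any(d is None for d in ds):
            return None
        return max(ds, default=1)


def plan_decoding(ghmm: Ghmm) -> DecodingPlan:
    plans = []
    for i, s in enumerate(ghmm.states):
        if ghmm.is_geometric[i]:
            plans.append(StatePlan(s.name, True, None, None,
                                   bool(getattr(s.emission, "is_factorable", False)),
                                   ghmm.predecessors[i]))
        else:
            supp = s.duration.support()
            plans.append(StatePlan(s.name, False, supp, int(supp.max()),
                                   bool(getattr(s.emission, "is_factorable", False)),
                                   ghmm.predecessors[i]))
    return DecodingPlan(plans, ghmm.max_out_degree)


# ---------------------------------------------------------------------------
# shared segment scoring (used by the naive decoder, the simulator's scorer
# and the optimized decoder's non-factorable fallback)
# ---------------------------------------------------------------------------


def _segment_emission(state: GhmmState, seq: Sequence, i0: int, j0: int) -> float:
    """Emission log-probability of seq[i0..j0] (0-based incl.) from a state."""
    em = state.emission
    if isinstance(em, ReverseComplementModel):
        return em.log_probability(seq, i0 + 1, j0 + 1, phase=state.emission_phase)
    if isinstance(em, FactorableModel):
        return em.log_probability(seq, i0 + 1, j0 + 1, phase=state.emission_phase)
    return em.log_probability(seq, i0 + 1, j0 + 1)


def _duration_weight(ghmm: Ghmm, k: int, d: int) -> float:
    """Log-weight of a length-d segment in state k (exit probability excluded:
    it is paid by the inter-segment transition)."""
    s = ghmm.states[k]
    if ghmm.is_geometric[k]:
        return (d - 1) * ghmm.self_log[k] if d > 1 else 0.0
    supp = s.duration.support()
    idx = np.nonzero(supp == d)[0]
    if idx.size == 0:
        return NEG_INF
    return float(s.duration.log_pmf()[idx[0]])


def path_log_likelihood(ghmm: Ghmm, seq: Sequence, segmentation: Segmentation) -> float:
    """Joint log-likelihood of a given segmentation of ``seq``."""
    total = 0.0
    prev = None
    for name, b, e in segmentation:
        k = ghmm.index[name]
        if prev is None:
            total += ghmm.log_pi[k]
        else:
            total += ghmm.log_trans.get((prev, k), NEG_INF)
        total += _duration_weight(ghmm, k, e - b + 1)
        total += _segment_emission(ghmm.states[k], seq, b - 1, e - 1)
        prev = k
        if total == NEG_INF:
            return NEG_INF
    return total


# ---------------------------------------------------------------------------
# naive reference decoder
# ---------------------------------------------------------------------------


def ghmm_viterbi_naive(ghmm: Ghmm, seq: Sequence) -> Segmentation:
    """Segment-DP reference decoder: every candidate segment is scored by a
    direct emission-model call; geometric states are treated as explicit
    durations with weight a_kk^(d-1) and unbounded support.  Quadratic in L;
    intended for small instances and cross-checking."""
    L = len(seq)
    K = ghmm.n_states
    V = np.full((K, L), NEG_INF)
    back: list[list[tuple[int, int] | None]] = [[None] * L for _ in range(K)]

    for t in range(L):
        for k in range(K):
            state = ghmm.states[k]
            if ghmm.is_geometric[k]:
                durations = [(d, (d - 1) * ghmm.self_log[k]) for d in range(1, t + 2)]
            else:
                durations = [(int(d), float(w))
                             for d, w in zip(state.duration.support(),
                                             state.duration.log_pmf()) if d <= t + 1]
            best = NEG_INF
            best_ptr = None
            for d, dw in durations:
                if dw == NEG_INF:
                    continue
                start = t - d + 1
                if start == 0:
                    prev_score, prev_state = float(ghmm.log_pi[k]), -1
                else:
                    prev_score, prev_state = NEG_INF, -1
                    for j, la in ghmm.predecessors[k]:
                        cand = V[j, start - 1] + la
                        if cand > prev_score:
                            prev_score, prev_state = cand, j
                if prev_score == NEG_INF:
                    continue
                em = _segment_emission(state, seq, start, t)
                score = prev_score + dw + em
                if score > best:
                    best = score
                    best_ptr = (d, prev_state)
            V[k, t] = best
            back[k][t] = best_ptr

    return _traceback_segments(ghmm, V, back, L)


def _traceback_segments(ghmm, V, back, L) -> Segmentation:
    best_k = int(np.argmax(V[:, L - 1]))
    loglik = float(V[best_k, L - 1])
    if loglik == NEG_INF:
        return Segmentation([], NEG_INF)
    segments: list[tuple[str, int, int]] = []
    k, t = best_k, L - 1
    while t >= 0:
        d, prev_state = back[k][t]
        segments.append((ghmm.state_names[k], t - d + 2, t + 1))
        t -= d
        if t < 0:
            break
        k = prev_state
    segments.reverse()
    return Segmentation(segments, loglik)


# ---------------------------------------------------------------------------
# optimized decoder
# ---------------------------------------------------------------------------


def ghmm_viterbi(ghmm: Ghmm, seq: Sequence, plan: DecodingPlan | None = None) -> Segmentation:
    """Viterbi decoding that auto-exploits the architecture.

    Geometric states use the d = 1 recursion over per-position emission terms;
    explicit-duration states loop only over their finite duration support,
    score candidate windows in O(1) through prefix sum arrays when the
    emission is factorable (with one array per phase for periodic models), and
    skip candidates whose window contains a zero-probability position.
    """
    if plan is None:
        plan = plan_decoding(ghmm)
    L = len(seq)
    K = ghmm.n_states
    if L == 0:
        return Segmentation([], NEG_INF)

    # one PSA per distinct factorable emission model
    psas: dict[int, PrefixSumArray] = {}
    for s in ghmm.states:
        if getattr(s.emission, "is_factorable", False) and id(s.emission) not in psas:
            psas[id(s.emission)] = PrefixSumArray(s.emission, seq)

    # per-position emission terms for geometric states
    geo_terms: dict[int, np.ndarray] = {}
    for k in range(K):
        if ghmm.is_geometric[k]:
            geo_terms[k] = psas[id(ghmm.states[k].emission)].position_terms()

    # precomputed window scores for fixed-width non-factorable signal states:
    # sig_scores[k][t] = emission score of the window of width w ending at t
    sig_scores: dict[int, np.ndarray] = {}
    for k in range(K):
        s = ghmm.states[k]
        if ghmm.is_geometric[k] or getattr(s.emission, "is_factorable", False):
            continue
        w = getattr(s.emission, "emission_length", None)
        supp = s.duration.support()
        if w is not None and len(supp) == 1 and int(supp[0]) == int(w):
            arr = np.full(L, NEG_INF)
            for t in range(w - 1, L):
                arr[t] = _segment_emission(s, seq, t - w + 1, t)
            sig_scores[k] = arr

    V = np.full((K, L), NEG_INF)
    W = np.full((K, L), NEG_INF)      # best predecessor score entering k after pos t
    Wptr = np.full((K, L), -1, dtype=np.int64)
    dur_ptr = np.zeros((K, L), dtype=np.int64)  # 0 = geometric continuation

    for t in range(L):
        for k in range(K):
            s = ghmm.states[k]
            if ghmm.is_geometric[k]:
                e = geo_terms[k][t]
                if e == NEG_INF:
                    V[k, t] = NEG_INF
                    continue
                if t == 0:
                    V[k, t] = ghmm.log_pi[k] + e
                    dur_ptr[k, t] = 1
                else:
                    enter = W[k, t - 1]
                    stay = V[k, t - 1] + ghmm.self_log[k]
                    if enter >= stay:
                        V[k, t] = enter + e
                        dur_ptr[k, t] = 1
                    else:
                        V[k, t] = stay + e
                        dur_ptr[k, t] = 0
            else:
                supp = s.duration.support()
                log_pmf = s.duration.log_pmf()
                mask = supp <= t + 1
                if not mask.any():
                    continue
                ds = supp[mask]
                dw = log_pmf[mask]
                starts = t - ds + 1
                prev = np.where(starts > 0, W[k, starts - 1], ghmm.log_pi[k])
                if k in sig_scores:
                    emis = np.array([sig_scores[k][t]])
                elif id(s.emission) in psas:
                    emis = psas[id(s.emission)].lookup_ends(starts, t, s.emission_phase)
                else:
                    emis = np.array([_segment_emission(s, seq, int(st), t)
                                     for st in starts])
                total = prev + dw + emis
                best_i = int(np.argmax(total))  # supports ascend: shortest d wins ties
                if total[best_i] > NEG_INF:
                    V[k, t] = total[best_i]
                    dur_ptr[k, t] = int(ds[best_i])
        # update entry scores for the next position
        for k in range(K):
            best, ptr = NEG_INF, -1
            for j, la in ghmm.predecessors[k]:
                cand = V[j, t] + la
                if cand > best:
                    best, ptr = cand, j
            W[k, t] = best
            Wptr[k, t] = ptr

    best_k = int(np.argmax(V[:, L - 1]))
    loglik = float(V[best_k, L - 1])
    if loglik == NEG_INF:
        return Segmentation([], NEG_INF)
    segments: list[tuple[str, int, int]] = []
    k, t = best_k, L - 1
    cur_end = t
    while t >= 0:
        d = int(dur_ptr[k, t])
        if d == 0:  # geometric continuation
            t -= 1
            continue
        segments.append((ghmm.state_names[k], t - d + 1 + 1, cur_end + 1))
        t -= d
        if t < 0:
            break
        k = int(Wptr[k, t])
        cur_end = t
    segments.reverse()
    return Segmentation(segments, loglik)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def ghmm_simulate(ghmm: Ghmm, length: int, rng=None, name: str = "sim"):
    """Sample (sequence, segmentation) of exactly ``length`` symbols.

    The hidden path follows the initial/transition/duration laws; the final
    segment is truncated at ``length``.  Factorable emissions condition on the
    previously emitted symbols (matching the decoder's scoring); fixed-width
    signal emissions are drawn as whole words.
    """
    if length < 1:
        raise ValueError("simulation length must be >= 1")
    rng = as_rng(rng)
    values: list[int] = []
    segments: list[tuple[str, int, int]] = []
    k = sample_categorical(ghmm.initial, rng)
    while len(values) < length:
        s = ghmm.states[k]
        d = s.duration.sample(rng)
        d = min(d, length - len(values))
        begin = len(values) + 1
        em = s.emission
        if isinstance(em, FactorableModel):
            for offset in range(d):
                phase = (s.emission_phase + offset) % getattr(em, "period", 1)
                values.append(em.sample_next(values, rng, phase))
        else:
            word = em.simulate(getattr(em, "emission_length", d), rng)
            values.extend(int(x) for x in word.values[:d])
        segments.append((s.name, begin, len(values)))
        if len(values) >= length:
            break
        # next state among non-self destinations
        dests = [(j, math.exp(la)) for (src, j), la in ghmm.log_trans.items()
                 if src == k and j != k]
        if not dests:
            break
        probs = np.array([p for _, p in dests])
        k = dests[sample_categorical(probs / probs.sum(), rng)][0]
    seq = Sequence(name, values, ghmm.alphabet)
    seg = Segmentation(segments, NEG_INF)
    try:
        seg.log_likelihood = path_log_likelihood(ghmm, seq, seg)
    except ValueError:
        # the final segment was truncated at the requested length and its
        # fixed-width emission cannot be scored as a partial word
        seg.log_likelihood = float("nan")
    return seq, seg
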