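"""Alphabets, index-encoded sequences, sequence I/O and the shared model contract.

Every model family in this package operates on sequences over a finite,
ordered symbol alphabet.  Symbols are arbitrary string tokens (not
necessarily single characters); sequences are stored internally as numpy
arrays of 0-based symbol indices.  All probabilities are kept in natural-log
space, with ``-inf`` representing probability zero.

Coordinates at the API surface are 1-based inclusive (``begin``/``end``);
internal array indices are 0-based.
"""

from __future__ import annotations

import io
import math
from abc import ABC, abstractmethod
from typing import Iterable, Iterator, Sequence as TypingSequence

import numpy as np

NEG_INF = float("-inf")

__all__ = [
    "NEG_INF",
    "Alphabet",
    "DNA",
    "Sequence",
    "SequenceModel",
    "FactorableModel",
    "encode",
    "reverse_complement",
    "read_sequences",
    "write_sequences",
    "as_rng",
]


def as_rng(seed_or_rng) -> np.random.Generator:
    """Return a numpy Generator from a seed, a Generator, or None."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


class Alphabet:
    """Ordered set of distinct string tokens with a token -> index bijection."""

    def __init__(self, symbols: Iterable[str]):
        symbols = [str(s) for s in symbols]
        if len(set(symbols)) != len(symbols):
            raise ValueError("alphabet has duplicate tokens: %r" % (symbols,))
        if not symbols:
            raise ValueError("alphabet must contain at least one token")
        self.symbols: tuple[str, ...] = tuple(symbols)
        self._index = {s: i for i, s in enumerate(self.symbols)}

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise KeyError("token %r not in alphabet %r" % (token, self.symbols))

    def symbol(self, index: int) -> str:
        return self.symbols[index]

    def __eq__(self, other) -> bool:
        return isinstance(other, Alphabet) and self.symbols == other.symbols

    def __hash__(self) -> int:
        return hash(self.symbols)

    def __repr__(self) -> str:
        return "Alphabet(%r)" % (list(self.symbols),)


#: The standard DNA alphabet in A,C,G,T order.
DNA = Alphabet("ACGT")

_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class Sequence:
    """A named, index-encoded sequence over an :class:`Alphabet`."""

    __slots__ = ("name", "values", "alphabet")

    def __init__(self, name: str, values, alphabet: Alphabet):
        values = np.asarray(values, dtype=np.int64)
        if values.ndim != 1:
            raise ValueError("sequence values must be one-dimensional")
        if values.size and (values.min() < 0 or values.max() >= len(alphabet)):
            raise ValueError(
                "sequence %r contains indices outside 0..%d" % (name, len(alphabet) - 1)
            )
        self.name = name
        self.values = values
        self.alphabet = alphabet

    def __len__(self) -> int:
        return int(self.values.size)

    def __getitem__(self, i):
        return self.values[i]

    def __iter__(self):
        return iter(self.values)

    def tokens(self) -> list[str]:
        return [self.alphabet.symbol(int(v)) for v in self.values]

    def __str__(self) -> str:
        sep = "" if all(len(s) == 1 for s in self.alphabet.symbols) else " "
        return sep.join(self.tokens())

    def __repr__(self) -> str:
        text = str(self)
        if len(text) > 60:
            text = text[:57] + "..."
        return "Sequence(%r, %r)" % (self.name, text)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Sequence)
            and self.alphabet == other.alphabet
            and np.array_equal(self.values, other.values)
        )


def encode(tokens: TypingSequence[str], alphabet: Alphabet, name: str = "") -> Sequence:
    """Encode a list of tokens into a :class:`Sequence`.

    Raises ``ValueError`` naming the offending token and its 1-based position
    when a token is not in the alphabet.
    """
    values = np.empty(len(tokens), dtype=np.int64)
    for pos, tok in enumerate(tokens):
        if tok not in alphabet:
            raise ValueError(
                "unknown token %r at position %d (alphabet %r)"
                % (tok, pos + 1, list(alphabet.symbols))
            )
        values[pos] = alphabet.index(tok)
    return Sequence(name, values, alphabet)


def reverse_complement(seq: Sequence) -> Sequence:
    """Reverse complement of a DNA sequence (tokens A/C/G/T)."""
    try:
        toks = [_DNA_COMPLEMENT[t] for t in reversed(seq.tokens())]
    except KeyError as exc:
        raise ValueError("cannot complement non-DNA token %s" % exc)
    return encode(toks, seq.alphabet, name=seq.name)


# ---------------------------------------------------------------------------
# Sequence I/O
#
# Two plain-text formats are accepted:
#   * FASTA, for single-character alphabets (parsed with Biopython);
#   * a whitespace format with one record per line, "name: tok1 tok2 ... tokL",
#     which supports multi-character tokens.  The writer emits this format.
# ---------------------------------------------------------------------------


def _is_fasta(text: str) -> bool:
    for line in text.splitlines():
        if line.strip():
            return line.lstrip().startswith(">")
    return False


def read_sequences(source, alphabet: Alphabet) -> list[Sequence]:
    """Read sequences from a path, file handle, or string of text.

    The format (FASTA vs "name: tok tok ...") is auto-detected from the first
    non-blank line.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        source = str(source)
        if "\n" in source or ":" in source and not _looks_like_path(source):
            text = source
        else:
            with open(source) as fh:
                text = fh.read()
    if _is_fasta(text):
        from Bio import SeqIO

        records = SeqIO.parse(io.StringIO(text), "fasta")
        return [encode(list(str(r.seq)), alphabet, name=r.id) for r in records]
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError("line %d: expected 'name: tok tok ...'" % lineno)
        name, _, rest = line.partition(":")
        out.append(encode(rest.split(), alphabet, name=name.strip()))
    return out


def _looks_like_path(s: str) -> bool:
    import os

    return os.path.exists(s)


def write_sequences(seqs: Iterable[Sequence], handle) -> None:
    """Write sequences in the "name: tok tok ..." one-record-per-line format."""
    close = False
    if not hasattr(handle, "write"):
        handle = open(handle, "w")
        close = True
    try:
        for s in seqs:
            handle.write("%s: %s\n" % (s.name or "seq", " ".join(s.tokens())))
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# The model contract
# ---------------------------------------------------------------------------


class SequenceModel(ABC):
    """Common contract satisfied by every model family.

    ``log_probability(seq, begin, end)`` returns the natural-log likelihood of
    the 1-based inclusive window ``seq[begin..end]``.  For chain models each
    position conditions on the actually available history in the *full*
    sequence (so a window likelihood equals the corresponding prefix-sum-array
    difference); signal models of fixed width condition only within their
    window.
    """

    #: family tag, one of iid | markov | vlmc | wam | imm | sbsw | hmm |
    #: profile-hmm | pair-hmm | ghmm
    family: str = "?"
    is_factorable: bool = False
    is_inhomogeneous: bool = False

    alphabet: Alphabet

    @abstractmethod
    def log_probability(self, seq: Sequence, begin: int = 1, end: int | None = None) -> float:
        """Log-likelihood of seq[begin..end] (1-based inclusive); -inf allowed."""

    @abstractmethod
    def simulate(self, length: int, rng=None, name: str = "sim") -> Sequence:
        """Sample a sequence of the given length; reproducible given a seed."""

    @abstractmethod
    def parameter_count(self) -> int:
        """Number of free parameters (used by AIC/BIC)."""

    def _check_window(self, seq: Sequence, begin: int, end: int | None) -> tuple[int, int]:
        if end is None:
            end = len(seq)
        if not (1 <= begin <= end <= len(seq)):
            raise ValueError(
                "invalid window [%d, %d] for sequence of length %d" % (begin, end, len(seq))
            )
        if seq.alphabet != self.alphabet:
            raise ValueError("sequence alphabet does not match model alphabet")
        return begin, end


class FactorableModel(SequenceModel):
    """A model whose log-likelihood is a sum of one term per position.

    Subclasses implement :meth:`position_log_prob`; ``period`` > 1 marks
    periodic (phase-indexed) models such as three-periodic coding chains.
    The per-position factorisation is what enables constant-time window
    scoring through a prefix sum array.
    """

    is_factorable = True
    #: number of phase-indexed parameter sets (1 = homogeneous)
    period: int = 1

    @abstractmethod
    def position_log_prob(self, values: np.ndarray, t: int, phase: int = 0) -> float:
        """Log P(values[t] | history), 0-based t; phase applies if period > 1."""

    @abstractmethod
    def sample_next(self, history: list[int], rng, phase: int = 0) -> int:
        """Sample the next symbol index given the (possibly empty) history."""

    def log_probability(self, seq: Sequence, begin: int = 1, end: int | None = None,
                        phase: int = 0) -> float:
        begin, end = self._check_window(seq, begin, end)
        total = 0.0
        for t in range(begin - 1, end):
            p = phase if self.period == 1 else (phase + (t - (begin - 1))) % self.period
            term = self.position_log_prob(seq.values, t, p)
            if term == NEG_INF:
                return NEG_INF
            total += term
        return total

    def simulate(self, length: int, rng=None, name: str = "sim") -> Sequence:
        if length < 1:
            raise ValueError("simulation length must be >= 1")
        rng = as_rng(rng)
        history: list[int] = []
        for t in range(length):
            phase = t % self.period
            history.append(self.sample_next(history, rng, phase))
        return Sequence(name, history, self.alphabet)


def log_safe(p: float) -> float:
    """Natural log mapping 0 -> -inf without warnings."""
    return math.log(p) if p > 0.0 else NEG_INF


def log_array(p: np.ndarray) -> np.ndarray:
    out = np.full(np.shape(p), NEG_INF)
    p = np.asarray(p, dtype=float)
    mask = p > 0.0
    out[mask] = np.log(p[mask])
    return out
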