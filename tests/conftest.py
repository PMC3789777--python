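import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from probseq import DNA, DiscreteIid, MarkovChain, Sequence
from probseq.hmm import Hmm


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def dna():
    return DNA


def random_distribution(rng, n, floor=0.05):
    x = rng.random(n) + floor
    return x / x.sum()


def random_hmm(rng, n_states, alphabet=DNA) -> Hmm:
    K, a = n_states, len(alphabet)
    pi = random_distribution(rng, K)
    A = np.vstack([random_distribution(rng, K) for _ in range(K)])
    E = np.vstack([random_distribution(rng, a) for _ in range(K)])
    return Hmm(alphabet, ["s%d" % i for i in range(K)], pi, A, E)


def random_markov(rng, order, alphabet=DNA) -> MarkovChain:
    a = len(alphabet)
    tables = [np.vstack([random_distribution(rng, a) for _ in range(a**m)])
              for m in range(order + 1)]
    return MarkovChain(alphabet, tables)


def random_iid(rng, alphabet=DNA) -> DiscreteIid:
    return DiscreteIid(alphabet, random_distribution(rng, len(alphabet)))


def random_sequence(rng, length, alphabet=DNA, name="rand") -> Sequence:
    return Sequence(name, rng.integers(0, len(alphabet), size=length), alphabet)
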