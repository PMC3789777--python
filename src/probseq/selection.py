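"""Model selection by information criteria and Bayesian classification.

The criteria are the standard Schwarz and Akaike forms,

    BIC = -2 log L + k ln n,        AIC = -2 log L + 2 k,

with k the model's free-parameter count and n the total number of observed
symbols across the training sequences (matching the per-symbol granularity of
the likelihood).  Selection picks the grid point with the smallest criterion
value; ties go to the smaller parameter count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
from scipy.special import logsumexp

from .core import NEG_INF, Sequence, SequenceModel

__all__ = [
    "count_parameters",
    "information_criterion",
    "select_model",
    "SelectionResult",
    "BayesClassifier",
    "bayes_classify",
]


def count_parameters(model: SequenceModel) -> int:
    """Free-parameter count of a trained model (delegates to the family)."""
    return model.parameter_count()


def total_log_likelihood(model: SequenceModel, seqs: Iterable[Sequence]) -> float:
    return sum(model.log_probability(s) for s in seqs)


def information_criterion(model: SequenceModel, seqs: Iterable[Sequence],
                          which: str = "bic") -> float:
    """BIC or AIC of a trained model on its training data (smaller is better)."""
    seqs = list(seqs)
    logl = total_log_likelihood(model, seqs)
    if logl == NEG_INF:
        raise ValueError("training set has probability zero under the model")
    k = count_parameters(model)
    n = sum(len(s) for s in seqs)
    which = which.lower()
    if which == "bic":
        return -2.0 * logl + k * math.log(n)
    if which == "aic":
        return -2.0 * logl + 2.0 * k
    raise ValueError("criterion must be 'bic' or 'aic'")


@dataclass
class SelectionResult:
    """Criterion table over a training-parameter grid and the chosen point."""

    table: dict  # grid point -> (k, n, max log-likelihood, criterion value)
    chosen: object
    failures: dict = field(default_factory=dict)

    @property
    def model(self):
        return self._models[self.chosen]

    _models: dict = field(default_factory=dict, repr=False)


def select_model(trainer: Callable, grid: Iterable, seqs: Iterable[Sequence],
                 which: str = "bic") -> SelectionResult:
    """Train at every grid point, score each fit, return table and argmin.

    ``trainer(point, seqs)`` must return a trained model.  A trainer failure
    at a grid point is recorded and the point skipped.  The chosen point
    minimises the criterion; ties break to the smallest parameter count.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    seqs = list(seqs)
    n = sum(len(s) for s in seqs)
    table: dict = {}
    models: dict = {}
    failures: dict = {}
    for point in grid:
        try:
            model = trainer(point, seqs)
            value = information_criterion(model, seqs, which)
            k = count_parameters(model)
            logl = total_log_likelihood(model, seqs)
        except Exception as exc:  # noqa: BLE001 - recorded, point skipped
            failures[point] = str(exc)
            continue
        table[point] = (k, n, logl, value)
        models[point] = model
    if not table:
        raise ValueError("every grid point failed: %r" % failures)
    chosen = min(table, key=lambda p: (table[p][3], table[p][0]))
    return SelectionResult(table=table, chosen=chosen, failures=failures, _models=models)


class BayesClassifier:
    """Bayesian classifier over labelled models with prior weights.

    posterior(label) ∝ exp(log-likelihood) · prior, computed stably in log
    space.  When every model assigns probability zero the predicted label is
    ``None`` and the posterior vector is flagged invalid (NaN).
    """

    def __init__(self, items: list[tuple[str, SequenceModel, float]]):
        if not items:
            raise ValueError("classifier needs at least one model")
        self.labels = [lab for lab, _m, _p in items]
        self.models = [m for _l, m, _p in items]
        priors = np.array([p for _l, _m, p in items], dtype=float)
        if np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-6:
            raise ValueError("priors must be non-negative and sum to 1")
        self.priors = priors

    def classify(self, seq: Sequence):
        """Return (per-label posterior dict, log-likelihood dict, predicted label)."""
        logliks = np.array([m.log_probability(seq) for m in self.models])
        with np.errstate(divide="ignore"):
            scores = logliks + np.log(self.priors)
        if np.all(scores == NEG_INF):
            post = {lab: float("nan") for lab in self.labels}
            return post, dict(zip(self.labels, logliks)), None
        total = logsumexp(scores)
        post_vec = np.exp(scores - total)
        label = self.labels[int(np.argmax(post_vec))]
        return (dict(zip(self.labels, post_vec)),
                dict(zip(self.labels, logliks)), label)


def bayes_classify(classifier: BayesClassifier, seq: Sequence):
    return classifier.classify(seq)
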