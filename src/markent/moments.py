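"""Exact and Monte-Carlo moments of entropy estimators on Markov chains.

An entropy estimator applied to a random sequence is itself a random
variable.  For short sequences its first two moments can be computed
exactly by enumerating every one of the ``L**N`` possible sequences and
weighting the estimator value by the exact Markov probability of the
sequence; the bias, standard deviation and mean squared error follow.  For
longer sequences the same statistics are estimated from ``M`` simulated
replicates (sample mean and unbiased sample variance).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from numpy.typing import NDArray

from . import estimators as est
from . import markov
from .exceptions import EnumerationTooLargeError, InvalidParameterError

__all__ = [
    "DEFAULT_ENUMERATION_BUDGET",
    "EstimatorStats",
    "enumerate_sequences",
    "exact_stats",
    "mc_stats",
]

DEFAULT_ENUMERATION_BUDGET = 2**22


@dataclass(frozen=True)
class EstimatorStats:
    """First two moments of an estimator plus the derived error measures."""

    estimator_id: str
    mean: float
    second_moment: float
    true_entropy: float

    @property
    def bias(self) -> float:
        return self.mean - self.true_entropy

    @property
    def sd(self) -> float:
        return math.sqrt(max(self.second_moment - self.mean**2, 0.0))

    @property
    def mse(self) -> float:
        return self.bias**2 + self.sd**2


def enumerate_sequences(
    alphabet_size: int,
    length: int,
    budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> Iterator[NDArray[np.int64]]:
    """Yield every sequence of the given length, in lexicographic order.

    Raises :class:`EnumerationTooLargeError` when ``L**N`` exceeds the
    budget (default 2**22), in which case Monte-Carlo estimation via
    :func:`mc_stats` is the fallback.
    """
    if alphabet_size < 1 or length < 1:
        raise InvalidParameterError("alphabet size and length must be >= 1")
    total = alphabet_size**length
    if total > budget:
        raise EnumerationTooLargeError(
            f"{alphabet_size}**{length} = {total} sequences exceed the budget {budget}; "
            "use mc_stats instead"
        )
    for tup in itertools.product(range(alphabet_size), repeat=length):
        yield np.array(tup, dtype=np.int64)


def _dedup_evaluator(estimator_id: str, alphabet_size: int):
    """Closure evaluating one estimator with caching for count-based ones.

    Count-based estimators depend on the sequence only through its count
    vector, so their values are cached by that key; order-sensitive ones
    (CC, CMM) are always evaluated on the full sequence.
    """
    if estimator_id in est.COUNT_BASED_IDS:
        cache: dict[tuple, float] = {}

        def ev(s: NDArray) -> float:
            key = tuple(np.bincount(s, minlength=alphabet_size))
            if key not in cache:
                cache[key] = est.evaluate(estimator_id, s, alphabet_size)
            return cache[key]

        return ev
    return lambda s: est.evaluate(estimator_id, s, alphabet_size)


def exact_stats(
    estimator_id: str,
    model: markov.TransitionModel,
    length: int,
    budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> EstimatorStats:
    """Exact moments by exhaustive enumeration.

    ``<H^k> = sum_S P(S) H(S)^k`` over all ``L**N`` sequences, with ``P(S)``
    the chain probability started from the stationary distribution.  The
    bias is taken against the entropy of the stationary distribution.
    Accumulation uses compensated (exact) summation so that the weights of
    deep enumerations still add up to one.
    """
    pi = markov.stationary_distribution(model)
    h_true = markov.true_entropy(pi)
    ev = _dedup_evaluator(estimator_id, model.alphabet_size)
    w_list: list[float] = []
    m1_list: list[float] = []
    m2_list: list[float] = []
    for s in enumerate_sequences(model.alphabet_size, length, budget):
        w = markov.sequence_probability(model, s, initial=pi)
        h = ev(s)
        w_list.append(w)
        m1_list.append(w * h)
        m2_list.append(w * h * h)
    norm = math.fsum(w_list)
    mean = math.fsum(m1_list) / norm
    second = math.fsum(m2_list) / norm
    return EstimatorStats(estimator_id, mean, second, h_true)


def mc_stats(
    estimator_id: str,
    model: markov.TransitionModel,
    length: int,
    n_replicates: int,
    seed: int | np.random.Generator = 0,
    *,
    initial: NDArray | None = None,
    true_entropy: float | None = None,
) -> EstimatorStats:
    """Monte-Carlo moments from ``n_replicates`` independent simulated chains.

    Reports the sample mean and the unbiased (M-1 denominator) sample
    variance; the ``second_moment`` field is reconstructed so that
    ``sd`` equals the unbiased sample standard deviation.  ``true_entropy``
    defaults to the entropy of the stationary distribution of ``model``.
    """
    if n_replicates < 2:
        raise InvalidParameterError("need at least two replicates")
    if initial is None:
        initial = markov.stationary_distribution(model)
    if true_entropy is None:
        true_entropy = markov.true_entropy(markov.stationary_distribution(model))
    seqs = markov.simulate_batch(
        model, length, n_replicates, initial=initial, seed=seed
    )
    ev = _dedup_evaluator(estimator_id, model.alphabet_size)
    values = np.fromiter((ev(row) for row in seqs), dtype=float, count=n_replicates)
    mean = float(values.mean())
    var = float(values.var(ddof=1))
    return EstimatorStats(estimator_id, mean, mean**2 + var, true_entropy)
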