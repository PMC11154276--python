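"""Estimator comparison studies on Markovian sequences.

Two studies are implemented:

* :func:`binary_grid_sweep` — exact bias / standard deviation / mean
  squared error of each estimator on two-state chains, swept over a grid of
  the self-transition probabilities ``(p00, p11)`` and aggregated over the
  grid with a ``step**2`` area prefactor.  The exact engine enumerates all
  ``2**N`` sequences once and reweights them per grid point, which makes
  the full 50x50 grid cheap even for all ten estimators.

* :func:`block_mc_experiment` — the undersampled regime.  Overlapping
  ``n``-bit windows of an i.i.d. Bernoulli(p) source form a Markov chain on
  ``2**n`` states; with window-sequence length ``N`` far below ``2**n`` the
  block entropy ``n H1`` must be estimated from badly undersampled counts.
  Statistics are Monte-Carlo (sample mean, unbiased sample variance over M
  replicates) and aggregated over the ``p`` grid with a ``step`` prefactor.
  All estimators are evaluated on the same simulated replicates (paired
  design), which removes simulation noise from estimator rankings.

Results are tidy :class:`pandas.DataFrame` tables, one row per (grid point,
estimator) and one per estimator for the aggregates; CSV-ready.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import estimators as est
from . import markov, moments
from .exceptions import EnumerationTooLargeError, InvalidParameterError

__all__ = [
    "default_binary_grid",
    "default_block_p_grid",
    "binary_grid_sweep",
    "block_mc_experiment",
]

logger = logging.getLogger(__name__)

POINT_COLUMNS = ["p00", "p11", "N", "estimator", "bias", "sd", "mse"]
AGG_COLUMNS = ["N", "estimator", "agg_bias", "agg_sd", "agg_mse"]


def default_binary_grid(step: float = 0.02, lo: float = 0.01, hi: float = 0.99) -> NDArray:
    """The standard sweep lattice: 0.01 to 0.99 in steps of 0.02 (50 values)."""
    n_steps = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n_steps + 1), 12)


def default_block_p_grid(step: float = 0.02, lo: float = 0.02, hi: float = 0.5) -> NDArray:
    """The block-study grid over the bit probability p: 0.02 to 0.5 step 0.02."""
    n_steps = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n_steps + 1), 12)


def _binary_sequence_table(length: int) -> dict[str, NDArray]:
    """All 2**N binary sequences with their sufficient statistics.

    Per sequence: the first symbol and the four bigram counts, which
    together determine the Markov probability at any grid point.
    """
    n_seq = 2**length
    idx = np.arange(n_seq, dtype=np.int64)
    bits = (idx[:, None] >> np.arange(length - 1, -1, -1)) & 1
    x, y = bits[:, :-1], bits[:, 1:]
    return {
        "bits": bits,
        "first": bits[:, 0],
        "a00": ((x == 0) & (y == 0)).sum(axis=1),
        "a01": ((x == 0) & (y == 1)).sum(axis=1),
        "a10": ((x == 1) & (y == 0)).sum(axis=1),
        "a11": ((x == 1) & (y == 1)).sum(axis=1),
        "ones": bits.sum(axis=1),
    }


def _binary_estimator_values(
    table: dict[str, NDArray], estimator_ids: Sequence[str], length: int
) -> dict[str, NDArray]:
    """Estimator value for each of the 2**N sequences.

    Count-based estimators depend only on the number of ones, so they are
    evaluated once per count and broadcast; order-sensitive ones are
    evaluated sequence by sequence.
    """
    values: dict[str, NDArray] = {}
    ones = table["ones"]
    for eid in estimator_ids:
        if eid in est.COUNT_BASED_IDS:
            per_count = np.array(
                [
                    est._count_value(
                        eid, est.CountSummary(np.array([length - k, k]))
                    )
                    for k in range(length + 1)
                ]
            )
            values[eid] = per_count[ones]
        else:
            values[eid] = np.array(
                [est.evaluate(eid, row, 2) for row in table["bits"]]
            )
    return values


def binary_grid_sweep(
    estimators: Sequence[str] | None = None,
    *,
    length: int = 4,
    step: float = 0.02,
    grid: NDArray | None = None,
    engine: str = "exact",
    n_replicates: int = 10**4,
    seed: int = 0,
    budget: int = moments.DEFAULT_ENUMERATION_BUDGET,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bias/sd/MSE of each estimator over the (p00, p11) grid, plus aggregates.

    With ``engine="exact"`` the statistics are exact enumeration moments;
    ``engine="mc"`` replaces them with Monte-Carlo estimates from
    ``n_replicates`` chains per grid point (for lengths whose ``2**N``
    enumeration would blow the budget).  Aggregates follow the area rule:
    ``step**2`` times the grid sum of |bias|, sd and MSE respectively.

    Returns ``(points, aggregates)`` data frames.
    """
    estimator_ids = tuple(estimators) if estimators is not None else est.ESTIMATOR_IDS
    p_values = grid if grid is not None else default_binary_grid(step)
    if engine not in ("exact", "mc"):
        raise InvalidParameterError(f"unknown engine {engine!r}")
    if engine == "exact" and 2**length > budget:
        raise EnumerationTooLargeError(
            f"2**{length} sequences exceed the enumeration budget; use engine='mc'"
        )
    logger.info(
        "binary sweep: N=%d engine=%s grid=%dx%d estimators=%s seed=%d",
        length, engine, len(p_values), len(p_values), ",".join(estimator_ids), seed,
    )

    rows: list[tuple] = []
    if engine == "exact":
        table = _binary_sequence_table(length)
        values = _binary_estimator_values(table, estimator_ids, length)
        a00, a01 = table["a00"], table["a01"]
        a10, a11 = table["a10"], table["a11"]
        first = table["first"]
        for p00 in p_values:
            for p11 in p_values:
                pi0 = (1.0 - p11) / (2.0 - p00 - p11)
                pi = np.array([pi0, 1.0 - pi0])
                h_true = markov.true_entropy(pi)
                w = (
                    pi[first]
                    * p00**a00
                    * (1.0 - p00) ** a01
                    * (1.0 - p11) ** a10
                    * p11**a11
                )
                for eid in estimator_ids:
                    h = values[eid]
                    mean = float(w @ h)
                    second = float(w @ (h * h))
                    bias = mean - h_true
                    sd = math.sqrt(max(second - mean**2, 0.0))
                    rows.append((p00, p11, length, eid, bias, sd, bias**2 + sd**2))
    else:
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(p_values) * len(p_values))
        k = 0
        for p00 in p_values:
            for p11 in p_values:
                model = markov.make_binary_chain(p00, p11)
                point_seed = int(children[k].generate_state(1)[0])
                k += 1
                for eid in estimator_ids:
                    # paired design: same replicate stream for every estimator
                    stats = moments.mc_stats(
                        eid, model, length, n_replicates, seed=point_seed
                    )
                    rows.append(
                        (p00, p11, length, eid, stats.bias, stats.sd, stats.mse)
                    )

    points = pd.DataFrame(rows, columns=POINT_COLUMNS)
    agg = _aggregate(points, prefactor=step**2, length=length)
    return points, agg


def _aggregate(points: pd.DataFrame, prefactor: float, length: int) -> pd.DataFrame:
    rows = []
    for eid, grp in points.groupby("estimator", sort=False):
        rows.append(
            (
                length,
                eid,
                prefactor * grp["bias"].abs().sum(),
                prefactor * grp["sd"].sum(),
                prefactor * grp["mse"].sum(),
            )
        )
    return pd.DataFrame(rows, columns=AGG_COLUMNS)


# ---------------------------------------------------------------------------
# Undersampled block study
# ---------------------------------------------------------------------------

def _profile_keys(counts: NDArray) -> list[tuple]:
    """Sorted nonzero count tuples per row (the sufficient statistic of the
    count-based estimators)."""
    keys = []
    for row in counts:
        nz = row[row > 0]
        nz.sort()
        keys.append(tuple(nz))
    return keys


def _batch_count_values(
    eid: str, keys: list[tuple], alphabet_size: int, cache: dict
) -> NDArray:
    out = np.empty(len(keys))
    for i, key in enumerate(keys):
        ck = (eid, key)
        if ck not in cache:
            vec = np.zeros(alphabet_size, dtype=np.int64)
            vec[: len(key)] = key
            cache[ck] = est._count_value(eid, est.CountSummary(vec))
        out[i] = cache[ck]
    return out


def block_mc_experiment(
    estimators: Sequence[str] | None = None,
    *,
    n: int = 6,
    length: int = 20,
    n_replicates: int = 10**4,
    step: float = 0.02,
    p_grid: NDArray | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monte-Carlo block-entropy study in the undersampled regime.

    For each bit probability ``p`` in the grid, ``n_replicates`` window
    sequences of ``length`` states are simulated from the block chain on
    ``2**n`` states (product-Bernoulli initial condition) and every
    estimator is evaluated on each.  The bias is measured against the true
    block entropy ``n H1(p)``; aggregates carry the ``step`` prefactor.

    Returns ``(points, aggregates)``; the ``p00`` column of the points
    table holds ``p`` and ``p11`` is NaN.
    """
    estimator_ids = tuple(estimators) if estimators is not None else est.ESTIMATOR_IDS
    p_values = p_grid if p_grid is not None else default_block_p_grid(step)
    L = 2**n
    logger.info(
        "block experiment: n=%d L=%d N=%d M=%d grid=%d estimators=%s seed=%d",
        n, L, length, n_replicates, len(p_values), ",".join(estimator_ids), seed,
    )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(p_values))
    cache: dict = {}
    rows: list[tuple] = []
    for p, child in zip(p_values, children):
        model = markov.block_chain(p, n)
        init = markov.block_stationary(p, n)
        h_true = markov.iid_block_entropy(p, n)
        seqs = markov.simulate_batch(
            model, length, n_replicates, initial=init,
            seed=np.random.default_rng(child),
        )
        counts = np.zeros((n_replicates, L), dtype=np.int64)
        np.add.at(counts, (np.arange(n_replicates)[:, None], seqs), 1)
        keys = _profile_keys(counts)
        for eid in estimator_ids:
            if eid in est.COUNT_BASED_IDS:
                vals = _batch_count_values(eid, keys, L, cache)
            elif eid == "CC":
                vals = np.fromiter(
                    (est.entropy_cc(row).value for row in seqs),
                    dtype=float, count=n_replicates,
                )
            else:  # CMM
                vals = np.fromiter(
                    (est.entropy_cmm(row, L).value for row in seqs),
                    dtype=float, count=n_replicates,
                )
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            bias = mean - h_true
            rows.append((p, np.nan, length, eid, bias, sd, bias**2 + sd**2))

    points = pd.DataFrame(rows, columns=POINT_COLUMNS)
    agg = _aggregate(points, prefactor=step, length=length)
    return points, agg
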