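"""Homogeneous Markov chains on a finite integer alphabet.

Provides construction and validation of row-stochastic transition models,
stationary distributions, exact sequence probabilities, chain simulation,
transition-matrix estimation from data, the spectral memory terms used by
the corrected Miller-Madow entropy estimator, and the block (sliding
window) dynamics that turn an i.i.d. binary source into a sparse Markov
chain on ``2**n`` states.

Conventions
-----------
* Symbols are integers ``0 .. L-1``; a sequence is a 1-D integer array.
* ``transitions[i, j]`` is the probability of moving from state ``i`` to
  state ``j``; every row sums to one.
* All entropies are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .exceptions import (
    DegenerateChainError,
    DegenerateSpectrumError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "TransitionModel",
    "make_binary_chain",
    "stationary_distribution",
    "true_entropy",
    "simulate",
    "sequence_probability",
    "estimate_transitions",
    "memory_term",
    "spectral_correction",
    "spectrum_summary",
    "block_chain",
    "encode_blocks",
    "decode_block",
    "iid_block_entropy",
    "n_block_sequences",
]

_ROW_SUM_TOL = 1e-12
#: Tolerance used both to identify the unit eigenvalue of a stochastic
#: matrix and to declare a second eigenvalue "on the unit circle".
UNIT_EIGENVALUE_TOL = 1e-9


@dataclass(frozen=True)
class TransitionModel:
    """A homogeneous Markov chain given by its row-stochastic matrix."""

    transitions: NDArray[np.float64]
    alphabet_size: int = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.transitions, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1] or t.shape[0] < 1:
            raise InvalidParameterError(
                f"transition matrix must be square and non-empty, got shape {t.shape}"
            )
        if np.any(t < 0.0) or np.any(t > 1.0):
            raise InvalidParameterError("transition probabilities must lie in [0, 1]")
        rows = t.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _ROW_SUM_TOL):
            worst = int(np.argmax(np.abs(rows - 1.0)))
            raise InvalidParameterError(
                f"row {worst} sums to {rows[worst]!r}, not 1 (tol {_ROW_SUM_TOL})"
            )
        t.setflags(write=False)
        object.__setattr__(self, "transitions", t)
        object.__setattr__(self, "alphabet_size", t.shape[0])

    def eigenvalues(self) -> NDArray[np.complex128]:
        return np.linalg.eigvals(self.transitions)


@dataclass(frozen=True)
class SpectrumSummary:
    """Eigenvalues of a transition matrix with the unit eigenvalue singled out."""

    eigenvalues: NDArray[np.complex128]
    unit_index: int
    degenerate: bool


def make_binary_chain(p00: float, p11: float) -> TransitionModel:
    """Two-state chain from the two self-transition probabilities.

    ``p00`` is the probability of staying at 0, ``p11`` of staying at 1;
    both must lie strictly inside (0, 1) so the chain is irreducible and
    aperiodic.
    """
    for name, p in (("p00", p00), ("p11", p11)):
        if not (0.0 < p < 1.0):
            raise InvalidParameterError(f"{name}={p!r} must lie strictly in (0, 1)")
    return TransitionModel(np.array([[p00, 1.0 - p00], [1.0 - p11, p11]]))


def stationary_distribution(model: TransitionModel) -> NDArray[np.float64]:
    """Unique probability vector pi with pi @ T == pi.

    Solved as the left null space of ``T - I`` augmented with the
    normalization constraint; raises :class:`DegenerateChainError` when the
    unit eigenvalue is not simple (e.g. reducible or periodic chains).
    """
    summ = spectrum_summary(model)
    if summ.degenerate:
        raise DegenerateChainError(
            "stationary distribution is not unique: a second eigenvalue lies on the unit circle"
        )
    t = model.transitions
    L = model.alphabet_size
    a = np.vstack([t.T - np.eye(L), np.ones(L)])
    b = np.zeros(L + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def true_entropy(pi: ArrayLike) -> float:
    """Shannon entropy -sum p ln p of a probability vector, in nats.

    Zero-probability entries contribute zero (the usual 0 ln 0 := 0
    convention).
    """
    p = np.asarray(pi, dtype=float)
    if np.any(p < -_ROW_SUM_TOL) or abs(p.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("input is not a probability vector")
    p = p[p > 0.0]
    return float(-(p * np.log(p)).sum())


def simulate(
    model: TransitionModel,
    length: int,
    *,
    initial: ArrayLike | None = None,
    seed: int | np.random.Generator = 0,
) -> NDArray[np.int64]:
    """Draw one realization of the chain.

    The first symbol is drawn from ``initial`` (stationary distribution by
    default), each later symbol from the transition row of its predecessor.
    Identical seeds give identical sequences.
    """
    if length < 1:
        raise InvalidParameterError("length must be >= 1")
    rng = np.random.default_rng(seed)
    if initial is None:
        initial = stationary_distribution(model)
    initial = np.asarray(initial, dtype=float)
    out = np.empty(length, dtype=np.int64)
    out[0] = rng.choice(model.alphabet_size, p=initial)
    cum = np.cumsum(model.transitions, axis=1)
    cum[:, -1] = 1.0  # guard against rounding in the last column
    u = rng.random(length - 1)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i - 1], side="right")
    return out


def simulate_batch(
    model: TransitionModel,
    length: int,
    n_sequences: int,
    *,
    initial: ArrayLike | None = None,
    seed: int | np.random.Generator = 0,
) -> NDArray[np.int64]:
    """Simulate ``n_sequences`` independent chains at once (rows of the result).

    Vectorized over replicates; used by the Monte-Carlo machinery where a
    per-replicate Python loop would dominate the runtime.
    """
    if length < 1:
        raise InvalidParameterError("length must be >= 1")
    rng = np.random.default_rng(seed)
    if initial is None:
        initial = stationary_distribution(model)
    initial = np.asarray(initial, dtype=float)
    out = np.empty((n_sequences, length), dtype=np.int64)
    cum0 = np.cumsum(initial)
    cum0[-1] = 1.0
    out[:, 0] = np.searchsorted(cum0, rng.random(n_sequences), side="right")
    cum = np.cumsum(model.transitions, axis=1)
    cum[:, -1] = 1.0
    for i in range(1, length):
        u = rng.random(n_sequences)
        rows = cum[out[:, i - 1]]
        out[:, i] = (u[:, None] >= rows).sum(axis=1)
    return out


def sequence_probability(
    model: TransitionModel,
    s: ArrayLike,
    *,
    initial: ArrayLike | None = None,
) -> float:
    """Exact probability of observing the ordered sequence ``s``.

    The chain rule for a first-order homogeneous chain: the initial
    distribution evaluated at the first symbol times the product of the
    one-step transition probabilities along the sequence.
    """
    s = np.asarray(s, dtype=np.int64)
    if s.ndim != 1 or s.size < 1:
        raise InvalidParameterError("sequence must be a non-empty 1-D array")
    if s.min() < 0 or s.max() >= model.alphabet_size:
        raise InvalidParameterError("sequence contains symbols outside the alphabet")
    if initial is None:
        initial = stationary_distribution(model)
    initial = np.asarray(initial, dtype=float)
    p = float(initial[s[0]])
    if s.size > 1:
        p *= float(np.prod(model.transitions[s[:-1], s[1:]]))
    return p


def estimate_transitions(s: ArrayLike, alphabet_size: int) -> tuple[TransitionModel, NDArray[np.int64]]:
    """Maximum-likelihood transition matrix from observed bigram counts.

    Row ``i`` is the empirical distribution of the successor of symbol
    ``i``.  States with no outgoing transition cannot be given a stochastic
    row, so they are dropped and the matrix is rebuilt on the retained
    states (renormalizing rows after the removal of dropped columns);
    dropping a state can strand another, so the reduction iterates until
    stable.  Returns the reduced model together with the retained state
    labels.  Raises :class:`InsufficientDataError` if the sequence has
    fewer than two symbols or no state survives the reduction.
    """
    s = np.asarray(s, dtype=np.int64)
    if s.size < 2:
        raise InsufficientDataError("need at least two symbols to estimate transitions")
    if s.min() < 0 or s.max() >= alphabet_size:
        raise InvalidParameterError("sequence contains symbols outside the alphabet")
    counts = np.zeros((alphabet_size, alphabet_size), dtype=np.int64)
    np.add.at(counts, (s[:-1], s[1:]), 1)
    keep = np.arange(alphabet_size)
    c = counts
    while True:
        out_deg = c.sum(axis=1)
        alive = out_deg > 0
        if alive.all():
            break
        keep = keep[alive]
        c = c[np.ix_(alive, alive)]
        if c.size == 0:
            raise InsufficientDataError(
                "no state retains an outgoing transition after reduction"
            )
    t = c / c.sum(axis=1, keepdims=True)
    return TransitionModel(t), keep


def spectrum_summary(model: TransitionModel, tol: float = UNIT_EIGENVALUE_TOL) -> SpectrumSummary:
    """Eigenvalues with the unit eigenvalue identified.

    The eigenvalue closest to ``1 + 0i`` is taken as the Perron eigenvalue
    (numerical spectra of stochastic matrices perturb it slightly); the
    summary is flagged degenerate when any *other* eigenvalue has modulus
    ``>= 1 - tol``.
    """
    lam = model.eigenvalues()
    unit = int(np.argmin(np.abs(lam - 1.0)))
    rest = np.delete(lam, unit)
    degenerate = bool(rest.size and np.any(np.abs(rest) >= 1.0 - tol))
    return SpectrumSummary(eigenvalues=lam, unit_index=unit, degenerate=degenerate)


def memory_term(model: TransitionModel, lag: int) -> float:
    """Excess return probability K(l) = Tr(T**l) - 1 at the given lag.

    Equals the sum of the l-th powers of the non-unit eigenvalues; it is
    identically zero for an independent (equal-rows) chain.
    """
    if lag < 1:
        raise InvalidParameterError("lag must be >= 1")
    power = np.linalg.matrix_power(model.transitions, lag)
    return float(np.trace(power) - 1.0)


def spectral_correction(model: TransitionModel, tol: float = UNIT_EIGENVALUE_TOL) -> float:
    """Geometric-series memory sum  sum_{i>=2} lambda_i / (1 - lambda_i).

    This is sum_l K(l) resummed in closed form over the non-unit
    eigenvalues.  Computed in complex arithmetic (conjugate pairs cancel)
    and returned as a real number.  Raises
    :class:`DegenerateSpectrumError` when a non-unit eigenvalue sits on the
    unit circle, in which case the series does not converge and callers
    should skip the correction.
    """
    summ = spectrum_summary(model, tol=tol)
    if summ.degenerate:
        raise DegenerateSpectrumError(
            "a non-unit eigenvalue has modulus ~1; memory series diverges"
        )
    rest = np.delete(summ.eigenvalues, summ.unit_index)
    if rest.size == 0:
        return 0.0
    total = np.sum(rest / (1.0 - rest))
    if abs(total.imag) > 1e-9:
        raise DegenerateSpectrumError(
            f"imaginary part {total.imag!r} of the spectral sum did not cancel"
        )
    return float(total.real)


# ---------------------------------------------------------------------------
# Block (sliding-window) dynamics of an i.i.d. binary source
# ---------------------------------------------------------------------------

def block_chain(p: float, n: int) -> TransitionModel:
    """Markov chain of overlapping length-``n`` windows of i.i.d. Bernoulli(p) bits.

    State ``z`` encodes the window with the oldest bit most significant.
    Sliding the window one step drops the oldest bit and appends a fresh
    one, so ``z`` moves to ``2z mod 2**n`` with probability ``1 - p`` or to
    ``2z mod 2**n + 1`` with probability ``p``; every row has exactly two
    nonzero entries.  The stationary law is the product-Bernoulli measure
    ``p**k (1-p)**(n-k)`` with ``k`` the popcount of ``z``.
    """
    if not (0.0 < p < 1.0):
        raise InvalidParameterError("p must lie strictly in (0, 1)")
    if n < 1:
        raise InvalidParameterError("block size n must be >= 1")
    L = 2**n
    t = np.zeros((L, L))
    z = np.arange(L)
    t[z, (2 * z) % L] = 1.0 - p
    t[z, (2 * z) % L + 1] = p
    return TransitionModel(t)


def block_stationary(p: float, n: int) -> NDArray[np.float64]:
    """Product-Bernoulli measure over ``n``-bit states: P(z) = p**popcount(z) (1-p)**(n-popcount)."""
    if not (0.0 < p < 1.0):
        raise InvalidParameterError("p must lie strictly in (0, 1)")
    z = np.arange(2**n, dtype=np.uint64)
    ones = np.array([int(v).bit_count() for v in z])
    return p**ones * (1.0 - p) ** (n - ones)


def encode_blocks(s: ArrayLike, n: int) -> NDArray[np.int64]:
    """Encode a binary sequence into its overlapping ``n``-bit window states.

    The j-th output is the integer whose binary digits are
    ``s[j] .. s[j+n-1]`` with the oldest bit most significant, so
    consecutive outputs satisfy ``z[j+1] = 2 z[j] mod 2**n + s[j+n]``.
    Output length is ``N - n + 1``.
    """
    s = np.asarray(s, dtype=np.int64)
    if n < 1:
        raise InvalidParameterError("block size n must be >= 1")
    if s.size < n:
        raise InsufficientDataError(f"sequence of length {s.size} is shorter than block size {n}")
    if s.min() < 0 or s.max() > 1:
        raise InvalidParameterError("block encoding requires a binary sequence")
    weights = 1 << np.arange(n - 1, -1, -1)
    windows = np.lib.stride_tricks.sliding_window_view(s, n)
    return windows @ weights


def decode_block(z: int, n: int) -> NDArray[np.int64]:
    """Inverse of :func:`encode_blocks` for a single state."""
    return np.array([(z >> (n - 1 - k)) & 1 for k in range(n)], dtype=np.int64)


def iid_block_entropy(p: float, n: int) -> float:
    """Entropy (nats) of one length-``n`` window of i.i.d. Bernoulli(p) bits.

    Independence makes the window entropy additive: ``n`` times the
    single-bit entropy ``-p ln p - (1-p) ln(1-p)``.
    """
    if not (0.0 < p < 1.0):
        raise InvalidParameterError("p must lie strictly in (0, 1)")
    if n < 1:
        raise InvalidParameterError("block size n must be >= 1")
    h1 = -p * np.log(p) - (1.0 - p) * np.log(1.0 - p)
    return float(n * h1)


def n_block_sequences(n: int, length: int) -> int:
    """Number of distinct sequences of ``length`` window states, (2**n)**length.

    Counts unconstrained state strings; it is the size of the sample space
    an exhaustive moment enumeration would have to visit, which is what
    makes the undersampled block study tractable only by Monte Carlo.
    """
    if n < 1 or length < 1:
        raise InvalidParameterError("n and length must be >= 1")
    return (2**n) ** length
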