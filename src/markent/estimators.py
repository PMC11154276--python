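"""Finite-sample Shannon entropy estimators.

Ten estimators are provided, all returning values in nats:

========  ==================================================================
id        estimator
========  ==================================================================
MLE       maximum-likelihood (plug-in) estimator
MM        Miller-Madow first-order bias correction
NSB       Nemenman-Shafee-Bialek Dirichlet-mixture Bayesian estimator
CS        Chao-Shen coverage-adjusted Horvitz-Thompson estimator
G         Grassberger Poisson-approximation estimator
BHM       Bonachela-Hinrichsen-Munoz balanced (MSE-minimizing) estimator
HS        Hausser-Strimmer James-Stein shrinkage estimator
CWJ       Chao-Wang-Jost singleton/doubleton tail-corrected estimator
CC        correlation coverage-adjusted estimator (order-sensitive)
CMM       corrected Miller-Madow with spectral memory term (order-sensitive)
========  ==================================================================

Eight of them are functions of the occurrence counts alone and are therefore
invariant under any permutation of the sequence; CC conditions its coverage
estimate on the order in which new symbols appear, and CMM estimates the
transition matrix of the sequence, so both are order-sensitive.

No estimator value is clamped to ``[0, ln L]``: some corrections (CC in
particular) can legitimately overshoot the maximum entropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, polygamma
from numpy.polynomial.legendre import leggauss
from numpy.typing import ArrayLike, NDArray

from . import markov
from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    MarkentError,
)

__all__ = [
    "ESTIMATOR_IDS",
    "COUNT_BASED_IDS",
    "ORDER_SENSITIVE_IDS",
    "CountSummary",
    "EntropyEstimate",
    "counts_from_sequence",
    "entropy_mle",
    "entropy_mm",
    "entropy_nsb",
    "entropy_cs",
    "entropy_grassberger",
    "entropy_bhm",
    "entropy_shrink",
    "entropy_cwj",
    "entropy_cc",
    "entropy_cmm",
    "estimate_all",
    "evaluate",
    "grassberger_table",
]

EULER_GAMMA = float(np.euler_gamma)

COUNT_BASED_IDS = ("MLE", "MM", "NSB", "CS", "G", "BHM", "HS", "CWJ")
ORDER_SENSITIVE_IDS = ("CC", "CMM")
ESTIMATOR_IDS = COUNT_BASED_IDS + ORDER_SENSITIVE_IDS


@dataclass(frozen=True)
class CountSummary:
    """Occurrence counts of a sequence plus the derived tallies.

    ``observed``/``singletons``/``doubletons`` are the number of symbols
    seen at least once, exactly once and exactly twice — the quantities
    that drive the missing-mass corrections.
    """

    counts: NDArray[np.int64]
    total: int = field(init=False)
    observed: int = field(init=False)
    singletons: int = field(init=False)
    doubletons: int = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or c.size < 1:
            raise InvalidParameterError("counts must be a non-empty 1-D array")
        if np.any(c < 0):
            raise InvalidParameterError("counts must be nonnegative")
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "total", int(c.sum()))
        object.__setattr__(self, "observed", int((c > 0).sum()))
        object.__setattr__(self, "singletons", int((c == 1).sum()))
        object.__setattr__(self, "doubletons", int((c == 2).sum()))

    @property
    def alphabet_size(self) -> int:
        return self.counts.size

    @property
    def nonzero(self) -> NDArray[np.int64]:
        return self.counts[self.counts > 0]


@dataclass(frozen=True)
class EntropyEstimate:
    """An entropy value (nats) tagged with the estimator that produced it."""

    value: float
    estimator_id: str
    fallback: bool = False


def counts_from_sequence(s: ArrayLike, alphabet_size: int) -> CountSummary:
    """Tally symbol occurrences of an integer sequence over ``0..L-1``."""
    s = np.asarray(s, dtype=np.int64)
    if s.size and (s.min() < 0 or s.max() >= alphabet_size):
        raise InvalidParameterError("sequence contains symbols outside the alphabet")
    return CountSummary(np.bincount(s, minlength=alphabet_size))


def _require_data(c: CountSummary) -> None:
    if c.total < 1:
        raise InsufficientDataError("estimator needs at least one observation")


# ---------------------------------------------------------------------------
# Plug-in and Miller-Madow
# ---------------------------------------------------------------------------

def _mle(nz: NDArray, N: int) -> float:
    p = nz / N
    return float(-(p * np.log(p)).sum())


def entropy_mle(c: CountSummary) -> EntropyEstimate:
    """Plug-in estimator: entropy of the empirical frequencies.

    Negatively biased for every distribution and sample size.
    """
    _require_data(c)
    return EntropyEstimate(_mle(c.nonzero, c.total), "MLE")


def entropy_mm(c: CountSummary) -> EntropyEstimate:
    """Miller-Madow estimator: plug-in plus the (N0 - 1)/2N bias correction,
    N0 being the number of distinct symbols observed."""
    _require_data(c)
    value = _mle(c.nonzero, c.total) + (c.observed - 1) / (2.0 * c.total)
    return EntropyEstimate(value, "MM")


# ---------------------------------------------------------------------------
# NSB: Dirichlet-mixture Bayesian estimator
# ---------------------------------------------------------------------------

_NSB_NODES = 200
_nsb_cache: dict[int, tuple[NDArray, NDArray, NDArray]] = {}


def _xi_of_beta(beta: NDArray | float, L: int) -> NDArray | float:
    """Expected entropy of a symmetric Dirichlet(beta) prior on L bins."""
    return digamma(L * beta + 1.0) - digamma(beta + 1.0)


def _nsb_quadrature(L: int) -> tuple[NDArray, NDArray, NDArray]:
    """Gauss-Legendre nodes on xi in (0, ln L) with the matching beta values.

    The map xi(beta) is strictly increasing from 0 to ln L, so each node is
    inverted once by bisection on log(beta) and cached per alphabet size.
    """
    if L in _nsb_cache:
        return _nsb_cache[L]
    from scipy.optimize import brentq

    x, w = leggauss(_NSB_NODES)
    ln_l = math.log(L)
    xi = 0.5 * ln_l * (x + 1.0)
    weights = 0.5 * ln_l * w
    betas = np.empty_like(xi)
    for k, target in enumerate(xi):
        f = lambda t: _xi_of_beta(math.exp(t), L) - target
        betas[k] = math.exp(brentq(f, -45.0, 45.0, xtol=1e-14, rtol=1e-15))
    _nsb_cache[L] = (xi, weights, betas)
    return _nsb_cache[L]


def _nsb(nz: NDArray, N: int, L: int) -> float:
    """Posterior-mean entropy under the entropy-uniformizing Dirichlet mixture.

    For each concentration beta the posterior over the probability vector is
    Dirichlet(n_i + beta) with conditional mean entropy

        E[H | beta, n] = psi(N + L beta + 1)
                         - sum_i (n_i + beta)/(N + L beta) psi(n_i + beta + 1),

    and marginal likelihood (up to count-only constants)

        P(n | beta) = Gamma(L beta)/Gamma(N + L beta) prod_i Gamma(n_i + beta)/Gamma(beta).

    The hyperprior is uniform in xi(beta) = psi(L beta + 1) - psi(beta + 1),
    the prior expected entropy, which runs over (0, ln L); the estimator is
    the evidence-weighted average of the conditional means over that range.
    Log-evidence is shifted by its maximum before exponentiation.
    """
    if L < 2:
        raise InvalidParameterError("NSB needs an alphabet of at least two symbols")
    _, weights, betas = _nsb_quadrature(L)
    k_obs = nz.size
    n_zero = L - k_obs
    b = betas[None, :]
    nzc = nz[:, None].astype(float)
    log_ev = (
        gammaln(L * betas)
        - gammaln(N + L * betas)
        + (gammaln(nzc + b) - gammaln(b)).sum(axis=0)
    )
    denom = N + L * betas
    h_cond = digamma(denom + 1.0) - (
        ((nzc + b) * digamma(nzc + b + 1.0)).sum(axis=0)
        + n_zero * betas * digamma(betas + 1.0)
    ) / denom
    log_w = np.log(weights) + log_ev
    log_w -= log_w.max()
    w = np.exp(log_w)
    return float((w * h_cond).sum() / w.sum())


def entropy_nsb(c: CountSummary) -> EntropyEstimate:
    """Nemenman-Shafee-Bialek Bayesian estimator.

    A mixture of symmetric Dirichlet priors whose hyperprior makes the
    prior expected entropy approximately uniform on [0, ln L]; with no data
    the estimate is therefore close to (ln L)/2.  Requires the alphabet
    size L.
    """
    return EntropyEstimate(_nsb(c.nonzero, c.total, c.alphabet_size), "NSB")


# ---------------------------------------------------------------------------
# Coverage-adjusted estimators (Chao-Shen and the sequential CC variant)
# ---------------------------------------------------------------------------

def _coverage_ht_entropy(p_adj: NDArray, N: int) -> float:
    """Horvitz-Thompson entropy sum  -p ln p / (1 - (1-p)^N)  over observed symbols."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = -p_adj * np.log(p_adj) / (1.0 - (1.0 - p_adj) ** N)
    # p_adj == 1 gives 0 * log(1) / 1 = 0; p_adj == 0 cannot occur for observed symbols
    return float(np.where(p_adj >= 1.0, 0.0, terms).sum())


def _cs(nz: NDArray, N: int, N1: int) -> float:
    if N1 == N:
        # every observation a singleton: the raw coverage 1 - N1/N would be
        # zero and the estimator undefined; use the customary N1 -> N - 1
        N1 = N - 1
    coverage = 1.0 - N1 / N
    p_adj = coverage * nz / N
    return _coverage_ht_entropy(p_adj, N)


def entropy_cs(c: CountSummary) -> EntropyEstimate:
    """Chao-Shen estimator: empirical frequencies scaled by the estimated
    sample coverage 1 - N1/N, summed with Horvitz-Thompson weights that
    compensate for unseen symbols."""
    _require_data(c)
    return EntropyEstimate(_cs(c.nonzero, c.total, c.singletons), "CS")


def first_occurrence_mask(s: NDArray) -> NDArray[np.bool_]:
    """Boolean mask marking positions where a symbol appears for the first time."""
    mask = np.zeros(s.size, dtype=bool)
    _, first = np.unique(s, return_index=True)
    mask[first] = True
    return mask


def cc_coverage(s: NDArray) -> float:
    """Sequential coverage estimate from the second half of the sequence.

    Walking the second half in order, each position that introduces a brand
    new symbol (never seen earlier in the sequence) subtracts 1/(N' + j)
    from the coverage, N' = floor(N/2).  Keeping the order makes the
    estimate sensitive to correlations.
    """
    s = np.asarray(s, dtype=np.int64)
    if s.size < 2:
        raise InsufficientDataError("coverage from halves needs at least two symbols")
    n_half = s.size // 2
    new = first_occurrence_mask(s)
    j = np.arange(1, n_half + 1)
    return float(1.0 - (new[n_half : 2 * n_half] / (n_half + j)).sum())


def entropy_cc(s: ArrayLike) -> EntropyEstimate:
    """Correlation coverage-adjusted estimator.

    Same Horvitz-Thompson construction as Chao-Shen but with the coverage
    estimated sequentially from the second half of the ordered sequence, so
    the value depends on the order of the data.  The alphabet size is not
    needed.  The estimate is not clamped and may exceed ln L.
    """
    s = np.asarray(s, dtype=np.int64)
    coverage = cc_coverage(s)
    counts = np.bincount(s)
    nz = counts[counts > 0]
    p_adj = coverage * nz / s.size
    return EntropyEstimate(_coverage_ht_entropy(p_adj, s.size), "CC")


# ---------------------------------------------------------------------------
# Grassberger
# ---------------------------------------------------------------------------

_g_table = np.array([np.nan, -EULER_GAMMA - math.log(2.0)])


def grassberger_table(n_max: int) -> NDArray[np.float64]:
    """Coefficients G_1 .. G_{n_max} (index 0 unused).

    G1 = -gamma - ln 2, G2 = 2 - gamma - ln 2, and the recurrence
    G_{2n+1} = G_{2n}, G_{2n+2} = G_{2n} + 2/(2n+1): odd-index coefficients
    repeat their even predecessor and even ones climb by two over the odd
    harmonic numbers.
    """
    global _g_table
    if n_max < len(_g_table):
        return _g_table[: n_max + 1]
    n_even = n_max // 2 + 1  # even indices 2, 4, ..., 2*n_even
    odd_recips = 2.0 / (2.0 * np.arange(1, n_even) + 1.0)
    g2 = 2.0 - EULER_GAMMA - math.log(2.0)
    g_even = g2 + np.concatenate([[0.0], np.cumsum(odd_recips)])
    table = np.empty(2 * n_even + 2)
    table[0] = np.nan
    table[1] = _g_table[1]
    table[2::2] = g_even
    table[3::2] = g_even
    _g_table = table
    return _g_table[: n_max + 1]


def _grassberger(nz: NDArray, N: int) -> float:
    g = grassberger_table(int(nz.max()))
    return float(math.log(N) - (nz * g[nz]).sum() / N)


def entropy_grassberger(c: CountSummary) -> EntropyEstimate:
    """Grassberger estimator: ln N - (1/N) sum_i n_i G_{n_i}, derived from a
    Poisson approximation valid when every symbol probability is small."""
    _require_data(c)
    return EntropyEstimate(_grassberger(c.nonzero, c.total), "G")


# ---------------------------------------------------------------------------
# Bonachela-Hinrichsen-Munoz
# ---------------------------------------------------------------------------

def _bhm(nz: NDArray, N: int, L: int) -> float:
    # sum_{j=a}^{b} 1/j = psi(b+1) - psi(a); zero-count bins contribute too
    outer = digamma(N + 3.0)
    acc = ((nz + 1.0) * (outer - digamma(nz + 2.0))).sum()
    acc += (L - nz.size) * (outer - digamma(2.0))
    return float(acc / (N + 2.0))


def entropy_bhm(c: CountSummary) -> EntropyEstimate:
    """Bonachela-Hinrichsen-Munoz balanced estimator: the harmonic double
    sum (1/(N+2)) sum_i (n_i+1) sum_{j=n_i+2}^{N+2} 1/j, including the
    unobserved bins, built to trade bias against variance."""
    _require_data(c)
    return EntropyEstimate(_bhm(c.nonzero, c.total, c.alphabet_size), "BHM")


# ---------------------------------------------------------------------------
# Hausser-Strimmer shrinkage
# ---------------------------------------------------------------------------

def _hs(nz: NDArray, N: int, L: int) -> float:
    p = nz / N
    if N <= 1:
        alpha = 1.0
    else:
        num = 1.0 - (p**2).sum()
        denom = (N - 1.0) * (((1.0 / L - p) ** 2).sum() + (L - nz.size) / L**2)
        alpha = 1.0 if denom <= 0.0 else min(1.0, num / denom)
    p_shrunk = alpha / L + (1.0 - alpha) * p
    acc = -(p_shrunk * np.log(p_shrunk)).sum()
    if alpha > 0.0 and L > nz.size:
        q = alpha / L
        acc -= (L - nz.size) * q * math.log(q)
    return float(acc)


def entropy_shrink(c: CountSummary) -> EntropyEstimate:
    """Hausser-Strimmer shrinkage estimator: plug-in entropy of the
    James-Stein mix  alpha/L + (1-alpha) p_hat  with the data-driven weight
    alpha chosen to minimize the MSE of the probability estimates (alpha set
    to 1 when the empirical distribution is already uniform or N = 1)."""
    _require_data(c)
    return EntropyEstimate(_hs(c.nonzero, c.total, c.alphabet_size), "HS")


# ---------------------------------------------------------------------------
# Chao-Wang-Jost
# ---------------------------------------------------------------------------

def _cwj_tail_series(one_minus_a: float, N: int) -> float:
    """sum_{m>=0} (1-A)^m / (N+m), the reindexed logarithmic tail.

    Equivalent to (1-A)^(-N) [-ln A - sum_{j=1}^{N-1} (1-A)^j / j] but free
    of the overflow/cancellation of that form.  Summed in blocks with a
    geometric truncation bound; falls back to the Lerch transcendent when
    1-A is so close to 1 that the series converges too slowly.
    """
    x = one_minus_a
    if x <= 0.0:
        return 1.0 / N
    need = -745.0 / math.log(x) if x < 1.0 else math.inf
    if need > 2e6:
        import mpmath

        return float(mpmath.lerchphi(x, 1, N))
    total = 0.0
    m0 = 0
    block = 65536
    while True:
        m = np.arange(m0, m0 + block, dtype=float)
        terms = x**m / (N + m)
        total += terms.sum()
        m0 += block
        # remaining tail bounded by a geometric series
        if terms[-1] * x / (1.0 - x) < 1e-17 * max(total, 1e-300):
            return total


def _cwj(nz: NDArray, N: int, N1: int, N2: int) -> float:
    lead = float((nz / N * (digamma(N) - digamma(nz))).sum())
    if N1 == 0:
        return lead
    if N2 > 0:
        a = 2.0 * N2 / ((N - 1.0) * N1 + 2.0 * N2)
    elif N1 > 0:
        a = 2.0 / ((N - 1.0) * (N1 - 1.0) + 2.0)
    else:
        a = 1.0
    if a >= 1.0:
        return lead
    tail = (N1 / N) * (1.0 - a) * _cwj_tail_series(1.0 - a, N)
    return lead + tail


def entropy_cwj(c: CountSummary) -> EntropyEstimate:
    """Chao-Wang-Jost estimator: a digamma series for the observed part plus
    a tail term, driven by the singleton and doubleton counts, that accounts
    for the undetected species; the tail vanishes when nothing is seen only
    once."""
    _require_data(c)
    return EntropyEstimate(_cwj(c.nonzero, c.total, c.singletons, c.doubletons), "CWJ")


# ---------------------------------------------------------------------------
# Corrected Miller-Madow
# ---------------------------------------------------------------------------

def entropy_cmm(s: ArrayLike, alphabet_size: int) -> EntropyEstimate:
    """Corrected Miller-Madow estimator for Markovian data.

    Adds to the Miller-Madow value the memory correction
    (1/N) sum_{i>=2} lambda_i / (1 - lambda_i) over the non-unit
    eigenvalues of the transition matrix estimated from the sequence
    itself.  When that matrix cannot be estimated or has a second
    eigenvalue on the unit circle (where the correction diverges) the
    plain Miller-Madow value is returned with ``fallback=True``.
    """
    s = np.asarray(s, dtype=np.int64)
    if s.size < 2:
        raise InsufficientDataError("CMM needs at least two symbols")
    c = counts_from_sequence(s, alphabet_size)
    mm = entropy_mm(c).value
    try:
        model, _ = markov.estimate_transitions(s, alphabet_size)
        corr = markov.spectral_correction(model)
    except MarkentError:
        return EntropyEstimate(mm, "CMM", fallback=True)
    return EntropyEstimate(mm + corr / c.total, "CMM")


# ---------------------------------------------------------------------------
# Dispatch helpers
# ---------------------------------------------------------------------------

def _count_value(estimator_id: str, c: CountSummary) -> float:
    nz, N, L = c.nonzero, c.total, c.alphabet_size
    if estimator_id == "MLE":
        return _mle(nz, N)
    if estimator_id == "MM":
        return _mle(nz, N) + (c.observed - 1) / (2.0 * N)
    if estimator_id == "NSB":
        return _nsb(nz, N, L)
    if estimator_id == "CS":
        return _cs(nz, N, c.singletons)
    if estimator_id == "G":
        return _grassberger(nz, N)
    if estimator_id == "BHM":
        return _bhm(nz, N, L)
    if estimator_id == "HS":
        return _hs(nz, N, L)
    if estimator_id == "CWJ":
        return _cwj(nz, N, c.singletons, c.doubletons)
    raise InvalidParameterError(f"unknown count-based estimator {estimator_id!r}")


def evaluate(estimator_id: str, s: ArrayLike, alphabet_size: int) -> float:
    """Value of one estimator on an integer sequence."""
    s = np.asarray(s, dtype=np.int64)
    if estimator_id == "CC":
        return entropy_cc(s).value
    if estimator_id == "CMM":
        return entropy_cmm(s, alphabet_size).value
    if estimator_id in COUNT_BASED_IDS:
        c = counts_from_sequence(s, alphabet_size)
        _require_data(c)
        return _count_value(estimator_id, c)
    raise InvalidParameterError(f"unknown estimator {estimator_id!r}")


def estimate_all(
    s: ArrayLike,
    alphabet_size: int,
    estimators: tuple[str, ...] = ESTIMATOR_IDS,
) -> dict[str, EntropyEstimate]:
    """All requested estimators on one sequence.

    The count-based ones share a single tally.  A failure of one estimator
    (recorded as a NaN value) does not abort the rest.
    """
    s = np.asarray(s, dtype=np.int64)
    if s.size < 2:
        raise InsufficientDataError("need at least two symbols")
    c = counts_from_sequence(s, alphabet_size)
    out: dict[str, EntropyEstimate] = {}
    for eid in estimators:
        try:
            if eid == "CC":
                out[eid] = entropy_cc(s)
            elif eid == "CMM":
                out[eid] = entropy_cmm(s, alphabet_size)
            else:
                out[eid] = EntropyEstimate(_count_value(eid, c), eid)
        except MarkentError:
            out[eid] = EntropyEstimate(math.nan, eid, fallback=True)
    return out
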