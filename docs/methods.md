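# Methods

## Setting

A homogeneous first-order Markov chain on the alphabet {0, …, L−1} is given
by a row-stochastic L×L matrix T, with `T[i, j] = P(X_{s+1}=j | X_s=i)`.
Sequences start from the stationary distribution π (πT = π) unless an
initial distribution is given explicitly, and the estimation target is the
Shannon entropy of π in nats. The binary chain is parameterized by its two
self-transition probabilities (p00, p11), restricted to the open interval
(0, 1) so the chain is irreducible and aperiodic; its stationary law is
p(0) = (1−p11)/(2−p00−p11).

An entropy estimator applied to a random length-N sequence is itself a
random variable; the package's subject is its bias B = ⟨Ĥ⟩ − H, standard
deviation σ and mean squared error B² + σ² as functions of the chain
parameters and N.

## Estimators: conventions and numerics

Everywhere, 0·ln 0 := 0, and no estimate is clamped to [0, ln L] — the
coverage-adjusted estimators can legitimately exceed ln L on tiny samples
and clamping would distort their moment statistics.

* **MLE / MM.** Plug-in entropy of the empirical frequencies; Miller–Madow
  adds (N0−1)/2N, N0 the number of distinct observed symbols, so MM ≥ MLE
  with equality exactly when one symbol is observed.
* **NSB.** Posterior-mean entropy under a mixture of symmetric
  Dirichlet(β) priors, with the mixing density chosen uniform in
  ξ(β) = ψ(Lβ+1) − ψ(β+1), the prior expected entropy, so that the prior
  over H is approximately flat on (0, ln L). The conditional posterior
  mean given β is the Wolpert–Wolf expression
  `ψ(N+Lβ+1) − Σ_i (n_i+β) ψ(n_i+β+1) / (N+Lβ)`, and the evidence is
  `Γ(Lβ)/Γ(N+Lβ) · Π_i Γ(n_i+β)/Γ(β)`. The ξ-integral uses 200-point
  Gauss–Legendre quadrature; the ξ→β inversion is done once per alphabet
  size by bisection on log β and cached; log-evidence is shifted by its
  maximum before exponentiation. The Gauss–Legendre nodes never push β
  beyond ~10⁶ even near ξ = ln L, which keeps the gammaln differences well
  inside double precision. Validated in the test suite against an
  independent dense-trapezoid oracle that avoids gammaln differences
  entirely (exact integer-count log sums); agreement is at the 1e-10
  level, far inside the 1e-6 test tolerance. With no data the estimate is
  (ln L)/2, the mean of the flat prior on H.
* **CS.** Coverage C = 1 − N1/N (N1 = singletons) rescales the empirical
  frequencies; observed symbols are summed with the Horvitz–Thompson
  weight 1/(1 − (1−p)^N). When every observation is a singleton (N1 = N)
  the raw coverage is 0 and the estimator undefined; the customary
  replacement N1 → N−1 is used.
* **G.** ln N − (1/N) Σ n_i G_{n_i}, with G₁ = −γ − ln 2,
  G₂ = 2 − γ − ln 2, G_{2n+1} = G_{2n}, G_{2n+2} = G_{2n} + 2/(2n+1). The
  coefficient table is built once by a vectorized cumulative sum and grown
  lazily.
* **BHM.** The balanced harmonic double sum
  (1/(N+2)) Σ_{i=1..L} (n_i+1) Σ_{j=n_i+2}^{N+2} 1/j, evaluated through
  digamma differences. The sum runs over **all** L bins, including
  unobserved ones — that is the estimator's definition, and the
  unobserved-bin term is what produces its characteristic behaviour in
  the undersampled regime (see Limitations).
* **HS.** James–Stein shrinkage of the frequencies toward uniform with
  weight α = min(1, (1−Σp̂²)/((N−1) Σ(1/L−p̂)²)); α := 1 when N = 1 or the
  denominator vanishes (the empirical distribution is already uniform, so
  every α gives the same mix).
* **CWJ.** Digamma lead sum over observed symbols plus a singleton tail
  with coefficient A from the three-case singleton/doubleton rule. The
  textbook tail form `(1−A)^{1−N} [−ln A − Σ_{j<N} (1−A)^j/j]` overflows
  and cancels catastrophically for large N; it is evaluated instead as the
  analytically identical series `(N1/N)(1−A) Σ_{m≥0} (1−A)^m/(N+m)`,
  summed in blocks with a geometric truncation bound and a Lerch-
  transcendent fallback when 1−A is within ~1/10⁶ of 1.
* **CC.** Same Horvitz–Thompson construction as CS, but the coverage is
  estimated sequentially: walking the second half of the ordered sequence,
  each position whose symbol was never seen before subtracts 1/(N′+j),
  N′ = ⌊N/2⌋ (the defining expression leaves the parity of N/2 open;
  flooring keeps every index inside the sequence). This makes CC
  order-sensitive and bounds its coverage below by 1 − ln 2.
* **CMM.** MM plus (1/N) Σ_{i≥2} λ̂_i/(1−λ̂_i) over the non-unit eigenvalues
  of the estimated transition matrix — the closed-form resummation of the
  excess return probabilities K(l) = Tr(T^l) − 1. The unit eigenvalue is
  identified as the one closest to 1+0i (tolerance 1e-9); if any other
  eigenvalue has modulus ≥ 1 − 1e-9 the geometric series diverges, the
  correction is skipped and the MM value returned with a fallback flag.
  Complex eigenvalue pairs are summed in complex arithmetic and the real
  part returned (the imaginary parts must cancel to 1e-9). States with no
  outgoing transition cannot carry a stochastic row, so transition
  estimation drops them and renormalizes on the retained states, iterating
  because a removal can strand another state; if nothing survives (e.g.
  the two-symbol sequence [0, 1]) CMM falls back to MM.

## Exact moments and Monte Carlo

For N within the enumeration budget (default L^N ≤ 2²²) the moments
⟨Ĥᵏ⟩ = Σ_S P(S) Ĥ(S)ᵏ are computed exactly over all sequences, with
compensated (`math.fsum`) accumulation and explicit renormalization by the
summed weights. Count-based estimator values are cached by count vector,
which collapses the 2ᴺ binary evaluations to N+1. The Monte-Carlo engine
reports the sample mean and unbiased (M−1 denominator) sample variance
over M independent simulated chains; a single integer seed makes every
stochastic path bit-reproducible.

The binary grid sweep exploits that the estimator value depends only on
the sequence while the probability depends only on the grid point: the
2ᴺ sequences and their sufficient statistics (first symbol, bigram
counts) are tabulated once, then each of the 2500 grid points is a pair of
dot products. The result is verified against the generic enumeration
engine in the tests.

## The undersampled block study

Overlapping n-bit windows of an i.i.d. Bernoulli(p) bit stream form a
Markov chain on 2ⁿ states whose stationary law is the product-Bernoulli
measure and whose rows have exactly two nonzero entries (shift-and-append
dynamics: z → 2z mod 2ⁿ plus the fresh bit, oldest bit most significant).
The block entropy target is n·H1(p) by independence. The experiment
simulates the window chain directly — the tests prove the exact
distributional identity between this chain and window-encoding an i.i.d.
bit stream — with defaults n = 6 (L = 64), window-sequence length N = 20,
p from 0.02 to 0.5 in steps of 0.02, and M = 10⁴ replicates per p
(M = 10³ in the reduced-scale test-suite and acceptance runs, which keeps
the full suite within minutes while leaving every ranking stable across
repetitions). All estimators are evaluated on the same replicates (paired
design), so ranking comparisons cancel simulation noise; count-based
estimators are evaluated once per distinct count multiset, which cuts the
per-replicate cost by roughly an order of magnitude.

Aggregation over a parameter grid uses the declared step as a measure:
B̄ = Δp² Σ |B| over the two-dimensional (p00, p11) lattice and
B̄ = Δp Σ |B| over the one-dimensional p grid (likewise σ̄ and MSĒ without
the absolute value, both statistics being nonnegative).

## What the generators do and do not emulate

The synthetic sources are exactly the model class the estimators are
analysed on: stationary homogeneous first-order chains (and the sparse
window chain they induce). They deliberately exclude higher-order memory,
nonstationarity, and continuous observations, so passing tests demonstrate
correctness of the estimators and of the bias/variance machinery on
first-order Markovian data, not robustness of any estimator on real
sequences with richer structure. Sequences start in the stationary state;
burn-in transients are out of scope.

## Known limitations

* BHM's inclusion of unobserved bins means that for N ≪ L its value is
  dominated by the deterministic term (L−N0)(ψ(N+3)−ψ(2))/(N+2): in the
  n = 6, N = 20 study its bias is several nats positive while its variance
  is the smallest of all ten estimators, and its aggregated |bias|
  decreases monotonically with N well past N = 30. Published comparisons
  that report a different qualitative picture for this estimator in such
  regimes are consistent with implementations that silently drop
  unobserved bins; this package keeps the defining formula.
* Chains of order m ≥ 2 are not modelled, and the CMM correction assumes
  the estimated spectrum is away from the unit circle; strongly periodic
  data triggers the MM fallback rather than an extrapolated correction.
* NSB assumes the alphabet size L is known exactly; feeding it an
  underestimate biases it like the plug-in.
* The exact engine is limited by the L^N budget; beyond it all statements
  are Monte Carlo with the quoted standard errors.
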