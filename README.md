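# markent — entropy estimation for Markovian sequences

Estimating the Shannon entropy

```
H[X] = - Σ_i p(x_i) ln p(x_i)        (nats)
```

of a discrete random variable from a finite observed sequence is a classic
hard problem: no unbiased estimator exists, and in the undersampled regime
(sample size N comparable to or below the alphabet size L) the popular
estimators disagree wildly. Most of them were built and benchmarked for
i.i.d. data, yet real symbolic data — neural spike words, DNA words,
linguistic sequences — is correlated, at minimum Markovian.

`markent` is a toolbox for studying exactly this setting. It provides:

* **Ten finite-sample entropy estimators** with a uniform API: the plug-in
  estimator (MLE), Miller–Madow (MM), the Nemenman–Shafee–Bialek
  Dirichlet-mixture Bayesian estimator (NSB), Chao–Shen (CS), Grassberger
  (G), Bonachela–Hinrichsen–Muñoz (BHM), Hausser–Strimmer shrinkage (HS),
  Chao–Wang–Jost (CWJ), the order-sensitive correlation coverage-adjusted
  estimator (CC), and a corrected Miller–Madow estimator (CMM)

  ```
  H_CMM = H_MM + (1/N) Σ_{i≥2} λ_i / (1 - λ_i)
  ```

  whose memory term sums over the non-unit eigenvalues λ_i of the
  transition matrix estimated from the sequence itself.
* **Homogeneous Markov chain machinery**: construction, stationary
  distributions, exact sequence probabilities P(S) = p(X₁) Π p(X_{i+1}|X_i),
  seeded simulation, transition estimation, and the block (sliding-window)
  chain that maps an i.i.d. Bernoulli(p) bit stream to a Markov chain on
  2ⁿ window states.
* **Exact estimator moments**: for short sequences, ⟨Ĥᵏ⟩ = Σ_S P(S) Ĥ(S)ᵏ by
  enumerating all Lᴺ sequences, giving exact bias B = ⟨Ĥ⟩ − H, standard
  deviation σ and MSE = B² + σ²; plus a seeded Monte-Carlo engine for
  everything beyond enumeration reach.
* **Two comparison studies**: an exact sweep of the binary chain's
  (p00, p11) grid with area-aggregated B̄, σ̄, MSĒ, and a Monte-Carlo
  block-entropy study deep in the undersampled regime (L = 2⁶ states,
  N = 20 observations), with paired replicates so estimator rankings are
  not blurred by simulation noise.

## Worked example

`python examples/binary_grid_study.py` sweeps all ten estimators over the
50×50 grid of binary self-transition probabilities at sequence length
N = 4, computing exact enumeration moments at every point:

```
aggregated statistics at N=4 (50x50 grid, exact enumeration):
 N estimator  agg_bias  agg_sd  agg_mse
 4       BHM    0.1070  0.0746   0.0215
 4       NSB    0.1254  0.1468   0.0454
 4       MLE    0.1574  0.2224   0.0903
 4        HS    0.1096  0.2451   0.0925
 4        MM    0.1065  0.2655   0.1000
 4       CWJ    0.1051  0.2716   0.1030
 4       CMM    0.0998  0.2840   0.1079
 4        CC    0.0896  0.3003   0.1171
 4        CS    0.0955  0.3056   0.1219
 4         G    0.1253  0.4128   0.2041
```

Each row aggregates a statistic over the whole grid (area-weighted sum,
prefactor Δp² = 0.0004): `agg_bias` is the total absolute bias of the
estimator at this sample size, `agg_sd` its total dispersion, `agg_mse`
their combination. At N = 4 the balanced BHM and Bayesian NSB estimators
dominate in MSE because of their small dispersion, while the
coverage-based CC and CMM win on bias alone. The other examples show
single-sequence estimation, exact-versus-Monte-Carlo agreement, and the
undersampled 6-bit block study (`examples/undersampled_blocks.py`), where
NSB has the lowest aggregated MSE and CC the flattest bias profile.

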