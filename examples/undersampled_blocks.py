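"""Block-entropy estimation deep in the undersampled regime.

Overlapping 6-bit windows of an i.i.d. binary source form a Markov chain on
64 states; with only N=20 window observations most states are never seen,
and the target block entropy (up to 6 ln 2 = 4.159 nats) must be estimated
from counts that are nearly all singletons. Monte-Carlo statistics over
M=1000 replicates per bit-probability p, aggregated over the p grid.
"""

from markent.experiments import block_mc_experiment

points, agg = block_mc_experiment(n=6, length=20, n_replicates=1000, seed=0)
print("aggregated statistics, 6-bit blocks, N=20, M=1000:")
print(agg.sort_values("agg_mse").to_string(index=False, float_format="%.4f"))

ranges = points.groupby("estimator")["bias"].agg(lambda b: b.max() - b.min())
print("\nbias range over p (flatness; smaller = more robust):")
print(ranges.sort_values().to_string(float_format="%.4f"))
print("\nThe coverage-based CC estimator keeps a small, nearly constant bias")
print("across p, at the price of dispersion; NSB wins on mean squared error.")
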