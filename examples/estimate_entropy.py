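"""Estimate the entropy of a correlated binary sequence with all ten estimators.

Simulates a persistent two-state Markov chain (p00=0.9, p11=0.8), whose
stationary distribution (2/3, 1/3) has entropy 0.6365 nats, and shows how
far each finite-sample estimator lands from that target at N=200.
"""

import numpy as np

from markent import estimate_all, make_binary_chain, simulate, stationary_distribution, true_entropy

model = make_binary_chain(0.9, 0.8)
h = true_entropy(stationary_distribution(model))
s = simulate(model, 200, seed=12)

print(f"true stationary entropy: {h:.6f} nats")
print(f"sequence: N={s.size}, counts={np.bincount(s)}")
print(f"{'estimator':>10s} {'value':>9s} {'error':>9s}")
for eid, r in estimate_all(s, 2).items():
    print(f"{eid:>10s} {r.value:9.6f} {r.value - h:+9.6f}")
print("\nCMM adds the estimated memory correction of the chain to the")
print("Miller-Madow value; on this persistent chain it lands closest to the")
print("target together with Grassberger, while the plug-in (MLE) is biased low.")
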