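"""Choosing the expression/motif trade-off lambda by minimizing
C(mu, lambda) = mu * H(lambda) + (1 - mu) * NonU(lambda)."""

import numpy as np

import motifsd as msd

# both channels informative but noisy: the interesting regime for the trade-off
spec = msd.BenchmarkSpec(m=15, N=120, n=6, K=2, noise_sd=0.5, fp_rate=0.2, fn_rate=0.2, seed=0)
X, W, _ = msd.simulate(spec)

grid = np.array([0.0, 0.01, 0.03, 0.08, 0.2, 0.5, 1.0])
curve = msd.select_lambda(X, W, grid=grid, seed=0)
print(curve.to_frame().round(3).to_string(index=False))
print(f"\nlambda* = {curve.lambda_star:g}")
# H: mean normalized entropy of motif occupancy (low = clusters dominated by
# few motifs). NonU: within-cluster expression variance (high = noisy
# clusters). Their sum is minimized strictly inside the grid when both data
# sources carry signal.
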