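"""Build a binding-strength matrix by scanning promoters with PWMs.

Uses planted-motif promoters so the separation between true binding sites
and background sequence is visible."""

import numpy as np

import motifsd as msd

spec = msd.BenchmarkSpec(m=6, N=40, n=3, K=1, fp_rate=0.0, fn_rate=0.0, seed=1)
_, _, truth = msd.simulate(spec)
pwms, promoters = msd.simulate_promoters(truth, motif_length=8, promoter_length=200, seed=1)
print(f"{len(pwms)} PWMs (8 bp), {len(promoters)} promoters (200 bp)")

W = msd.build_binding_matrix(pwms, promoters, gene_ids=truth.gene_ids, cutoff=0.0)
planted, background = [], []
for ti, tf in enumerate(truth.tf_ids):
    for gi, gene in enumerate(truth.gene_ids):
        (planted if (tf, gene) in truth.edges else background).append(W.values[ti, gi])
print(f"planted sites: min normalized score {min(planted):.3f}")
print(f"background:    95th percentile      {np.quantile(background, 0.95):.3f}")
# scores are min-max normalized log-odds in [0, 1]; a cutoff of 0.75 keeps
# essentially all planted sites and discards the background.
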