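"""Recovering planted sources with the block-structured ICA.

Draws target-context pairs from the planted generative model (context
sources mixed into both vectors, unpaired sources into the target only),
fits the staged decomposition, and measures how well the unpaired sources
are recovered.  Amplitudes of the fitted model must also be insensitive to
the context once the unpaired sources are held fixed -- the property that
makes the conditional density of a target given its context depend on the
unpaired components alone.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from ctxsal import PlantedModel, amplitudes, fit_structured_ica, gen_structured_samples

pm = PlantedModel.random(d_c=12, d_s=16, k_s=8, k_u=4, seed=3)
batch, s_s, s_u = gen_structured_samples(pm, 50_000, seed=7)
ica = fit_structured_ica(batch, k_c=12, k_s=8, k_u=4, seed=1)

U = amplitudes(ica, batch.X_c, batch.X_s)
C = np.corrcoef(U.T, s_u.T)[:4, 4:]
ri, ci = linear_sum_assignment(-np.abs(C))
print("matched |corr| between recovered and planted unpaired sources:")
print(" ", np.round(np.abs(C[ri, ci]), 4), "(1.0 = perfect recovery)")

rng = np.random.default_rng(0)
s_u_fixed = rng.laplace(size=(50, 4))
u1 = amplitudes(ica, *ica.generate_pairs(rng.laplace(size=(50, 8)), s_u_fixed))
u2 = amplitudes(ica, *ica.generate_pairs(rng.laplace(size=(50, 8)), s_u_fixed))
print(f"max amplitude change under context resampling: {np.abs(u1 - u2).max():.2e}")
print("  (near machine precision: the context-mediated part cancels exactly)")
print(f"max cross-correlation between source groups: {ica.diagnostics['max_cross_corr']:.4f}")
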