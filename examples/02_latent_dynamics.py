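"""Fit neural modes and measure trial-to-trial reliability.

PCA on one individual's trial-averaged activity gives the neural modes;
projecting each of the three trials onto those modes gives per-trial latent
dynamics whose pairwise correlations measure response reliability.
"""

import numpy as np

import canaldyn as cd

spec = cd.CohortSpec(n_fish=1, n_neurons=250, trial_noise_sd=0.1, seed=1)
ts = cd.filter_responsive(cd.simulate_cohort(spec)[0])
ta = cd.trial_average(ts)
model = cd.fit_latent(ta, k=5)

cum = model.variance_explained.cumsum() * 100
print("cumulative % variance of modes 1-5:", np.round(cum, 1))
# Most population variance concentrates in a handful of covariation patterns.

rbar = cd.trial_consistency(ts, model)
print("mean inter-trial correlation per mode:", np.round(rbar, 3))
# Values near 1 mean the individual produces nearly the same latent
# trajectory on every stimulus repetition.
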