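"""Bias-adjust a simulated meta-analysis with empirical bias evidence.

Simulates a 10-trial benefit=OR<1 meta-analysis in which flagged trials carry
benefit-exaggerating biases, then compares the unadjusted Bayesian
random-effects fit with the data-based adjustment (method 1): the adjusted
odds ratio should sit closer to the true effect, and closer to 1, than the
unadjusted one.
"""

import numpy as np

from biasmeta import (
    MCMCConfig,
    default_bias_table,
    fit_bias_adjusted,
    priors_from_table,
    simulate_meta_analysis,
)

table = default_bias_table()
records, truth = simulate_meta_analysis(
    n_trials=10, d=-0.35, tau=0.3, bias_spec=table, seed=42
)
priors = priors_from_table(records, table)
config = MCMCConfig(n_chains=3, n_iter=12_000, n_burnin=2_000, seed=7)

_, adjusted = fit_bias_adjusted(records, priors, config)
_, unadjusted = fit_bias_adjusted(records, None, config)

print(f"true mean effect: OR {np.exp(truth.d):.2f} (log OR {truth.d:.2f})")
print(
    f"unadjusted: OR {unadjusted.or_median:.2f} "
    f"({unadjusted.or_lo:.2f}-{unadjusted.or_hi:.2f}), "
    f"tau^2 {unadjusted.tau2_median:.3f}"
)
print(
    f"adjusted (data-based): OR {adjusted.or_median:.2f} "
    f"({adjusted.or_lo:.2f}-{adjusted.or_hi:.2f}), "
    f"tau^2 {adjusted.tau2_median:.3f}, max Rhat {adjusted.rhat_max:.3f}"
)
print(
    "The biases exaggerate benefit, so the unadjusted OR overstates the "
    "effect; adjustment moves the estimate toward the truth and absorbs "
    "part of the between-trial heterogeneity."
)
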