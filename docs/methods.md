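# Methods

## The bias-adjustment model

Each trial contributes exact binomial likelihoods for both arms. Trials at
low risk of bias in all three assessed domains (sequence generation,
allocation concealment, blinding) estimate the true effect delta_i
directly; trials at high or unclear risk in any domain estimate
delta_i + beta_i, where beta_i is the total bias on the log
ratio-of-odds-ratios scale. High and unclear judgements are merged into a
single flag per domain at parse time because high-risk judgements are rare
in practice; the original judgement strings are retained for display.

Knowledge about beta_i enters as a fixed normal prior N(mu_i, sigma_i^2):
the model deliberately does not place a hierarchical prior over the mu_i,
so the five quantification methods can be compared on identical footing.
True effects are exchangeable, delta_i ~ N(d, tau^2), with a vague
N(0, 1e5) prior on d and a Uniform(0, 2) prior on the between-trial
standard deviation tau, which is a sensible weakly-informative range on the
log-odds-ratio scale. Control-arm log odds alpha_i get the same vague
normal as d. Bias priors are always expressed on the "negative log-ROR =
exaggeration of benefit" orientation; for meta-analyses where benefit means
OR > 1 the data are recoded internally (events <-> non-events) and effect
draws flipped back for reporting, so the same bias tables apply unchanged.

### Sampler

Sampling is Metropolis-within-Gibbs, vectorized across chains and trials:

- random-walk Metropolis for alpha_i;
- random-walk Metropolis for eta_i = delta_i + x_i beta_i against its
  collapsed prior N(d + mu_i, tau^2 + sigma_i^2), followed by an exact
  conditional decomposition of eta_i back into (delta_i, beta_i) — the
  likelihood depends on the two only through their sum, so this mixes far
  better than updating them separately;
- conjugate Gibbs for d;
- an exact Gibbs step for tau: under the uniform prior the conditional of
  the precision tau^-2 is a truncated Gamma((n-1)/2, S/2), inverted via the
  regularized incomplete gamma function;
- a joint translation move on (d, all delta_i), which removes the
  slow mixing that otherwise appears when tau is small (the centered
  funnel).

Proposal scales adapt by Robbins-Monro only during burn-in (targets 0.44
for scalar moves, 0.30 for the joint moves) and are frozen afterwards, so
retained draws target the exact posterior. Chains start from overdispersed
initial values (effects offset over [-1, 1], tau over [0.2, 1.8]).
Convergence is summarized by the largest split-chain potential scale
reduction factor over d, tau and all delta_i, computed on the second halves
of the chains; results carry a non-convergence flag when it exceeds 1.05
(the diagnostic itself is standard; the 1.05 threshold is this package's
choice). Identical constant chains return 1.0 by convention, and the
statistic is clamped below at 1.0. Zero-cell trials need no continuity
correction because the likelihood is exact binomial and all priors are
proper.

Posterior summaries are medians and central 95% intervals of exp(d) and
tau^2, using type-7 (linear interpolation) quantiles — credible-interval
endpoints depend on this convention, so it is fixed and documented.
`fit_bias_adjusted` accepts `tau_fixed`: `0` switches to a dedicated
common-effect sampler (delta_i = d for all trials, random-walk updates for
d and each beta_i), which is the regime where the posterior mean of d has a
precision-weighted closed form used by the oracle tests.

## Quantifying the bias priors

### Empirical evidence (method 1)

The meta-epidemiological model is additive and per-domain with two levels
of variation: within meta-analysis m, trial t has
theta_mt = delta_mt + sum_c x_mtc beta_mtc with
beta_mtc ~ N(b_mc, kappa_c^2) and b_mc ~ N(b0_c, phi_c^2); effects
delta_mt ~ N(d_m, tau_m^2) per meta-analysis. Hyperpriors:
b0_c ~ N(0, 1e3), phi_c, kappa_c ~ U(0, 2) (configurable; they mirror the
scale conventions of the adjustment model). Domains are a priori
independent and additive — published per-profile bias distributions are the
only external constraint available on the model's exact form, so this
explicit approximation was chosen over guessing richer structure; anyone
with a preferred meta-epidemiological fit can bypass it entirely via
`load_bias_table`. The same Metropolis-within-Gibbs machinery applies, with
the eta decomposition generalized to one effect plus up to three bias
components (conditioning independent normals on their sum).

The predictive distribution for total bias in a new trial with a given
profile sums the flagged domains' predictives N(b0_c, phi_c^2 + kappa_c^2)
over posterior samples and is summarized as a normal via the law of total
variance, because every downstream consumer takes a normal. A floor of
1e-6 on the predictive sd protects downstream samplers from degenerate
priors. The within-meta bias sd kappa_c is the slowest-mixing parameter
(a hierarchical funnel); runs of a few thousand iterations can show
Rhat > 1.05 and are flagged rather than silently accepted.

### Elicited opinion (methods 2, 4, 5)

Numeric IQRs on the ROR scale are log-transformed, rounded to the nearest
0.02 (ties away from zero — the tie rule is centralized in one function; a
1e-9 guard absorbs binary float representation), and read as
mean ± 0.67 sd. The 0.67 constant is the 75th standard-normal percentile
rounded to two decimals and is stored once, never recomputed as 0.6745,
because the elicitation arithmetic uses 0.67 exactly. An IQR whose bounds
collapse to one grid point is rejected as a zero-width opinion. Any finite
range is accepted (opinions may disagree with, and lie outside, a plotted
reference distribution).

Methods 2 and 4 differ only in what the assessor saw; their records flow
through the identical processing path and the strategy label matters only
for grouping and consistency analysis.

Method 5 area selections are resolved in probability space: areas A-D are
the quartile regions of the reference normal, the outer areas extending to
probability 0 and 1 (not to plotted axis limits), so a contiguous selection
with cumulative bounds (p_lo, p_hi) is an exactly truncated normal. Its
25%/75% quantiles are reference quantiles at p_lo + 0.25 (p_hi - p_lo) and
p_lo + 0.75 (p_hi - p_lo). These quartiles then pass through the same 0.02
rounding and 0.67 mapping as numeric IQRs, for uniform processing (whether
to round derived quartiles was an open choice; uniformity won). A very
narrow reference can make a single-quartile selection collapse on the grid,
which raises the zero-width error rather than fabricating a width.

Pooling across assessors takes the median of the means and the median of
the sds (midpoint of the central pair for even panels), so the pooled
distribution represents a typical assessor and single extreme opinions move
it by at most one order statistic. Linear and logarithmic opinion pools are
deliberately not offered.

### Fusion (method 3)

The pooled opinion N(mu_o, sigma_o^2) is treated as one observation of the
bias with known variance and the data-based N(mu_d, sigma_d^2) as its
prior. The posterior is the conjugate normal-normal update — implemented in
closed form rather than inside the MCMC for determinism and speed, with an
MCMC equivalence test guarding the identity. The update is symmetric in its
inputs and gives both sources equal weight; an `opinion_power` parameter on
the opinion precision is reserved for sensitivity analyses and defaults
to 1. The fused distribution then enters the meta-analysis like any other
prior; the meta-analysis data update it further inside the joint posterior,
so no separate "update by the data" step exists (that would double-count).

## Assessor consistency

The mixed model mean_ij = a_j + u_i + e_ij (assessors fixed, trials random)
is estimated by direct maximum likelihood, profiling over the variance
ratio lambda = sigma_trial^2 / sigma_resid^2: for fixed lambda the GLS fit
reduces to fractional group demeaning (Woodbury identity on I + lambda J),
leaving a one-dimensional optimization on log lambda with the lambda = 0
and residual-free boundaries handled explicitly and variances clipped at
zero. The ICC is sigma_trial^2 / (sigma_trial^2 + sigma_resid^2). The 95%
CI is the 2.5/97.5 percentile interval of ICCs refit on parametric
bootstrap datasets simulated from the fitted model with the same layout,
conditioning on the fitted assessor effects (resampling them is the other
defensible choice; conditioning matches the fixed-effects treatment).
Degenerate tables (no variation at all) return ICC 0 with a degenerate-CI
flag instead of failing.

## Synthetic data: what it emulates, and what it does not

The generators implement exactly the models above, with defaults chosen to
resemble the intended application conditions:

- per-domain bias components b0 = -0.07, phi = kappa = 0.05, so one flagged
  domain means a typical ROR of 0.93, all three 0.81, and per-profile
  predictive sds run 0.07-0.12 — magnitudes in line with published
  meta-epidemiological evidence for subjectively assessed binary outcomes;
- meta-analyses of 10 (or 25) trials with one all-low trial and flagged
  profiles drawn uniformly; control rates 0.1-0.4, arms of 50-300
  participants;
- elicitation panels of four assessors per strategy. Assessor behaviour has
  three dispersion components on the log-ROR scale: a persistent assessor
  offset, trial-by-assessor disagreement about the centre (this is the
  residual of the ICC model), and the stated width of each opinion.
  Defaults are (0.05, 0.12, 0.16) for the plain scale and (0.02, 0.04,
  0.10) for the data-informed strategies, so plain-scale panels produce
  wider distributions and markedly lower ICCs, as observed with real
  assessors;
- strategy-c assessors select the quartile areas of the reference
  distribution overlapped by their centre ± 0.67 x width interval.

Passing tests on these generators shows internal coherence — the samplers
recover the generative parameters, intervals attain nominal coverage under
the model, adjustment moves estimates toward the null by the right amount —
but not robustness to what real data add: model misspecification
(non-normal biases, correlated domains, outcome-dependent bias), real
assessor psychology (anchoring, overconfidence, heaping), selective
reporting, or risk-of-bias misclassification. Conclusions about real
meta-analyses still depend on the plausibility of the priors fed in.

## Problem sizes and numerical choices

Tests and examples run the sampler at 3 chains x 4,000-20,000 iterations
and the calibration study at 200 replicate meta-analyses of 10 trials with
3 x 10,000 chains; these sizes give Monte Carlo error comfortably below
each check's tolerance while keeping the suite quick. The default
configuration (3 x 500,000 after 25,000 burn-in) is intended for final
analyses. Other numerical choices: type-7 quantiles throughout; the 0.02
grid tie rule is half-away-from-zero; sums of squares in scale-parameter
Gibbs steps are floored at 1e-12; the truncated-gamma shape is floored at
0.005 to keep the single-group degenerate case proper; bootstrap and
sampler seeds derive from a single SeedSequence per call, so every pipeline
is bit-reproducible given one seed.

## Known limitations

- Binary outcomes only; no continuous or time-to-event likelihoods.
- Incomplete-outcome-data bias is not modelled as a domain.
- The meta-epidemiological model assumes domain independence and
  additivity; correlated domain effects would be absorbed into the
  per-profile predictives only approximately.
- The two-stage normal-approximation route (adjusting summary log ORs
  instead of refitting binomial likelihoods) is a natural extension not
  implemented in v1, as is network meta-analysis.
- ICC confidence intervals are percentile bootstrap; no bias correction or
  acceleration.
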