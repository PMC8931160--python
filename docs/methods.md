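# Methods

## The titration staircase and its precision

Each decision cell pairs one high-effort level (load index 1–3) with a base
amount b ∈ {2, 3, 4}. Trial 1 offers b for both options; the chosen option
becomes the titrated side. Adjustment k (k = 1..4 for the default 5-choice
cell) has step b/2^k and moves the titrated offer down after a choice of the
titrated option, up otherwise; the fixed side stays at b. The indifference
point is the titrated offer after the last adjustment; the fifth choice is
recorded (it can be drawn for the incentive payout) but triggers no further
adjustment. This reading makes the arithmetic 3 loads × 3 amounts × 5
choices = 45 decision trials per domain come out exactly; a 6-choice reading
is available via `n_trials_per_cell`.

Offers are `fractions.Fraction` values, so staircase arithmetic is exact;
CSV logs serialize offers with six decimal digits, which round-trips every
dyadic offer the 5- or 6-trial staircase can produce (b/2^4 with b = 3 needs
four decimals; two would not round-trip).

For a deterministic threshold agent the staircase is a binary search: the
endpoint lies within b/2^4 of the agent's indifference offer everywhere on
(0, 1) ∪ (1, 2) in SV units, verified in the tests against exhaustive
enumeration of all choice paths. Exact ties are resolved toward the
low-effort option, which never overstates effort seeking.

Replay of logged trials revalidates every offer against the schedule and
rejects (naming the trial) rather than silently correcting inconsistent
logs.

## Subjective-value scoring

SV = ip/b when the easy option was chosen first, 1 + (b − ip)/b when the
hard option was chosen first; both formulas give 1 at ip = b, so the score
is continuous across the branches. The per-domain summary is the arithmetic
mean over the 9 cells; missing or duplicate cells are completeness errors,
never imputed. Composites are sums of z-scores (L-span, O-span, Sym-span
for capacity; BAS total, GRAPES reward expectancy, SPSRQ reward sensitivity
for reward sensitivity), z-scored over the analyzed sample — i.e. after
exclusions — making them invariant to affine rescaling of any raw
component. Keyword intelligibility is the proportion of a sentence's four
key words typed back, with case-insensitive, punctuation-stripped,
order-free token matching and each keyword credited at most once; no
stemming or homophone handling is attempted.

Exclusions: the primary rules drop participants without headphones or with
incomplete discounting data. Dropping effort-seekers (grand-mean SV > 1
across both domains) is a sensitivity mode, never a default; the pipeline
always reports both samples. The grand-mean reading of the criterion (vs
per-domain) is a deliberate choice: it flags globally reverse-discounting
participants rather than domain-specific ones.

## Mixed models and residualization

Subjective value and TLX models are random-intercept linear mixed models
fit by REML (statsmodels `MixedLM`) with Gaussian 95% intervals; load is
coded numerically 0/1/2 so one coefficient carries the graded load effect.
The original analyses fit the same structures in a Bayesian wrapper with
flat priors, a setup its authors describe as ML-equivalent, so REML is the
reference implementation here — deterministic and fast. R² is the
explained-variance ratio var(fixed + BLUP predictions) over total, bounded
in [0, 1].

The residual that feeds the cross-domain correlation subtracts only the
fixed-effect prediction. Subtracting the participant's random intercept
would remove precisely the stable between-person variance that the
domain-generality hypothesis is about; with fixed-effects-only residuals
the trait variance survives into the per-participant averaged residual
(this is also the only reading under which a residualized correlation can
exceed the zero-order one, as observed in this literature). The alternative
is exposed as `subtract_random_intercept=True`.

Because REML re-estimates variance components, residualizing residuals a
second time is idempotent only up to the re-estimated GLS weighting;
per-participant means change by < 1e−6 in practice, not exactly 0.

## Bayesian correlation and Bayes factors

The likelihood of ρ given observed r and n is the exact sampling density of
the Pearson correlation (hypergeometric form). Posterior and marginal
likelihood are computed on a fine grid over (−1, 1) (1601 points by
default; results stable to ~1e−4), giving deterministic medians, central
95% credible intervals, and BF10 against the point null. Partial
correlations residualize both variables on the covariates by least squares
and use effective sample size n − k, matching classical partial-correlation
sampling theory.

Priors: the default is the stretched beta ((ρ+1)/2 ~ Beta(1/w, 1/w),
"medium" w = 1/3). A central Cauchy with scale √2/2 — the conventional
*t-test* default that correlation reports sometimes name — is available in
two readings: renormalized to (−1, 1) (a proper prior) and unrenormalized
(the density evaluated as-is, total mass ≈ 0.61 on the support), which is
what Savage–Dickey implementations effectively use when handed that prior
for a bounded correlation. The unrenormalized reading scales BF10 down by
the truncation mass and leaves posterior summaries unchanged.

Paired domain contrasts use the one-sample t statistic on within-person
differences with the default JZS Bayes factor (Cauchy scale √2/2 on the
standardized effect), computed by numerical integration of the
noncentral-t likelihood; the tests cross-check it against the independent
Zellner–Siow g-integral form.

## Sequential design analysis

Replicates accumulate bivariate-normal observations (data grow, never
regenerate); at each scheduled look the correlation Bayes factor is
computed on the data so far and sampling stops at BF10 ≥ 10, BF10 ≤ 0.1,
or n_max = 300. The reproduction preset uses the registered look schedule
(first look at n = 100, then every 10) with the unrenormalized
Cauchy(0, √2/2) kernel. Two facts drove this choice. First, under any
proper prior on (−1, 1) whose density at 0 is ≳ 0.6, BF01 cannot exceed
~9 by n = 300, so a lower evidence boundary of 10 is unreachable — null
stopping medians near 140 are only consistent with an evidence kernel
whose effective prior mass extends beyond the bounded support. Second,
with that kernel the registered schedule yields asymptotic stopping
medians of 110 (upper boundary, ρ = 0.3) and 150 (lower boundary, ρ = 0),
the closest joint match to published values for this design among the
schedules and kernels examined; every-participant look schedules yield
(83, 142) instead. Both medians sit adjacent to look-schedule atoms
(P(stop ≤ 100) ≈ 0.496 under ρ = 0.3; P(stop ≤ 150) ≈ 0.502 under ρ = 0),
so the acceptance script pools 100k–200k replicates to pin the sample
median to its asymptotic value; scientific conclusions do not depend on
which side of the atom the median falls.

## Synthetic cohorts

Each participant draws (u_wm, u_speech, capacity, reward, NCS) from a
multivariate normal. True SV is defined on the *instrument's* 0–2 scale —
the value an ideal noiseless staircase-plus-scoring chain would report —
and the latent preference that drives choices is its inverse instrument
map (identity below 1, θ = 1/(2 − SV) above 1), so ground truth and ideal
measurement coincide by construction on both branches. True SV for domain
d, load ℓ, amount a is

  SV = intercept_d + slope_d·(ℓ−1) + subject_sd·u_d + s·I(seeker)
       + coupling_d·z_perf(d, ℓ) + cell noise,  clipped to [0, 2],

with defaults: intercepts 0.75 (working memory) / 0.85 (speech), load
slopes −0.09 / −0.19 per level, subject SD 0.25, cell noise SD 0.15,
effort-seeker probability 0.05 with shift s = 0.6, and performance
couplings 0.016 / 0.01 SV per performance SD (the working-memory value
corresponds to a hit-rate regression coefficient of ≈ 0.2 on the SV
scale). Choices follow a logistic policy in
(SV·offer_high − offer_low)/temperature with temperature $0.20;
temperature 0 is the deterministic threshold agent. Performance declines
linearly in load (hit rate 0.85 → 0.65; intelligibility 0.90 → 0.45 across
−4/−8/−12 dB) with a small capacity loading; TLX ratings rise ~3.7 (mental
demand), 2.5 (effort) and 1.0 (frustration) points per level on the 1–21
scale. Span and questionnaire totals load 0.7–0.8 on their factors at
realistic means and SDs.

Two channels couple the domains outside the Gaussian copula: the shared
effort-seeker shift and capacity acting through the performance coupling.
The generator solves the covariance bookkeeping analytically so that the
population cross-domain correlation of true mean SV equals `rho_domains`
exactly; consequently extreme values of rho_domains can be unreachable for
some mixture settings, which is reported as a configuration error rather
than silently approximated. Randomness uses one root seed with
per-participant counter-derived substreams, so participant i is identical
across cohort sizes.

What the generator does **not** emulate: item-level questionnaire
responses, sequential/order effects and learning across the familiarization
phase, non-stationary choice strategies, heavy-tailed or censored RT
distributions, and real speech materials. Passing recovery tests therefore
demonstrates that the estimation chain is unbiased and appropriately
calibrated under the assumed generative structure, not that the model
family is correct for any particular real dataset.

## Problem sizes used in the tests

Recovery acceptance uses 100 replicate cohorts of n = 300 at
ρ ∈ {0, 0.3, 0.5} (posterior-coverage and Bayes-factor checks), 50
random datasets for the dual-implementation Bayes-factor oracle, full
0.01-grid enumeration of staircase endpoints for every base amount, and
50k–150k sequential-design replicates. These sizes keep the full suite in
the tens of minutes on a single core while leaving Monte-Carlo error well
inside each test's tolerance.

## Known limitations

- The Bayes-factor grid integration is exact to ~1e−4 but the design
  engine defaults to a coarser 401-point grid for speed; boundary
  decisions within ~1e−3 of a threshold can differ between grids (a
  measure-zero event under continuous sampling).
- REML mixed models can sit at a variance boundary (σ²_u = 0) for data
  with no trait variance; fixed effects then match OLS only to numerical
  optimization tolerance.
- The effort-seeker mixture uses a constant shift, not a separate full
  distribution.
- Recovery is assessed against each cohort's realized ground-truth
  correlation: a finite mixture cohort's latent correlation fluctuates
  around the population target (sd ≈ 0.05–0.08 at n = 300, driven by the
  binomial effort-seeker count), and that composition noise is invisible
  to any analysis of the cohort itself.
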