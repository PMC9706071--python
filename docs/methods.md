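# Methods

## Scope and coordinates

All headings are angles in degrees relative to the ego-centric
(straight-ahead) direction at 0°, positive rightward. Stimulus
rendering (optic-flow dot clouds) is out of scope: the package operates
on trial tables of actual heading (AH) and perceived heading (PH),
which is what the statistical questions need.

## Block designs

Six presets cover the study designs the pipeline emulates. Uniform
blocks repeat each heading 50 times (600 trials for the 12-heading wide
sets, 300 for the 6-heading narrow sets). The right-heavied nonuniform
block assigns counts (16, 16, 16, 16, 16, 22, 42, 84, 124, 124, 82, 42)
to the 12 headings −33°…33° in ascending order, totalling 600 trials
with a count-weighted mean of 12.0°. Trial schedules are full uniform
shuffles of the block multiset (no constraint on immediate repeats),
reproducible from an integer seed via `numpy`'s PCG64 generator; the
shuffle preserves the empirical distribution exactly, so the schedule
mean equals the design mean to machine precision.

## Synthetic observer

The generator produces, per trial,

    PH_i = shift_delta
           + slope_s · [(1 − ct_weight)·AH_i + ct_weight·m]
           + 2 · sd_coef · (AH_{i−1} − m)        (0 on the first trial)
           + ε_i,   ε_i ~ N(0, noise_sigma²)

with `m` the block's distribution mean. Parameters, defaults, and why:

| parameter     | meaning                                   | default |
|---------------|-------------------------------------------|---------|
| `slope_s`     | center-bias compression slope (unitless)  | 0.8     |
| `shift_delta` | constant response shift (deg)             | 0       |
| `ct_weight`   | attraction toward the block mean (0–1; negative = repulsion) | 0 |
| `sd_coef`     | serial-dependence coefficient on the s′ scale (unitless) | 0 |
| `noise_sigma` | response noise SD (deg)                   | 3       |

The default slope of 0.8 and the 0.15 between-participant slope SD
match the magnitudes typical of heading-report experiments (group
slopes ≈ 0.75–0.86 with SEs of 0.03–0.05 at n = 20); the 3° response
noise combines the 1–2° perceptual precision reported for optic-flow
heading with probe/motor noise. The default two-block nonuniform study
adds, in the right-heavied block only, `shift_delta = −2°` and
`sd_coef = −0.01`, the effect sizes the analyses are designed to detect
(a ≈2° leftward bias difference and a repulsive serial slope ≈ −0.01).

**Why the serial term is `2·sd_coef·(AH_prev − m)` and not
`sd_coef·(AH_prev − AH_cur)`.** The analysis estimates serial
dependence by regressing each participant's residual heading error
(RHE, the residual of their own PH-on-AH fit) on the relative heading
RH = AH_prev − AH_cur. Any generative term containing −c·AH_cur is
absorbed into the fitted slope (which becomes s − c), and the surviving
residual signal, c·(AH_prev − m), projects onto RH with factor
Var(AH_prev)/Var(RH) = 1/2 on a shuffled schedule — so a naive c·RH
term would bias the fitted center-bias slope by −c and be recovered as
c/2. Writing the term as 2c·(AH_prev − m) keeps the center-bias slope
unbiased and makes the group-level regression consistent for `sd_coef`
(verified analytically and by simulation: at 20 participants × 600
trials the mean recovered s′ is −0.0100 for a generative −0.01). The
halving is a genuine property of the residual-regression estimator
worth remembering when mapping measured s′ values back to underlying
trial-to-trial influences.

What the generator does *not* emulate: heading-dependent
(heteroscedastic) response noise, nonlinear (e.g. DoG-shaped) serial
dependence, drift or learning across a block, lapses, and oculomotor or
probe dynamics. Passing recovery tests therefore shows the pipeline is
correct for linear-Gaussian structure at these effect sizes, not that
real data satisfy those assumptions.

## Bayesian ideal observer

On a grid spanning [−90°, 90°] (default step 0.1°; ≥5 SD beyond the
extreme ±33° headings so normalization is defensible), the posterior
for a measurement M is

    p(X_j | M) ∝ N(M; X_j, σ_m²) · N(X_j; θ_ego, σ_ego²) · p_dis(X_j),

computed in log space and normalized to sum to one. Choices:

* **Likelihood family.** Gaussian in degrees; adequate in the
  small-angle regime (|heading| ≤ 33°) where linear angle space is a
  good approximation.
* **Distribution prior.** `"uniform"` is an exact constant (for the
  66°-wide design, 1/66 per degree) and cancels from the normalized
  posterior — the analytic identity `posterior == ego-only posterior`
  is enforced in tests to < 1e−9 pointwise. A nonuniform prior is the
  count-weighted Gaussian kernel density over the design headings
  (default kernel 3°, half the 6° heading spacing, so the density is
  smooth but local); with kernel width 0 the counts sit on the nearest
  grid points as spikes.
* **Read-out.** Posterior mean by default (MAP available). Predicted
  PH for a true heading averages the read-out over `n_mc` simulated
  measurements M ~ N(AH, σ_m²); with the posterior-mean read-out this
  converges to the conjugate shrinkage `σ_ego²/(σ_ego²+σ_m²)·AH`, the
  closed form used as the test oracle (posterior mean within 1e−4° of
  the conjugate value at grid step 0.01°).

The model is used predictively only; it is not fitted to data. Its role
is to make the qualitative predictions executable: a uniform prior
changes nothing, a right-heavied prior pulls predictions toward 12° —
an attraction that data showing a leftward (repulsive) shift
contradict.

## Statistical pipeline

* **Center bias.** OLS of PH on AH per participant and condition
  (intercept included); one-sample two-sided t-test of participant
  slopes against 1; Cohen's d = |mean − 1| / SD. Degenerate inputs
  (all slopes identical) return t = 0 at the null rather than NaN.
* **ANOVAs.** Per-participant cell means (participant × distribution ×
  heading) feed a repeated-measures ANOVA (pingouin), mixed when the
  two conditions come from different cohorts. Greenhouse–Geisser
  corrected p-values and fractional degrees of freedom are reported for
  within factors with more than two levels; ε is bounded by
  1/(k−1) ≤ ε ≤ 1 and is checked against a from-scratch matrix-algebra
  oracle (orthonormal-contrast covariance form) to 1e−8. Effect size is
  partial eta squared. Zero-variance cells (e.g. a condition compared
  with itself) yield F = 0, p = 1 rather than 0/0.
* **Serial dependence.** Per participant, RHE is the residual of their
  own center-bias fit; the block's first trial has no predecessor and
  is excluded. RH = AH_prev − AH_cur, so repulsion from the previous
  heading gives a negative slope. s′ is the pooled group-level OLS
  slope of RHE on RH (computed from per-participant sufficient
  statistics). The 95% CI is s′ ± t(0.975, n−1)·SE_boot with SE_boot
  from a participant-level nonparametric bootstrap (default 10,000
  resamples, vectorized over the moment sums). The raw percentile
  interval was measured at a 7–9% type-I rate with 20 participants in
  null simulations; the t-scaled bootstrap-SE interval holds ≈5% and is
  therefore the default.
* **Mean PH bias.** Per participant, PH is averaged within each heading
  and then unweighted across headings before averaging over
  participants. This keeps the statistic on the ANOVA's cell-mean scale
  and prevents a nonuniform trial allocation from dragging the mean
  toward its dense headings — with the right-heavied design a
  trial-weighted mean would sit near slope·12° ≈ +9.6° from center bias
  alone and mask the constant shift the statistic is meant to measure.
  CI by participant-level bootstrap (percentile; the statistic is a
  plain mean, where percentile coverage is adequate).
* **Decomposition.** Per condition, the serial-dependence-induced bias
  is the mean over realized trials of s′·RH; the induced difference
  (shifted − reference condition) is expressed as a percentage of the
  total mean-bias difference. On shuffled schedules mean RH ≈ 0, so the
  induced share is near zero even with a clearly negative s′ — the
  point of the analysis: serial dependence cannot explain a constant
  distributional shift. The fraction is undefined (explicit error) when
  the total difference is zero, and is scale-invariant under rescaling
  of all PH.
* Two-sided tests, α = .05 throughout. Post-hoc per-heading paired
  t-tests after a significant interaction are reported without
  multiplicity correction and flagged as such.

## Problem sizes and seeds

Recovery checks run 100 replicates of the full study size (20
participants × 600 trials): mean fitted slope within [0.78, 0.82] for a
generative 0.8 under 3° noise, and mean recovered s′ within ±0.003 of a
generative −0.01 with the correct sign in ≥99/100 replicates. Null
calibration runs 1,000 replicates with trial counts scaled to 10 per
heading (the F test and the bootstrap CI are calibrated by
participants, not trials, so scaling trials keeps the check honest
while keeping it quick); both the distribution-effect test and the s′
CI must reject in 5% ± 2% of replicates. All simulations derive
per-participant/block streams from a single master seed via
`numpy.random.SeedSequence`, so every table, statistic and report is
bit-reproducible; re-running a pipeline from its manifest reproduces
identical numerical outputs.

## Known limitations

* The generator is linear and homoscedastic; none of the analyses
  require that, but the recovery guarantees are stated under it.
* The ideal-observer module predicts only attraction (a prior can only
  pull toward its mass); it cannot produce the repulsive distribution
  effect, and no model of that effect is attempted here.
* The mixed-design path supports one within factor and one between
  factor, which is all the cross-cohort comparison needs.
* Bootstrap CIs are participant-level only; trial-level resampling
  (which would have to respect serial structure) is not implemented.
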