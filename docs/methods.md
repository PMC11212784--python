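# Methods

This note documents the models, conventions, and design choices behind the
package, in the spirit of a model-documentation page: what is computed, under
which assumptions, and where genuinely open choices were settled.

## Scoring

Heartbeat-counting accuracy uses the Schandry transformation: each trial
contributes `1 − |recorded − counted| / recorded` and Performance is 100
times the mean.  Two conventions matter:

- **1/n averaging.** The canonical three-trial form divides by 3; the scorer
  divides by the actual trial count so the same function serves three- and
  four-trial protocols.
- **No clipping.** A trial score is negative when the participant over-counts
  by more than the recorded number of beats.  Scores are kept as-is; clipping
  at zero would bias aggregates upward and hide pathological over-counting.

The posterior prospective self-efficacy belief is defined as the exact mean
of the half-duration and double-duration forecasts.  Performance confidence
is the unweighted mean of the per-trial confidence ratings that are present
(durations do not weight it; no rating present means the value is flagged
missing, never imputed as zero).  The interoceptive trait prediction error
(ITPE) is z(sensibility) − z(objective accuracy) with both z-scores computed
within the supplied cohort using the population (ddof = 0) standard
deviation, so the measure sums to zero over the cohort.  Which questionnaire
supplies "sensibility" is the caller's choice; the pipeline uses the EDI-3
Interoceptive Deficits subscale.

## The belief-update model

The core rule is a one-shot conjugate-Gaussian update,
`posterior = prior + λ (evidence − prior)` with
`λ = π_ε / (π_θ + π_ε)`.  It assumes a single exchange of evidence (no
sequential filtering), Gaussian belief distributions summarised by their
means, and observable proxies standing in for the precisions:

- prior precision π_θ: the prior prospective confidence rating (0–100);
- evidence precision π_ε: either performance confidence (0–100) or the
  EDI-3-ID raw score rescaled as `(1 − raw / 36) × 100`.

Confidence ratings and rescaled questionnaire scores are used directly as
unitless precision weights: λ depends only on their ratio, so any common
scaling cancels.  The EDI rescaling direction maps *more* interoceptive
deficits to *lower* evidence precision; the maximum raw score (36) is
configurable, as is the direction-setting transformation through the
function itself.

The realised learning rate `λ_actual = (posterior − prior) / (evidence −
prior)` is reported **unclamped**: values outside [0, 1] mean the participant
overshot the evidence or moved away from it, which is diagnostically
meaningful, and the out-of-range counts are summarised rather than hidden.
Participants with `evidence = prior` (denominator within 1e−9) are excluded
from realised-rate analyses and counted; participants with both precision
weights zero are excluded from prediction and logged.  Nothing is imputed.

Model registry: four target rules form the 2 × 2 evidence × precision-proxy
grid (labels `x.1` … `x.4`; the `x` becomes the panel number 1–4 for the
all/HC/AN/p-AN panels in reports), plus three baselines — λ = 1 under each
evidence source (`b.1`, `b.2`) and λ = 0 (`b.0`).

## Model comparison

None of the rules fits free parameters, so comparison is purely on
residuals.  BIC uses a Gaussian likelihood with the residual variance
profiled out: `n ln(RSS/n) + k ln n`, with `k = 1` (the profiled variance)
charged to every rule so penalties are comparable; `k` is configurable for
sensitivity analysis.  RSS is floored at 1e−9 to keep exact fits finite.
All rules in one comparison are evaluated on the **intersection** of
participants valid under every rule, so BIC values share the same n.  The
winner minimises BIC; exact ties break toward lower k, then declared order,
and are logged.  MAE is reported alongside as the secondary measure.

## The synthetic-cohort generator

The generator produces the statistical structure the analysis assumes, so
every downstream stage is testable without human data.  The reference
configuration encodes the study conditions the pipeline targets: group sizes
35 AN / 40 p-AN / 117 HC over four sites; an AN prior-belief deficit of
about −13.6 percentage points from an HC mean of 55; learning-rate means
0.47 (HC), 0.45 (p-AN), 0.38 (AN) with SD 0.15; group-equal counting
behaviour; resting heart rates near 69.3 / 71.3 / 73.0 bpm; and
group-shifted depression and stress scores (means 20.3 / 14.0 / 6.9 and
22.9 / 21.2 / 11.1).  Values not pinned by those conditions (prior-belief
and confidence SDs, counting-fraction parameters, noise SDs) are documented
defaults chosen to give realistic dispersion on the 0–100 scales.

Key generative choices:

- **Truncated-normal sampling** for every bounded quantity (beliefs and
  confidences on [0, 100], λ on [0, 1], counting fraction on [0, 1.2],
  questionnaire scores on their ranges).  Truncation, not clipping, avoids
  point masses at the bounds that would distort regressions; configured
  means are therefore honoured only approximately near a bound.
- **Counting-fraction model.** Each participant reports a fraction of the
  true beats (mean 0.55, SD 0.20, group-equal — accuracy does not differ by
  group by construction).  Recorded beats follow the drawn resting heart
  rate and trial duration with ±1-beat jitter.  A per-trial wobble of the
  fraction (SD 0.12) sets the within-participant share of performance
  variance; with the between-participant SD of 0.20 this yields an
  intraclass correlation around 0.7 in the per-trial mixed model, matching
  the strongly trait-like counting styles seen in real HCT data.
- **Confidence budget.** The participant's λ is the primary draw; prior
  confidence and performance confidence are derived by splitting a drawn
  total-precision budget C as π_θ = (1 − λ) C and π_ε = λ C.  This makes
  the precision-weighted learning rate recomputed from generated confidences
  equal the generative λ exactly while keeping both confidences inside
  [0, 100] (C is truncated at 100 / max(λ, 1 − λ)).  The budget mean is set
  to `prior-confidence target / (1 − λ mean)` so configured prior-confidence
  group means are approximately honoured.  The alternative — drawing both
  confidences independently and deriving λ — would leave the λ group means
  uncontrolled, which the parameter-recovery tests require.
- **Generating rule.** Posterior prospective beliefs are produced by the
  update rule applied to the *realised* prior, evidence, and precision
  quantities of a configurable generating rule (default: retrospective
  beliefs as evidence, performance confidence as precision), then half- and
  double-duration ratings add independent noise (SD 5) before downstream
  averaging.  With all noise SDs at zero the generated posterior is exactly
  the rule's prediction, giving exact round-trip tests.
- **Mediation regimes.** Under `mood_mediated`, λ's mean is a linearly
  decreasing function of depression + stress, anchored so the configured HC
  and AN λ means are reproduced at the HC and AN mood means — group
  differences in λ (and hence in performance confidence) are carried
  entirely by mood.  Under `direct_only`, mood scores are group-shifted but
  λ depends only on group.  Under `none`, all quantities follow their
  configured group parameters independently.
- **Sites.** Round-robin assignment with a site-level random intercept
  (SD 3 percentage points) added to prior beliefs and, scaled by 1/100, to
  the counting fraction, so multilevel machinery estimates real (small)
  site variance.
- **Missingness** is off by default; an optional rate blanks per-trial
  confidence ratings for robustness tests.

What the generator does **not** emulate: item-level questionnaires,
physiological waveforms or heart-rate variability, skewed or censored rating
distributions (everything is truncated normal), correlations between
questionnaires beyond the group structure, dropout, and any direct
dependence of counting accuracy on clinical state.  Tests passing on these
cohorts therefore establish that the pipeline recovers the structure it
assumes — not that real data satisfy those assumptions.

## Statistical layer

- HC is always the reference level; tests are two-sided at α = 0.05 with
  95% CIs.
- The per-trial performance model is a linear mixed model with random
  intercepts for participant (nested in site) and site, fit by REML through
  a standard mixed-model routine.  Gradient optimizers can stall when a
  variance component sits on its zero boundary, so a derivative-free Powell
  refit is used as fallback and the solution with the better restricted
  likelihood kept.  Fixed-effect p-values use a t distribution on the
  residual-df approximation (n_obs − n_fixed); with four sites the site
  variance is necessarily imprecise, and a single-level site factor is
  dropped with a warning.  ICC = (τ_participant + τ_site)/(τ_participant +
  τ_site + σ²); marginal and conditional R² are variance partitions.
- The Bayes factor uses the BIC approximation `BF10 = exp((BIC_null −
  BIC_alt)/2)` (unit-information prior), comparing `outcome ~ covariates`
  against `outcome ~ group + covariates`.  Interpretation uses the
  conventional symmetric bands: > 3 evidence for the alternative, < 1/3
  evidence for the null, otherwise inconclusive.
- Holm correction delegates to the standard step-down implementation and is
  validated against a brute-force transcription of the definition.
- Baron–Kenny mediation runs mediator ~ group (step 1), outcome ~ mediators
  (step 2), outcome ~ group + mediators (step 3).  "Attenuation" of the AN
  effect is operationalised as losing significance in step 3 or shrinking
  by ≥ 30% in magnitude versus the group-only model; a mediator is
  mediation-consistent only when its step-1 and step-2 effects are
  significant *and* the group effect attenuates.  Per-group follow-up
  regressions (AN-only, p-AN-only) are Holm-corrected across their mediator
  p-values.  The 30% threshold is a qualitative judgement call — Baron–Kenny
  offers no quantitative criterion — and is exposed as a parameter.

## Numerical conventions

- Degenerate denominators: |evidence − prior| ≤ 1e−9.
- Truncated-normal draws degenerate to the clipped mean when SD = 0.
- One run seed derives per-stage child seeds by hashing the full stage name
  into a seed sequence (all children < 2³¹), so stages are independently
  reproducible and replicate streams never collide.
- Reproducibility contract: identical config + seed give field-for-field
  identical cohorts and byte-identical numeric outputs.

## Problem sizes in the test suite

Simulation-based tests use cohort sizes chosen to make their statistical
targets sharp at desk scale: model recovery uses 50 replicates of n ≈ 200
with prospective noise SD 5; learning-rate recovery uses 200 replicates at
the reference sample sizes (35 AN / 117 HC); mediation detection and
specificity use 100 replicates of n = 600; null calibration uses 1000
replicates (n = 90) for the OLS test and 200 replicates (n = 45) for the
mixed model, with rejection rates judged against binomial 99% bounds around
the nominal 5%.

## Known limitations

- The belief-update model is one-shot; no sequential or hierarchical
  inference is attempted, by design.
- BIC's likelihood and parameter count for fixed prediction rules are a
  convention (profiled Gaussian, k = 1); alternative conventions shift all
  BICs equally and rarely change winners, and k is configurable.
- Mixed-model p-values use the residual-df approximation; with few sites
  this is mildly liberal for site-level contrasts (group contrasts, which
  are participant-level, calibrate at the nominal rate in the suite).
- The mediation verdict is the qualitative Baron–Kenny pattern, not a
  causal-mediation estimand; no bootstrap indirect-effect CIs are computed.
- Generated data are idealised (see the generator section); effect sizes
  recovered from them inherit the generator's assumptions.
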