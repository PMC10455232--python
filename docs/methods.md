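# Methods

This note documents the models, numerical choices and simulator design
behind `cathflow`, in the order data flows through the package.

## Trace model and preprocessing

A catheterisation trace is (tᵢ, vᵢ, pᵢ): seconds since catheter insertion,
cumulative drained volume (mL), and intra-catheter pressure (cmH₂O,
atmospheric-corrected, suction negative), logged at a nominal ~2.5 Hz.
Drained urine is weighed on a precision scale; the package converts mass to
volume at 1 g = 1 mL (urine density taken as 1.000 — the density of urine
varies by ~±2.5% with specific gravity, negligible against the endpoints'
effect sizes).

Scale noise makes the raw cumulative series occasionally decrease by
fractions of a gram. The reader repairs this with a running maximum before
any differentiation, which (a) is idempotent, (b) never lowers a sample,
and (c) makes the derived flowrate non-negative by construction. Traces
claiming ~2.5 Hz are rejected if their median sampling interval falls
outside 0.2–0.8 s; gaps longer than 2 s are flagged as dropouts and never
interpolated, because interpolation across a dropout could fabricate or
erase a flow-stop.

## Flowrate estimation

Flowrate at sample i is the slope of an ordinary-least-squares line fitted
to cumulative volume over timestamps within ±`smooth_halfwidth` (default
0.6 s, i.e. about three samples), clipped below at zero. First differences
were rejected: with ~0.05 g scale noise at 0.4 s spacing their standard
deviation (~0.18 mL/s) is a substantial fraction of the 0.8 mL/s detection
threshold, producing spurious threshold crossings; the windowed slope cuts
this by ~2× while smearing step edges by at most one sample. The
implementation uses windowed prefix sums (O(n)) with globally centred
variables to limit floating-point cancellation.

## Flow-stop detection

The clinical rule: a flow-stop is an interval where flowrate stays below
0.8 mL/s for at least 2 s. The detector adds four deterministic
conventions, all exposed in `DetectorConfig`:

1. **Flow onset.** Non-terminal episodes are sought only at or after the
   first sample with flowrate ≥ threshold; otherwise the dead time between
   insertion and first drainage would count as a leading "stop". A trace
   whose flowrate never reaches threshold is returned as a single terminal
   episode spanning the whole recording.
2. **Merging.** Sub-threshold runs separated by an above-threshold gap
   shorter than `merge_gap` (default 0.4 s, one sample) are merged. This
   replaces the manual-inspection step of the clinical workflow with a
   reproducible rule; episodes whose padded-window peak suction falls below
   −5 cmH₂O are additionally flagged `pressure_supported`, preserving the
   pressure-corroboration idea as metadata rather than a human judgement.
3. **Terminal episode.** The last episode marks the end of catheterisation
   and is discounted from the flow-stop count, so a catheterisation with a
   single episode has zero flow-stops.
4. **Boundaries.** Episode intervals are closed on the left, open on the
   right; an episode's end time is the timestamp where flow resumes.

RV1 = V_Total − V at onset of the *first* episode, terminal or not: this is
what reconciles strictly positive RV1 with zero counted flow-stops. Onset
(not offset) is used because RV1 represents what would remain if the
catheter were withdrawn when flow first stops. Peak suction for an episode
is the most negative pressure within the episode padded by
`pressure_window_pad` (default 1 s), accommodating the slight lag between
flow cessation and the pressure extremum.

A deliberately naive per-sample reference scan (`cathflow.reference`)
implements the same rules with explicit loops and no shared scanning code;
the test suite and the acceptance script require exact episode-set
agreement on ~1000 simulated traces, including under non-default detector
configurations.

## Clinical measurements

Bladder-scan triplets are aggregated by arithmetic mean (mean vs median is
immaterial for three values without gross outliers; mean keeps the summary
linear). Eligibility requires all three pre-catheterisation scans ≥ 150 mL.
The seven dipstick categories dichotomise with haemolysed 25 (1+) and above
(four categories) positive, the two trace categories and negative (three)
negative.

## Synthetic data

### Trace level

`simulate_profile` renders a catheterisation phenomenologically: a ~2.5 s
flow ramp, a plateau flow Q₀ ~ U(2.5, 5.5) mL/s decaying as
(remaining/total)^0.3 with a 1.2 mL/s floor, injected mucosal-suction
events during which flow is zero and pressure falls into a well of
device-specific amplitude, terminal cessation, then a slow (< 0.45 mL/s)
post-terminal dribble and a 4.5 s zero-flow tail. Gaussian noise is added
to cumulative mass (SD 0.05 g, a precision scale) and pressure (SD 0.5
cmH₂O); pressure is clipped to [−device extreme, 0].

Per-device marginals are calibrated so detector-derived endpoints resemble
the published device summaries, and are labelled synthetic calibration, not
estimates: event counts Poisson (MHZC mean 0.17, CEC 1.09); RV1 targets
lognormal (MHZC mean 5.1 mL, log-SD 0.75 — ~90% below 10 mL; CEC mean
39.4 mL, log-SD 1.4 — right-skewed with ~8% above 100 mL); suction
amplitudes lognormal (medians 14 and 95 cmH₂O, log-SD 0.6) truncated at
the observed per-device extremes (−87.7 and −423.2 cmH₂O), so simulated
pressures can never exceed them. Bladder volume is U(150, 500) mL —
respecting the 150 mL eligibility floor — and the true post-void residual
N(6.5, 3) clipped at zero.

Event placement is volume-triggered: the first event fires when drained
volume reaches V_Total − RV1_target, later events spread over the span
before terminal onset. Targets that are geometrically unresolvable (a first
stop within ~2 mL of the terminal dribble, or events too crowded to leave
an above-threshold gap between them) are adjusted minimally, and the
returned ground truth always records what was actually injected — so
recovery checks are exact, not approximate. Events cannot occur during the
ramp or the tail, keeping ground truth unambiguous.

### Trial level

`simulate_trial` draws endpoints directly from the generating models the
analysis assumes: AB/BA sequences block-randomised in fours; for each
endpoint a linear predictor μ + device + visit + bᵢ with bᵢ ~ N(0, σ_b²),
with Gaussian error on the identity scale (continuous), Poisson on the log
scale (counts), or Bernoulli on the logit scale (haematuria). Default
effects and SDs are calibrated so a 42-subject trial reproduces the
published interval widths (e.g. σ_resid = 45.8 mL for RV1 gives a ±19.6 mL
CI on the device difference). Dropout removes visit-2 rows with
probability 1/42. The continuous endpoint is deliberately Gaussian here —
unbiased mean-difference recovery is the property under test — even though
real RV1 is non-negative and skewed; the trace-level generator, which must
render physical volumes, uses the lognormal calibration instead. This is
the main respect in which passing calibration tests does not certify
behaviour on real data: real RV1 residuals are skewed (hence the
signed-rank robustness check), real event rates may be over-dispersed
relative to Poisson (a negative-binomial check is future work), and real
traces contain artefacts (coughs, catheter handling) the simulator does
not emulate.

`simulate_trial_with_traces` renders a trace per catheterisation with
per-subject lognormal frailty shared across endpoints, and records the
trace ground truth as the dataset's endpoint values, keeping dataset and
traces mutually consistent; a two-sample Kolmogorov–Smirnov check (n = 500
per arm) confirms detector output matches the generator's draws in
distribution.

## Mixed models

Continuous endpoints use REML linear mixed models (statsmodels `MixedLM`)
with a random intercept per participant. Inference on the device contrast
uses a t reference with df = N_obs − n_subjects − (p − 1) — the classical
within-subject df for a crossover (40 for a complete 42-subject trial);
Wald-z intervals would be anti-conservative at this size. A
`force_zero_variance` option refits by OLS for degenerate-limit checks.
Boundary fits (between-subject variance at zero) proceed with a note.

Count and binary endpoints use a purpose-built random-intercept GLMM
(`cathflow.glmm`): the marginal likelihood integrates the intercept out by
adaptive Gauss–Hermite quadrature, 15 nodes recentred at each cluster's
posterior mode (found by a vectorised damped Newton iteration) and rescaled
by its Laplace curvature. Poisson with log link was chosen for counts
because the effect is reported as a rate ratio; negative binomial is out of
scope (counts this small at n = 42 give little power to detect
over-dispersion). log σ is bounded in [−10, 3]; at the lower bound the
quadrature collapses to the fixed-effects GLM, which the tests verify to
1e-4 against statsmodels GLM, and the full fit is cross-checked against
lme4's `glmer(nAGQ = 15)` to 2e-3 on the device coefficient. Wald
covariance comes from a numerically differentiated Hessian of the profile
objective. Degenerate data are handled explicitly: an all-zero arm (rate
ratio → 0) switches the device-effect CI to profile likelihood (bracketed
bisection on the deviance, −∞ lower bound reported when the likelihood
never drops); suspected separation in the logit model refits with a weak
(1e-2) ridge on non-intercept coefficients and a warning note.

Effect orientation: differences are CEC − MHZC, ratios MHZC/CEC, matching
the trial's reporting convention (positive difference / ratio < 1 favour
the micro-hole catheter). Missing visit-2 data enter the likelihood as-is;
no imputation. The medical-history covariate (neurogenic vs non-neurogenic)
is optional in every model and used by default only in the haematuria
analysis, where catheterisation trauma plausibly depends on history.

## Gatekeeping and the signed-rank check

The co-primary endpoints are tested in fixed sequence — RV1 first, then
flow-stop count — each at unadjusted α = 0.05, stopping at the first
non-rejection. Because a later hypothesis is tested only after all earlier
ones reject, the family-wise error rate under any null configuration is at
most α; the simulation suite confirms ~5% family-wise rejection under the
global null over 2000 replicates.

The Wilcoxon signed-rank statistic W⁺ drops zero differences and assigns
average ranks to ties. For ≤ 25 non-zero pairs the null distribution is
enumerated exactly by dynamic programming over doubled ranks (doubling
makes tied half-ranks integral; the convolution covers all 2ⁿ sign
assignments without enumerating them). Above 25, a normal approximation
with continuity correction and the standard tie-corrected variance is used;
at n = 15 the two routes agree within 0.02.

## Problem sizes and tolerances

The validation suite uses 1000 traces for oracle equivalence (runtime a few
seconds), 400 for ground-truth recovery, 2000 trial replicates for the null
calibration and 500 for effect recovery — sizes at which the Monte-Carlo
standard errors (±0.010 on the type-I rate; ±0.45 mL on the mean recovered
difference) are small against the tolerances being checked. RV1 recovery is
required within one sample's drained volume at the maximum plateau flow
(5.5/2.5 = 2.2 mL); observed errors are an order of magnitude smaller.
Detector equality checks are exact, not approximate. Seeds are fixed
throughout; identical seeds reproduce every dataset byte-for-byte.

## Known limitations

- The detector conventions (smoothing window, merge gap, onset rule) are
  this package's decisions where the clinical workflow relied on vendor
  software and manual inspection; they are exposed as configuration, and
  the oracle-equivalence guarantee covers any configuration, but derived
  endpoint values can shift slightly under different conventions.
- The simulator is phenomenological: no urethral/abdominal pressure
  dynamics, no catheter-handling artefacts, no within-trace correlation
  between suction amplitude and event duration.
- The GLMM engine supports a single random intercept only — sufficient for
  a two-period crossover, not for multi-level designs.
- Conditional (subject-level) and marginal device means differ for the
  nonlinear models; the report shows conditional means, which is the usual
  mixed-model convention but not identical to raw arm averages.
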