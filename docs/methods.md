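# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what its synthetic validation does and
does not establish about real recordings.

## Conventions

All timestamps are milliseconds, positions degrees of visual angle,
sample intervals half-open 0-based `[onset, offset)`. The native gaze
format is tab-separated text with columns
`t_ms, x_l, y_l, x_r, y_r, pupil_l, pupil_r`; missing pupil (blink) is an
empty field in the file and NaN in memory. Pixel-unit inputs are converted
with `deg = atan(offset_cm / viewing_distance)`, viewing distance
defaulting to the classic 57 cm.

## Screening

Blinks are maximal runs of missing pupil in either eye; semi-blinks are
maximal runs where the absolute first difference of raw pupil area
strictly exceeds 50 units/sample in either eye (the pupil is never fully
occluded, but partial lid closure produces these fast area transients).
Both thresholds are tracker-specific conventions: pupil "units" are
arbitrary, and the literature does not fix whether the 50 units/sample
criterion applies to raw or smoothed pupil area — the raw first difference
is used here. Every artifact is padded by 200 ms on each side to remove
the ramps where the pupil is still partially occluded, clipped at trial
boundaries. "Erroneous (temporary intermittent signal)" data has no
standard numeric criterion; it is operationalized as non-finite or
out-of-range gaze positions (±45° default bounds, configurable) while the
pupil is present.

Any artifact invalidates the sample for *both* eyes: only binocular events
are analysed, and a monocular gap makes the binocular criterion
unevaluable. Masking is idempotent and monotone (adding an interval never
adds valid samples); reason codes have precedence
missing > semiblink > erroneous > padding.

## Detection

The detector is the velocity-threshold scheme of Engbert & Kliegl with the
5-sample moving-average differentiator
`v_n = (x_{n+2} + x_{n+1} − x_{n−1} − x_{n−2}) · rate / 6` (exact for
linear motion). Velocities are computed within valid segments only; a
velocity sample is usable only if its whole stencil is valid, so estimates
never cross masked gaps. The threshold per eye and component is
`η = λ·σ` with `σ² = median(v²) − (median v)²` and λ = 6. σ is estimated
per trial over all usable samples rather than per segment — with many
short segments the per-segment estimator is unstable — and floored at
10⁻⁶ deg/s with a degeneracy warning; trials with fewer than 50 usable
velocity samples are flagged and skipped.

A monocular candidate is a maximal run with
`(v_x/η_x)² + (v_y/η_y)² > 1`. Runs separated by a subthreshold gap
shorter than 20 ms are merged *before* the 6 ms minimum-duration test,
treating the second run as an overshoot correction rather than a new
saccade. Binocular events need at least one sample of left/right overlap;
when several pairings are possible the largest overlap wins, ties resolved
by earlier onset, and each monocular event joins at most one binocular
event. The binocular interval is the union of the paired intervals, but
amplitude (onset-to-offset Euclidean displacement, not maximal deviation)
and peak velocity are measured per eye over that eye's own interval before
averaging. Microsaccade classification requires amplitude strictly below
2° in both eyes; note that onset-to-offset displacement over the
suprathreshold run systematically underestimates the full movement
amplitude (the subthreshold tails are excluded), which is conservative
with respect to the 2° bound.

`msaccade.reference` restates the whole chain as plain per-sample loops
sharing no code with the vectorized path; the two must produce identical
event lists, which the test suite and the acceptance script verify on
randomized segments.

## Synthetic gaze model

The generator produces what the analysis assumes: a fixating observer
recorded binocularly at 1000 Hz for 60 s trials.

* **Drift** — an Ornstein–Uhlenbeck position process (random walk with
  mean reversion), shared by both eyes. Defaults: diffusion
  0.002 deg²/s, pullback 2 s⁻¹. The diffusion sits at the lower end of
  literature estimates for fixational drift; within the OU parameterization
  larger values produce unrealistically fast sample-to-sample drift
  velocities at 1000 Hz. The OU choice is the simplest stationary model
  that keeps gaze near fixation over a minute.
* **Tremor / instrument noise** — AR(1)-correlated Gaussian noise per eye
  and axis, normalized to 0.01° RMS, correlation 0.95 (≈ 20 ms time
  constant). Video tracker output is heavily low-pass filtered, so its
  noise is temporally correlated; white noise of the same RMS would more
  than double the differentiated-velocity noise floor and is available by
  setting `tremor_ar = 0`.
* **Microsaccades** — amplitudes lognormal (median 0.5°, log-SD 0.45),
  resampled to stay strictly below the 2° cap so every injected event is a
  microsaccade by construction; peak velocity from the main sequence
  `V = 90 · A^0.9` deg/s; a raised-cosine velocity profile (smooth, zero
  endpoints) whose duration `D = 2A/V` (≈ 19–23 ms for the defaults,
  clipped to 6–25 ms) makes the discrete displacement integrate exactly to
  the drawn amplitude. Events are conjugate in the two eyes up to ±1
  sample of per-eye onset jitter, which exercises the one-sample binocular
  overlap rule. Directions are uniform on the circle by default (no
  directional structure is analysed); an optional center-corrective mode
  biases directions back toward fixation.
* **Event times** — candidate onsets follow a renewal process with
  exponential gaps and a dead time (event duration + 50 ms refractory)
  after each event, with the gap rate compensated so the realized long-run
  rate equals the configured `ms_rate` exactly. The dead time keeps ground
  truth disjoint and farther apart than the 20 ms merging window, so
  detector merging never fuses distinct true events. The raw
  (un-thinned) Poisson sampler is exposed as `draw_poisson_onsets` and
  carries the exponential inter-onset property verified by the tests.
  Events never start inside a window extending one padding length plus one
  maximal event duration before an artifact and one padding length after
  it, so all ground truth survives screening; this thinning costs well
  under 1% of the nominal rate at default artifact loads.
* **Artifacts** — blinks at 10/min (uniform 100–300 ms, pupil and
  position missing) and semi-blinks at 3/min (triangular pupil-area dips
  at 80 units/sample, above the 50 units/sample screening threshold),
  mutually separated by ≥ 100 ms. Pupil baseline 1000 units with small
  Gaussian jitter.
* **Experiments** — the default 3 × 3 design injects per-cell rates built
  additively from the marginal means 0.53/0.92/1.09 events/s (visual
  load) and 0.96/0.80/0.79 events/s (mental load). The two sets of
  marginals imply slightly different grand means (0.8467 vs 0.85), so both
  are rescaled to their common average before the additive reconstruction
  `M[i,j] = v_i + c_j − grand`; the reconstructed matrix reproduces the
  rescaled marginals exactly and is strictly positive. Each of the 18
  subjects gets one lognormal rate multiplier (mean 1, log-SD 0.17,
  matching the reported between-subject coefficient of variation of
  0.15–0.19); 3 blocks per cell. Per-trial seeds derive from the master
  seed via `SeedSequence(seed, spawn_key=...)` — a splittable scheme that
  never consults the wall clock, so identical seeds give bit-identical
  datasets and adding subjects does not perturb existing streams.

A waveform-free counterpart, `simulate_rate_experiment`, draws per-trial
microsaccade *counts* directly from the same generative rate model
(Poisson given the subject multiplier and cell rate). Calibration studies
that need thousands of replicate experiments — the type-I error of the
GG-corrected test, the stability of the marginal ordering — run at this
level; the full waveform pipeline is exercised end to end at the study's
actual size (18 × 9 × 3 one-minute trials) once per validation run.

### What the simulation does not emulate

No smooth pursuit, vergence, torsion or head movement; no image-dependent
gaze behavior or task-locked rate dynamics (rates are stationary within a
trial); instrument noise is Gaussian and stationary, without the
pupil-size-dependent wander of real trackers; drift has no self-avoiding
or corrective structure beyond mean reversion. Passing the validation
suite therefore shows that the pipeline recovers what it assumes —
correct screening, detection, rate arithmetic and test calibration — not
that the detector is robust to every pathology of real recordings.

## Rates and statistics

The dependent variable is microsaccades per second of *valid* recording
time (detection is impossible on masked samples; the nominal trial
duration is available as a sensitivity option). Blocks are averaged within
subject and cell first; condition means and SDs are computed across
subjects. Subjects missing any cell are excluded listwise with a logged
notice.

The repeated-measures ANOVA decomposes the subject × 3 × 3 cell means
into both main effects and the interaction, each tested against its own
effect-by-subject error term. Greenhouse–Geisser ε is computed per effect
as `(Σλ)² / (d·Σλ²)` over the eigenvalues of that effect's
orthonormal-contrast covariance (d = 2, 2, 4), clipped to its analytic
range `[1/d, 1]`; corrected p-values use ε-scaled numerator and
denominator degrees of freedom. Mauchly's W uses the same contrast
covariance with the standard chi-square approximation; a singular
covariance yields the explicit "sphericity maximally violated" result
(W = 0, p = 0) rather than an error. Huynh–Feldt ε and multivariate
(Wilks/Pillai) statistics are deliberately out of scope: the analysis of
record reports GG-corrected univariate F tests, so the univariate
decomposition is the primary implementation even where a "MANOVA" label
appears in the literature. The implementation reproduces `car::Anova`
(type-3, GG) to machine precision on fixture data, including the
interaction ε, and pingouin for main effects.

Pairwise comparisons are paired t-tests with `p_bonf = min(1, m·p)` over
all `m = k(k−1)/2` level pairs; a zero-variance zero-mean difference
yields t = 0, p = 1 by convention. The linear trend over ordered
visual-load levels uses the contrast (−1, 0, 1) per subject;
`F = t²` of the one-sample t of the contrast scores, df (1, n−1).

Note that with n = 18 complete subjects the uncorrected error df for a
3-level main effect is 34 (and 17 for the trend contrast); published
analyses of comparable designs sometimes print other denominators (e.g.
21 or 23.68), which cannot arise from 18 complete cases. This package
always reports the df implied by its own formulas.

## Numerical choices and degenerate inputs

Strict inequalities at both decision boundaries (50 units/sample,
2° amplitude); exactly-at-threshold values are kept/not flagged. Flat
ANOVA input (zero effect and zero error SS) returns F = 0, p = 1;
positive effect with zero error returns F = ∞, p = 0. Velocity-SD floor
10⁻⁶ deg/s; ε clipped to `[1/d, 1]`; Bonferroni p clipped at 1. Trials
whose valid duration is zero, or whose threshold cannot be estimated, are
excluded with a logged reason rather than failing the run.

## Validation problem sizes

The validation suite uses 100 two-second segments for detector/reference
equivalence, 15 sixty-second trials (~900 events) for recall/precision,
one full-size waveform experiment (486 one-minute trials) for rate
recovery and the statistical battery, 2000 count-level replicates for the
null calibration, and 200 for ordering stability — sizes chosen so each
estimate's Monte-Carlo error is small against the margin it is checked
with (e.g. the null rejection rate has SE ≈ 0.5% against a ±1.5% band).

## Known limitations

The "modified" aspects of published detector variants beyond the stated
parameters are not documented in the literature this follows; only the
stated parameters (λ, durations, ISI, overlap, amplitude bound) are
implemented. Drift and blink statistics of real observers under these
task loads are not publicly characterized; the generator's defaults are
literature-plausible conventions, not fits. The per-trial σ estimate
(rather than per-segment) is a stability choice and switchable in
principle; with the default artifact load the difference is negligible.
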