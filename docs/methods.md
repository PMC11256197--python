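# Methods

`flashtox` quantifies the normal-tissue-sparing effect of ultra-high
dose-rate (FLASH) proton irradiation relative to conventional dose rates
(CONV), for a murine hindleg model irradiated inside a spread-out Bragg
peak (SOBP) delivered by pencil-beam scanning (PBS). It has two halves: a
physical one (reconstructing dose-rate metrics from timed spot deliveries)
and a statistical one (grade-wise logistic dose-response, TD50s, and
dose-modifying factors from graded toxicity scores). A synthetic-cohort
generator supplies data with the exact statistical structure the analysis
assumes, so the whole pipeline is testable without the animal study.

## Delivery model

A field is a `rows x cols` grid of spots with spacing `spacing` (default
5 x 7 at 6 mm, extents 24 x 36 mm), centered on the origin of the
treatment plane. Spots on the grid perimeter carry `rim_factor` (default
1.4) times the interior weight, the usual trick for flattening the lateral
profile of a small field. Spot ordering within a painting is a serpentine
row-major scan (configurable to plain raster); per-spot beam-on time is
proportional to spot weight, i.e. constant beam current within a field.

Two schedulers share this plan:

* **FLASH** — one contiguous pass; total duration = dose / field dose
  rate. Default field dose rate 60 Gy/s.
* **CONV** — `n_repaints` passes with each spot's weight split evenly
  across passes and a fixed pause (default 4.4 ms) after every spot
  delivery except the last. Beam-on durations are scaled so the field dose
  rate (dose / total duration, pauses included) hits the requested value
  (default 0.35 Gy/s). If the pause time alone exceeds the required
  duration the schedule is infeasible and the scheduler raises. The
  repaint count, when not given, is linear in dose between 144 repaints at
  19.9 Gy and 360 at 49.7 Gy — the observed operating regime; outside it
  the count is clipped.

Pauses are modelled at their mean rather than as a distribution (only the
mean is known), and there is no intra-field beam-current modulation. Both
choices only affect the fine time structure, which the DR_PBS95% metric
integrates over.

## Dose accumulation and DR_PBS95%

Each spot deposits dose laterally as an isotropic 2D Gaussian with scale
`sigma` (default 8 mm, the spot spread at SOBP depth), normalized to 1 at
its center. A single scalar calibration maps unit dose-weight to Gy at a
spot center; `calibration_for_dose` chooses it so a reference point (the
field center by default) receives the prescribed dose, mirroring an
absolute ionization-chamber calibration. No depth dimension, LET, or
sub-spot pulse structure is modelled; the quoted "8 mm" spread is treated
as a Gaussian sigma (it could be read as a FWHM; the parameter is
explicit, so either convention can be supplied).

Cumulative dose at a point is piecewise linear: rising during each spot
event, flat during pauses. The local PBS dose rate is

    DR_PBS95% = 0.95 * D / (t_97.5 - t_2.5)

where D is the point's total dose and t_q the first time the cumulative
dose reaches q% of D (first crossing on flat segments; exact linear
interpolation inside events). Useful analytic facts, all asserted in the
test suite:

* a single constant-rate delivery gives exactly the field dose rate;
* `DR_PBS95% >= 0.95 * D / T` for any schedule of total duration T;
* with heavy repainting the metric converges to the point's mean dose rate
  `D/T` — equal to the field dose rate wherever the point dose matches the
  prescribed dose;
* for a single-paint field it exceeds the field dose rate, because most of
  a point's dose arrives while nearby spots are painted.

The field summary takes the mean and range of DR_PBS95% over the
high-dose region, the lattice points receiving at least 95% of a reference
dose. The reference is the prescribed dose by default (an argument, since
"95% or higher" could also be read against the maximum delivered dose).
The default evaluation lattice has 1 mm pitch over the field extents plus
a 2-sigma margin. With the synthetic contiguous schedules the single-paint
high-region mean lands near 67 Gy/s for a 60 Gy/s field — the directional
relationship is reproducible, but the exact published field statistics
depend on the real machine-log time structure, which is not modelled.

## Toxicity analysis

Scores are longitudinal grades per mouse: acute skin toxicity graded 1.5
to 3.5 in 0.5 steps (daily, days 8–28) and fibrosis graded 2 to 4 via a
leg-extension assay (biweekly, weeks 9–30). The endpoint is the maximal
grade per mouse; for each grade of interest each mouse becomes a binomial
observation (did it ever reach the grade), aggregated per (arm, dose).
Responder sets are nested across grades by construction, so fitted TD50s
rise with grade severity on well-behaved data.

The dose-response model is the two-parameter logistic

    P(d) = 1 / (1 + exp(-(d - TD50) / b))

fitted by binomial maximum likelihood as a logit GLM in (β0, β1), with
TD50 = -β0/β1 and b = 1/β1. The (TD50, b) covariance comes from the delta
method on the GLM covariance. TD50 95% CIs use the delta method by
default, with a profile-likelihood alternative (`ci="profile"`); both are
provided because the asymmetric intervals typical of such data suggest
non-Wald constructions, and the choice is recorded on the fit. Complete
separation (all-or-none groups split cleanly by dose) is detected from the
data pattern and reported as a non-converged, infinitely steep fit rather
than an exception; no penalized fallback is applied by default.

The dose-modifying factor is DMF = TD50_FLASH / TD50_CONV per grade; > 1
means FLASH spares tissue. Its default 95% CI is the delta method on the
log ratio with independent arms; a seeded parametric bootstrap (resampling
binomial responders at the fitted probabilities) is available. Grade-wise
DMFs are summarized by their arithmetic mean and (min, max) range — the
range is the spread across grades, not a sampling interval. Cross-study
comparisons take per-grade TD50 ratios between two studies and summarize
the same way.

## Synthetic cohorts

The generator inverts the analysis model. Per mouse and assay a latent
tolerance z = dose + ε, ε ~ Logistic(0, b), is drawn once; the maximal
grade is the highest grade g with z ≥ TD50_g. This makes P(max ≥ g)
exactly logistic in dose at every grade and guarantees nesting — the
reason for a shared latent rather than independent per-grade draws. Acute
and fibrosis latents are independent (no joint information is available to
calibrate a correlation; it is configurable).

Defaults are the reference study conditions: the per-arm dose-group design
(73 FLASH / 67 CONV analyzed mice for the skin assay), the grade-wise
acute and fibrosis TD50 tables, b = 3 Gy (the slope is never published;
3 Gy reproduces dose-response curves spanning 0→100% across each arm's
dose range, as observed), acute onset ~ Normal(12, 1) days truncated to
[9, 14], peak reached within days 14–17, dose-dependent plateau length
(~dose/10 days), and alanine readings Normal(97.4%, 2.4%) of plan (the
pooled published arm means). Trajectory shapes beyond these anchors are
qualitative stand-ins — they exist to exercise the max-grade reduction,
whose contract (trajectory max = assigned max, exactly) is what the
pipeline consumes; they carry no biology. Gross alanine errors are
injected as uniform [0.5, 0.84] relative doses at a configurable rate;
necrosis exclusions, when enabled, are Bernoulli with probability logistic
in dose. Identical (config, seed) pairs give bit-identical cohorts.

What passing tests show, and don't: parameter recovery on these cohorts
demonstrates that the estimator is consistent and calibrated *under the
assumed model* (logistic tolerances, no scoring noise, no litter or cage
effects, planned dose = delivered dose). Real data could violate any of
those; the generator makes the assumptions explicit rather than hiding
them.

## QA and exclusions

Alanine readings are corrected by the beam-quality factor kQ = 1.032
(Co-60-referenced readout in a proton SOBP; the ±0.021 uncertainty is
carried as metadata only and not propagated into the fits). A mouse is
excluded when |corrected relative dose − 1| > 0.15, strict at the
boundary, using the corrected value. Externally flagged exclusions
(technical, weight loss, off-target, necrosis) apply at two stages:
pre-acute and pre-fibrosis, the latter a strict subset operation so the
fibrosis analysis set is always contained in the acute one. One primary
rule per mouse per stage, fixed precedence. A missing alanine record warns
but retains the mouse — the QA is a gross-error catch, not a gate.

## Numerical choices and problem sizes

* Threshold crossings on flat cumulative-dose segments take the first
  crossing (deterministic, conservative).
* GLM fits run IRLS to statsmodels defaults (deviance tolerance 1e-8);
  the brute-force likelihood-grid oracle in the tests refines an 81×81
  grid five times, giving ~1e-4 resolution, independent of the GLM path.
* Recovery studies use 200 replicates of the full 140-mouse design; the
  acceptance script derives per-replicate seeds below 2^31 from its
  `--seed`. Simulation-based checks (CLT, coverage) use 3-sigma bands.
* Degenerate inputs: 1×1 grids are all-perimeter; a zero-dose point has
  undefined DR_PBS95% (error); single-dose-level responder tables raise;
  an all-zero or all-responder arm yields a flagged non-estimable fit that
  does not abort other grades.

## Known limitations

* No SOBP/depth physics: the treatment plane is 2D and the spot sigma is
  an input, so absolute published dose-rate field statistics that depend
  on real machine logs are reproduced directionally, not numerically.
* The logistic slope b of the reference experiment is unknown; recovery
  results are conditional on the b = 3 Gy default.
* DMF CIs from reference TD50 tables are point estimates only — published
  tables carry no covariances.
* Time-to-event structure (onset, duration of damage) is generated but not
  modelled statistically; only the max-grade binomial endpoint is analyzed.
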