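# Methods

This note documents the models, parameter choices and numerical decisions
behind `ripvent`, and what the synthetic-night tests do and do not show
about real recordings.

## Signal model and processing rates

All signals live on a uniform internal clock, 25 Hz by default
(`RunConfig.resample_hz`). The respiratory band tops out near 2 Hz, so
25 Hz leaves an order-of-magnitude margin while keeping 8-hour nights cheap
to process; inputs at other rates are polyphase-resampled on ingestion.
Times are seconds from recording start; all intervals are half-open
`[onset, end)`. NaN runs up to 1 s are linearly interpolated; longer runs
are zero-filled, logged, and carried as `bad_spans` on the signal.

## Breath detection

RIP breaths are trough-to-trough cycles of whichever belt has the larger
excursion over a 30 s rolling window, so segmentation survives paradoxical
epochs where the calibrated sum is near zero (detection must precede
calibration). Belts are low-passed (4th-order zero-phase Butterworth,
1.5 Hz) and detrended with a 60 s rolling median before trough finding so
that body-movement baseline steps do not distort cycle boundaries. Each
candidate cycle must be accompanied by a concurrent cycle — of either
phase — on the other belt whose period is within ±40% of the cycle's own
span (or of the median breath period, for cycles truncated at the recording
edges); this encodes "concurrent movement in both belts" without requiring
a calibrated sum. Cycles shorter than half the median period at the
recording edges are merged into their neighbour, which keeps the count on
periodic input at frequency × duration for any phase. Duration bounds
(1.5–15 s), an amplitude floor (5% of the rolling median excursion, below
which a cycle becomes an apneic gap) and an amplitude ceiling (5× the
rolling median, rejecting movement artifact) are configurable.

Flow breaths use the classical recipe: 1-minute rolling-median baseline
removal (hence invariance to any constant offset), cumulative integration
to volume, trough finding on the volume trace.

Gaps longer than 1.5 pre-gap breath periods (central apneas) are filled
with evenly spaced breaths at the median rate of the five preceding
breaths; imputed breaths measure their (near-zero) tidal volume from the
signal excursion in their span.

## Powerloss calibration

The objective `RMS((1−k)·dTH + k·dAB) / (RMS((1−k)·dTH) + RMS(k·dAB))` is
evaluated exactly on a 0.001-step k grid via the second-moment
decomposition and refined by bounded scalar minimization. It is bounded in
[0, 1] by the triangle inequality and scale-invariant. Two limits make it
identifiable: natural breath-to-breath variability of the thoracoabdominal
split (the QDC limit) and paradoxical obstruction (the isovolume limit);
both pull the argmin to the same mixing weight when the belts are linear
sensors of their compartments. When the objective's range over the grid is
below 0.01 the period is non-identifiable (no paradox and little split
variability) and inherits the nearest previous identifiable `k` (0.5 at
recording start).

Calibration periods are the spans between detected body movements. Two
robustness details matter in practice. First, a baseline step low-passes
into a derivative transient ~20× the breathing power, so the fit excludes
an 8 s guard at each period edge; without it the transient acts as a large
common-mode mass that flattens the objective. Second, after a movement the
20-breath reference pattern straddles the step for ~20 breaths and
re-triggers spuriously; movement flags are therefore suppressed until the
reference is movement-free again, on top of the 5 s merge window. At
period boundaries `k` crossfades linearly over 2 s to avoid derivative
spikes in the calibrated flow.

## OCF and power law

The per-breath thorax–abdomen Pearson correlation `r` is computed on the
band-limited, baseline-removed belts over the breath span; undefined `r`
(a flat belt, e.g. imputed breaths) is treated as 1 (no suppression). The
sigmoid gain uses the squared-logistic form
`(1 − y_min)·L² + y_min` by default, with the plain logistic selectable
via `ocf.exponent_form = 1`; defaults `x0 = 0.034`, `k = 31.0`,
`y_min = 0.22`. The gain is applied as a piecewise-constant per-breath
multiplier on the flow samples (gap samples take the nearest breath's
gain), since `r` is a per-breath quantity. `fit_ocf_params` recovers the
sigmoid from paired data by pooling breaths into r-deciles and
least-squares fitting the family to the decile medians of the
reference/RIP ventilation ratio.

The power law `v → 100·(v/100)^1.17` is applied to eupnea-normalized
per-breath ventilation rather than raw flow: normalization makes the
operation scale-free (RIP units are arbitrary) and pins the fixed point at
100%.

## Ventilation, events, traits

Raw per-breath ventilation is the excursion of the integrated flow over
the breath, divided by duration. The excursion removes the line through
the breath's endpoints first: a trough-to-trough breath starts and ends at
the same volume, so any endpoint ramp is residual drift, and subtracting
it prevents integration drift — or detrending transients near event
edges — from inflating small breaths. The eupneic baseline is the
duration-weighted mean raw ventilation over a centered 420 s window
(truncated at the edges, event breaths included — the baseline is a local
average, not an event-free one). Consequently %eupnea values inside events
sit a few percent above the naive `100·(1 − severity)` whenever several
deep events fall in one window; this is a property of the definition, not
an error, and the tests account for it.

Events are maximal runs of breaths strictly below 70 %eupnea spanning
strictly more than 10 s; a single recovered breath splits a run. The nadir
is the single lowest breath (configurable to the lowest mean of two
consecutive breaths). Average event depth ensembles the per-event traces
on a duration-normalized [0, 1] grid (50 points, ends anchored) and takes
100 minus the minimum of the pointwise mean; ventilatory burden is the
exact product depth × mean duration (min) × rate (events per analyzed
hour — the simulator has no sleep staging, so the denominator is recording
time rather than sleep time).

## Concordance statistics

Breaths are paired greedily by midpoint proximity within 2 s. Strata use
the reference value: small < 70, large > 130, medium the closed interval
between. Relative errors exclude pairs with reference below 5 %eupnea;
absolute summaries keep them. ICC(2,1) is computed from the two-way ANOVA
mean squares; the bootstrap for paired ICC differences resamples targets
with replacement, evaluating both methods on the same resample, and is
bit-reproducible under a fixed seed. Bland–Altman limits are
bias ± 1.96·sample SD, with both x-axis conventions (reference value, and
mean of methods) emitted. Event-level agreement scores events on the
reference series and evaluates the test series' depth over the same
intervals.

## The synthetic night

The generator is a two-compartment belt model. True volume `V(t)` is built
breath-by-breath from raised-cosine cycles (lognormal period jitter
σ = 0.08 around 15 breaths/min, lognormal amplitude jitter σ = 0.07). The
compartments split it as `V_th = (1−ρ_b)·V + p`, `V_ab = ρ_b·V − p`, where
`ρ_b` is the per-breath thoracoabdominal split (SD 0.10 around 0.5 —
breath-to-breath redistribution is what makes natural breathing
informative for calibration) and `p` is isovolume paradoxical motion. The
belts read the compartments with gains `1/(2(1−k*))` and `1/(2k*)`, so the
k*-weighted sum equals `V/2` for every breath regardless of the split and
the paradox cancels exactly at `k*`.

Obstructive events scale `V` by `1 − severity` and add effort `p` whose
amplitude grows superlinearly with severity (onset 0.6, quadratic, 2×
eupneic tidal amplitude at total occlusion): mild obstruction leaves the
belts largely synchronized while complete occlusion drives full
counter-motion, which reproduces the empirical pattern that overestimation
is concentrated at strongly negative `r`. The non-cancelling residual —
the error source the OCF exists to fix — is a quarter-cycle (sine-phase)
component fed equally to both compartments, scaled so that perfectly
calibrated RIP reads `paradox_residual` × eupnea during total obstruction;
because it is orthogonal to the effort waveform, no mixing weight can
remove it. Central apneas silence both compartments; hypopneas are
in-phase amplitude reductions; movements add persistent alternating-sign
baseline steps sized in multiples of each belt's own tidal excursion;
white noise (SD 2% of eupneic tidal amplitude) is added to belts and to
the reference flow `dV/dt`. Everything is deterministic under one seed.

The standard test night lasts 2 h with ten movements at 600 s spacing and
31 events (20 obstructive apneas with severity 0.7–1.0 and residual
0.2–0.4, 6 hypopneas at severity 0.55–0.65, 5 central apneas), placed so
every calibration period contains at least one obstructive event. Problem
sizes throughout the tests (a 2 h night at 25 Hz, 10⁴ bootstrap
iterations, 10³ random series for the autoscorer oracle) keep the full
suite under a minute while leaving every statistic well away from its
decision thresholds.

What the simulator does not emulate: cardiogenic oscillations, sensor
nonlinearity and slow drift, REM/NREM structure, position changes that
alter `k*` gradually rather than stepwise, flow limitation shapes, and the
heavy-tailed artifact menagerie of real polysomnography. Passing tests
therefore demonstrate correctness of the algorithms under the stated
signal model — recovery of known mixing weights, exact event logic,
correct statistics — not clinical performance on patients.

## Known limitations

* The OCF constants are taken as given; on data whose residual-vs-r
  relation differs from the regime those constants encode, the correction
  can over- or under-suppress partial obstructions (visible here as a
  small negative small-breath bias after correction).
* Calibration assumes belts are linear in compartment volume within a
  period; gain drift inside a period biases `k`.
* Event rate uses analyzed recording time, not sleep time, so it is not an
  AHI in the clinical sense.
* The EDF writer covers the minimal single-rate, 16-bit case the simulator
  needs; it is not a general EDF+ exporter.
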