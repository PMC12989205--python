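# ripvent

Breath-level ventilation and obstructive-sleep-apnea (OSA) severity metrics
from respiratory-inductance-plethysmography (RIP) belts.

Standard polysomnography scores apnea and hypopnea from nasal-pressure
airflow, which oral breathing can silently corrupt. The RIP belts around the
thorax and abdomen are already part of every sleep study and track the two
compartments' volume excursions — but raw belts badly overestimate airflow
during obstruction, when the two compartments move out of phase
(paradoxical breathing) and their motions no longer sum to a volume change.
`ripvent` implements a three-step "RIP correction" that turns the two belt
signals into a quantitative %eupnea minute-ventilation series, autoscores
respiratory events from it, and derives the advanced severity traits
*average event depth* and *ventilatory burden*, together with the
agreement-statistics battery used to validate such a method against a
pneumotachograph reference and a fully scripted synthetic-night simulator
for testing without patient data.

## The correction

1. **Powerloss calibration.** A mixing weight `k ∈ [0, 1]` scales the belts
   so that `(1−k)·RIP_th + k·RIP_ab` is proportional to tidal volume. `k`
   minimizes

   `RMS((1−k)·dRIP_th + k·dRIP_ab) / (RMS((1−k)·dRIP_th) + RMS(k·dRIP_ab))`,

   the residual power of the weighted derivative sum: paradoxical motion
   cancels exactly at the right `k`. The night is split into constant-`k`
   calibration periods at detected body movements (belt-baseline jumps
   exceeding 15× the running median tidal volume against a 20-breath
   reference pattern).

2. **Overestimation correction factor (OCF).** Even optimally mixed belts
   leave a non-cancelling residual during obstruction. Each breath's
   thorax–abdomen Pearson correlation `r` gauges paradox; the flow of that
   breath is scaled by the sigmoid gain

   `OCF(r) = (1 − y_min)·L² + y_min`, `L = 1 / (1 + e^{−k·((r+1)/2 − x0)})`

   with defaults `x0 = 0.034`, `k = 31.0`, `y_min = 0.22` (≈1 for
   synchronous breaths, ≈0.27 at complete paradox).

3. **Power-law linearization.** Eupnea-normalized ventilation `v` (in %)
   maps to `100·(v/100)^1.17`, deepening small breaths and boosting large
   ones while fixing 100% exactly.

Minute ventilation is tidal volume over breath duration, normalized to the
duration-weighted mean over a centered 7-minute window (100 %eupnea = local
normal breathing). Events are maximal runs of breaths below 70 %eupnea
lasting over 10 s; event depth is 100 minus the nadir; *average event
depth* comes from the ensemble-synchronized mean event trace, and
*ventilatory burden* = average event depth × mean event duration ×
event rate (%eupnea·min/hr). A fixed 2:1 abdomen:thorax mixing with no OCF
or power law serves as the benchmark the correction is judged against.

## Worked example

```python
import numpy as np
import ripvent as rv
from ripvent.config import RunConfig

cfg = rv.default_test_night(seed=7)          # scripted 2 h night, k* = 0.62
belts, flow, truth = rv.simulate_recording(cfg)

corrected = rv.process_belts(belts, RunConfig(method="corrected", seed=7))
benchmark = rv.process_belts(belts, RunConfig(method="benchmark_2to1", seed=7))
reference = rv.process_flow(flow, RunConfig(seed=7))

print(f"calibration periods: {len(corrected.periods)}, "
      f"mean k = {np.mean([p.k for p in corrected.periods]):.3f} (true 0.62)")
rep_c = rv.compare_series(corrected.vent, reference.vent, reference.events)
rep_b = rv.compare_series(benchmark.vent, reference.vent, reference.events)
print(f"small-breath median bias: benchmark "
      f"{rep_b.breath_errors['small']['median_bias']:+.1f}, corrected "
      f"{rep_c.breath_errors['small']['median_bias']:+.1f} %eupnea")
print(f"event-depth ICC: benchmark {rep_b.event_icc:.2f}, "
      f"corrected {rep_c.event_icc:.2f}")
print(f"ventilatory burden: reference {reference.traits.ventilatory_burden:.0f}, "
      f"corrected {corrected.traits.ventilatory_burden:.0f} %eupnea.min/hr")
```

prints

```
calibration periods: 11, mean k = 0.621 (true 0.62)
small-breath median bias: benchmark +9.0, corrected -3.6 %eupnea
event-depth ICC: benchmark 0.23, corrected 0.69
ventilatory burden: reference 400, corrected 389 %eupnea.min/hr
```

The adaptive calibration recovers the scripted mixing weight in every
period; the correction removes most of the benchmark's overestimation of
small (obstructed) breaths, roughly triples the event-depth ICC, and brings
the ventilatory burden to within a few percent of the flow-derived
reference.

The same pipeline is available from the shell:

```sh
ripvent simulate --out night.edf --seed 7
ripvent process night.edf --out-dir run/ --method corrected
ripvent concordance run/ run/ --out report.json
```

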