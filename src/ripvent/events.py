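"""Respiratory-event autoscoring and patient-level severity traits.

An event is a maximal run of consecutive breaths whose ventilation is
strictly below 70 %eupnea, spanning strictly more than 10 seconds — the
ventilation analogue of the clinical >=30 %-reduction hypopnea rule, applied
without desaturation or arousal criteria.  Event depth is 100 minus the
nadir %eupnea.  The patient-level traits are the average event depth
(100 minus the minimum of the ensemble-synchronized mean event trace), the
mean event duration, the event rate per analyzed hour, and the ventilatory
burden — the exact product of the three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import EventConfig
from .ventilation import VentilationSeries


@dataclass
class RespiratoryEvent:
    start_s: float
    end_s: float
    nadir_ventilation: float
    breath_idx: tuple[int, int]     # [first, last] index into the series

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def depth(self) -> float:
        return float(np.clip(100.0 - self.nadir_ventilation, 0.0, 100.0))


@dataclass
class TraitSummary:
    average_event_depth: float       # %eupnea
    mean_event_duration_min: float
    event_rate_per_hr: float
    n_events: int

    @property
    def ventilatory_burden(self) -> float:
        return ventilatory_burden(self.average_event_depth,
                                  self.mean_event_duration_min,
                                  self.event_rate_per_hr)


def autoscore_events(vent: VentilationSeries,
                     cfg: EventConfig | None = None) -> list[RespiratoryEvent]:
    """Score maximal sub-threshold breath runs as respiratory events.

    A run ends at any breath at or above the threshold (a single recovered
    breath therefore separates two distinct events) and becomes an event only
    if the span from the first breath's onset to the last breath's end
    exceeds ``min_duration_s`` strictly.
    """
    cfg = cfg or EventConfig()
    events: list[RespiratoryEvent] = []
    pct = vent.percent_eupnea
    breaths = vent.breaths
    i, n = 0, len(breaths)
    while i < n:
        if pct[i] < cfg.threshold_pct:
            j = i
            while j + 1 < n and pct[j + 1] < cfg.threshold_pct:
                j += 1
            start = breaths[i].onset_s
            end = breaths[j].end_s
            if end - start > cfg.min_duration_s:
                nadir = event_nadir(pct[i:j + 1], cfg)
                events.append(RespiratoryEvent(start, end, nadir, (i, j)))
            i = j + 1
        else:
            i += 1
    return events


def event_nadir(pct_run: np.ndarray, cfg: EventConfig | None = None) -> float:
    """Nadir ventilation of an event: the single lowest breath by default,
    or the lowest mean of ``nadir_breaths`` consecutive breaths."""
    cfg = cfg or EventConfig()
    pct_run = np.asarray(pct_run, float)
    m = cfg.nadir_breaths
    if m <= 1 or pct_run.size < m:
        return float(np.min(pct_run))
    means = np.convolve(pct_run, np.ones(m) / m, mode="valid")
    return float(np.min(means))


def event_depth(event: RespiratoryEvent) -> float:
    return event.depth


def average_event_depth(events: list[RespiratoryEvent],
                        vent: VentilationSeries,
                        grid_n: int = 50) -> float:
    """Depth of the ensemble-synchronized mean event trace.

    Each event's breath-level %eupnea trace is mapped onto normalized event
    time (0 = start, 1 = end; breath midpoints interior, endpoints anchored
    to the first/last breath values), linearly interpolated onto a common
    ``grid_n``-point grid, and averaged pointwise across events; the average
    event depth is 100 minus the minimum of that mean trace.
    """
    if not events:
        raise ValueError("no events")
    grid = np.linspace(0.0, 1.0, grid_n)
    traces = np.empty((len(events), grid_n))
    for row, ev in enumerate(events):
        i, j = ev.breath_idx
        vals = vent.percent_eupnea[i:j + 1]
        mids = vent.time_s[i:j + 1]
        span = ev.end_s - ev.start_s
        u = (mids - ev.start_s) / span
        traces[row] = np.interp(grid, u, vals)
    mean_trace = traces.mean(axis=0)
    return float(np.clip(100.0 - mean_trace.min(), 0.0, 100.0))


def ventilatory_burden(depth: float, mean_duration_min: float,
                       rate_per_hr: float) -> float:
    """Exact product depth x duration x rate (%eupnea . min / hr)."""
    if min(depth, mean_duration_min, rate_per_hr) < 0:
        raise ValueError("inputs must be non-negative")
    return depth * mean_duration_min * rate_per_hr


def summarize_traits(events: list[RespiratoryEvent], vent: VentilationSeries,
                     analyzed_hours: float,
                     cfg: EventConfig | None = None) -> TraitSummary:
    """Patient-level trait summary; zero events yields an all-zero summary."""
    cfg = cfg or EventConfig()
    if not events:
        return TraitSummary(0.0, 0.0, 0.0, 0)
    depth = average_event_depth(events, vent, cfg.ensemble_grid_n)
    dur = float(np.mean([e.duration_s for e in events])) / 60.0
    rate = len(events) / analyzed_hours
    return TraitSummary(depth, dur, rate, len(events))
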