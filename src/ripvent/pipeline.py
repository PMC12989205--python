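"""End-to-end processing: belts (and optionally reference flow) to breath,
ventilation, event and trait outputs.

``process_belts`` runs detection -> adaptive powerloss calibration -> OCF ->
eupnea normalization -> power law -> autoscoring for the corrected method,
or the fixed 2:1 mixing with none of the corrections for the benchmark.
``process_flow`` runs the reference pneumotach pipeline.  Both return a
:class:`RunResult` carrying every intermediate of interest plus a
machine-readable run report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .breaths import Breath, detect_breaths_flow, detect_breaths_rip, \
    gaps_between, impute_breaths
from .config import RunConfig
from .correction import CalibrationPeriod, FlowSeries, apply_ocf, \
    apply_power_law, benchmark_2to1, calibrate_flow, detect_movements, \
    segment_calibration_periods
from .events import RespiratoryEvent, TraitSummary, autoscore_events, \
    summarize_traits
from .signals import BeltPair, Signal
from .ventilation import VentilationSeries, integrated_volume, \
    ventilation_series


@dataclass
class RunResult:
    method: str
    breaths: list[Breath]
    vent: VentilationSeries
    events: list[RespiratoryEvent]
    traits: TraitSummary
    flow_series: FlowSeries
    periods: list[CalibrationPeriod] = field(default_factory=list)
    movements: list[float] = field(default_factory=list)
    config: RunConfig | None = None

    def report(self) -> dict:
        cfg = self.config or RunConfig()
        return {
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "method": self.method,
            "n_breaths": len(self.breaths),
            "n_imputed": sum(b.imputed for b in self.breaths),
            "n_ocf_applications": (
                0 if self.flow_series.breath_gains is None
                else int(np.sum(self.flow_series.breath_gains < 0.999))),
            "movements": list(self.movements),
            "calibration_periods": [
                {"start_s": p.start_s, "end_s": p.end_s, "k": p.k,
                 "objective": None if np.isnan(p.objective) else p.objective,
                 "fallback": p.fallback}
                for p in self.periods
            ],
            "n_events": len(self.events),
            "traits": {
                "average_event_depth": self.traits.average_event_depth,
                "mean_event_duration_min": self.traits.mean_event_duration_min,
                "event_rate_per_hr": self.traits.event_rate_per_hr,
                "ventilatory_burden": self.traits.ventilatory_burden,
            },
            "config": cfg.to_dict(),
        }

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=2)


def process_belts(belts: BeltPair, config: RunConfig | None = None) -> RunResult:
    """Full RIP pipeline for the configured method."""
    cfg = config or RunConfig()
    breaths = detect_breaths_rip(belts, cfg.breath)

    periods: list[CalibrationPeriod] = []
    movements: list[float] = []
    if cfg.method == "corrected":
        movements = detect_movements(belts, breaths, cfg.movement,
                                     cfg.breath.lowpass_hz)
        periods = segment_calibration_periods(
            belts, breaths, cfg.calibration, cfg.movement, movements)
        fs = calibrate_flow(belts, periods, cfg.calibration,
                            cfg.breath.lowpass_hz)
    elif cfg.method == "benchmark_2to1":
        fs = benchmark_2to1(belts, cfg.benchmark_abdomen_weight,
                            cfg.breath.lowpass_hz)
        w = cfg.benchmark_abdomen_weight
        periods = [CalibrationPeriod(belts.start_time,
                                     belts.start_time + belts.duration,
                                     w / (w + 1.0), np.nan, False)]
    else:
        raise ValueError(f"unknown method {cfg.method!r}")

    gaps = gaps_between(breaths, belts.start_time,
                        belts.start_time + belts.duration,
                        min_gap_s=2.0 * cfg.breath.min_breath_s)
    breaths = impute_breaths(breaths, gaps, volume=fs.volume, cfg=cfg.breath)

    if cfg.method == "corrected":
        fs = apply_ocf(fs, breaths, cfg.ocf)

    vent = ventilation_series(fs, breaths, cfg.eupnea)
    if cfg.method == "corrected":
        vent = vent.with_percent(
            apply_power_law(np.maximum(vent.percent_eupnea, 0.0),
                            cfg.powerlaw.exponent))

    events = autoscore_events(vent, cfg.event)
    traits = summarize_traits(events, vent, belts.duration / 3600.0, cfg.event)
    return RunResult(cfg.method, vent.breaths, vent, events, traits, fs,
                     periods, movements, cfg)


def process_flow(flow: Signal, config: RunConfig | None = None) -> RunResult:
    """Reference pneumotach pipeline: detection, imputation, normalization."""
    cfg = config or RunConfig()
    breaths = detect_breaths_flow(flow, cfg.breath)
    fs = FlowSeries(flow=flow, volume=None, method="oronasal")
    fs.volume = integrated_volume(fs)
    gaps = gaps_between(breaths, flow.start_time, flow.end_time,
                        min_gap_s=2.0 * cfg.breath.min_breath_s)
    breaths = impute_breaths(breaths, gaps, volume=fs.volume, cfg=cfg.breath)
    vent = ventilation_series(fs, breaths, cfg.eupnea, provenance="oronasal")
    events = autoscore_events(vent, cfg.event)
    traits = summarize_traits(events, vent, flow.duration / 3600.0, cfg.event)
    return RunResult("oronasal", vent.breaths, vent, events, traits, fs,
                     config=cfg)
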