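"""Run configuration with documented defaults.

Every threshold the pipeline uses lives here so that a run can be reproduced
from its JSON run-report alone.  Defaults follow the published method where a
published value exists (OCF sigmoid parameters, power-law exponent, 7-minute
eupnea window, 70 %eupnea event threshold, 10 s minimum event duration,
15x tidal-volume movement threshold, 20-breath movement reference, 10,000
bootstrap iterations); the remaining knobs are pragmatic signal-processing
choices documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class OCFConfig:
    """Overestimation-correction-factor sigmoid, gain as a function of the
    per-breath thorax/abdomen Pearson correlation r.

    With x = (r + 1) / 2 and L = 1 / (1 + exp(-k * (x - x0))):
    gain = (1 - y_min) * L**exponent_form + y_min.
    """

    x0: float = 0.034
    k: float = 31.0
    y_min: float = 0.22
    exponent_form: int = 2  # 2 = squared logistic (default); 1 = plain logistic


@dataclass
class CalibrationConfig:
    grid_step: float = 0.001        # k grid resolution for the powerloss search
    fallback_k: float = 0.5         # used when the objective is non-identifiable
    identifiability_floor: float = 0.01   # min objective range for a real fit
    min_breaths: int = 10           # periods with fewer breaths inherit k
    crossfade_s: float = 2.0        # linear k transition at period boundaries
    edge_guard_s: float = 8.0       # exclude movement artifact at period edges


@dataclass
class MovementConfig:
    tv_multiple: float = 15.0       # baseline deviation threshold, x median TV
    ref_breaths: int = 20           # trailing reference-pattern length
    merge_s: float = 5.0            # flags closer than this merge to one instant


@dataclass
class BreathConfig:
    lowpass_hz: float = 1.5
    filter_order: int = 4
    min_breath_s: float = 1.5
    max_breath_s: float = 15.0
    amplitude_floor_frac: float = 0.05   # of rolling median excursion
    amplitude_ceiling_frac: float = 5.0  # movement-artifact rejection
    prominence_frac: float = 0.10        # of rolling median tidal volume
    validate_window_frac: float = 0.40   # cross-belt cycle period tolerance
    dominance_window_s: float = 30.0
    detrend_window_s: float = 60.0       # rolling-median baseline removal
    impute_lookback: int = 5             # breaths defining the pre-gap rate
    impute_min_gap_periods: float = 1.5


@dataclass
class EupneaConfig:
    window_s: float = 420.0          # 7-minute moving window


@dataclass
class EventConfig:
    threshold_pct: float = 70.0      # breaths strictly below are "in event"
    min_duration_s: float = 10.0     # events must span strictly more
    ensemble_grid_n: int = 50
    nadir_breaths: int = 1           # 1 = single lowest breath; 2 = mean of lowest pair


@dataclass
class StatsConfig:
    small_max: float = 70.0          # stratum bounds on reference %eupnea
    large_min: float = 130.0
    relative_floor: float = 5.0      # reference below this excluded from relative errors
    pair_tolerance_s: float = 2.0
    n_boot: int = 10_000


@dataclass
class PowerLawConfig:
    exponent: float = 1.17


@dataclass
class RunConfig:
    """Top-level configuration for a processing run."""

    resample_hz: float = 25.0
    method: str = "corrected"        # "corrected" | "benchmark_2to1"
    benchmark_abdomen_weight: float = 2.0
    seed: int = 0
    breath: BreathConfig = field(default_factory=BreathConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    movement: MovementConfig = field(default_factory=MovementConfig)
    ocf: OCFConfig = field(default_factory=OCFConfig)
    powerlaw: PowerLawConfig = field(default_factory=PowerLawConfig)
    eupnea: EupneaConfig = field(default_factory=EupneaConfig)
    event: EventConfig = field(default_factory=EventConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for name, sub in (
            ("breath", BreathConfig), ("calibration", CalibrationConfig),
            ("movement", MovementConfig), ("ocf", OCFConfig),
            ("powerlaw", PowerLawConfig), ("eupnea", EupneaConfig),
            ("event", EventConfig), ("stats", StatsConfig),
        ):
            if name in kw and isinstance(kw[name], dict):
                kw[name] = sub(**kw[name])
        return cls(**kw)
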