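"""Synthetic overnight recordings with known ground truth.

The generator emulates the signal regimes the correction pipeline must
handle, with every quantity of interest known by construction:

* a true tidal-volume waveform ``V(t)`` built breath-by-breath from
  raised-cosine cycles with lognormal rate and amplitude jitter;
* a two-compartment belt model with a true mixing weight ``k*``: the
  compartments split the volume as ``V_th = (1 - rho_b) V + p`` and
  ``V_ab = rho_b V - p``, where ``rho_b`` is the per-breath
  thoracoabdominal split (jittered around one half) and ``p`` is
  isovolume paradoxical motion (what one compartment gains the other
  loses); the belts read the compartments with gains ``1 / (2 (1 - k*))``
  and ``1 / (2 k*)``, so ``(1-k*)*thorax + k*(abdomen)`` equals ``V / 2``
  for every breath regardless of the split, and the paradox cancels
  exactly at ``k*`` — both the natural-breathing (QDC-like) and the
  obstructed (isovolume) limits of the powerloss objective identify the
  same ``k*``;
* obstructive events: amplitude scaled by ``1 - severity``, a large
  antiphase effort component ``p`` (respiratory effort rises during
  obstruction), and a non-cancelling residual — a quarter-cycle
  (sine-phase) component fed equally to both compartments so that *no*
  mixing weight can remove it; this is precisely the error source the
  overestimation correction factor exists to suppress;
* central apneas: both belts quiescent (noise only);
* hypopneas: in-phase amplitude reduction;
* body movements: persistent baseline steps on both belts;
* reference flow: ``dV/dt`` plus white noise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .signals import BeltPair, Signal


@dataclass
class SimEvent:
    kind: str                     # obstructive_apnea | hypopnea | central_apnea
    start_s: float
    duration_s: float
    severity: float               # 1 = total obstruction
    paradox_residual: float = 0.0  # residual amplitude, x eupneic tidal volume

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def depth(self) -> float:
        return 100.0 * self.severity


@dataclass
class SimMovement:
    time_s: float
    shift_tv_multiple: float = 20.0


@dataclass
class SimConfig:
    duration_s: float = 7200.0
    rate_hz: float = 25.0
    true_k: float | list = 0.62          # constant, or [(start_s, k), ...]
    breath_rate_bpm: float = 15.0
    breath_rate_jitter: float = 0.08     # lognormal sigma on breath period
    amplitude_jitter: float = 0.07       # lognormal sigma on tidal amplitude
    compartment_jitter: float = 0.10     # SD of per-breath thoracoabdominal split
    effort_gain: float = 2.0             # paradox amplitude at total obstruction
    paradox_onset_severity: float = 0.6  # paradox appears above this severity
    paradox_exponent: float = 2.0        # how sharply paradox grows with severity
    noise_sd: float = 0.02               # white noise, fraction of eupneic TV
    events: list[SimEvent] = field(default_factory=list)
    movements: list[SimMovement] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        evs = sorted(self.events, key=lambda e: e.start_s)
        for a, b in zip(evs[:-1], evs[1:]):
            if a.end_s > b.start_s:
                raise ValueError(f"overlapping events at {a.start_s} and {b.start_s}")
        for e in evs:
            if not 0.0 <= e.severity <= 1.0:
                raise ValueError("severity must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the pipeline is later asked to recover."""

    breath_onsets: np.ndarray
    breath_ends: np.ndarray
    breath_amp: np.ndarray          # true volume amplitude per breath (a.u.)
    breath_pct: np.ndarray          # true ventilation, % of eupneic a0/period
    events: list[SimEvent]
    movements: list[SimMovement]
    k_schedule: list[tuple[float, float]]   # (start_s, k*)

    def k_at(self, t: float) -> float:
        k = self.k_schedule[0][1]
        for start, kk in self.k_schedule:
            if t >= start:
                k = kk
        return k

    def to_json(self, path) -> None:
        d = {
            "breath_onsets": self.breath_onsets.tolist(),
            "breath_ends": self.breath_ends.tolist(),
            "breath_amp": self.breath_amp.tolist(),
            "breath_pct": self.breath_pct.tolist(),
            "events": [vars(e) for e in self.events],
            "movements": [vars(m) for m in self.movements],
            "k_schedule": self.k_schedule,
        }
        with open(path, "w") as fh:
            json.dump(d, fh)


def _k_schedule(cfg: SimConfig) -> list[tuple[float, float]]:
    if isinstance(cfg.true_k, (int, float)):
        return [(0.0, float(cfg.true_k))]
    return [(float(t), float(k)) for t, k in cfg.true_k]


def simulate_recording(cfg: SimConfig
                       ) -> tuple[BeltPair, Signal, GroundTruth]:
    """Generate (belts, reference flow, ground truth) for one night."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.rate_hz
    n = int(round(cfg.duration_s * rate))
    t_axis = np.arange(n) / rate

    period0 = 60.0 / cfg.breath_rate_bpm
    a0 = 1.0                                      # eupneic tidal amplitude
    schedule = _k_schedule(cfg)

    def event_at(t: float) -> SimEvent | None:
        for e in cfg.events:
            if e.start_s <= t < e.end_s:
                return e
        return None

    volume = np.zeros(n)
    thorax = np.zeros(n)
    abdomen = np.zeros(n)

    onsets, ends, amps, pcts = [], [], [], []
    t = 0.0
    while t < cfg.duration_s - 0.5:
        dur = period0 * rng.lognormal(0.0, cfg.breath_rate_jitter)
        dur = float(np.clip(dur, 2.0, 8.0))
        end = min(t + dur, cfg.duration_s)
        mid = 0.5 * (t + end)
        ev = event_at(mid)

        amp_b = a0 * rng.lognormal(0.0, cfg.amplitude_jitter)
        rho = float(np.clip(0.5 + rng.normal(0.0, cfg.compartment_jitter),
                            0.1, 0.9))
        v_amp, p_amp, q_amp = amp_b, 0.0, 0.0
        if ev is not None:
            if ev.kind == "central_apnea":
                v_amp = p_amp = q_amp = 0.0
            elif ev.kind == "obstructive_apnea":
                v_amp = amp_b * (1.0 - ev.severity)
                # paradoxical effort emerges progressively with obstruction:
                # mild obstruction keeps the belts synchronized, complete
                # occlusion drives full isovolume counter-motion
                u_par = np.clip(
                    (ev.severity - cfg.paradox_onset_severity)
                    / (1.0 - cfg.paradox_onset_severity), 0.0, 1.0)
                p_amp = cfg.effort_gain * amp_b * u_par ** cfg.paradox_exponent
                # scaled so RIP ventilation during total obstruction reads
                # paradox_residual x eupnea after perfect linear calibration
                q_amp = 0.25 * ev.paradox_residual * amp_b
            elif ev.kind == "hypopnea":
                v_amp = amp_b * (1.0 - ev.severity)
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")

        i0, i1 = int(round(t * rate)), int(round(end * rate))
        if i1 <= i0:
            break
        u = (np.arange(i0, i1) / rate - t) / (end - t)
        h = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))     # 0 at both cycle ends
        s = np.sin(2.0 * np.pi * u)                   # quarter-cycle component

        k_star = _k_lookup(schedule, mid)
        g_th = 1.0 / (2.0 * (1.0 - k_star))           # belt sensor gains
        g_ab = 1.0 / (2.0 * k_star)

        v_th = (1.0 - rho) * v_amp * h + p_amp * h + q_amp * s
        v_ab = rho * v_amp * h - p_amp * h + q_amp * s
        volume[i0:i1] = v_amp * h
        thorax[i0:i1] = g_th * v_th
        abdomen[i0:i1] = g_ab * v_ab

        onsets.append(t)
        ends.append(end)
        amps.append(v_amp)
        # true ventilation is tidal volume over duration, relative to the
        # eupneic reference a0 / period0
        pcts.append(100.0 * (v_amp / (end - t)) / (a0 / period0))
        t = end

    # persistent baseline steps on both belts, alternating sign; step sizes
    # are multiples of each belt's own eupneic tidal excursion (0.5 a0 gain)
    base_th = np.zeros(n)
    base_ab = np.zeros(n)
    k0 = _k_lookup(schedule, 0.0)
    for j, mv in enumerate(cfg.movements):
        sign = 1 if j % 2 == 0 else -1
        m = t_axis >= mv.time_s
        base_th[m] += sign * mv.shift_tv_multiple * 0.5 * a0 / (2 * (1 - k0))
        base_ab[m] += sign * mv.shift_tv_multiple * 0.5 * a0 / (2 * k0)
    thorax = thorax + base_th
    abdomen = abdomen + base_ab

    noise = cfg.noise_sd * a0
    thorax = thorax + rng.normal(0.0, noise, n)
    abdomen = abdomen + rng.normal(0.0, noise, n)

    flow = np.gradient(volume) * rate
    flow_noise = cfg.noise_sd * a0 * (2.0 * np.pi / period0)
    flow = flow + rng.normal(0.0, flow_noise, n)

    belts = BeltPair(
        Signal(thorax, rate, 0.0, "Thorax", "a.u."),
        Signal(abdomen, rate, 0.0, "Abdomen", "a.u."),
    )
    flow_sig = Signal(flow, rate, 0.0, "Flow", "a.u./s")
    truth = GroundTruth(
        breath_onsets=np.array(onsets), breath_ends=np.array(ends),
        breath_amp=np.array(amps), breath_pct=np.array(pcts),
        events=sorted(cfg.events, key=lambda e: e.start_s),
        movements=sorted(cfg.movements, key=lambda m: m.time_s),
        k_schedule=schedule,
    )
    return belts, flow_sig, truth


def _k_lookup(schedule: list[tuple[float, float]], t: float) -> float:
    k = schedule[0][1]
    for start, kk in schedule:
        if t >= start:
            k = kk
    return k


def default_test_night(seed: int = 7, duration_s: float = 7200.0,
                       true_k: float = 0.62) -> SimConfig:
    """A standard 2-hour test night.

    Ten movements at 600 s intervals split the night into eleven calibration
    periods; every period contains at least one obstructive event so the
    mixing weight stays identifiable throughout.  Events: 20 obstructive
    apneas (severity 0.7-1.0, paradox residual 0.2-0.4), 6 hypopneas
    (severity 0.55-0.65), 5 central apneas; all events last 15-20 s with
    >= 20 s spacing.
    """
    rng = np.random.default_rng(seed)
    events: list[SimEvent] = []
    # two obstructive events in each of the first 9 periods, one in each of
    # the last two sub-spans of the final (1200 s) period
    ob_starts = [600.0 * j + off for j in range(9) for off in (120.0, 360.0)]
    ob_starts += [5520.0, 6120.0]
    for s in ob_starts:
        events.append(SimEvent(
            "obstructive_apnea", s,
            duration_s=float(rng.uniform(15.0, 20.0)),
            severity=float(rng.uniform(0.7, 1.0)),
            paradox_residual=float(rng.uniform(0.2, 0.4)),
        ))
    for j, s in enumerate([1050.0, 2250.0, 3450.0, 4650.0, 5850.0, 6900.0]):
        events.append(SimEvent("hypopnea", s,
                               duration_s=float(rng.uniform(15.0, 20.0)),
                               severity=float(rng.uniform(0.55, 0.65))))
    for s in [850.0, 2050.0, 3250.0, 4450.0, 6650.0]:
        events.append(SimEvent("central_apnea", s,
                               duration_s=float(rng.uniform(15.0, 20.0)),
                               severity=1.0))
    movements = [SimMovement(600.0 * j, 20.0) for j in range(1, 10)]
    movements.append(SimMovement(5700.0, 20.0))
    cfg = SimConfig(duration_s=duration_s, true_k=true_k, events=events,
                    movements=sorted(movements, key=lambda m: m.time_s),
                    seed=seed)
    cfg.validate()
    return cfg


def write_simulated_edf(path, belts: BeltPair, flow: Signal) -> None:
    """Write a simulated night as EDF (channels Thorax, Abdomen, Flow)."""
    from .edf import write_edf
    write_edf(path, [belts.thorax, belts.abdomen, flow])
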