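"""RIP correction: adaptive powerloss calibration, paradox suppression, and
power-law linearization.

The three steps convert two uncalibrated belt signals into a flow signal
whose breath-level ventilation tracks true ventilation:

1. *Powerloss calibration* finds the mixing weight ``k`` minimizing
   RMS((1-k)*dTH + k*dAB) / (RMS((1-k)*dTH) + RMS(k*dAB)), where dTH/dAB are
   the belt time-derivatives.  Paradoxical (antiphase) motion cancels in the
   weighted sum at the right ``k``, so the ratio dips well below 1 exactly
   when obstruction makes ``k`` identifiable.  ``k`` is refit per calibration
   period, the spans between detected body movements.

2. *Overestimation correction factor* (OCF): even optimally mixed belts leave
   a non-cancelling residual during obstruction.  Each breath's
   thorax/abdomen Pearson correlation r gauges paradox; a sigmoid gain in r
   (~1 for synchronous breaths, ~y_min for fully paradoxical ones)
   multiplies the flow samples of that breath.

3. *Power law*: eupnea-normalized ventilation v (in %) is mapped to
   100*(v/100)**1.17, deepening small breaths and boosting large ones while
   fixing 100% exactly.

A fixed 2:1 abdomen:thorax mixing without steps 2-3 is provided as the
benchmark against which the correction is evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .breaths import Breath, pearson_r
from .config import BreathConfig, CalibrationConfig, MovementConfig, OCFConfig
from .signals import BeltPair, Signal, lowpass

log = logging.getLogger(__name__)


@dataclass
class CalibrationPeriod:
    """A span of the night over which one mixing weight k is held constant."""

    start_s: float
    end_s: float
    k: float
    objective: float
    fallback: bool


@dataclass
class FlowSeries:
    """Calibrated RIP flow (derivative of the weighted belt sum)."""

    flow: Signal
    volume: Signal
    method: str = "rip_corrected"
    breath_gains: np.ndarray | None = None   # OCF gain actually applied per breath


# ---------------------------------------------------------------------------
# powerloss


def powerloss_objective(k: float, dth: np.ndarray, dab: np.ndarray) -> float:
    """Residual-power ratio of the k-weighted belt-derivative sum.

    Bounded in [0, 1] by the triangle inequality; 1 when the weighted
    components are collinear in phase, 0 when they cancel exactly.
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"k={k} outside [0, 1]")
    dth = np.asarray(dth, float)
    dab = np.asarray(dab, float)
    if dth.shape != dab.shape or dth.size < 2:
        raise ValueError("dth and dab must be equal-length, length >= 2")
    num = np.sqrt(np.mean(((1 - k) * dth + k * dab) ** 2))
    den = (1 - k) * np.sqrt(np.mean(dth ** 2)) + k * np.sqrt(np.mean(dab ** 2))
    if den == 0.0:
        raise ValueError("both derivative signals are all-zero")
    return float(num / den)


def _objective_on_grid(dth: np.ndarray, dab: np.ndarray, grid: np.ndarray
                       ) -> np.ndarray:
    # second-moment form: vectorized exact evaluation over the whole grid
    a = float(np.mean(dth ** 2))
    b = float(np.mean(dab ** 2))
    c = float(np.mean(dth * dab))
    k = grid
    num = np.sqrt(np.maximum((1 - k) ** 2 * a + k ** 2 * b + 2 * k * (1 - k) * c, 0.0))
    den = (1 - k) * np.sqrt(a) + k * np.sqrt(b)
    with np.errstate(invalid="ignore", divide="ignore"):
        obj = num / den
    return np.where(den > 0, obj, 1.0)


def fit_powerloss_k(belts: BeltPair, interval: tuple[float, float],
                    cfg: CalibrationConfig | None = None,
                    lowpass_hz: float = 1.5,
                    ) -> tuple[float, float, bool]:
    """Fit the mixing weight on one interval.

    Returns ``(k, objective, fallback)``; ``fallback`` is set when the
    objective is flat over the k grid (range below the identifiability
    floor — no paradox in the interval), in which case ``k`` is the
    configured fallback and the caller typically substitutes an inherited
    value.
    """
    cfg = cfg or CalibrationConfig()
    a, b = interval
    # periods are delimited by body movements whose baseline steps turn into
    # large derivative transients; keep the fit clear of them
    guard = min(cfg.edge_guard_s, 0.25 * (b - a))
    a, b = a + guard, b - guard
    th = lowpass(belts.thorax, lowpass_hz).slice(a, b)
    ab = lowpass(belts.abdomen, lowpass_hz).slice(a, b)
    if th.size < 4:
        raise ValueError("interval too short to calibrate")
    dth = np.gradient(th) * belts.rate
    dab = np.gradient(ab) * belts.rate

    grid = np.arange(0.0, 1.0 + cfg.grid_step / 2, cfg.grid_step)
    obj = _objective_on_grid(dth, dab, grid)
    if float(obj.max() - obj.min()) < cfg.identifiability_floor:
        return cfg.fallback_k, float(obj.min()), True
    i = int(np.argmin(obj))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(lambda k: powerloss_objective(k, dth, dab),
                          bounds=(lo, hi), method="bounded")
    return float(res.x), float(res.fun), False


# ---------------------------------------------------------------------------
# movements and calibration periods


def detect_movements(belts: BeltPair, breaths: list[Breath],
                     cfg: MovementConfig | None = None,
                     lowpass_hz: float = 1.5) -> list[float]:
    """Times of body movements, from belt-baseline jumps.

    Each breath's trough level (per belt) is compared with the median trough
    level of the trailing ``ref_breaths`` breaths; a deviation beyond
    ``tv_multiple`` times the running median tidal volume on either belt
    flags a movement.  Flags separated by less than ``merge_s`` merge into a
    single instant.
    """
    cfg = cfg or MovementConfig()
    if len(breaths) < cfg.ref_breaths:
        return []
    th = lowpass(belts.thorax, lowpass_hz)
    ab = lowpass(belts.abdomen, lowpass_hz)
    trough_th = np.array([float(np.min(th.slice(b.onset_s, b.end_s)))
                          for b in breaths])
    trough_ab = np.array([float(np.min(ab.slice(b.onset_s, b.end_s)))
                          for b in breaths])
    tvs = np.array([b.tidal_volume for b in breaths])

    # a chain of flags each within merge_s of the previous one is one
    # movement; after an accepted movement, flags are suppressed until the
    # trailing reference pattern is movement-free again (ref_breaths breaths),
    # since a reference straddling the step re-triggers spuriously
    n_ref = cfg.ref_breaths
    merged: list[float] = []
    prev_flag = None
    last_idx = -n_ref
    for i in range(n_ref, len(breaths)):
        sl = slice(i - n_ref, i)
        tv_med = float(np.median(tvs[sl]))
        if tv_med <= 0:
            continue
        dev = max(abs(trough_th[i] - float(np.median(trough_th[sl]))),
                  abs(trough_ab[i] - float(np.median(trough_ab[sl]))))
        if dev > cfg.tv_multiple * tv_med:
            t = breaths[i].onset_s
            fresh = i - last_idx >= n_ref
            if fresh and (prev_flag is None or t - prev_flag >= cfg.merge_s):
                merged.append(t)
                last_idx = i
            prev_flag = t
    return merged


def segment_calibration_periods(belts: BeltPair, breaths: list[Breath],
                                cal_cfg: CalibrationConfig | None = None,
                                mov_cfg: MovementConfig | None = None,
                                movements: list[float] | None = None,
                                ) -> list[CalibrationPeriod]:
    """Partition the recording at movement instants and fit k per period.

    Periods whose objective is non-identifiable, or which contain fewer than
    ``min_breaths`` breaths, inherit the nearest previous non-fallback k
    (the configured fallback value at recording start).
    """
    cal_cfg = cal_cfg or CalibrationConfig()
    if movements is None:
        movements = detect_movements(belts, breaths, mov_cfg)
    t0, t1 = belts.start_time, belts.start_time + belts.duration
    bounds = [t0] + [m for m in movements if t0 < m < t1] + [t1]

    periods: list[CalibrationPeriod] = []
    last_good = cal_cfg.fallback_k
    for a, b in zip(bounds[:-1], bounds[1:]):
        inside = [br for br in breaths if a <= br.midpoint_s < b]
        if len(inside) < cal_cfg.min_breaths:
            periods.append(CalibrationPeriod(a, b, last_good, np.nan, True))
            continue
        k, obj, fb = fit_powerloss_k(belts, (a, b), cal_cfg)
        if fb:
            k = last_good
        else:
            last_good = k
        periods.append(CalibrationPeriod(a, b, k, obj, fb))
    return periods


# ---------------------------------------------------------------------------
# calibrated flow


def _k_of_t(periods: list[CalibrationPeriod], times: np.ndarray,
            crossfade_s: float) -> np.ndarray:
    k = np.empty_like(times)
    for p in periods:
        m = (times >= p.start_s) & (times < p.end_s)
        k[m] = p.k
    if times.size:
        k[times >= periods[-1].end_s] = periods[-1].k
        k[times < periods[0].start_s] = periods[0].k
    # linear crossfade across each interior boundary
    half = crossfade_s / 2.0
    for prev, nxt in zip(periods[:-1], periods[1:]):
        tb = prev.end_s
        m = (times >= tb - half) & (times <= tb + half)
        if m.any() and crossfade_s > 0:
            frac = (times[m] - (tb - half)) / crossfade_s
            k[m] = prev.k + frac * (nxt.k - prev.k)
    return k


def calibrate_flow(belts: BeltPair, periods: list[CalibrationPeriod],
                   cfg: CalibrationConfig | None = None,
                   lowpass_hz: float = 1.5) -> FlowSeries:
    """Weighted belt sum and its derivative under the per-period k schedule."""
    cfg = cfg or CalibrationConfig()
    th = lowpass(belts.thorax, lowpass_hz)
    ab = lowpass(belts.abdomen, lowpass_hz)
    k = _k_of_t(periods, th.times(), cfg.crossfade_s)
    vol = (1.0 - k) * th.samples + k * ab.samples
    flow = np.gradient(vol) * belts.rate
    return FlowSeries(
        flow=Signal(flow, belts.rate, belts.start_time, "RIP flow", "a.u./s"),
        volume=Signal(vol, belts.rate, belts.start_time, "RIP volume", "a.u."),
        method="rip_corrected",
    )


def benchmark_2to1(belts: BeltPair, abdomen_weight: float = 2.0,
                   lowpass_hz: float = 1.5) -> FlowSeries:
    """Fixed 2:1 abdomen:thorax mixing (k = 2/3), no OCF, no power law."""
    w = abdomen_weight
    period = CalibrationPeriod(belts.start_time,
                               belts.start_time + belts.duration,
                               k=w / (w + 1.0), objective=np.nan, fallback=False)
    fs = calibrate_flow(belts, [period], lowpass_hz=lowpass_hz)
    return replace(fs, method="rip_benchmark")


# ---------------------------------------------------------------------------
# OCF


def breath_paradox_r(belts: BeltPair, breath: Breath,
                     breath_cfg: BreathConfig | None = None) -> float:
    """Pearson correlation of the band-limited belts over one breath."""
    cfg = breath_cfg or BreathConfig()
    th = lowpass(belts.thorax, cfg.lowpass_hz).slice(breath.onset_s, breath.end_s)
    ab = lowpass(belts.abdomen, cfg.lowpass_hz).slice(breath.onset_s, breath.end_s)
    th = th - th.mean()
    ab = ab - ab.mean()
    return pearson_r(th, ab)


def ocf(r, params: OCFConfig | None = None):
    """Overestimation correction gain for thorax/abdomen correlation ``r``.

    Monotone non-decreasing on [-1, 1]; ~1 for synchronous breathing,
    ~y_min for complete paradox.
    """
    params = params or OCFConfig()
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < -1.0 - 1e-9) or np.any(r_arr > 1.0 + 1e-9):
        raise ValueError("r outside [-1, 1]")
    x = (np.clip(r_arr, -1.0, 1.0) + 1.0) / 2.0
    L = 1.0 / (1.0 + np.exp(-params.k * (x - params.x0)))
    gain = (1.0 - params.y_min) * L ** params.exponent_form + params.y_min
    return float(gain) if np.isscalar(r) else gain


def apply_ocf(fs: FlowSeries, breaths: list[Breath],
              params: OCFConfig | None = None) -> FlowSeries:
    """Scale flow samples breath-by-breath by each breath's OCF gain.

    Samples outside any breath use the nearest breath's gain; breaths with
    undefined r (e.g. imputed) get gain 1.
    """
    params = params or OCFConfig()
    if not breaths:
        return replace(fs, breath_gains=np.array([]))
    rs = np.array([b.paradox_r for b in breaths])
    gains = np.where(np.isnan(rs), 1.0, ocf(np.nan_to_num(rs, nan=1.0), params))
    times = fs.flow.times()
    onsets = np.array([b.onset_s for b in breaths])
    ends = np.array([b.end_s for b in breaths])
    mids = np.array([b.midpoint_s for b in breaths])

    # breath index per sample; gap samples -> nearest breath midpoint
    idx = np.searchsorted(onsets, times, side="right") - 1
    idx = np.clip(idx, 0, len(breaths) - 1)
    in_breath = (times >= onsets[idx]) & (times < ends[idx])
    nearest = np.clip(np.searchsorted(mids, times), 1, len(breaths) - 1)
    nearest = np.where(
        np.abs(times - mids[nearest - 1]) <= np.abs(times - mids[nearest]),
        nearest - 1, nearest,
    ) if len(breaths) > 1 else np.zeros_like(idx)
    sample_gain = np.where(in_breath, gains[idx], gains[nearest])

    out_flow = replace(fs.flow, samples=fs.flow.samples * sample_gain,
                       bad_spans=list(fs.flow.bad_spans))
    return replace(fs, flow=out_flow, breath_gains=gains)


def fit_ocf_params(r: np.ndarray, ratio: np.ndarray,
                   exponent_form: int = 2, n_bins: int = 10) -> OCFConfig:
    """Recover OCF sigmoid parameters from paired per-breath data.

    ``ratio`` is reference/RIP ventilation per breath.  Breaths are pooled
    into r-deciles, the median ratio per decile is computed, and the sigmoid
    family is least-squares fitted to the (decile median r, median ratio)
    points.
    """
    r = np.asarray(r, float)
    ratio = np.asarray(ratio, float)
    ok = np.isfinite(r) & np.isfinite(ratio) & (ratio > 0)
    r, ratio = r[ok], ratio[ok]
    if r.size < n_bins:
        raise ValueError(f"need at least {n_bins} valid breaths")
    if np.ptp(r) < 1e-12:
        raise ValueError("all r values identical; sigmoid not identifiable")
    edges = np.quantile(r, np.linspace(0, 1, n_bins + 1))
    which = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_bins - 1)
    centers, medians = [], []
    for b in range(n_bins):
        m = which == b
        if m.any():
            centers.append(float(np.median(r[m])))
            medians.append(float(np.median(ratio[m])))
    centers = np.array(centers)
    medians = np.array(medians)

    def model(rr, x0, k_sig, y_min):
        return ocf(rr, OCFConfig(x0=x0, k=k_sig, y_min=y_min,
                                 exponent_form=exponent_form))

    p0 = (0.034, 31.0, float(np.clip(medians.min(), 0.01, 0.99)))
    popt, _ = curve_fit(model, centers, medians, p0=p0,
                        bounds=([-2.0, 1e-3, 1e-6], [2.0, 1e3, 1.0]),
                        maxfev=20000)
    return OCFConfig(x0=float(popt[0]), k=float(popt[1]),
                     y_min=float(popt[2]), exponent_form=exponent_form)


# ---------------------------------------------------------------------------
# power law


def apply_power_law(percent_eupnea, exponent: float = 1.17):
    """Map %eupnea v to 100*(v/100)**exponent; fixes 0 and 100 exactly."""
    v = np.asarray(percent_eupnea, dtype=float)
    if np.any(v < 0):
        raise ValueError("percent_eupnea must be non-negative")
    out = 100.0 * (v / 100.0) ** exponent
    return float(out) if np.isscalar(percent_eupnea) else out
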