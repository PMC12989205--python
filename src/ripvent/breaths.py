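"""Breath segmentation for RIP belts and for airflow, plus apnea imputation.

Two detectors are provided.  For RIP, breaths are trough-to-trough cycles of
whichever belt shows the larger excursion locally (so segmentation keeps
working when the belts move out of phase during obstruction), with each cycle
validated by requiring a concurrent cycle of similar period — of either
phase — on the other belt.  For airflow, the trace is baseline-corrected with
a one-minute rolling median, integrated to volume, and segmented at volume
troughs.  Central-apnea gaps, where neither detector finds cycles, are filled
afterwards by :func:`impute_breaths` at the pre-gap respiratory rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .config import BreathConfig
from .signals import BeltPair, Signal, lowpass, rolling_median_baseline

log = logging.getLogger(__name__)


@dataclass
class Breath:
    """One respiratory cycle, [onset_s, end_s)."""

    onset_s: float
    end_s: float
    tidal_volume: float = np.nan     # peak-trough volume excursion (a.u.)
    ventilation: float = np.nan      # tidal_volume / duration (a.u./min)
    percent_eupnea: float = np.nan   # filled by the ventilation stage
    paradox_r: float = np.nan        # thorax/abdomen Pearson r over the span
    imputed: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.onset_s + self.end_s)


# ---------------------------------------------------------------------------
# trough finding


def _candidate_troughs(x: np.ndarray, rate: float, min_sep_s: float,
                       prominence_frac: float) -> np.ndarray:
    """Indices of respiratory troughs of ``x``.

    A first pass enumerates every local minimum; the keep threshold is then
    ``prominence_frac`` of the 90th-percentile prominence, a robust proxy for
    the typical tidal excursion that tolerates slow amplitude drift while
    rejecting sample-level noise.
    """
    scale = float(np.std(x))
    if scale == 0.0:
        return np.array([], dtype=int)
    dist = max(int(min_sep_s * rate), 1)
    idx, props = find_peaks(-x, prominence=1e-9 * scale, distance=dist)
    if idx.size == 0:
        return idx
    ref = np.percentile(props["prominences"], 90)
    return idx[props["prominences"] >= prominence_frac * ref]


def _cycle_bounds(trough_t: np.ndarray, t0: float, t1: float) -> list[tuple[float, float]]:
    """Half-open cycle intervals from trough times, treating the recording
    edges as boundaries and merging partial edge cycles shorter than half the
    median period into their neighbour (keeps the cycle count at
    frequency x duration for periodic input regardless of phase)."""
    tt = np.asarray(trough_t, dtype=float)
    if tt.size == 0:
        return []
    bounds = [t0, *tt.tolist(), t1]
    if tt.size >= 2:
        med = float(np.median(np.diff(tt)))
        half = 0.5 * med
        first = bounds[1] - bounds[0]
        last = bounds[-1] - bounds[-2]
        if first < half and len(bounds) > 2:
            del bounds[1]
        if last < half and len(bounds) > 2:
            del bounds[-2]
        if first >= half and last >= half and first + last <= 1.25 * med \
                and len(bounds) > 2:
            # two surviving edge partials that sum to one period are the two
            # halves of a single cycle broken by the recording boundary
            if first <= last:
                del bounds[1]
            else:
                del bounds[-2]
    return [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def _rolling_dominance(th: np.ndarray, ab: np.ndarray, rate: float,
                       window_s: float) -> np.ndarray:
    """Boolean mask, True where the thorax excursion dominates locally."""
    w = max(int(window_s * rate) | 1, 3)
    s_th = pd.Series(th).rolling(w, center=True, min_periods=1).std().to_numpy()
    s_ab = pd.Series(ab).rolling(w, center=True, min_periods=1).std().to_numpy()
    return s_th >= s_ab


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 1.0 when either input has no variance (treated
    as 'no paradox' so no suppression is applied downstream)."""
    if a.size < 4 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return 1.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# RIP detector


def detect_breaths_rip(belts: BeltPair, cfg: BreathConfig | None = None
                       ) -> list[Breath]:
    """Segment a belt pair into breaths.

    Returns time-ordered, non-overlapping breaths with provisional
    ``tidal_volume`` (dominant-belt excursion, arbitrary units) and
    ``paradox_r``.  Spans where no valid cycle exists (central apneas, flat
    signal, movement artifact) are simply absent and may be imputed later.
    """
    cfg = cfg or BreathConfig()
    rate = belts.rate
    th_f = lowpass(belts.thorax, cfg.lowpass_hz, cfg.filter_order).samples
    ab_f = lowpass(belts.abdomen, cfg.lowpass_hz, cfg.filter_order).samples
    w = int(cfg.detrend_window_s * rate)
    th_d = th_f - rolling_median_baseline(th_f, w)
    ab_d = ab_f - rolling_median_baseline(ab_f, w)

    dom_th = _rolling_dominance(th_d, ab_d, rate, cfg.dominance_window_s)

    tr_th = _candidate_troughs(th_d, rate, cfg.min_breath_s / 2, cfg.prominence_frac)
    tr_ab = _candidate_troughs(ab_d, rate, cfg.min_breath_s / 2, cfg.prominence_frac)

    # segment on whichever belt dominates at each trough's location
    keep = np.concatenate([
        tr_th[dom_th[tr_th]] if tr_th.size else tr_th,
        tr_ab[~dom_th[tr_ab]] if tr_ab.size else tr_ab,
    ])
    keep = np.unique(keep)
    if keep.size >= 2:   # drop near-duplicate boundaries at dominance switches
        min_sep = int(cfg.min_breath_s * rate / 2)
        keep = keep[np.concatenate([[True], np.diff(keep) >= min_sep])]

    t0 = belts.start_time
    trough_t = t0 + keep / rate
    cycles = _cycle_bounds(trough_t, t0, t0 + belts.duration)
    if not cycles:
        return []

    # cross-belt validation intervals: trough-to-trough and peak-to-peak
    # cycles on the *other* belt, either phase
    def extrema_intervals(x: np.ndarray) -> np.ndarray:
        tr = _candidate_troughs(x, rate, cfg.min_breath_s / 2, cfg.prominence_frac)
        pk = _candidate_troughs(-x, rate, cfg.min_breath_s / 2, cfg.prominence_frac)
        t_end = t0 + belts.duration
        spans = []
        for e in (tr, pk):
            if e.size >= 2:
                spans.extend(zip(t0 + e[:-1] / rate, t0 + e[1:] / rate))
            if e.size:   # partial cycles truncated by the recording edges
                spans.append((t0, t0 + e[0] / rate))
                spans.append((t0 + e[-1] / rate, t_end))
        return np.array(sorted(spans)) if spans else np.empty((0, 2))

    iv_th = extrema_intervals(th_d)
    iv_ab = extrema_intervals(ab_d)

    med_period = (float(np.median(np.diff(trough_t)))
                  if trough_t.size >= 2 else cfg.max_breath_s)

    def has_concurrent(ivs: np.ndarray, a: float, b: float) -> bool:
        if ivs.size == 0:
            return False
        dur = b - a
        ok = (ivs[:, 0] < b) & (ivs[:, 1] > a)
        ivdur = ivs[:, 1] - ivs[:, 0]
        # a concurrent cycle may match this cycle's own span or — for cycles
        # truncated at the recording edges — the typical breath period
        close = (np.abs(ivdur - dur) <= cfg.validate_window_frac * dur) | \
                (np.abs(ivdur - med_period)
                 <= cfg.validate_window_frac * med_period)
        return bool(np.any(ok & close))

    def excursion(x: np.ndarray, a: float, b: float) -> float:
        i0 = max(int((a - t0) * rate), 0)
        i1 = min(int(np.ceil((b - t0) * rate)), x.size)
        seg = x[i0:i1]
        return float(np.ptp(seg)) if seg.size else 0.0

    breaths: list[Breath] = []
    exc_hist: list[float] = []
    for a, b in cycles:
        dur = b - a
        if not (cfg.min_breath_s <= dur <= cfg.max_breath_s):
            continue
        i0, i1 = int((a - t0) * rate), int((b - t0) * rate)
        dom_here = bool(np.mean(dom_th[i0:max(i1, i0 + 1)]) >= 0.5)
        exc = excursion(th_d if dom_here else ab_d, a, b)
        ref = float(np.median(exc_hist[-20:])) if exc_hist else exc
        if ref > 0 and not (cfg.amplitude_floor_frac * ref <= exc
                            <= cfg.amplitude_ceiling_frac * ref):
            continue   # sub-floor cycles are apneic gaps; super-ceiling are artifact
        if not has_concurrent(iv_ab if dom_here else iv_th, a, b):
            continue
        r = pearson_r(th_d[i0:i1], ab_d[i0:i1])
        breaths.append(Breath(a, b, tidal_volume=exc, paradox_r=r))
        exc_hist.append(exc)
    return breaths


# ---------------------------------------------------------------------------
# flow detector


def detect_breaths_flow(flow: Signal, cfg: BreathConfig | None = None,
                        baseline_window_s: float = 60.0) -> list[Breath]:
    """Segment an airflow trace into breaths.

    The baseline is removed with a one-minute rolling median (making the
    result invariant to any constant offset), flow is integrated to volume,
    and breath onsets are the volume troughs.  ``tidal_volume`` is the volume
    peak minus the preceding trough within each cycle.
    """
    cfg = cfg or BreathConfig()
    rate = flow.rate
    f = flow.samples - rolling_median_baseline(flow.samples,
                                               int(baseline_window_s * rate))
    vol = cumulative_trapezoid(f, dx=1.0 / rate, initial=0.0)
    vol = vol - rolling_median_baseline(vol, int(baseline_window_s * rate))

    troughs = _candidate_troughs(vol, rate, cfg.min_breath_s / 2,
                                 cfg.prominence_frac)
    t0 = flow.start_time
    cycles = _cycle_bounds(t0 + troughs / rate, t0, flow.end_time)

    breaths: list[Breath] = []
    exc_hist: list[float] = []
    for a, b in cycles:
        dur = b - a
        if not (cfg.min_breath_s <= dur <= cfg.max_breath_s):
            continue
        i0 = max(int((a - t0) * rate), 0)
        i1 = min(int(np.ceil((b - t0) * rate)), vol.size)
        seg = vol[i0:i1]
        if seg.size < 2:
            continue
        tv = float(np.max(seg) - np.min(seg))
        ref = float(np.median(exc_hist[-20:])) if exc_hist else tv
        if ref > 0 and not (cfg.amplitude_floor_frac * ref <= tv
                            <= cfg.amplitude_ceiling_frac * ref):
            continue
        breaths.append(Breath(a, b, tidal_volume=tv,
                              ventilation=tv / dur * 60.0))
        exc_hist.append(tv)
    return breaths


# ---------------------------------------------------------------------------
# gaps and imputation


def gaps_between(breaths: list[Breath], t0: float, t1: float,
                 min_gap_s: float = 0.5) -> list[tuple[float, float]]:
    """Intervals of [t0, t1) not covered by any breath."""
    gaps = []
    cursor = t0
    for b in breaths:
        if b.onset_s - cursor >= min_gap_s:
            gaps.append((cursor, b.onset_s))
        cursor = max(cursor, b.end_s)
    if t1 - cursor >= min_gap_s:
        gaps.append((cursor, t1))
    return gaps


def impute_breaths(breaths: list[Breath],
                   gap_intervals: list[tuple[float, float]],
                   volume: Signal | None = None,
                   cfg: BreathConfig | None = None) -> list[Breath]:
    """Fill apneic gaps with evenly spaced breaths at the pre-gap rate.

    The breath period is the median duration of the last ``impute_lookback``
    breaths preceding the gap; gaps shorter than ``impute_min_gap_periods``
    pre-gap periods are left alone.  Imputed breaths carry the (near-flat)
    signal excursion in their span as tidal volume when ``volume`` is given.
    """
    cfg = cfg or BreathConfig()
    out = list(breaths)
    for g0, g1 in gap_intervals:
        prior = [b for b in breaths if b.end_s <= g0 + 1e-9 and not b.imputed]
        if len(prior) < 3:
            log.warning("gap at %.1f s has <3 preceding breaths; left unfilled", g0)
            continue
        period = float(np.median([b.duration_s
                                  for b in prior[-cfg.impute_lookback:]]))
        gap = g1 - g0
        if gap < cfg.impute_min_gap_periods * period:
            continue
        n = max(int(round(gap / period)), 1)
        edges = np.linspace(g0, g1, n + 1)
        for a, b in zip(edges[:-1], edges[1:]):
            tv = 0.0
            if volume is not None:
                seg = volume.slice(a, b)
                tv = float(np.ptp(seg)) if seg.size else 0.0
            out.append(Breath(a, b, tidal_volume=tv,
                              ventilation=tv / (b - a) * 60.0,
                              paradox_r=np.nan, imputed=True))
    out.sort(key=lambda b: b.onset_s)
    return out
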