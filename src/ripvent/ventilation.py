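"""Breath-level minute ventilation normalized to a local eupneic baseline.

Ventilation is tidal volume (peak minus trough of the integrated flow over
the breath) divided by breath duration, per minute.  Because RIP amplitude
is in arbitrary units, values are expressed as a percentage of the local
baseline — the duration-weighted mean ventilation of all breaths whose
midpoints fall in a centered 7-minute moving window — so that 100 %eupnea
is normal local breathing and 0 % is apnea.  The normalization makes the
series invariant to any overall amplitude scale and absorbs slow drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .breaths import Breath
from .config import EupneaConfig
from .correction import FlowSeries
from .signals import Signal, rolling_median_baseline

log = logging.getLogger(__name__)


@dataclass
class VentilationSeries:
    """Per-breath ventilation with its local eupneic baseline."""

    time_s: np.ndarray           # breath midpoints
    raw: np.ndarray              # a.u./min
    baseline: np.ndarray         # a.u./min, > 0
    percent_eupnea: np.ndarray   # 100 * raw / baseline
    breaths: list[Breath]
    provenance: str = "rip_corrected"

    def __len__(self) -> int:
        return len(self.time_s)

    def with_percent(self, pct: np.ndarray) -> "VentilationSeries":
        breaths = [replace_pct(b, p) for b, p in zip(self.breaths, pct)]
        return VentilationSeries(self.time_s, self.raw, self.baseline,
                                 np.asarray(pct, float), breaths, self.provenance)


def replace_pct(b: Breath, pct: float) -> Breath:
    from dataclasses import replace as dc_replace
    return dc_replace(b, percent_eupnea=float(pct))


def _excursion(seg: np.ndarray) -> float:
    """Peak-to-trough excursion after removing the line through the segment
    endpoints.  A trough-to-trough breath starts and ends at the same volume,
    so residual baseline slope (integration drift, event-edge transients of
    the rolling-median detrend) shows up as an endpoint ramp that would
    otherwise inflate small breaths."""
    if seg.size < 2:
        return 0.0
    ramp = np.linspace(seg[0], seg[-1], seg.size)
    return float(np.ptp(seg - ramp))


def breath_ventilation(fs: FlowSeries, breath: Breath) -> float:
    """Raw ventilation of one breath from the flow signal (a.u./min)."""
    vol = integrated_volume(fs, detrend=False)
    tv = _excursion(vol.slice(breath.onset_s, breath.end_s))
    return tv / breath.duration_s * 60.0


def integrated_volume(fs: FlowSeries, detrend: bool = False,
                      detrend_window_s: float = 60.0) -> Signal:
    """Cumulative integral of flow.

    Per-breath excursions are taken from the raw integral (each breath is
    anchored by its own endpoint ramp, see :func:`_excursion`), so no global
    detrend is applied by default; ``detrend=True`` subtracts a rolling
    median for uses that need a drift-free waveform as a whole.
    """
    vol = cumulative_trapezoid(fs.flow.samples, dx=1.0 / fs.flow.rate,
                               initial=0.0)
    if detrend:
        vol = vol - rolling_median_baseline(
            vol, int(detrend_window_s * fs.flow.rate))
    return replace(fs.flow, samples=vol, label="integrated volume", units="a.u.")


def ventilation_series(fs: FlowSeries, breaths: list[Breath],
                       cfg: EupneaConfig | None = None,
                       provenance: str | None = None) -> VentilationSeries:
    """Per-breath raw ventilation from ``fs`` followed by eupnea normalization."""
    vol = integrated_volume(fs)
    raw = np.empty(len(breaths))
    for i, b in enumerate(breaths):
        raw[i] = _excursion(vol.slice(b.onset_s, b.end_s)) / b.duration_s * 60.0
    return normalize_to_eupnea(breaths, raw, cfg,
                               provenance or fs.method)


def normalize_to_eupnea(breaths: list[Breath], raw: np.ndarray,
                        cfg: EupneaConfig | None = None,
                        provenance: str = "rip_corrected") -> VentilationSeries:
    """Normalize raw per-breath ventilation to the local eupneic baseline.

    The baseline for each breath is the duration-weighted mean raw
    ventilation of all breaths whose midpoints lie within the centered
    ``window_s`` window (truncated at the recording edges; event breaths are
    not excluded).  Windows with zero mean carry the nearest valid baseline.
    """
    cfg = cfg or EupneaConfig()
    raw = np.asarray(raw, dtype=float)
    mids = np.array([b.midpoint_s for b in breaths])
    durs = np.array([b.duration_s for b in breaths])
    half = cfg.window_s / 2.0

    n = len(breaths)
    baseline = np.zeros(n)
    lo = np.searchsorted(mids, mids - half, side="left")
    hi = np.searchsorted(mids, mids + half, side="right")
    cw = np.concatenate([[0.0], np.cumsum(raw * durs)])
    cd = np.concatenate([[0.0], np.cumsum(durs)])
    with np.errstate(invalid="ignore", divide="ignore"):
        baseline = (cw[hi] - cw[lo]) / (cd[hi] - cd[lo])

    bad = ~np.isfinite(baseline) | (baseline <= 0)
    if bad.any():
        good = np.flatnonzero(~bad)
        if good.size == 0:
            raise ValueError("no window with nonzero ventilation")
        log.warning("%d breaths with all-zero window; baseline carried "
                    "from nearest valid window", int(bad.sum()))
        nearest = good[np.argmin(np.abs(mids[bad][:, None] - mids[good][None, :]),
                                 axis=1)]
        baseline[bad] = baseline[nearest]

    pct = 100.0 * raw / baseline
    out_breaths = [replace_pct(b, p) for b, p in zip(breaths, pct)]
    for b, v in zip(out_breaths, raw):
        b.ventilation = float(v)
    return VentilationSeries(mids, raw, baseline, pct, out_breaths, provenance)
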