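"""Uniformly sampled signal containers and resampling.

``Signal`` is the package-wide waveform representation: a float array with a
sample rate, a start time (seconds from recording start) and free-text label
and units.  ``BeltPair`` aligns the thoracic and abdominal RIP channels onto
a common clock at construction so every downstream stage can index the two
belts sample-for-sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

log = logging.getLogger(__name__)

#: longest NaN run (seconds) that is gap-filled by linear interpolation;
#: longer runs are zero-filled and reported so callers can exclude them.
MAX_INTERP_GAP_S = 1.0


@dataclass
class Signal:
    """A uniformly sampled real-valued waveform."""

    samples: np.ndarray
    rate: float
    start_time: float = 0.0
    label: str = ""
    units: str = "a.u."
    #: [start_s, end_s) spans of NaN runs too long to interpolate
    bad_spans: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if np.isnan(self.samples).any():
            self.samples, self.bad_spans = _fill_nans(
                self.samples, self.rate, self.start_time
            )
        if not np.isfinite(self.samples).all():
            raise ValueError(f"non-finite samples in signal {self.label!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` (clipped to the valid range)."""
        i = int(round((t - self.start_time) * self.rate))
        return min(max(i, 0), self.n - 1)

    def slice(self, t0: float, t1: float) -> np.ndarray:
        """Samples in the half-open interval [t0, t1)."""
        i0 = max(int(np.ceil((t0 - self.start_time) * self.rate - 1e-9)), 0)
        i1 = min(int(np.ceil((t1 - self.start_time) * self.rate - 1e-9)), self.n)
        return self.samples[i0:i1]

    def resample(self, rate: float) -> "Signal":
        """Polyphase resample to ``rate`` (duration preserved to one sample)."""
        if np.isclose(rate, self.rate):
            return self
        frac = Fraction(rate / self.rate).limit_denominator(1000)
        out = sps.resample_poly(self.samples, frac.numerator, frac.denominator)
        n_target = int(round(self.n * rate / self.rate))
        if out.size > n_target:
            out = out[:n_target]
        elif out.size < n_target:
            out = np.pad(out, (0, n_target - out.size), mode="edge")
        return replace(self, samples=out, rate=rate, bad_spans=list(self.bad_spans))


def _fill_nans(x: np.ndarray, rate: float, start: float):
    """Interpolate NaN runs <= MAX_INTERP_GAP_S, zero-fill longer runs."""
    x = x.copy()
    isnan = np.isnan(x)
    bad_spans = []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], isnan.view(np.int8), [0]])))
    max_len = int(MAX_INTERP_GAP_S * rate)
    t = np.arange(x.size)
    good = ~isnan
    if not good.any():
        raise ValueError("signal is all-NaN")
    filled = np.interp(t, t[good], x[good])
    for a, b in idx.reshape(-1, 2):
        if b - a <= max_len:
            x[a:b] = filled[a:b]
        else:
            x[a:b] = 0.0
            bad_spans.append((start + a / rate, start + b / rate))
            log.warning("zero-filled %.1f s NaN run at t=%.1f s", (b - a) / rate, start + a / rate)
    return x, bad_spans


@dataclass
class BeltPair:
    """Thorax and abdomen RIP signals on a common clock.

    Channels are resampled to the higher of the two rates (or ``rate`` if
    given) and trimmed to the overlapping span on construction.
    """

    thorax: Signal
    abdomen: Signal

    def __init__(self, thorax: Signal, abdomen: Signal, rate: float | None = None):
        if rate is None:
            rate = max(thorax.rate, abdomen.rate)
        thorax = thorax.resample(rate)
        abdomen = abdomen.resample(rate)
        t0 = max(thorax.start_time, abdomen.start_time)
        t1 = min(thorax.end_time, abdomen.end_time)
        if t1 <= t0:
            raise ValueError("belt channels do not overlap in time")
        n = int(round((t1 - t0) * rate))

        def trim(s: Signal) -> Signal:
            i0 = int(round((t0 - s.start_time) * rate))
            return replace(s, samples=s.samples[i0:i0 + n], start_time=t0,
                           bad_spans=list(s.bad_spans))

        self.thorax = trim(thorax)
        self.abdomen = trim(abdomen)

    @property
    def rate(self) -> float:
        return self.thorax.rate

    @property
    def n(self) -> int:
        return self.thorax.n

    @property
    def start_time(self) -> float:
        return self.thorax.start_time

    @property
    def duration(self) -> float:
        return self.thorax.duration

    def times(self) -> np.ndarray:
        return self.thorax.times()

    def bad_spans(self) -> list:
        return sorted(self.thorax.bad_spans + self.abdomen.bad_spans)


def lowpass(sig: Signal, cutoff_hz: float, order: int = 4) -> Signal:
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sig.rate, output="sos")
    out = sps.sosfiltfilt(sos, sig.samples)
    return replace(sig, samples=out, bad_spans=list(sig.bad_spans))


def rolling_median_baseline(x: np.ndarray, window_n: int) -> np.ndarray:
    """Centered rolling-median baseline (pandas skiplist implementation)."""
    import pandas as pd

    w = max(int(window_n) | 1, 3)
    return (
        pd.Series(x).rolling(w, center=True, min_periods=1).median().to_numpy()
    )
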