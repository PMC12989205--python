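"""EDF/EDF+ reading and writing.

Reading goes through :func:`mne.io.read_raw_edf`; channel resolution is a
case-insensitive substring match against user-supplied (or default) label
patterns.  Writing — needed so the simulator can emit standard files — uses a
minimal EDF writer: 16-bit samples, 1-second data records, physical scaling
from the per-channel data range.
"""

from __future__ import annotations

import numpy as np

from .signals import BeltPair, Signal

#: default label patterns, matched case-insensitively as substrings
DEFAULT_CHANNEL_MAP = {
    "thorax": ("thorax", "thor", "chest", "rib"),
    "abdomen": ("abdomen", "abdo", "abd"),
    "flow": ("flow", "pneumo", "pnasal", "cannula"),
}


class ChannelResolutionError(ValueError):
    """Raised when a required channel cannot be resolved unambiguously."""


def _resolve(names: list[str], patterns: tuple[str, ...], role: str,
             required: bool) -> str | None:
    hits = [n for n in names if any(p.lower() in n.lower() for p in patterns)]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        if required:
            raise ChannelResolutionError(
                f"no channel matching {role!r} (patterns {patterns}); "
                f"found channels: {names}"
            )
        return None
    raise ChannelResolutionError(
        f"ambiguous {role!r} channels {hits}; pass an explicit channel_map"
    )


def read_edf(path, channel_map: dict | None = None, resample_hz: float = 25.0
             ) -> tuple[BeltPair, Signal | None]:
    """Read an EDF file into a (BeltPair, optional flow Signal) pair.

    Parameters
    ----------
    path : str or Path
    channel_map : dict, optional
        Maps roles ``thorax``/``abdomen``/``flow`` either to exact channel
        names or to tuples of substring patterns; unspecified roles fall back
        to :data:`DEFAULT_CHANNEL_MAP`.
    resample_hz : float
        Common rate all channels are brought to (polyphase resampling).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    cmap = dict(DEFAULT_CHANNEL_MAP)
    for role, val in (channel_map or {}).items():
        cmap[role] = (val,) if isinstance(val, str) else tuple(val)

    picked = {}
    for role, required in (("thorax", True), ("abdomen", True), ("flow", False)):
        name = _resolve(names, cmap[role], role, required)
        if name is not None:
            data = raw.get_data(picks=[name])[0]
            picked[role] = Signal(data, rate=float(raw.info["sfreq"]),
                                  label=name).resample(resample_hz)

    belts = BeltPair(picked["thorax"], picked["abdomen"], rate=resample_hz)
    return belts, picked.get("flow")


def _pad(s: str, width: int) -> bytes:
    b = s.encode("ascii")[:width]
    return b.ljust(width)


def write_edf(path, signals: list[Signal], start_date: str = "01.01.20",
              start_time: str = "00.00.00") -> None:
    """Write signals to an EDF file (1 s records, int16, shared duration).

    All signals must share ``start_time=0`` and an integer samples/second
    rate; the recording is padded to a whole number of seconds by repeating
    the final sample.
    """
    rates = [s.rate for s in signals]
    if any(abs(r - round(r)) > 1e-9 for r in rates):
        raise ValueError("EDF writer requires integer sample rates")
    n_rec = int(np.ceil(max(s.duration for s in signals)))
    n_sig = len(signals)

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2020 X X X", 80),
        _pad(start_date, 8),
        _pad(start_time, 8),
        _pad(str(256 * (n_sig + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(n_sig), 4),
    ])

    phys = []
    for s in signals:
        lo, hi = float(np.min(s.samples)), float(np.max(s.samples))
        if hi <= lo:
            hi = lo + 1.0
        # widen slightly so rounding never exceeds the digital range
        span = hi - lo
        phys.append((lo - 1e-4 * span, hi + 1e-4 * span))

    fields = [
        [_pad(s.label or f"ch{i}", 16) for i, s in enumerate(signals)],
        [_pad("", 80)] * n_sig,
        [_pad(s.units[:8], 8) for s in signals],
        [_pad(f"{lo:.6g}"[:8], 8) for lo, _ in phys],
        [_pad(f"{hi:.6g}"[:8], 8) for _, hi in phys],
        [_pad("-32768", 8)] * n_sig,
        [_pad("32767", 8)] * n_sig,
        [_pad("", 80)] * n_sig,
        [_pad(str(int(round(s.rate))), 8) for s in signals],
        [_pad("", 32)] * n_sig,
    ]
    header += b"".join(b"".join(f) for f in fields)

    with open(path, "wb") as fh:
        fh.write(header)
        sprs = [int(round(s.rate)) for s in signals]
        for r in range(n_rec):
            for s, spr, (lo, hi) in zip(signals, sprs, phys):
                chunk = s.samples[r * spr:(r + 1) * spr]
                if chunk.size < spr:
                    fill = chunk[-1] if chunk.size else lo
                    chunk = np.concatenate([chunk, np.full(spr - chunk.size, fill)])
                dig = np.round((chunk - lo) / (hi - lo) * 65535.0 - 32768.0)
                fh.write(dig.astype("<i2").tobytes())
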