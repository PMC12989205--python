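"""CSV/JSON tables for breaths, events and traits.

The breath table is the package's interchange format: write/read round-trips
every field at full float precision, extra columns are ignored, and a missing
required column raises a schema error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .breaths import Breath

BREATH_COLUMNS = ["onset_s", "end_s", "tidal_volume", "ventilation",
                  "percent_eupnea", "r", "imputed"]


class SchemaError(ValueError):
    pass


def breaths_to_frame(breaths: list[Breath]) -> pd.DataFrame:
    return pd.DataFrame({
        "onset_s": [b.onset_s for b in breaths],
        "end_s": [b.end_s for b in breaths],
        "tidal_volume": [b.tidal_volume for b in breaths],
        "ventilation": [b.ventilation for b in breaths],
        "percent_eupnea": [b.percent_eupnea for b in breaths],
        "r": [b.paradox_r for b in breaths],
        "imputed": [bool(b.imputed) for b in breaths],
    }, columns=BREATH_COLUMNS)


def frame_to_breaths(df: pd.DataFrame) -> list[Breath]:
    missing = [c for c in BREATH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"breath table missing columns: {missing}")
    return [
        Breath(
            onset_s=float(row.onset_s), end_s=float(row.end_s),
            tidal_volume=float(row.tidal_volume),
            ventilation=float(row.ventilation),
            percent_eupnea=float(row.percent_eupnea),
            paradox_r=float(row.r), imputed=bool(row.imputed),
        )
        for row in df.itertuples()
    ]


def write_breath_table(breaths: list[Breath], path) -> None:
    # 17 significant digits: float64 round-trips losslessly through text
    breaths_to_frame(breaths).to_csv(path, index=False, float_format="%.17g")


def read_breath_table(path) -> list[Breath]:
    return frame_to_breaths(pd.read_csv(path, float_precision="round_trip"))


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame({
        "start_s": [e.start_s for e in events],
        "end_s": [e.end_s for e in events],
        "duration_s": [e.duration_s for e in events],
        "nadir": [e.nadir_ventilation for e in events],
        "depth": [e.depth for e in events],
    })


def write_event_table(events, path) -> None:
    events_to_frame(events).to_csv(path, index=False, float_format="%.17g")


def trait_to_dict(traits) -> dict:
    return {
        "average_event_depth": traits.average_event_depth,
        "mean_event_duration_min": traits.mean_event_duration_min,
        "event_rate_per_hr": traits.event_rate_per_hr,
        "ventilatory_burden": traits.ventilatory_burden,
        "n_events": traits.n_events,
    }


def signal_to_frame(samples: np.ndarray, rate: float) -> pd.DataFrame:
    return pd.DataFrame({"t": np.arange(len(samples)) / rate, "value": samples})
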