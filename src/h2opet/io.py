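"""Plain-text interchange helpers for TAC tables and fit results."""

from __future__ import annotations

import json

import pandas as pd

from . import __version__
from .errors import SchemaError
from .kinetics import FrameSchedule, TimeActivityCurve

TAC_COLUMNS = ("frame_start_s", "frame_duration_s", "activity_kBq_per_mL")


def write_tac_csv(path, tac: TimeActivityCurve) -> None:
    pd.DataFrame({
        "frame_start_s": tac.schedule.frame_start,
        "frame_duration_s": tac.schedule.frame_duration,
        "activity_kBq_per_mL": tac.activity,
    }).to_csv(path, index=False)


def read_tac_csv(path, decay_corrected: bool = True) -> TimeActivityCurve:
    df = pd.read_csv(path)
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"TAC table missing columns: {missing}")
    schedule = FrameSchedule(df.frame_start_s.to_numpy(float),
                             df.frame_duration_s.to_numpy(float))
    return TimeActivityCurve(schedule, df.activity_kBq_per_mL.to_numpy(float),
                             decay_corrected)


def write_fit_json(path, payload: dict, seed: int | None = None) -> None:
    """Persist a fit-result dict with software version and seed attached."""
    body = {"software": "h2opet", "version": __version__, "seed": seed, **payload}
    with open(path, "w") as fh:
        json.dump(body, fh, indent=2)
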