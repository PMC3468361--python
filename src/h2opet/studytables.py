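"""Per-patient study records: the seven-patient observed dataset.

The observed cohort (seven patients with advanced malignancies on sunitinib
50 mg/day, schedule 4/2) is packaged here as a typed fixture: week-2 tumour
perfusion and FDG-SUV changes, week-4 metabolic response, week-12 radiological
labels, treatment duration, clinical benefit, day-15 drug trough levels and
day-15:day-1 plasma biomarker ratios.  Biomarker ratios are missing for
patients 6 and 7.  These records drive the cohort statistics and their tests.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import pandas as pd

from .errors import SchemaError


@dataclass(frozen=True)
class PatientRecord:
    patient_id: int
    primary_tumour: str
    reference_site: str
    baseline_perfusion: float        # mL/g/min
    perfusion_change_pct: float      # week 2 vs baseline
    baseline_fdg_suv: float
    suv_change_wk2_pct: float
    suv_change_wk4_pct: float
    fdg_pet_response: bool           # overall metabolic response at week 4
    radiological_response_lesion: str  # RECIST, reference lesion, week 12
    radiological_response_overall: str
    duration_cycles: int             # 6-week treatment cycles
    clinical_benefit: bool
    trough_ng_ml: float              # day-15 sunitinib + SU12662
    vegf_d15_d1: float | None
    svegfr2_d15_d1: float | None


_RECORDS = (
    PatientRecord(1, "Renal", "Right hepatic lobe", 0.81, -85, 4.6, -39, -48,
                  True, "SD", "SD", 4, True, 76.4, 5.29, 0.66),
    PatientRecord(2, "Colon", "Right hepatic lesion", 1.18, -77, 6.5, -37, -59,
                  True, "SD", "SD", 6, True, 134.9, 4.85, 0.44),
    PatientRecord(3, "Colon", "Right hepatic lobe", 1.52, -59, 4.2, -33, -29,
                  True, "PD", "PD", 2, False, 90.8, 8.67, 0.34),
    PatientRecord(4, "Colon", "Right hepatic lobe", 1.28, -34, 9.8, -44, -13,
                  True, "PD", "PD", 2, False, 27.6, 2.56, 0.75),
    PatientRecord(5, "NSCLC", "Left lung lesion", 0.74, -69, 12.3, -67, -66,
                  True, "SD", "SD", 12, True, 107.1, 4.17, 0.49),
    PatientRecord(6, "Colon", "Right hepatic lesion", 1.39, -38, 6.0, -32, -18,
                  True, "SD", "SD", 7, True, 88.8, None, None),
    PatientRecord(7, "Oesophageal", "Right hepatic dome", 1.23, -20, 4.1, -29, -41,
                  False, "PD", "PD", 2, False, 105.0, None, None),
)

REQUIRED_COLUMNS = tuple(PatientRecord.__dataclass_fields__)


def fixture_table() -> list[PatientRecord]:
    """The seven observed patient records, exactly as printed (missing
    biomarker ratios preserved as None)."""
    return list(_RECORDS)


def to_dataframe(records=None) -> pd.DataFrame:
    records = fixture_table() if records is None else list(records)
    return pd.DataFrame([asdict(r) for r in records])


def from_dataframe(df: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        kw = {c: getattr(row, c) for c in REQUIRED_COLUMNS}
        for c in ("vegf_d15_d1", "svegfr2_d15_d1"):
            v = kw[c]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                kw[c] = None
            else:
                kw[c] = float(v)
        kw["patient_id"] = int(kw["patient_id"])
        kw["duration_cycles"] = int(kw["duration_cycles"])
        for c in ("fdg_pet_response", "clinical_benefit"):
            kw[c] = bool(kw[c])
        records.append(PatientRecord(**kw))
    return records


def write_csv(path, records=None) -> None:
    to_dataframe(records).to_csv(path, index=False)


def read_csv(path) -> list[PatientRecord]:
    return from_dataframe(pd.read_csv(path))
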