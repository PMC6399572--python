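"""Patient-table helpers: score EQ-5D columns and summarize QALY gains by arm."""

from __future__ import annotations

import pandas as pd

from .outcomes import DIMENSIONS, EQ5DState, QALYRecord, TariffCoefficients, arm_mean_qaly, score_eq5d
from .stats import two_sample_t

__all__ = ["qaly_records_from_patients", "trial_qaly_summary"]


def _state(row: pd.Series, when: str) -> EQ5DState:
    levels = []
    for dim in DIMENSIONS:
        value = row[f"eq5d_{dim}_{when}"]
        levels.append(None if pd.isna(value) else int(value))
    vas = row.get(f"eq5d_vas_{when}")
    return EQ5DState.from_levels(levels, vas=None if pd.isna(vas) else float(vas))


def qaly_records_from_patients(
    patients: pd.DataFrame, tariff: TariffCoefficients, duration_years: float = 1.0
) -> list[QALYRecord]:
    records = []
    for _, row in patients.iterrows():
        u0 = score_eq5d(_state(row, "baseline"), tariff)
        u1 = score_eq5d(_state(row, "followup"), tariff)
        records.append(QALYRecord(str(row["patient_id"]), u0, u1, duration_years))
    return records


def trial_qaly_summary(
    patients: pd.DataFrame, tariff: TariffCoefficients, duration_years: float = 1.0
) -> dict:
    """Per-arm mean QALY gain over complete pairs, with a two-sample t test."""
    out: dict = {"source": "patient table"}
    gains = {}
    for arm in ("standard", "telemedicine"):
        records = qaly_records_from_patients(
            patients[patients["arm"] == arm], tariff, duration_years)
        mean, sd, n = arm_mean_qaly(records)
        out[arm] = {"mean_gain": mean, "sd": sd, "n_complete": n}
        gains[arm] = [r.qaly_gain for r in records if r.complete]
    test = two_sample_t(gains["standard"], gains["telemedicine"])
    out["p_value"] = test.p_value
    out["difference"] = out["telemedicine"]["mean_gain"] - out["standard"]["mean_gain"]
    return out
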