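"""Shared long-format study CSV schema.

One row per reading:

    participant_id, device_role {test,reference}, reading_index,
    timestamp_s, pwv_ms

plus per-participant columns repeated on every row of that participant:
demographics (age, sex, bmi, rhythm, vasoactive_meds, hours_since_dose,
relevant_stenosis, severe_aortic_stenosis, palpable_arteries), the session
mode, and hemodynamic context (hr/sbp/dbp before and after). Schema
validation is strict and errors carry participant ids.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import MeasurementSession, Reading
from .errors import ValidationDataError
from .screening import ParticipantRecord

__all__ = ["write_study_csv", "read_study_csv", "study_to_frame",
           "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = (
    "participant_id", "device_role", "reading_index", "timestamp_s", "pwv_ms",
    "age", "sex", "bmi", "rhythm", "vasoactive_meds", "hours_since_dose",
    "relevant_stenosis", "severe_aortic_stenosis", "palpable_arteries",
    "mode", "hr_before", "hr_after", "sbp_before", "sbp_after",
    "dbp_before", "dbp_after",
)

_BOOL_COLS = ("vasoactive_meds", "relevant_stenosis",
              "severe_aortic_stenosis", "palpable_arteries")


def study_to_frame(records: Sequence[ParticipantRecord],
                   sessions: Sequence[MeasurementSession]) -> pd.DataFrame:
    """Flatten (participant, session) pairs into the long-format frame."""
    by_id = {r.id: r for r in records}
    rows = []
    for s in sessions:
        rec = by_id.get(s.participant_id)
        if rec is None:
            raise ValidationDataError("session without participant record",
                                      participant_id=s.participant_id)
        base = {
            "participant_id": rec.id, "age": rec.age, "sex": rec.sex,
            "bmi": rec.bmi, "rhythm": rec.rhythm,
            "vasoactive_meds": rec.vasoactive_meds,
            "hours_since_dose": rec.hours_since_dose,
            "relevant_stenosis": rec.relevant_stenosis,
            "severe_aortic_stenosis": rec.severe_aortic_stenosis,
            "palpable_arteries": rec.palpable_arteries,
            "mode": s.mode,
            "hr_before": s.hr_before, "hr_after": s.hr_after,
            "sbp_before": s.sbp_before, "sbp_after": s.sbp_after,
            "dbp_before": s.dbp_before, "dbp_after": s.dbp_after,
        }
        for role, readings in (("test", s.test_readings),
                               ("reference", s.reference_readings)):
            for idx, r in enumerate(readings, start=1):
                rows.append({**base, "device_role": role, "reading_index": idx,
                             "timestamp_s": r.timestamp, "pwv_ms": r.pwv})
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_study_csv(records: Sequence[ParticipantRecord],
                    sessions: Sequence[MeasurementSession], path) -> None:
    study_to_frame(records, sessions).to_csv(path, index=False)


def _opt(value):
    return None if pd.isna(value) else float(value)


def read_study_csv(path) -> tuple[list[ParticipantRecord],
                                  list[MeasurementSession]]:
    """Parse the long-format study CSV back into records and sessions.

    Per-participant reference PWV (mean of the reference readings) is
    filled into each :class:`ParticipantRecord`.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationDataError(f"missing required columns: {missing}")
    bad_roles = set(df["device_role"].unique()) - {"test", "reference"}
    if bad_roles:
        raise ValidationDataError(f"unknown device_role values: {bad_roles}")
    records: list[ParticipantRecord] = []
    sessions: list[MeasurementSession] = []
    for pid, grp in df.groupby("participant_id", sort=False):
        first = grp.iloc[0]
        for col in ("age", "sex", "bmi", "mode"):
            if grp[col].nunique() > 1:
                raise ValidationDataError(
                    f"inconsistent {col} across rows", participant_id=str(pid))
        readings = {}
        for role in ("test", "reference"):
            sub = grp[grp["device_role"] == role].sort_values("reading_index")
            readings[role] = tuple(
                Reading(timestamp=float(r.timestamp_s), pwv=float(r.pwv_ms))
                for r in sub.itertuples())
        ref_pwv = (float(np.mean([r.pwv for r in readings["reference"]]))
                   if readings["reference"] else None)
        records.append(ParticipantRecord(
            id=str(pid), age=float(first["age"]), sex=str(first["sex"]),
            bmi=float(first["bmi"]), rhythm=str(first["rhythm"]),
            vasoactive_meds=bool(first["vasoactive_meds"]),
            hours_since_dose=_opt(first["hours_since_dose"]),
            relevant_stenosis=bool(first["relevant_stenosis"]),
            severe_aortic_stenosis=bool(first["severe_aortic_stenosis"]),
            palpable_arteries=bool(first["palpable_arteries"]),
            reference_pwv=ref_pwv))
        sessions.append(MeasurementSession(
            participant_id=str(pid), mode=str(first["mode"]),
            test_readings=readings["test"],
            reference_readings=readings["reference"],
            hr_before=_opt(first["hr_before"]), hr_after=_opt(first["hr_after"]),
            sbp_before=_opt(first["sbp_before"]),
            sbp_after=_opt(first["sbp_after"]),
            dbp_before=_opt(first["dbp_before"]),
            dbp_after=_opt(first["dbp_after"])))
    return records, sessions
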