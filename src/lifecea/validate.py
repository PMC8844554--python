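"""Input-table validation.

`validate_tables` checks column presence, value ranges, time monotonicity
and referential integrity across the patient-level tables and returns a
violation report (one row per problem, naming the table, patient and
column).  It never raises on bad data — the caller decides fatality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import EQ5D_DIMENSIONS, TrialData

_REQUIRED = {
    "patients": ["patient_id", "arm", "age", "sex", "followup_end"],
    "utilities": ["patient_id", "visit_time", "instrument", *EQ5D_DIMENSIONS],
    "resource_use": [
        "patient_id", "period_start", "period_end", "inpatient_days",
        "outpatient_visits", "study_drug_doses",
    ],
    "events": ["patient_id", "event", "time"],
}


def validate_tables(data: TrialData) -> pd.DataFrame:
    """Return a violation report; empty frame means the tables are well formed."""
    rows: list[tuple] = []

    def add(table, pid, column, message):
        rows.append((table, pid, column, message))

    tables = {
        "patients": data.patients,
        "utilities": data.utilities,
        "resource_use": data.resource_use,
        "events": data.events,
    }
    for name, required in _REQUIRED.items():
        missing = [c for c in required if c not in tables[name].columns]
        for c in missing:
            add(name, "", c, "required column missing")
    if rows:
        return _report(rows)

    pat = data.patients
    ids = set(pat["patient_id"])
    if pat["patient_id"].duplicated().any():
        for pid in pat.loc[pat["patient_id"].duplicated(), "patient_id"]:
            add("patients", pid, "patient_id", "duplicate patient id")
    for _, r in pat.iterrows():
        if not r["age"] > 0:
            add("patients", r["patient_id"], "age", "age must be positive")
        if not r["followup_end"] > 0:
            add("patients", r["patient_id"], "followup_end", "follow-up must be positive")
        if "diabetes_duration" in pat.columns and r["diabetes_duration"] < 0:
            add("patients", r["patient_id"], "diabetes_duration", "must be non-negative")
        if not pd.isna(r.get("death_time")) and r["death_time"] > r["followup_end"] + 1e-9:
            add("patients", r["patient_id"], "death_time", "death after end of follow-up")

    fu = pat.set_index("patient_id")["followup_end"]
    for _, r in data.utilities.iterrows():
        pid = r["patient_id"]
        if pid not in ids:
            add("utilities", pid, "patient_id", "unknown patient id")
            continue
        if r["visit_time"] < 0 or r["visit_time"] > fu[pid] + 1e-9:
            add("utilities", pid, "visit_time", "visit outside follow-up")
        top = 3 if r["instrument"] == "EQ5D3L" else 5
        for dim in EQ5D_DIMENSIONS:
            v = r[dim]
            if not pd.isna(v) and not (1 <= v <= top):
                add("utilities", pid, dim, f"level outside 1-{top}")

    ru = data.resource_use
    for col in ("inpatient_days", "outpatient_visits", "study_drug_doses"):
        bad = ru[ru[col] < 0]
        for _, r in bad.iterrows():
            add("resource_use", r["patient_id"], col, "negative count")
    unknown = ru[~ru["patient_id"].isin(ids)]
    for _, r in unknown.iterrows():
        add("resource_use", r["patient_id"], "patient_id", "unknown patient id")
    for pid, grp in ru.groupby("patient_id"):
        g = grp.sort_values("period_start")
        if (g["period_end"].to_numpy()[:-1] > g["period_start"].to_numpy()[1:] + 1e-9).any():
            add("resource_use", pid, "period_start", "overlapping periods")

    for _, r in data.events.iterrows():
        if r["patient_id"] not in ids:
            add("events", r["patient_id"], "patient_id", "unknown patient id")
        elif r["time"] > fu[r["patient_id"]] + 1e-9:
            add("events", r["patient_id"], "time", "event after end of follow-up")
    return _report(rows)


def _report(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["table", "patient_id", "column", "message"])
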