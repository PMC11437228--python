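"""Cohort data model, eligibility filtering, service linkage and outcomes.

The in-memory representation is deliberately plain: a wide per-patient
:class:`pandas.DataFrame` (one row per preoperative evaluation) plus a long
events table ``(patient_id, event_type, date)`` holding both preoperative
service events (consultation, echocardiogram, stress test, catheterization)
and postoperative outcome events (MI, revascularization, acute CHF, death,
ICU stay, ED visit, readmission). :class:`CohortTable` pairs the two.

Column dictionary (wide table)
------------------------------
patient_id            opaque string identifier
visit_date            date of the preoperative-center visit (ISO date)
surgery_date          date of the index surgery (>= visit_date)
age                   integer years, >= 18
sex                   "male" | "female"
race                  "Asian" | "African American" | "White" |
                      "American Indian" | "Others"
hispanic              bool
atrial_fibrillation, cad, chf, cva_tia, ckd, diabetes
                      comorbidity booleans
mets_lt4              bool, functional capacity below 4 METS
asa_class             int 1-4 (ASA physical status)
rcri_*                six boolean RCRI components (see ``preopcard.risk``)
mica_risk_pct         Gupta MICA predicted MACE risk, percent in [0, 100]
nsqip_risk_pct        optional externally supplied risk percent (may be NaN)
surgical_risk         "low" | "moderate" | "high"
active_cardiac_condition, cardiac_disease_unclear_status, ischemia_concern,
ecg_flag, testing_may_change_management
                      clinical flags feeding the risk algorithm
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import PRE, POST, StudyConfig, _as_date

SERVICES = ("consult", "echo", "stress", "cath")
OUTCOMES = ("mi", "revasc", "chf_acute", "death", "icu", "ed_visit", "readmission")
MACE_COMPONENTS = ("mi", "revasc", "chf_acute", "death")

SEXES = ("male", "female")
RACES = ("Asian", "African American", "White", "American Indian", "Others")
SURGICAL_RISK_LEVELS = ("low", "moderate", "high")

COMORBIDITIES = ("atrial_fibrillation", "cad", "chf", "cva_tia", "ckd", "diabetes")

RCRI_COLUMNS = (
    "rcri_high_risk_surgery",
    "rcri_ischemic_heart_disease",
    "rcri_chf_history",
    "rcri_cerebrovascular_disease",
    "rcri_insulin_treated_diabetes",
    "rcri_creatinine_gt_2mgdl",
)

CLINICAL_FLAGS = (
    "active_cardiac_condition",
    "cardiac_disease_unclear_status",
    "ischemia_concern",
    "ecg_flag",
    "testing_may_change_management",
)

#: columns whose absence means "missing preoperative risk scores"
RISK_SCORE_COLUMNS = RCRI_COLUMNS + ("mica_risk_pct", "mets_lt4", "asa_class")

DATE_COLUMNS = ("visit_date", "surgery_date")


@dataclass
class ExclusionAccounting:
    """Bookkeeping for eligibility filtering.

    Invariant: ``n_final == n_screened - n_duplicates - n_missing_scores``.
    """

    n_screened: int = 0
    n_duplicates: int = 0
    n_missing_scores: int = 0

    @property
    def n_final(self) -> int:
        return self.n_screened - self.n_duplicates - self.n_missing_scores

    def validate(self) -> None:
        for name in ("n_screened", "n_duplicates", "n_missing_scores"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_final < 0:
            raise ValueError("exclusions exceed screened count")


@dataclass
class CohortTable:
    """Wide patient table plus long events table."""

    patients: pd.DataFrame
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["patient_id", "event_type", "date"]
        )
    )

    def __len__(self) -> int:
        return len(self.patients)


def _coerce_dates(df: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    df = df.copy()
    for c in columns:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c]).dt.date
    return df


def read_cohort(patients_csv: str | Path, events_csv: str | Path | None = None) -> CohortTable:
    """Load a cohort from delimited flat files.

    ``patients_csv`` is the wide per-patient file; ``events_csv`` (optional)
    is the long ``patient_id,event_type,date`` file.
    """
    patients = pd.read_csv(patients_csv)
    patients = _coerce_dates(patients, DATE_COLUMNS)
    if events_csv is not None:
        events = pd.read_csv(events_csv)
        events = _coerce_dates(events, ["date"])
    else:
        events = pd.DataFrame(columns=["patient_id", "event_type", "date"])
    return CohortTable(patients=patients, events=events)


def write_cohort(cohort: CohortTable, patients_csv: str | Path, events_csv: str | Path | None = None) -> None:
    cohort.patients.to_csv(patients_csv, index=False)
    if events_csv is not None:
        cohort.events.to_csv(events_csv, index=False)


def apply_exclusions(patients: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionAccounting]:
    """Remove duplicate visits and records with missing risk-tool fields.

    Duplicates are repeated ``(patient_id, surgery_date)`` rows; the
    chronologically first visit is kept (ties broken by input order).
    A record is "missing scores" when any RCRI component, the MICA risk,
    the METS class, or the ASA class is absent. Duplicate removal happens
    first, so the accounting identity
    ``n_final = n_screened - n_duplicates - n_missing_scores`` holds exactly.
    """
    acct = ExclusionAccounting(n_screened=len(patients))
    if len(patients) == 0:
        return patients.copy(), acct

    df = patients.copy()
    order = np.arange(len(df))
    df = df.assign(_ingest=order)
    df = df.sort_values(["patient_id", "surgery_date", "visit_date", "_ingest"],
                        kind="stable")
    keep = ~df.duplicated(subset=["patient_id", "surgery_date"], keep="first")
    acct.n_duplicates = int((~keep).sum())
    df = df[keep]

    present = [c for c in RISK_SCORE_COLUMNS if c in df.columns]
    missing_cols = [c for c in RISK_SCORE_COLUMNS if c not in df.columns]
    if missing_cols:
        # a wholly absent column means every remaining row lacks that score
        miss = pd.Series(True, index=df.index)
    else:
        miss = df[present].isna().any(axis=1)
    acct.n_missing_scores = int(miss.sum())
    df = df[~miss]

    df = df.sort_values("_ingest", kind="stable").drop(columns="_ingest")
    acct.validate()
    assert len(df) == acct.n_final
    return df.reset_index(drop=True), acct


def assign_period(visit_date, cutover_date) -> str:
    """Dichotomize a visit into the pre or post period.

    *pre* iff the visit is strictly before the cutover date; *post*
    otherwise (the cutover day itself opens the post period).
    """
    return PRE if _as_date(visit_date) < _as_date(cutover_date) else POST


def add_period(patients: pd.DataFrame, config: StudyConfig | None = None) -> pd.DataFrame:
    """Attach ``period`` and ``in_window`` columns.

    Visits outside ``[study_start, study_end]`` are flagged
    ``in_window=False`` and should be excluded from analysis.
    """
    config = config or StudyConfig()
    df = patients.copy()
    visits = pd.to_datetime(df["visit_date"]).dt.date
    df["period"] = np.where(visits < config.cutover, PRE, POST)
    df["in_window"] = [
        config.study_start <= v <= config.study_end for v in visits
    ]
    return df


def _flag_events(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    event_types: Iterable[str],
    lo: int,
    hi: int,
) -> pd.DataFrame:
    """Flag, per patient and event type, any event with day offset in [lo, hi].

    The offset is ``(event_date - surgery_date)`` in days; preoperative
    windows use negative offsets. Multiple qualifying events collapse to a
    single flag, so the result is invariant to event ordering.
    """
    out = pd.DataFrame(
        False, index=patients.index, columns=list(event_types)
    )
    if len(events) == 0 or len(patients) == 0:
        return out
    surg = pd.Series(
        pd.to_datetime(patients["surgery_date"]).values,
        index=patients["patient_id"].values,
    )
    ev = events[events["event_type"].isin(list(event_types))].copy()
    ev = ev[ev["patient_id"].isin(surg.index)]
    if len(ev) == 0:
        return out
    ev_dates = pd.to_datetime(ev["date"])
    offsets = (ev_dates.values - surg.loc[ev["patient_id"]].values) / np.timedelta64(1, "D")
    ev = ev.assign(_off=offsets)
    ev = ev[(ev["_off"] >= lo) & (ev["_off"] <= hi)]
    if len(ev) == 0:
        return out
    pid_to_pos = pd.Series(np.arange(len(patients)), index=patients["patient_id"].values)
    col_to_pos = {c: i for i, c in enumerate(out.columns)}
    rows = pid_to_pos.loc[ev["patient_id"]].to_numpy()
    cols = np.array([col_to_pos[t] for t in ev["event_type"]])
    vals = out.to_numpy()
    vals[rows, cols] = True
    return pd.DataFrame(vals, index=patients.index, columns=out.columns)


def link_preop_services(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    window_days: int = 60,
) -> pd.DataFrame:
    """Per-patient preoperative service flags.

    A service counts iff it occurred within ``window_days`` before surgery,
    day of surgery inclusive: ``0 <= surgery_date - event_date <= window``.
    Events after surgery are ignored. Returns one boolean column per service
    in :data:`SERVICES`, aligned with ``patients``.
    """
    return _flag_events(patients, events, SERVICES, lo=-window_days, hi=0)


def compute_30d_outcomes(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    window_days: int = 30,
) -> pd.DataFrame:
    """Per-patient 30-day outcome flags plus the MACE composite.

    An outcome counts iff ``0 < event_date - surgery_date <= window``.
    MACE is the union (not the sum) of acute MI, revascularization, acute
    CHF and all-cause death, so a patient with several component events
    contributes once.
    """
    flags = _flag_events(patients, events, OUTCOMES, lo=1, hi=window_days)
    flags["mace"] = flags[list(MACE_COMPONENTS)].any(axis=1)
    return flags
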