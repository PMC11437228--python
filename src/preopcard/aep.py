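"""Deterministic preoperative cardiac risk algorithm (AEP engine).

Each patient is routed through a fixed sequence of gates and stops at
exactly one algorithm end point (AEP). The gates, in order:

1. active cardiac condition            -> AEP 1, cardiology before surgery
2. known cardiac disease, unclear status -> AEP 2, consider cardiology
3. concern for myocardial ischemia     -> AEP 3, consider cardiology
4. new/unworked-up abnormal ECG        -> AEP 4, consider cardiology
5. low-risk surgery                    -> AEP 5, proceed
6. RCRI score 0 and age < 65           -> AEP 6, proceed
7. MICA (or supplied NSQIP) risk < 1%  -> AEP 7, proceed
8. elevated risk but METS >= 4         -> AEP 8, proceed
9. elevated risk, poor capacity, testing may change management
                                       -> AEP 9, consider cardiology
   otherwise (testing would not change management)
                                       -> AEP 8, proceed (documented rationale)

"Possible indication for consultation" is AEP 1, 2, 3, 4 or 9; every other
end point is "no clear indication". The AEP-id numbering of the proceed
branches is held in one table (:data:`AEP_TABLE`) so renumbering cannot
affect the routing logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import math

import numpy as np
import pandas as pd

from .risk import is_low_risk_mica, is_low_risk_rcri_gate

CARDIOLOGY_BEFORE_SURGERY = "cardiology_before_surgery"
CONSIDER_CARDIOLOGY = "consider_cardiology"
PROCEED = "proceed_to_surgery"

POSSIBLE_INDICATION = "possible_indication"
NO_CLEAR_INDICATION = "no_clear_indication"

POSSIBLE_INDICATION_AEPS = frozenset({1, 2, 3, 4, 9})

#: aep_id -> (label, recommendation); the single place ids are defined
AEP_TABLE: dict[int, tuple[str, str]] = {
    1: ("active cardiac condition", CARDIOLOGY_BEFORE_SURGERY),
    2: ("known cardiac disease with unclear status", CONSIDER_CARDIOLOGY),
    3: ("concern for myocardial ischemia", CONSIDER_CARDIOLOGY),
    4: ("new ECG changes or abnormal ECG without workup", CONSIDER_CARDIOLOGY),
    5: ("low-risk surgery", PROCEED),
    6: ("RCRI score 0 and age under 65", PROCEED),
    7: ("estimated MACE risk under 1%", PROCEED),
    8: ("adequate functional capacity or testing unlikely to change management", PROCEED),
    9: ("elevated risk, poor capacity, testing may change management", CONSIDER_CARDIOLOGY),
}


class GateEvaluationError(ValueError):
    """A gate could not be evaluated because a required field is missing."""


@dataclass
class AEPResult:
    """Outcome of routing one patient through the algorithm."""

    aep_id: int
    label: str
    recommendation: str
    indication_class: str
    trace: list[tuple[str, str, object]] = field(default_factory=list)

    def trace_json(self) -> str:
        return json.dumps([list(step) for step in self.trace])


def indication_class(aep_id: int) -> str:
    """Dichotomize an end point: possible indication iff AEP 1-4 or 9."""
    if aep_id not in AEP_TABLE:
        raise ValueError(f"invalid AEP id: {aep_id}")
    return POSSIBLE_INDICATION if aep_id in POSSIBLE_INDICATION_AEPS else NO_CLEAR_INDICATION


def _result(aep_id: int, trace: list) -> AEPResult:
    label, rec = AEP_TABLE[aep_id]
    return AEPResult(aep_id=aep_id, label=label, recommendation=rec,
                     indication_class=indication_class(aep_id), trace=trace)


def _require(record: Mapping, key: str, gate: str):
    value = record.get(key, None)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise GateEvaluationError(f"gate {gate!r} needs field {key!r}")
    return value


def evaluate(record: Mapping) -> AEPResult:
    """Route one patient record to its algorithm end point.

    ``record`` is any mapping exposing the clinical flags, ``surgical_risk``,
    ``rcri_score``, ``age``, ``mica_risk_pct`` (or ``nsqip_risk_pct``),
    ``mets_lt4`` and ``testing_may_change_management``. Fields are only
    required at the gate that reads them; a missing field at an evaluated
    gate raises :class:`GateEvaluationError` naming the gate. The function
    is pure: the same record always yields the same result.
    """
    trace: list[tuple[str, str, object]] = []

    def gate(step: str, predicate: str, value) -> bool:
        trace.append((step, predicate, value))
        return bool(value)

    if gate("1", "active_cardiac_condition",
            _require(record, "active_cardiac_condition", "active cardiac condition")):
        return _result(1, trace)
    if gate("2", "cardiac_disease_unclear_status",
            _require(record, "cardiac_disease_unclear_status", "unclear cardiac status")):
        return _result(2, trace)
    if gate("3", "ischemia_concern",
            _require(record, "ischemia_concern", "ischemia concern")):
        return _result(3, trace)
    if gate("4", "ecg_flag", _require(record, "ecg_flag", "ECG flag")):
        return _result(4, trace)

    surgical = _require(record, "surgical_risk", "low-risk surgery")
    if gate("5", "surgical_risk == low", surgical == "low"):
        return _result(5, trace)

    score = int(_require(record, "rcri_score", "RCRI gate"))
    age = int(_require(record, "age", "RCRI gate"))
    if gate("6", "rcri_score == 0 and age < 65", is_low_risk_rcri_gate(score, age)):
        return _result(6, trace)

    # the externally supplied NSQIP percent, when present, stands in for MICA
    risk_pct = record.get("nsqip_risk_pct", None)
    if risk_pct is None or (isinstance(risk_pct, float) and math.isnan(risk_pct)):
        risk_pct = _require(record, "mica_risk_pct", "estimated MACE risk")
    if gate("7", "estimated MACE risk < 1%", is_low_risk_mica(float(risk_pct))):
        return _result(7, trace)

    poor_capacity = bool(_require(record, "mets_lt4", "functional capacity"))
    if gate("8", "METS >= 4", not poor_capacity):
        return _result(8, trace)

    if gate("9", "testing_may_change_management",
            _require(record, "testing_may_change_management", "testing utility")):
        return _result(9, trace)
    # elevated risk, poor capacity, but testing would not change management:
    # proceed, sharing AEP 8's proceed recommendation and indication class
    trace.append(("8*", "testing would not change management: proceed", True))
    return _result(8, trace)


def evaluate_frame(patients: pd.DataFrame) -> pd.DataFrame:
    """Vector convenience: evaluate every row, returning aep columns.

    Requires an ``rcri_score`` column (see :func:`preopcard.pipeline` which
    derives it from the six component columns). Returns a frame aligned with
    ``patients`` holding ``aep_id``, ``recommendation``, ``indication_class``
    and a JSON-encoded ``trace``.
    """
    rows = []
    for rec in patients.to_dict("records"):
        res = evaluate(rec)
        rows.append((res.aep_id, res.recommendation, res.indication_class,
                     res.trace_json()))
    return pd.DataFrame(
        rows, index=patients.index,
        columns=["aep_id", "recommendation", "indication_class", "trace"],
    )


def aep_outcome_table(aep_ids: pd.Series, mace: pd.Series) -> pd.DataFrame:
    """Per-AEP MACE counts and rates.

    Returns one row per AEP id 1-9 with ``n``, ``mace``, and ``mace_pct``
    (percent, NaN when the end point is empty). The ``n`` column partitions
    the cohort: it sums to the number of patients.
    """
    aep_ids = pd.Series(aep_ids).astype(int)
    mace = pd.Series(mace).astype(bool)
    rows = []
    for aep_id in sorted(AEP_TABLE):
        sel = aep_ids == aep_id
        n = int(sel.sum())
        k = int(mace[sel.to_numpy()].sum()) if n else 0
        pct = 100.0 * k / n if n else np.nan
        rows.append((aep_id, AEP_TABLE[aep_id][0], n, k, pct))
    out = pd.DataFrame(rows, columns=["aep_id", "label", "n", "mace", "mace_pct"])
    assert out["n"].sum() == len(aep_ids)
    return out
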