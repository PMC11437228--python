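"""Perioperative cardiac risk calculators and categorizations.

Three tools feed the decision algorithm:

* the Revised Cardiac Risk Index (RCRI), a count of six binary components,
  with the low-risk gate "score 0 and age under 65";
* the Gupta MICA logistic model, which maps patient and procedure features
  to a perioperative myocardial-infarction-or-cardiac-arrest risk percent,
  with risk below 1% classed as low;
* an institutional procedure-to-surgical-risk map (low / moderate / high).

The MICA model here is a generic logistic: published coefficient sets can be
loaded from a YAML file. The file shipped with the package
(``data/mica_synthetic.yaml``) is a synthetic illustration for testing, not
the published regression; see its header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import math

import pandas as pd
import yaml

RCRI_COMPONENT_NAMES = (
    "high_risk_surgery",
    "ischemic_heart_disease",
    "chf_history",
    "cerebrovascular_disease",
    "insulin_treated_diabetes",
    "creatinine_gt_2mgdl",
)

#: strict thresholds, per the rule wording ("<1%", "<4 METS", "<65 years")
MICA_LOW_RISK_PCT = 1.0
METS_POOR_THRESHOLD = 4.0
RCRI_GATE_AGE = 65


def rcri_score(components: Mapping[str, bool]) -> int:
    """Count of positive RCRI components (0-6).

    ``components`` must supply all six names in
    :data:`RCRI_COMPONENT_NAMES`; a missing or null component is an error
    because such records are excluded upstream.
    """
    total = 0
    for name in RCRI_COMPONENT_NAMES:
        if name not in components:
            raise ValueError(f"missing RCRI component: {name}")
        value = components[name]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"null RCRI component: {name}")
        total += bool(value)
    return total


def is_low_risk_rcri_gate(score: int, age: int) -> bool:
    """Low-risk gate: RCRI score of zero AND age strictly below 65 years."""
    if not 0 <= score <= 6:
        raise ValueError("RCRI score must be 0-6")
    if age < 18:
        raise ValueError("age must be >= 18")
    return score == 0 and age < RCRI_GATE_AGE


@dataclass(frozen=True)
class MICAModel:
    """Logistic risk model: ``risk = 100 * expit(intercept + sum coef*x)``."""

    intercept: float
    coefficients: Mapping[str, float]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MICAModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(intercept=float(raw["intercept"]),
                   coefficients={k: float(v) for k, v in raw["coefficients"].items()})


def mica_risk(model: MICAModel, features: Mapping[str, float]) -> float:
    """Predicted MACE risk percent from a logistic coefficient set.

    Every feature key must match a model coefficient; an unknown key raises
    by name so configuration errors surface immediately.
    """
    for key in features:
        if key not in model.coefficients:
            raise KeyError(f"unknown MICA feature: {key!r}")
    lp = model.intercept + sum(
        model.coefficients[k] * float(v) for k, v in features.items()
    )
    return 100.0 / (1.0 + math.exp(-lp))


def is_low_risk_mica(risk_pct: float) -> bool:
    """Low risk iff predicted MACE risk is strictly below 1%."""
    return risk_pct < MICA_LOW_RISK_PCT


def functional_capacity_class(mets: float) -> str:
    """Classify functional capacity: "poor" below 4 METS, else "adequate"."""
    if mets <= 0:
        raise ValueError("METS must be positive")
    return "poor" if mets < METS_POOR_THRESHOLD else "adequate"


def load_surgical_risk_map(path: str | Path) -> dict[str, str]:
    """Read a ``procedure,level`` CSV into a procedure→risk-level map."""
    df = pd.read_csv(path)
    bad = set(df["level"]) - {"low", "moderate", "high"}
    if bad:
        raise ValueError(f"invalid surgical risk levels: {sorted(bad)}")
    return dict(zip(df["procedure"].str.strip().str.lower(), df["level"]))


def surgical_risk_level(procedure: str, risk_map: Mapping[str, str]) -> str:
    """Look up a procedure's institutional risk level.

    An unmapped procedure is an error: the map must be configured
    explicitly rather than silently defaulting.
    """
    key = procedure.strip().lower()
    if key not in risk_map:
        raise KeyError(f"procedure not in surgical risk map: {procedure!r}")
    return risk_map[key]
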