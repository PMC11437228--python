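"""Seeded synthetic cohort generator.

Generates patient tables with the statistical structure the analysis
pipeline assumes: two calendar-defined periods, binary comorbidities and
risk-tool categories drawn marginally at configured prevalences, optional
confounding between covariates and period assignment, preoperative service
events placed inside the 60-day window, and 30-day outcome events.

The shipped specification ``data/table1_matched.yaml`` encodes the matched
cohort margins of the motivating study: arm sizes of 11,645, the matched
covariate prevalences, the matched service-utilization rates (consultation
23.2% vs 17.9%, echocardiogram 6.9% vs 5.1%, stress test 1.7% vs 1.6%,
catheterization 0.45% vs 0.38%) and the 30-day outcome rates.

Covariates are generated marginally (independently); real comorbidities are
correlated, so this emulates the reported margins, not the joint law.
Confounding is injected by re-assigning period labels via exponential
tilting: each record's odds of landing in the post arm are multiplied by
``exp(confounding_strength)`` per positive tilt covariate, with arm sizes
held exactly at ``n_pre``/``n_post`` (Gumbel top-k weighted sampling
without replacement).
"""

from __future__ import annotations

import copy
import datetime as dt
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CLINICAL_FLAGS,
    COMORBIDITIES,
    CohortTable,
    OUTCOMES,
    RCRI_COLUMNS,
    SERVICES,
)
from .config import PRE, POST, StudyConfig

#: binary covariates whose presence tilts a record toward the post arm
DEFAULT_TILT_COVARIATES = COMORBIDITIES + ("mets_lt4",)


def _per_period(value, period: str) -> float:
    """A rate may be a scalar (both periods) or a {pre:, post:} mapping."""
    if isinstance(value, Mapping):
        return float(value[period])
    return float(value)


def _check_prob(p: float, name: str) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of [0,1] for {name}: {p}")
    return p


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Rates given as scalars apply to both periods; mappings ``{pre:, post:}``
    give per-period values. ``confounding_strength`` is the per-covariate
    log-odds shift of post-period assignment (0 disables confounding).
    """

    n_pre: int = 1000
    n_post: int = 1000
    seed: int = 0
    age_quantiles: dict = dc_field(
        default_factory=lambda: {0.0: 18, 0.25: 53, 0.5: 64, 0.75: 72, 1.0: 95}
    )
    sex_female: object = 0.562
    race: dict = dc_field(
        default_factory=lambda: {
            "Asian": 0.012, "African American": 0.079, "White": 0.793,
            "American Indian": 0.004, "Others": 0.112,
        }
    )
    hispanic: object = 0.118
    comorbidities: dict = dc_field(
        default_factory=lambda: {
            "atrial_fibrillation": 0.080, "cad": 0.103, "chf": 0.033,
            "cva_tia": 0.040, "ckd": 0.102, "diabetes": 0.201,
        }
    )
    mets_lt4: object = 0.146
    asa_34: object = 0.350
    rcri_component_p: float = 0.066
    mica_median_pct: float = 0.27
    mica_sigma: float = 0.8
    surgical_risk: dict = dc_field(
        default_factory=lambda: {"low": 0.232, "moderate": 0.559, "high": 0.209}
    )
    flags: dict = dc_field(
        default_factory=lambda: {
            "active_cardiac_condition": 0.005,
            "cardiac_disease_unclear_status": 0.15,
            "ischemia_concern": 0.08,
            "ecg_flag": 0.10,
            "testing_may_change_management": 0.5,
        }
    )
    confounding_strength: float = 0.0
    tilt_covariates: tuple = DEFAULT_TILT_COVARIATES
    service_rates: dict = dc_field(
        default_factory=lambda: {
            "consult": {"pre": 0.232, "post": 0.179},
            "echo": {"pre": 0.069, "post": 0.051},
            "stress": {"pre": 0.017, "post": 0.016},
            "cath": {"pre": 0.0045, "post": 0.0038},
        }
    )
    outcome_rates: dict = dc_field(
        default_factory=lambda: {
            "mi": 0.0012, "revasc": {"pre": 0.00017, "post": 0.00043},
            "chf_acute": {"pre": 0.0019, "post": 0.0021}, "death": 0.0014,
            "icu": {"pre": 0.0145, "post": 0.0157},
            "ed_visit": {"pre": 0.058, "post": 0.054},
            "readmission": {"pre": 0.064, "post": 0.065},
        }
    )
    out_of_window_service_rate: float = 0.01
    study: StudyConfig = dc_field(default_factory=StudyConfig)

    def validate(self) -> None:
        if self.n_pre < 0 or self.n_post < 0:
            raise ValueError("arm sizes must be non-negative")
        for period in (PRE, POST):
            for name, rates in (("service", self.service_rates),
                                ("outcome", self.outcome_rates)):
                for key, value in rates.items():
                    _check_prob(_per_period(value, period), f"{name} {key}")
            for cov, value in self.comorbidities.items():
                _check_prob(_per_period(value, period), cov)
            for flag, value in self.flags.items():
                _check_prob(_per_period(value, period), flag)
            _check_prob(_per_period(self.sex_female, period), "sex_female")
            _check_prob(_per_period(self.hispanic, period), "hispanic")
            _check_prob(_per_period(self.mets_lt4, period), "mets_lt4")
            _check_prob(_per_period(self.asa_34, period), "asa_34")
        _check_prob(self.rcri_component_p, "rcri_component_p")
        _check_prob(self.out_of_window_service_rate, "out_of_window_service_rate")
        if abs(sum(self.race.values()) - 1.0) > 1e-6:
            raise ValueError("race probabilities must sum to 1")
        if abs(sum(self.surgical_risk.values()) - 1.0) > 1e-6:
            raise ValueError("surgical risk probabilities must sum to 1")


def load_spec(path: str | Path) -> CohortSpec:
    """Load a :class:`CohortSpec` from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return spec_from_dict(raw)


def spec_from_dict(raw: dict) -> CohortSpec:
    raw = copy.deepcopy(raw)
    raw.pop("name", None)
    if "study" in raw and isinstance(raw["study"], dict):
        raw["study"] = StudyConfig(**raw["study"])
    if "tilt_covariates" in raw:
        raw["tilt_covariates"] = tuple(raw["tilt_covariates"])
    spec = CohortSpec(**raw)
    spec.validate()
    return spec


def default_spec() -> CohortSpec:
    """The shipped matched-margin specification (``table1_matched.yaml``)."""
    ref = resources.files("preopcard").joinpath("data/table1_matched.yaml")
    with resources.as_file(ref) as path:
        return load_spec(path)


def inject_effect(spec: CohortSpec, service: str, relative_odds: float) -> CohortSpec:
    """Multiply the post-period odds of one service by ``relative_odds``.

    Everything else is unchanged; returns a new spec. This creates a known
    ground-truth effect for pipeline recovery tests: the pre-vs-post odds
    ratio of the service becomes ``(pre odds / post odds) / relative_odds``
    relative to the base spec.
    """
    if relative_odds <= 0:
        raise ValueError("relative_odds must be positive")
    if service not in spec.service_rates:
        raise ValueError(f"service not configured: {service}")
    new = copy.deepcopy(spec)
    p_post = _per_period(spec.service_rates[service], POST)
    p_pre = _per_period(spec.service_rates[service], PRE)
    odds = p_post / (1.0 - p_post) * relative_odds
    new.service_rates[service] = {"pre": p_pre, "post": odds / (1.0 + odds)}
    return new


def _draw_ages(rng: np.random.Generator, n: int, quantiles: Mapping[float, float]) -> np.ndarray:
    """Ages via a piecewise-linear inverse CDF through configured quantiles.

    Reproduces the configured median and IQR by construction.
    """
    qs = np.array(sorted(quantiles))
    vals = np.array([quantiles[q] for q in qs], dtype=float)
    u = rng.uniform(size=n)
    return np.round(np.interp(u, qs, vals)).astype(int)


def _bern(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    return rng.uniform(size=n) < p


def generate(spec: CohortSpec, seed: int | None = None) -> CohortTable:
    """Generate one cohort table; byte-identical given the same seed + spec.

    ``seed`` overrides ``spec.seed`` when given.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_pre + spec.n_post
    if n == 0:
        patients = pd.DataFrame(columns=_columns())
        return CohortTable(patients=patients)

    period = np.array([PRE] * spec.n_pre + [POST] * spec.n_post, dtype=object)

    cols: dict[str, np.ndarray] = {}
    cols["age"] = _draw_ages(rng, n, spec.age_quantiles)

    def per_period_bern(value) -> np.ndarray:
        p = np.where(period == PRE, _per_period(value, PRE), _per_period(value, POST))
        return rng.uniform(size=n) < p

    cols["sex"] = np.where(per_period_bern(spec.sex_female), "female", "male")
    races = list(spec.race)
    cols["race"] = rng.choice(races, size=n, p=[spec.race[r] for r in races])
    cols["hispanic"] = per_period_bern(spec.hispanic)
    for cov in COMORBIDITIES:
        cols[cov] = per_period_bern(spec.comorbidities[cov])
    cols["mets_lt4"] = per_period_bern(spec.mets_lt4)
    asa34 = per_period_bern(spec.asa_34)
    # within each band, the lower class is the more common one
    cols["asa_class"] = np.where(
        asa34, np.where(_bern(rng, n, 0.9), 3, 4), np.where(_bern(rng, n, 0.3), 1, 2)
    )
    for comp in RCRI_COLUMNS:
        cols[comp] = _bern(rng, n, spec.rcri_component_p)
    cols["mica_risk_pct"] = np.minimum(
        100.0,
        np.exp(np.log(spec.mica_median_pct) + spec.mica_sigma * rng.standard_normal(n)),
    )
    levels = list(spec.surgical_risk)
    cols["surgical_risk"] = rng.choice(
        levels, size=n, p=[spec.surgical_risk[lv] for lv in levels]
    )
    for flag in CLINICAL_FLAGS:
        cols[flag] = per_period_bern(spec.flags[flag])

    # confounding: re-assign periods, arm sizes fixed, post-odds tilted by
    # exp(strength) per positive tilt covariate (Gumbel top-k sampling)
    if spec.confounding_strength != 0.0 and spec.n_pre > 0 and spec.n_post > 0:
        k = np.zeros(n)
        for cov in spec.tilt_covariates:
            k += np.asarray(cols[cov], dtype=float)
        keys = spec.confounding_strength * k + rng.gumbel(size=n)
        post_idx = np.argsort(-keys, kind="stable")[: spec.n_post]
        period = np.array([PRE] * n, dtype=object)
        period[post_idx] = POST

    study = spec.study
    pre_span = (study.cutover - study.study_start).days
    post_span = (study.study_end - study.cutover).days + 1
    offsets = rng.integers(0, np.where(period == PRE, pre_span, post_span))
    anchor = np.where(period == PRE, study.study_start.toordinal(),
                      study.cutover.toordinal())
    visit_ord = anchor + offsets
    surgery_ord = visit_ord + rng.integers(1, 46, size=n)

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "visit_date": [dt.date.fromordinal(int(o)) for o in visit_ord],
            "surgery_date": [dt.date.fromordinal(int(o)) for o in surgery_ord],
            **cols,
            "period": period,
        }
    )

    events = _draw_events(rng, patients, spec)
    return CohortTable(patients=patients, events=events)


def _draw_events(rng: np.random.Generator, patients: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    n = len(patients)
    period = patients["period"].to_numpy()
    surgery_ord = np.array([d.toordinal() for d in patients["surgery_date"]])
    pid = patients["patient_id"].to_numpy()
    window = spec.study.preop_window_days
    rows: list[tuple[str, str, dt.date]] = []

    for service in SERVICES:
        p = np.where(period == PRE,
                     _per_period(spec.service_rates[service], PRE),
                     _per_period(spec.service_rates[service], POST))
        hit = rng.uniform(size=n) < p
        # in-window events: 0..window days before surgery (day 0 inclusive)
        lag = rng.integers(0, window + 1, size=n)
        for i in np.flatnonzero(hit):
            rows.append((pid[i], service,
                         dt.date.fromordinal(int(surgery_ord[i] - lag[i]))))
        # sprinkle of out-of-window events, which linkage must ignore
        noise = rng.uniform(size=n) < spec.out_of_window_service_rate
        noise_lag = rng.integers(window + 1, window + 120, size=n)
        for i in np.flatnonzero(noise):
            rows.append((pid[i], service,
                         dt.date.fromordinal(int(surgery_ord[i] - noise_lag[i]))))

    postop = spec.study.postop_window_days
    for outcome in OUTCOMES:
        p = np.where(period == PRE,
                     _per_period(spec.outcome_rates[outcome], PRE),
                     _per_period(spec.outcome_rates[outcome], POST))
        hit = rng.uniform(size=n) < p
        lag = rng.integers(1, postop + 1, size=n)
        for i in np.flatnonzero(hit):
            rows.append((pid[i], outcome,
                         dt.date.fromordinal(int(surgery_ord[i] + lag[i]))))

    return pd.DataFrame(rows, columns=["patient_id", "event_type", "date"])


def _columns() -> list[str]:
    return (
        ["patient_id", "visit_date", "surgery_date", "age", "sex", "race",
         "hispanic"]
        + list(COMORBIDITIES)
        + ["mets_lt4", "asa_class"]
        + list(RCRI_COLUMNS)
        + ["mica_risk_pct", "surgical_risk"]
        + list(CLINICAL_FLAGS)
        + ["period"]
    )
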