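"""End-to-end pipeline orchestration and table rendering.

``run_pipeline`` composes the stages in study order — exclusions, period
assignment, risk scoring, algorithm-end-point classification, service and
outcome linkage, propensity matching, and effect/sensitivity analysis —
and returns a bundle of table analogues:

* ``balance``      covariate balance before/after matching (Table-1-style)
* ``utilization``  matched per-service utilization with p and E-values
                   (Table-2-style)
* ``outcomes``     matched 30-day outcome comparison (Table-3-style)
* ``indication``   post-period MACE stratified by consultation indication
                   and completed consultation (Table-4-style)
* ``aep_mace``     per-end-point MACE counts and rates
* ``monthly``      time-binned service-utilization series

A :class:`RunManifest` records the seed, configuration hash, per-stage
record counts and package version so any bundle can be regenerated.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aep import NO_CLEAR_INDICATION, POSSIBLE_INDICATION, aep_outcome_table, evaluate_frame
from .cohort import (
    CohortTable,
    MACE_COMPONENTS,
    OUTCOMES,
    SERVICES,
    add_period,
    apply_exclusions,
    compute_30d_outcomes,
    link_preop_services,
)
from .config import POST, PRE, StudyConfig
from .effects import contingency_test, format_pct, utilization_report
from .psm import (
    DEFAULT_COVARIATES,
    add_derived_covariates,
    balance_table,
    fit_propensity,
    match_pairs,
    matched_frame,
)
from .simulate import CohortSpec, generate


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    stage_counts: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class ReportBundle:
    accounting: dict
    balance: pd.DataFrame
    utilization: pd.DataFrame
    outcomes: pd.DataFrame
    indication: pd.DataFrame
    aep_mace: pd.DataFrame
    monthly: pd.DataFrame
    matched_n_pairs: int
    manifest: RunManifest

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.balance.to_csv(out / "table1_balance.csv", index=False)
        self.utilization.to_csv(out / "table2_utilization.csv", index=False)
        self.outcomes.to_csv(out / "table3_outcomes.csv", index=False)
        self.indication.to_csv(out / "table4_indication.csv", index=False)
        self.aep_mace.to_csv(out / "aep_mace.csv", index=False)
        self.monthly.to_csv(out / "monthly_series.csv", index=False)
        (out / "accounting.json").write_text(json.dumps(self.accounting, indent=2))
        (out / "manifest.json").write_text(self.manifest.to_json())


def monthly_series(
    patients: pd.DataFrame,
    service_flags: pd.DataFrame,
    service: str,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Per-calendar-month utilization rate of one service.

    Month index is relative to the cutover month (month 0 = the month the
    form went live). Months inside the study window with no visits are
    emitted with n=0 and a null rate.
    """
    config = config or StudyConfig()
    visits = pd.to_datetime(patients["visit_date"])
    month = visits.dt.year * 12 + visits.dt.month
    cut = config.cutover.year * 12 + config.cutover.month
    idx = month - cut
    lo = (config.study_start.year * 12 + config.study_start.month) - cut
    hi = (config.study_end.year * 12 + config.study_end.month) - cut
    flags = service_flags[service].to_numpy(bool)
    rows = []
    for mi in range(lo, hi + 1):
        sel = (idx == mi).to_numpy()
        n = int(sel.sum())
        k = int(flags[sel].sum())
        rows.append({"month_index": mi, "n": n, "service_n": k,
                     "service_pct": format_pct(k, n) if n else np.nan})
    return pd.DataFrame(rows)


def outcomes_comparison(pre_flags: pd.DataFrame, post_flags: pd.DataFrame,
                        fisher_threshold: float = 5.0) -> pd.DataFrame:
    """Matched 30-day outcome comparison, one row per outcome plus MACE."""
    names = list(OUTCOMES) + ["mace"]
    n_pre, n_post = len(pre_flags), len(post_flags)
    rows = []
    for name in names:
        a, c = int(pre_flags[name].sum()), int(post_flags[name].sum())
        row = {"outcome": name, "total_n": a + c,
               "total_pct": format_pct(a + c, n_pre + n_post),
               "pre_n": a, "pre_pct": format_pct(a, n_pre),
               "post_n": c, "post_pct": format_pct(c, n_post)}
        if 0 < a + c < n_pre + n_post:
            res = contingency_test(
                np.array([[a, n_pre - a], [c, n_post - c]]), fisher_threshold)
            row["p_value"], row["test_used"] = res.p_value, res.test_used
        else:
            row["p_value"], row["test_used"] = np.nan, "degenerate"
        rows.append(row)
    return pd.DataFrame(rows)


def indication_table(post_patients: pd.DataFrame, consult: pd.Series,
                     mace: pd.Series, fisher_threshold: float = 5.0) -> pd.DataFrame:
    """Post-period MACE by consultation-indication class and consultation.

    One row per (indication class, consulted yes/no) cell with its MACE
    count and percent, plus a per-class p-value comparing MACE with vs
    without a completed consultation.
    """
    rows = []
    for cls in (NO_CLEAR_INDICATION, POSSIBLE_INDICATION):
        sel = (post_patients["indication_class"] == cls).to_numpy()
        n_cls = int(sel.sum())
        cells = {}
        for consulted in (False, True):
            s = sel & (consult.to_numpy(bool) == consulted)
            n = int(s.sum())
            k = int(mace.to_numpy(bool)[s].sum())
            cells[consulted] = (n, k)
        table = np.array([[cells[False][1], cells[False][0] - cells[False][1]],
                          [cells[True][1], cells[True][0] - cells[True][1]]])
        try:
            p = contingency_test(table, fisher_threshold).p_value
        except ValueError:
            p = np.nan
        for consulted in (False, True):
            n, k = cells[consulted]
            rows.append({
                "indication_class": cls, "n_class": n_cls,
                "consulted": consulted, "n": n,
                "n_pct_of_class": format_pct(n, n_cls),
                "mace_n": k, "mace_pct": format_pct(k, n),
                "p_value": p,
            })
    return pd.DataFrame(rows)


def run_pipeline(
    source: CohortSpec | CohortTable,
    seed: int = 0,
    config: StudyConfig | None = None,
    covariates=DEFAULT_COVARIATES,
    caliper_sd_logit: float | None = None,
) -> ReportBundle:
    """Execute the full retrospective-cohort analysis.

    ``source`` is either a :class:`CohortSpec` (a synthetic cohort is
    generated under ``seed``) or an already-loaded :class:`CohortTable`.
    Record counts are conserved and asserted between stages. The same
    source, seed and configuration always regenerate an identical bundle.
    """
    if isinstance(source, CohortSpec):
        config = config or source.study
        cohort = generate(source, seed=seed)
        spec_hash = hashlib.sha256(
            yaml.safe_dump(_spec_dict(source), sort_keys=True).encode()
        ).hexdigest()
    else:
        config = config or StudyConfig()
        cohort = source
        spec_hash = hashlib.sha256(
            pd.util.hash_pandas_object(cohort.patients["patient_id"]).values.tobytes()
        ).hexdigest()
    if caliper_sd_logit is None:
        caliper_sd_logit = config.caliper_sd_logit

    manifest = RunManifest(
        seed=seed, config_hash=spec_hash,
        timestamp=dt.datetime.now().isoformat(timespec="seconds"),
    )
    manifest.stage_counts["input"] = len(cohort.patients)

    patients, acct = apply_exclusions(cohort.patients)
    manifest.stage_counts["after_exclusions"] = len(patients)
    assert len(patients) == acct.n_final

    patients = add_period(patients, config)
    n_before = len(patients)
    patients = patients[patients["in_window"]].reset_index(drop=True)
    manifest.stage_counts["in_window"] = len(patients)
    assert len(patients) <= n_before

    patients = add_derived_covariates(patients)
    aep_cols = evaluate_frame(patients)
    patients = pd.concat([patients, aep_cols], axis=1)

    services = link_preop_services(patients, cohort.events, config.preop_window_days)
    outcomes = compute_30d_outcomes(patients, cohort.events, config.postop_window_days)

    fit = fit_propensity(patients, covariates)
    matched = match_pairs(fit, caliper_sd_logit=caliper_sd_logit, seed=seed)
    manifest.stage_counts["matched_records"] = 2 * matched.n_pairs

    balance = balance_table(patients, matched, covariates)
    pre_svc = services.loc[matched.pre_indices]
    post_svc = services.loc[matched.post_indices]
    pre_out = outcomes.loc[matched.pre_indices]
    post_out = outcomes.loc[matched.post_indices]

    utilization = utilization_report(
        pre_svc, post_svc, list(SERVICES),
        fisher_threshold=config.fisher_threshold,
        common_outcome_prevalence=config.common_outcome_prevalence,
    )
    outcome_cmp = outcomes_comparison(pre_out, post_out, config.fisher_threshold)

    post_all = patients[patients["period"] == POST]
    indication = indication_table(
        post_all, services.loc[post_all.index, "consult"],
        outcomes.loc[post_all.index, "mace"], config.fisher_threshold)
    aep_mace = aep_outcome_table(post_all["aep_id"], outcomes.loc[post_all.index, "mace"])
    monthly = monthly_series(patients, services, "consult", config)

    return ReportBundle(
        accounting={"n_screened": acct.n_screened,
                    "n_duplicates": acct.n_duplicates,
                    "n_missing_scores": acct.n_missing_scores,
                    "n_final": acct.n_final},
        balance=balance,
        utilization=utilization,
        outcomes=outcome_cmp,
        indication=indication,
        aep_mace=aep_mace,
        monthly=monthly,
        matched_n_pairs=matched.n_pairs,
        manifest=manifest,
    )


def _spec_dict(spec: CohortSpec) -> dict:
    from dataclasses import asdict

    d = asdict(spec)
    d["study"] = spec.study.to_dict()
    d["tilt_covariates"] = list(spec.tilt_covariates)
    return d
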