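"""Study-level configuration: calendar windows and analysis constants.

All dates are timezone-free calendar days. The default two-year study window
runs July 2021 through June 2023 with the form cutover on 2022-07-01; a visit
strictly before the cutover belongs to the *pre* period, on or after it to
the *post* period.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

PRE = "pre"
POST = "post"


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return dt.date.fromisoformat(str(x))


@dataclass(frozen=True)
class StudyConfig:
    """Calendar windows and statistical constants for one analysis run.

    Attributes
    ----------
    study_start, cutover, study_end
        The enrolment window and the intervention cutover date. Records with
        visits outside ``[study_start, study_end]`` are flagged out of window.
    preop_window_days
        A service event counts as preoperative iff it occurred between
        ``window`` days before surgery and the day of surgery, both inclusive.
    postop_window_days
        An outcome counts iff it occurred from the day after surgery through
        day ``window`` after surgery, both inclusive.
    fisher_threshold
        Minimum expected cell count below which a 2x2 comparison switches
        from the Pearson chi-square to the Fisher exact test.
    common_outcome_prevalence
        Pooled prevalence at or above which an outcome is treated as common
        for the odds-ratio-to-risk-ratio conversion in the E-value.
    caliper_sd_logit
        Matching caliper as a multiple of the SD of the logit propensity.
    """

    study_start: dt.date = dt.date(2021, 7, 1)
    cutover: dt.date = dt.date(2022, 7, 1)
    study_end: dt.date = dt.date(2023, 6, 30)
    preop_window_days: int = 60
    postop_window_days: int = 30
    fisher_threshold: float = 5.0
    common_outcome_prevalence: float = 0.15
    caliper_sd_logit: float = 0.2

    def __post_init__(self) -> None:
        for name in ("study_start", "cutover", "study_end"):
            object.__setattr__(self, name, _as_date(getattr(self, name)))
        if not self.study_start <= self.cutover <= self.study_end:
            raise ValueError("require study_start <= cutover <= study_end")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, dt.date):
                d[k] = v.isoformat()
        return d


DEFAULT_CONFIG = StudyConfig()
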