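import datetime as dt

import numpy as np
import pandas as pd
import pytest

from preopcard.cohort import CLINICAL_FLAGS, RCRI_COLUMNS
from preopcard.simulate import CohortSpec


def make_patients(n, rng, **overrides):
    """Minimal valid wide patient frame for unit tests."""
    base = dt.date(2022, 1, 1)
    visit = [base + dt.timedelta(days=int(d)) for d in rng.integers(0, 300, n)]
    surgery = [v + dt.timedelta(days=int(d)) for v, d in zip(visit, rng.integers(1, 40, n))]
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "visit_date": visit,
            "surgery_date": surgery,
            "age": rng.integers(18, 90, n),
            "sex": rng.choice(["male", "female"], n),
            "race": rng.choice(["White", "Others"], n),
            "hispanic": rng.uniform(size=n) < 0.1,
            "atrial_fibrillation": rng.uniform(size=n) < 0.08,
            "cad": rng.uniform(size=n) < 0.1,
            "chf": rng.uniform(size=n) < 0.03,
            "cva_tia": rng.uniform(size=n) < 0.04,
            "ckd": rng.uniform(size=n) < 0.1,
            "diabetes": rng.uniform(size=n) < 0.2,
            "mets_lt4": rng.uniform(size=n) < 0.15,
            "asa_class": rng.integers(1, 5, n),
            "mica_risk_pct": rng.uniform(0.05, 3.0, n),
            "surgical_risk": rng.choice(["low", "moderate", "high"], n),
        }
    )
    for c in RCRI_COLUMNS:
        df[c] = rng.uniform(size=n) < 0.07
    for c in CLINICAL_FLAGS:
        df[c] = rng.uniform(size=n) < 0.1
    for k, v in overrides.items():
        df[k] = v
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20230701)


@pytest.fixture
def small_spec():
    """A fast, balanced spec for simulation-based tests."""
    return CohortSpec(n_pre=800, n_post=800, seed=5, confounding_strength=0.0)
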