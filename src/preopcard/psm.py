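"""Propensity-score estimation, 1:1 greedy matching, balance diagnostics.

The propensity score is the modeled probability of belonging to the *post*
period given baseline covariates, fitted by unpenalized logistic regression
(statsmodels). Matching is greedy nearest-neighbor without replacement on
the logit of the score, processing the smaller arm in a seeded random
order, with an optional caliper expressed as a multiple of the SD of the
logit scores (0.2 by default, standard practice). Ties in distance are
broken by record ingestion order. Balance is reported both as standardized
mean differences (sample-size-free) and as the same hypothesis tests used
before matching, because p-value balance checks alone are sample-size
dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit

from .config import POST, PRE
from .cohort import COMORBIDITIES

#: the baseline covariate set used for matching (demographics, comorbidity,
#: functional capacity, ASA band, RCRI band, MICA band, surgical risk)
DEFAULT_COVARIATES = (
    ("age", "continuous"),
    ("sex", "categorical"),
    ("race", "categorical"),
    ("hispanic", "binary"),
    *[(c, "binary") for c in COMORBIDITIES],
    ("mets_lt4", "binary"),
    ("asa_34", "binary"),
    ("rcri_2plus", "binary"),
    ("mica_elevated", "binary"),
    ("surgical_risk", "categorical"),
)


def add_derived_covariates(patients: pd.DataFrame) -> pd.DataFrame:
    """Attach the banded covariates used for matching and Table-1 layouts."""
    df = patients.copy()
    if "asa_34" not in df and "asa_class" in df:
        df["asa_34"] = df["asa_class"].astype(int) >= 3
    if "rcri_score" not in df:
        from .cohort import RCRI_COLUMNS

        df["rcri_score"] = df[list(RCRI_COLUMNS)].astype(bool).sum(axis=1)
    if "rcri_2plus" not in df:
        df["rcri_2plus"] = df["rcri_score"] >= 2
    if "mica_elevated" not in df and "mica_risk_pct" in df:
        df["mica_elevated"] = df["mica_risk_pct"].astype(float) >= 1.0
    return df


@dataclass
class PropensityFit:
    covariates: list
    params: pd.Series
    scores: np.ndarray          # P(post | x), one per record, in (0,1)
    logit_scores: np.ndarray
    is_post: np.ndarray         # boolean, aligned with the input frame
    index: pd.Index


@dataclass
class MatchedCohort:
    """1:1 matched pairs; indices refer to the fitted frame's index."""

    pre_indices: np.ndarray
    post_indices: np.ndarray
    distances: np.ndarray
    unmatched_pre: np.ndarray
    unmatched_post: np.ndarray
    caliper: float | None

    @property
    def n_pairs(self) -> int:
        return len(self.pre_indices)


def _design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    parts = []
    for name, kind in covariates:
        if kind == "categorical":
            d = pd.get_dummies(df[name].astype(str), prefix=name, drop_first=True)
            parts.append(d.astype(float))
        else:
            parts.append(df[[name]].astype(float))
    if not parts:
        return pd.DataFrame(index=df.index)
    X = pd.concat(parts, axis=1)
    return X


def fit_propensity(patients: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> PropensityFit:
    """Fit P(post | covariates) by unpenalized logistic regression.

    With an empty covariate list the model is intercept-only and every score
    equals the empirical post proportion. Perfect separation raises a
    ``ValueError`` advising covariate review.
    """
    df = add_derived_covariates(patients)
    y = (df["period"] == POST).to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both periods must be present to fit a propensity model")
    X = _design(df, covariates)
    X = sm.add_constant(X, has_constant="add")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X.to_numpy()).fit(disp=0, method="newton", maxiter=100)
        except Exception:
            res = sm.Logit(y, X.to_numpy()).fit(disp=0, method="lbfgs", maxiter=500)
    p = np.asarray(res.predict(X.to_numpy()), dtype=float)
    post_scores, pre_scores = p[y == 1], p[y == 0]
    if post_scores.min() > pre_scores.max() or pre_scores.min() > post_scores.max():
        raise ValueError(
            "the covariates perfectly separate the two periods; "
            "no score overlap exists for matching — review the covariate set"
        )
    # quasi-separation on rare covariate levels can push a handful of
    # scores to the boundary; clip so the logit stays finite
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return PropensityFit(
        covariates=list(covariates),
        params=pd.Series(res.params, index=list(X.columns)),
        scores=p,
        logit_scores=logit(p),
        is_post=y.astype(bool),
        index=df.index,
    )


def match_pairs(
    fit: PropensityFit,
    caliper_sd_logit: float | None = 0.2,
    seed: int = 0,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Records of the smaller arm are processed in a seeded random order; each
    is paired with the nearest still-unmatched record of the other arm on
    the logit-propensity scale, provided the distance is within
    ``caliper_sd_logit`` times the SD of all logit scores (``None`` disables
    the caliper). A matched record is never reused. Ties in distance are
    broken toward the earlier-ingested record. Deterministic given ``seed``.
    """
    lp = fit.logit_scores
    post_pos = np.flatnonzero(fit.is_post)
    pre_pos = np.flatnonzero(~fit.is_post)
    caliper = None
    if caliper_sd_logit is not None:
        sd = float(np.std(lp, ddof=1)) if len(lp) > 1 else 0.0
        caliper = caliper_sd_logit * sd

    if len(post_pos) <= len(pre_pos):
        treated, control = post_pos, pre_pos
        treated_is_post = True
    else:
        treated, control = pre_pos, post_pos
        treated_is_post = False

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(treated))

    # controls sorted by logit score; stable sort keeps ingestion order on
    # ties so the left-walk below hits the earlier record first
    c_sort = control[np.argsort(lp[control], kind="stable")]
    c_vals = lp[c_sort]
    m = len(c_sort)
    # "nearest unused" jump pointers over the sorted controls, compressed
    # as they are walked (union-find style), so the total walk cost stays
    # near-linear even at cohort scale
    used = np.zeros(m, dtype=bool)
    nxt = np.arange(m)   # candidate for first unused position >= i
    prv = np.arange(m)   # candidate for last unused position <= i

    t_sel, c_sel, dists = [], [], []
    for k in order:
        t = treated[k]
        x = lp[t]
        pos = int(np.searchsorted(c_vals, x))
        # nearest unused on the right (>= pos) and left (< pos)
        r = pos
        path = []
        while r < m and used[r]:
            path.append(r)
            r = nxt[r]
        for j in path:
            nxt[j] = r
        l = pos - 1
        path = []
        while l >= 0 and used[l]:
            path.append(l)
            l = prv[l]
        for j in path:
            prv[j] = l

        best = -1
        if r < m and l >= 0:
            dr, dl = abs(c_vals[r] - x), abs(x - c_vals[l])
            if dl < dr:
                best = l
            elif dr < dl:
                best = r
            else:
                # distance tie: earlier-ingested control wins
                best = l if c_sort[l] < c_sort[r] else r
        elif r < m:
            best = r
        elif l >= 0:
            best = l
        if best < 0:
            continue
        d = abs(c_vals[best] - x)
        if caliper is not None and d > caliper:
            continue
        used[best] = True
        nxt[best] = best + 1
        prv[best] = best - 1
        t_sel.append(t)
        c_sel.append(c_sort[best])
        dists.append(d)

    t_arr = np.array(t_sel, dtype=int)
    c_arr = np.array(c_sel, dtype=int)
    if treated_is_post:
        post_sel, pre_sel = t_arr, c_arr
    else:
        post_sel, pre_sel = c_arr, t_arr
    assert len(np.unique(pre_sel)) == len(pre_sel)
    assert len(np.unique(post_sel)) == len(post_sel)
    idx = fit.index.to_numpy()
    return MatchedCohort(
        pre_indices=idx[pre_sel],
        post_indices=idx[post_sel],
        distances=np.array(dists),
        unmatched_pre=idx[np.setdiff1d(pre_pos, pre_sel)],
        unmatched_post=idx[np.setdiff1d(post_pos, post_sel)],
        caliper=caliper,
    )


def matched_frame(patients: pd.DataFrame, matched: MatchedCohort) -> pd.DataFrame:
    """Subset of the fitted frame containing matched records, with pair ids."""
    pre = patients.loc[matched.pre_indices].copy()
    post = patients.loc[matched.post_indices].copy()
    pre["pair_id"] = np.arange(matched.n_pairs)
    post["pair_id"] = np.arange(matched.n_pairs)
    return pd.concat([pre, post])


def _smd_binary(p1: float, p2: float) -> float:
    denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    return 0.0 if denom == 0 else (p1 - p2) / denom


def _smd_continuous(a: np.ndarray, b: np.ndarray) -> float:
    denom = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    return 0.0 if denom == 0 else (np.mean(a) - np.mean(b)) / denom


def covariate_smd(pre: pd.DataFrame, post: pd.DataFrame, name: str, kind: str) -> float:
    """Standardized mean difference for one covariate (pre minus post).

    Categorical covariates report the largest absolute per-level SMD.
    """
    if kind == "continuous":
        return _smd_continuous(pre[name].to_numpy(float), post[name].to_numpy(float))
    if kind == "binary":
        return _smd_binary(pre[name].astype(bool).mean(), post[name].astype(bool).mean())
    levels = sorted(set(pre[name].astype(str)) | set(post[name].astype(str)))
    smds = [
        _smd_binary((pre[name].astype(str) == lv).mean(),
                    (post[name].astype(str) == lv).mean())
        for lv in levels
    ]
    return max(smds, key=abs) if smds else 0.0


def balance_table(
    patients: pd.DataFrame,
    matched: MatchedCohort,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-covariate balance before and after matching.

    Emits, per covariate: SMD before and after, and the p-value of the same
    test used in the unmatched comparison (chi-square / Fisher for
    categorical, Mann-Whitney for continuous).
    """
    from .effects import contingency_test, mann_whitney

    df = add_derived_covariates(patients)
    pre_all = df[df["period"] == PRE]
    post_all = df[df["period"] == POST]
    pre_m = df.loc[matched.pre_indices]
    post_m = df.loc[matched.post_indices]

    def p_value(pre: pd.DataFrame, post: pd.DataFrame, name: str, kind: str):
        if kind == "continuous":
            return mann_whitney(pre[name].to_numpy(float), post[name].to_numpy(float)), "mann_whitney"
        a = pre[name].astype(str)
        b = post[name].astype(str)
        levels = sorted(set(a) | set(b))
        if len(levels) < 2:
            return np.nan, "degenerate"
        table = np.array([[int((a == lv).sum()) for lv in levels],
                          [int((b == lv).sum()) for lv in levels]])
        res = contingency_test(table)
        return res.p_value, res.test_used

    rows = []
    for name, kind in covariates:
        p_b, test = p_value(pre_all, post_all, name, kind)
        p_a, _ = p_value(pre_m, post_m, name, kind)
        rows.append(
            {
                "covariate": name,
                "kind": kind,
                "smd_before": covariate_smd(pre_all, post_all, name, kind),
                "smd_after": covariate_smd(pre_m, post_m, name, kind),
                "p_before": p_b,
                "p_after": p_a,
                "test_used": test,
            }
        )
    return pd.DataFrame(rows)
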