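import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from preopcard.config import PRE, POST
from preopcard.psm import (
    DEFAULT_COVARIATES,
    PropensityFit,
    add_derived_covariates,
    balance_table,
    fit_propensity,
    match_pairs,
    matched_frame,
)
from preopcard.simulate import CohortSpec, generate

from conftest import make_patients


def fit_from_scores(scores, is_post):
    scores = np.asarray(scores, dtype=float)
    is_post = np.asarray(is_post, dtype=bool)
    return PropensityFit(
        covariates=[], params=pd.Series(dtype=float), scores=scores,
        logit_scores=logit(scores), is_post=is_post,
        index=pd.RangeIndex(len(scores)),
    )


def brute_force_greedy(lp, is_post, caliper, seed):
    """Independent O(n^2) re-simulation of the matching policy: process the
    smaller arm in the seeded random order, pair each record with the
    nearest unused record of the other arm (ties toward the earlier-ingested
    record), subject to the caliper."""
    post = np.flatnonzero(is_post)
    pre = np.flatnonzero(~is_post)
    treated, control = (post, pre) if len(post) <= len(pre) else (pre, post)
    order = np.random.default_rng(seed).permutation(len(treated))
    available = list(control)
    pairs = []
    for k in order:
        t = treated[k]
        if not available:
            break
        dists = [(abs(lp[c] - lp[t]), c) for c in available]
        d, c = min(dists)
        if caliper is not None and d > caliper:
            continue
        available.remove(c)
        pairs.append((t, c, d))
    return pairs


def brute_force_optimal(t_vals, c_vals, caliper):
    """Exhaustive assignment: maximum pair count, then minimum total distance."""
    nt, nc = len(t_vals), len(c_vals)
    for size in range(min(nt, nc), -1, -1):
        best = None
        for tsub in itertools.combinations(range(nt), size):
            for csub in itertools.permutations(range(nc), size):
                ds = [abs(t_vals[a] - c_vals[b]) for a, b in zip(tsub, csub)]
                if caliper is not None and any(d > caliper for d in ds):
                    continue
                tot = sum(ds)
                if best is None or tot < best:
                    best = tot
        if best is not None:
            return size, best
    return 0, 0.0


class TestFitPropensity:
    def test_intercept_only_scores_equal_post_proportion(self, rng):
        df = make_patients(50, rng)
        df["period"] = [POST] * 20 + [PRE] * 30
        fit = fit_propensity(df, covariates=[])
        np.testing.assert_allclose(fit.scores, 0.4, atol=1e-9)

    def test_single_binary_covariate_matches_closed_form(self, rng):
        # 2x2 cell counts: exposed, post: 30/50; unexposed, post: 20/80
        df = make_patients(130, rng)
        df["cad"] = [True] * 50 + [False] * 80
        df["period"] = ([POST] * 30 + [PRE] * 20) + ([POST] * 20 + [PRE] * 60)
        fit = fit_propensity(df, covariates=[("cad", "binary")])
        b0 = np.log(20 / 60)
        b1 = np.log(30 / 20) - b0
        assert fit.params["const"] == pytest.approx(b0, abs=1e-6)
        assert fit.params["cad"] == pytest.approx(b1, abs=1e-6)

    def test_confounding_separates_score_distributions(self):
        spec = CohortSpec(n_pre=1500, n_post=1500, confounding_strength=0.6)
        df = generate(spec, seed=9).patients
        fit = fit_propensity(df)
        from scipy.stats import ks_2samp

        ks_conf = ks_2samp(fit.scores[fit.is_post], fit.scores[~fit.is_post]).statistic

        null = generate(CohortSpec(n_pre=1500, n_post=1500,
                                   confounding_strength=0.0), seed=9).patients
        fit0 = fit_propensity(null)
        ks_null = ks_2samp(fit0.scores[fit0.is_post], fit0.scores[~fit0.is_post]).statistic
        assert ks_conf > ks_null + 0.05

    def test_perfect_separation_raises(self, rng):
        df = make_patients(40, rng)
        df["period"] = [PRE] * 20 + [POST] * 20
        df["cad"] = [False] * 20 + [True] * 20
        with pytest.raises(ValueError, match="separate"):
            fit_propensity(df, covariates=[("cad", "binary")])

    def test_single_period_raises(self, rng):
        df = make_patients(10, rng)
        df["period"] = PRE
        with pytest.raises(ValueError, match="both periods"):
            fit_propensity(df)


class TestMatchPairs:
    def test_identical_scores_match_min_arm(self):
        fit = fit_from_scores([0.5] * 9, [True] * 4 + [False] * 5)
        m = match_pairs(fit, caliper_sd_logit=0.2, seed=1)
        assert m.n_pairs == 4

    def test_no_control_reuse_and_determinism(self, rng):
        scores = rng.uniform(0.1, 0.9, 400)
        is_post = rng.uniform(size=400) < 0.5
        fit = fit_from_scores(scores, is_post)
        m1 = match_pairs(fit, seed=7)
        m2 = match_pairs(fit, seed=7)
        assert len(np.unique(m1.pre_indices)) == m1.n_pairs
        assert len(np.unique(m1.post_indices)) == m1.n_pairs
        np.testing.assert_array_equal(m1.pre_indices, m2.pre_indices)
        np.testing.assert_array_equal(m1.post_indices, m2.post_indices)

    def test_matches_brute_force_resimulation(self, rng):
        """The skip-list implementation agrees exactly with an independent
        quadratic re-simulation of the same greedy policy."""
        for trial in range(60):
            n = int(rng.integers(4, 40))
            scores = rng.uniform(0.05, 0.95, n)
            is_post = np.zeros(n, bool)
            is_post[: int(rng.integers(1, n))] = True
            rng.shuffle(is_post)
            if is_post.all() or not is_post.any():
                continue
            fit = fit_from_scores(scores, is_post)
            cal = 0.3 if trial % 2 else None
            seed = int(rng.integers(1 << 20))
            m = match_pairs(fit, caliper_sd_logit=cal, seed=seed)
            oracle = brute_force_greedy(fit.logit_scores, is_post, m.caliper, seed)
            assert m.n_pairs == len(oracle)
            got = {(int(a), int(b)) for a, b in zip(m.pre_indices, m.post_indices)}
            want = {(c, t) if is_post[t] else (t, c) for t, c, _ in oracle}
            assert got == want

    def test_shrinking_caliper_never_increases_pairs(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 60))
            scores = rng.uniform(0.05, 0.95, n)
            is_post = rng.uniform(size=n) < 0.5
            if is_post.all() or not is_post.any():
                continue
            fit = fit_from_scores(scores, is_post)
            counts = [
                match_pairs(fit, caliper_sd_logit=c, seed=3).n_pairs
                for c in (1.0, 0.5, 0.2, 0.05)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_within_documented_bound_of_optimal_assignment(self, rng):
        """Tiny cohorts vs exhaustive assignment search: greedy never beats
        the optimum, keeps every pair within the caliper, and (being maximal
        on the caliper graph) retains at least half the optimal pair count."""
        for trial in range(60):
            nt = int(rng.integers(1, 5))
            nc = int(rng.integers(1, 5))
            scores = rng.uniform(0.05, 0.95, nt + nc)
            is_post = np.array([True] * nt + [False] * nc)
            fit = fit_from_scores(scores, is_post)
            cal_mult = 0.5 if trial % 2 else None
            m = match_pairs(fit, caliper_sd_logit=cal_mult, seed=trial)
            lp = fit.logit_scores
            opt_n, opt_d = brute_force_optimal(
                list(lp[:nt]), list(lp[nt:]), m.caliper)
            assert 2 * m.n_pairs >= opt_n
            assert m.distances.sum() >= opt_d - 1e-12
            if m.caliper is not None:
                assert (m.distances <= m.caliper + 1e-12).all()
            if m.n_pairs == opt_n == min(nt, nc) and cal_mult is None:
                # without a caliper greedy always forms the full pairing
                assert m.n_pairs == min(nt, nc)


class TestBalance:
    def test_cloned_pairs_give_zero_smd_and_p_one(self, rng):
        half = make_patients(60, rng)
        pre = half.copy()
        post = half.copy()
        pre["period"] = PRE
        post["period"] = POST
        post["patient_id"] = post["patient_id"] + "_b"
        df = pd.concat([pre, post], ignore_index=True)
        m = match_pairs(fit_from_scores([0.5] * 120, df["period"] == POST), seed=0)
        table = balance_table(df, m)
        assert np.allclose(table["smd_after"], 0.0, atol=1e-12)
        after = table["p_after"].dropna()
        assert np.allclose(after, 1.0, atol=1e-9)

    def test_matching_reduces_max_smd_under_confounding(self):
        """Expected max |SMD| across covariates shrinks after matching when
        period assignment is confounded (20 seeds)."""
        before, after = [], []
        for seed in range(20):
            spec = CohortSpec(n_pre=1200, n_post=1200, confounding_strength=0.4)
            df = generate(spec, seed=seed).patients
            fit = fit_propensity(df)
            m = match_pairs(fit, seed=seed)
            table = balance_table(df, m)
            before.append(table["smd_before"].abs().max())
            after.append(table["smd_after"].abs().max())
        assert np.mean(after) < np.mean(before)

    def test_matched_frame_has_aligned_pairs(self, rng):
        df = make_patients(80, rng)
        df["period"] = [PRE] * 40 + [POST] * 40
        fit = fit_propensity(df, covariates=[("age", "continuous")])
        m = match_pairs(fit, seed=2)
        mf = matched_frame(df, m)
        assert len(mf) == 2 * m.n_pairs
        assert (mf.groupby("pair_id").size() == 2).all()
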