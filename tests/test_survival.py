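"""Survival statistics against closed forms, enumeration and independent
reference implementations (statsmodels), plus the discordant-patient
benchmark construction."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from ctcgate import (
    benchmark_discordant,
    cox_univariate,
    fisher_exact,
    km_fit,
    kruskal,
    logrank,
    mannwhitney,
    median_iqr,
    simulate_cohort,
    spearman,
    stratify_and_compare,
)
from ctcgate.synthetic import CohortSimSpec


class TestKaplanMeier:
    def test_three_uncensored_subjects_closed_form(self):
        m = km_fit([1, 2, 3], [1, 1, 1])
        assert m.times.tolist() == [0.0, 1.0, 2.0, 3.0]
        assert m.survival.tolist() == pytest.approx([1.0, 2 / 3, 1 / 3, 0.0])
        assert m.median == 2.0

    def test_all_censored_curve_stays_at_one(self):
        m = km_fit([5, 8, 13], [0, 0, 0])
        assert np.all(m.survival == 1.0)
        assert m.median is None

    def test_single_subject_event_drops_to_zero(self):
        m = km_fit([7.0], [1])
        assert m.survival_at(6.9) == 1.0
        assert m.survival_at(7.0) == 0.0

    def test_censoring_rescales_later_steps(self):
        # events at 1 and 3, censor at 2: S = 2/3 on [1,3), then 2/3*0 = 0
        m = km_fit([1, 2, 3], [1, 0, 1])
        assert m.survival_at(1.5) == pytest.approx(2 / 3)
        assert m.survival_at(3.0) == pytest.approx(0.0)

    def test_non_positive_times_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            km_fit([0.0, 1.0], [1, 1])

    def test_km_median_equals_sample_convention_without_censoring(self, rng):
        # no censoring: smallest observation with empirical survival <= 0.5
        for _ in range(20):
            t = rng.exponential(10, size=int(rng.integers(3, 30)))
            m = km_fit(t, np.ones_like(t))
            srt = np.sort(t)
            surv = 1 - np.arange(1, t.size + 1) / t.size
            expected = srt[np.argmax(surv <= 0.5)]
            assert m.median == pytest.approx(expected)

    def test_invariants_s0_one_and_nonincreasing(self, rng):
        t = rng.exponential(10, 40)
        e = (rng.random(40) < 0.6).astype(int)
        m = km_fit(t, e)
        assert m.survival[0] == 1.0
        assert np.all(np.diff(m.survival) <= 1e-12)
        assert np.all(np.diff(m.at_risk) <= 0)


def _logrank_oracle(t1, e1, t2, e2):
    """Hand-rolled two-sample log-rank chi-square (hypergeometric moments)."""
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    O = E = V = 0.0
    for u in np.unique(t[e == 1]):
        at = t >= u
        n, n1 = at.sum(), (at & (g == 0)).sum()
        d = ((t == u) & (e == 1)).sum()
        d1 = ((t == u) & (e == 1) & (g == 0)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_statistic_zero_p_one(self):
        chi2, p = logrank([([1, 2, 3], [1, 1, 1]), ([1, 2, 3], [1, 1, 1])])
        assert chi2 == 0.0
        assert p == 1.0

    def test_matches_independent_formula_on_random_data(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(10, 40, 2)
            t1 = np.round(rng.exponential(10, n1), 1) + 0.1
            t2 = np.round(rng.exponential(6, n2), 1) + 0.1
            e1 = (rng.random(n1) < 0.7).astype(int)
            e2 = (rng.random(n2) < 0.7).astype(int)
            if e1.sum() + e2.sum() == 0:
                continue
            chi2, _ = logrank([(t1, e1), (t2, e2)])
            assert chi2 == pytest.approx(_logrank_oracle(t1, e1, t2, e2), abs=1e-8)

    def test_separated_groups_reject_strongly(self, rng):
        t1 = rng.uniform(1, 10, 60)
        t2 = rng.uniform(20, 30, 60)
        _, p = logrank([(t1, np.ones(60)), (t2, np.ones(60))])
        assert p < 1e-6

    def test_invariant_under_monotone_time_transform(self, rng):
        t1 = rng.exponential(10, 30)
        t2 = rng.exponential(5, 30)
        e1 = (rng.random(30) < 0.8).astype(int)
        e2 = (rng.random(30) < 0.8).astype(int)
        chi2_a, _ = logrank([(t1, e1), (t2, e2)])
        chi2_b, _ = logrank([(np.exp(t1 / 10), e1), (np.exp(t2 / 10), e2)])
        assert chi2_a == pytest.approx(chi2_b, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([([1, 2], [1, 1]), ([], [])])


class TestCox:
    def test_null_covariate_gives_hr_near_one(self, rng):
        n = 2000
        t = rng.exponential(10, n)
        x = rng.integers(0, 2, n).astype(float)  # independent of t
        r = cox_univariate(t, np.ones(n), x)
        assert 0.9 < r.hr < 1.1

    def test_matches_statsmodels_efron_on_random_datasets(self, rng):
        import statsmodels.api as sm

        for _ in range(100):
            n = int(rng.integers(30, 80))
            x = rng.integers(0, 2, n).astype(float)
            if x.sum() in (0, n):
                continue
            t = rng.exponential(10 * np.exp(-0.5 * x))
            e = (rng.random(n) < 0.8).astype(int)
            if e.sum() < 2:
                continue
            r = cox_univariate(t, e, x)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = sm.PHReg(t, x[:, None], status=e, ties="efron").fit(
                    method="newton", tol=1e-12, disp=False
                )
            assert r.log_hr == pytest.approx(ref.params[0], abs=1e-6)
            assert r.se == pytest.approx(np.sqrt(ref.cov_params()[0, 0]), abs=1e-6)

    def test_breslow_ties_match_statsmodels(self, rng):
        import statsmodels.api as sm

        for _ in range(30):
            n = 60
            x = rng.integers(0, 2, n).astype(float)
            t = np.round(rng.exponential(10 * np.exp(-0.5 * x)), 1) + 0.1
            e = (rng.random(n) < 0.8).astype(int)
            if e.sum() < 2 or x.sum() in (0, n):
                continue
            r = cox_univariate(t, e, x, tie_method="breslow")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = sm.PHReg(t, x[:, None], status=e, ties="breslow").fit(
                    method="newton", tol=1e-12, disp=False
                )
            assert r.log_hr == pytest.approx(ref.params[0], abs=1e-6)

    def test_hr_invariant_under_time_rescaling(self, rng):
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10 * np.exp(-0.7 * x))
        e = (rng.random(n) < 0.8).astype(int)
        r1 = cox_univariate(t, e, x)
        r2 = cox_univariate(t * 12.0, e, x)
        assert r1.log_hr == pytest.approx(r2.log_hr, abs=1e-8)

    def test_log_hr_sign_flips_when_indicator_complemented(self, rng):
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10 * np.exp(-0.7 * x))
        e = (rng.random(n) < 0.8).astype(int)
        r1 = cox_univariate(t, e, x)
        r2 = cox_univariate(t, e, 1 - x)
        assert r1.log_hr == pytest.approx(-r2.log_hr, abs=1e-8)

    def test_complete_separation_is_flagged_not_silent(self):
        # all events in one group occur strictly before the other group's
        t = np.concatenate([np.arange(1, 11), np.arange(100, 110)])
        e = np.ones(20, int)
        x = np.concatenate([np.ones(10), np.zeros(10)])
        r = cox_univariate(t, e, x)
        assert r.flagged

    def test_constant_indicator_rejected(self):
        with pytest.raises(ValueError, match="two values"):
            cox_univariate([1, 2, 3], [1, 1, 1], [1, 1, 1])


class TestRankStatistics:
    def test_spearman_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 5], [10, 20, 22, 90])
        assert rho == 1.0
        rho, _ = spearman([1, 2, 3, 5], [90, 22, 20, 10])
        assert rho == -1.0

    def test_spearman_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_mannwhitney_exact_small_sample(self):
        u, p = mannwhitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_mannwhitney_matches_full_enumeration(self, rng):
        # exact two-sided p = share of group assignments at least as extreme
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            pooled = rng.permutation(rng.uniform(0, 1, n1 + n2))
            x, y = pooled[:n1], pooled[n1:]
            u_obs, p = mannwhitney(x, y)
            mid = n1 * n2 / 2

            def u_of(idx):
                xs = pooled[list(idx)]
                ys = np.delete(pooled, list(idx))
                return sum((xi > ys).sum() for xi in xs)

            us = [u_of(idx) for idx in itertools.combinations(range(n1 + n2), n1)]
            p_enum = np.mean([abs(u - mid) >= abs(u_obs - mid) - 1e-12 for u in us])
            assert p == pytest.approx(p_enum, abs=1e-12)

    def test_kruskal_identical_groups(self):
        h, p = kruskal([[1, 2, 3], [1, 2, 3]])
        assert h == 0.0

    def test_kruskal_matches_scipy_on_random_groups(self, rng):
        from scipy import stats

        groups = [rng.normal(loc, 1, 15) for loc in (0, 0.5, 1.0)]
        h, p = kruskal(groups)
        ref = stats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)

    def test_median_iqr(self):
        med, q1, q3 = median_iqr([1, 2, 3, 4, 5])
        assert (med, q1, q3) == (3.0, 2.0, 4.0)


def _fisher_oracle(table):
    """Two-sided Fisher p by full enumeration over the margin-fixed family."""
    from scipy.stats import hypergeom

    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    rv = hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        if rv.pmf(x) <= p_obs * (1 + 1e-9):
            total += rv.pmf(x)
    return total


class TestFisherExact:
    def test_diagonal_2_2_table_enumeration(self):
        # margins (2,2)x(2,2): three tables with probs 1/6, 4/6, 1/6
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact([[0, 0], [3, 5]]) == 1.0
        assert fisher_exact([[2, 0], [5, 0]]) == 1.0

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])

    def test_matches_enumeration_on_all_small_tables(self):
        # every 2x2 table with total <= 8
        for n in range(1, 9):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        table = [[a, b], [c, d]]
                        assert fisher_exact(table) == pytest.approx(
                            _fisher_oracle(table), abs=1e-10
                        ), table


class TestStratifyAndCompare:
    def test_bundles_km_logrank_cox_consistently(self):
        df, gt = simulate_cohort(CohortSimSpec(seed=21))
        res = stratify_and_compare(df, "ctc_manual", cutoff=1)
        assert res.negative.n + res.positive.n == len(df)
        assert res.cox.hr > 0
        assert 0 <= res.logrank_p <= 1

    def test_null_simulation_ci_covers_one(self):
        covered = 0
        for rep in range(60):
            spec = CohortSimSpec(
                n_patients=300, log_hr=0.0, seed=40_000 + rep,
                detection_p_manual=1.0, fp_rate_manual=0.0,
            )
            df, _ = simulate_cohort(spec)
            try:
                res = stratify_and_compare(df, "ctc_manual", cutoff=1)
            except ValueError:
                continue
            covered += res.cox.ci_low <= 1.0 <= res.cox.ci_high
        assert covered / 60 >= 0.85

    def test_empty_stratum_error_names_cutoff(self):
        df = pd.DataFrame(
            {"ctc_manual": [5, 6, 7], "os_months": [1, 2, 3], "os_event": [1, 1, 1]}
        )
        with pytest.raises(ValueError, match="cutoff 1"):
            stratify_and_compare(df, "ctc_manual", cutoff=1)


def _benchmark_cohort(seed=0, n=200):
    rng = np.random.default_rng(seed)
    true = rng.poisson(0.8, n)
    status = true >= 1
    t = rng.exponential(np.where(status, 8, 45))
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "ctc_manual": true + rng.poisson(0.7, n),  # noisy method A
            "ctc_auto": true,                          # truth-faithful method B
            "os_months": np.maximum(t, 0.1),
            "os_event": np.ones(n, int),
        }
    )
    return df


class TestBenchmarkDiscordant:
    def test_patient_far_above_both_medians_favors_negative_call(self):
        # concordant strata with clearly separated survival
        rows = []
        for i, (t, pos) in enumerate(
            [(5, 1), (6, 1), (7, 1), (8, 1), (40, 0), (45, 0), (50, 0), (55, 0)]
        ):
            rows.append(("C%d" % i, pos, pos, t))
        rows.append(("D0", 0, 1, 200.0))  # discordant, survives far beyond both
        df = pd.DataFrame(rows, columns=["patient_id", "ctc_manual", "ctc_auto", "os_months"])
        df["os_event"] = 1
        for policy in ("nearest_median", "midpoint", "km_likelihood"):
            res = benchmark_discordant(
                df, "ctc_manual", "ctc_auto", cutoff=1, policy=policy
            )
            adj = res.adjudications[0]
            assert adj["expected_positive"] is False
            assert adj["method_a_correct"] is True   # manual called negative
            assert adj["method_b_correct"] is False  # automated called positive

    def test_zero_discordant_patients_flagged_with_empty_matrix(self):
        df = pd.DataFrame(
            {
                "patient_id": ["P1", "P2", "P3", "P4"],
                "ctc_manual": [0, 0, 2, 3],
                "ctc_auto": [0, 0, 5, 9],
                "os_months": [40.0, 35.0, 8.0, 6.0],
                "os_event": [1, 1, 1, 1],
            }
        )
        res = benchmark_discordant(df, "ctc_manual", "ctc_auto", cutoff=1)
        assert res.flagged
        assert res.matrix == [[0, 0], [0, 0]]
        assert res.fisher_p is None

    def test_matrix_cells_sum_to_twice_discordant_count(self):
        df = _benchmark_cohort(seed=1)
        res = benchmark_discordant(df, "ctc_manual", "ctc_auto", cutoff=1)
        assert sum(sum(row) for row in res.matrix) == 2 * res.n_discordant

    def test_truth_faithful_method_wins_most_replicates(self):
        wins = tries = 0
        for seed in range(50):
            df = _benchmark_cohort(seed=seed)
            try:
                res = benchmark_discordant(df, "ctc_manual", "ctc_auto", cutoff=1)
            except ValueError:
                continue
            if res.fisher_p is None:
                continue
            tries += 1
            wins += res.correct_fraction("b") >= res.correct_fraction("a")
        assert tries > 40
        assert wins / tries >= 0.85

    def test_empty_concordant_stratum_rejected(self):
        df = pd.DataFrame(
            {
                "patient_id": ["P1", "P2", "P3"],
                "ctc_manual": [1, 2, 0],
                "ctc_auto": [1, 2, 1],
                "os_months": [10.0, 12.0, 30.0],
                "os_event": [1, 1, 1],
            }
        )
        with pytest.raises(ValueError, match="concordant"):
            benchmark_discordant(df, "ctc_manual", "ctc_auto", cutoff=1)
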