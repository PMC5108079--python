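"""Outcome statistics: adjudication, ROC, rates, survival, NRI, agreement."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import septalge as s
class TestAdjudication:
    def test_published_event_tally(self, paper_count_cohort):
        df = s.adjudicate_endpoints(paper_count_cohort)
        assert int(df["primary_event"].sum()) == 20
        assert int(df["secondary_event"].sum()) == 15

    def test_patient_with_both_counts_once_at_earliest_time(self):
        df = pd.DataFrame(
            {
                "patient_id": ["A"],
                "followup_years": [3.0],
                "cardiac_death": [1],
                "appropriate_icd": [1],
                "scd": [0],
                "noncardiac_death": [0],
                "time_cardiac_death": [2.5],
                "time_appropriate_icd": [1.0],
            }
        )
        out = s.adjudicate_endpoints(df)
        assert int(out["primary_event"].sum()) == 1
        assert out.loc[0, "primary_time"] == 1.0

    def test_event_after_followup_rejected_with_patient_id(self):
        df = pd.DataFrame(
            {
                "patient_id": ["A", "B"],
                "followup_years": [1.0, 1.0],
                "cardiac_death": [0, 1],
                "appropriate_icd": [0, 0],
                "scd": [0, 0],
                "noncardiac_death": [0, 0],
                "time_cardiac_death": [np.nan, 2.0],
            }
        )
        with pytest.raises(ValueError, match="B"):
            s.adjudicate_endpoints(df)

    def test_no_events_all_censored(self):
        df = pd.DataFrame(
            {
                "patient_id": ["A", "B"],
                "followup_years": [1.0, 2.0],
                "cardiac_death": [0, 0],
                "appropriate_icd": [0, 0],
                "scd": [0, 0],
                "noncardiac_death": [0, 0],
            }
        )
        out = s.adjudicate_endpoints(df)
        assert out["primary_event"].sum() == 0
        assert (out["primary_time"] == out["followup_years"]).all()


class TestRocCutoff:
    def test_perfect_separation_reports_midpoint(self):
        cutoff, sens, spec = s.roc_optimal_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert cutoff == pytest.approx(0.5)
        assert sens == 100.0 and spec == 100.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            s.roc_optimal_cutoff([1.0, 1.0, 1.0], [0, 1, 0])
        with pytest.raises(ValueError, match="classes"):
            s.roc_optimal_cutoff([1.0, 2.0], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    def test_equals_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        v = np.round(rng.normal(size=20), 1)  # ties are likely
        y = rng.random(20) < 0.4
        if y.all() or not y.any() or np.unique(v).size < 2:
            return
        cutoff, sens, spec = s.roc_optimal_cutoff(v, y)
        # oracle: brute-force loop over every midpoint candidate
        distinct = sorted(set(v))
        best = None
        for a, b in zip(distinct[:-1], distinct[1:]):
            c = (a + b) / 2
            tp = sum(1 for vi, yi in zip(v, y) if yi and vi > c)
            tn = sum(1 for vi, yi in zip(v, y) if not yi and vi <= c)
            se_ = tp / y.sum()
            sp_ = tn / (~y).sum()
            key = (se_ + sp_ - 1, sp_, c)
            if best is None or key > best[0]:
                best = (key, c, se_, sp_)
        assert cutoff == pytest.approx(best[1])
        assert sens == pytest.approx(100 * best[2])
        assert spec == pytest.approx(100 * best[3])


class TestDiagnostics:
    def test_reconstructed_2x2(self):
        # 20 events / 98 non-events; TP 14, FN 6, TN 73, FP 25
        test = [True] * 14 + [False] * 6 + [True] * 25 + [False] * 73
        outcome = [True] * 20 + [False] * 98
        d = s.diagnostic_metrics(test, outcome)
        assert d.sensitivity == pytest.approx(70.0)
        assert d.specificity == pytest.approx(100 * 73 / 98)
        assert d.npv == pytest.approx(100 * 73 / 79)
        assert d.n_missed == 6
        assert d.tp + d.fn == 20  # TP+FN equals the event count

    def test_perfect_test(self):
        d = s.diagnostic_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert (d.sensitivity, d.specificity, d.ppv, d.npv) == (100.0, 100.0, 100.0, 100.0)
        assert d.n_missed == 0

    def test_all_negative_test(self):
        d = s.diagnostic_metrics([0, 0, 0, 0], [1, 1, 0, 0])
        assert d.sensitivity == 0.0
        assert d.n_missed == 2
        assert math.isnan(d.ppv)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            s.diagnostic_metrics([1, 0], [1, 1])


class TestAnnualEventRate:
    def test_person_time_arithmetic(self):
        times = [2.0] * 10
        events = [1, 1, 1, 1] + [0] * 6
        res = s.annual_event_rate(times, events, ["g"] * 10)
        assert res.rates["g"] == pytest.approx(20.0)  # 4 / 20 py per 100

    def test_zero_events_zero_rate(self):
        res = s.annual_event_rate([1.0, 2.0], [0, 0], ["a", "b"])
        assert res.rates == {"a": 0.0, "b": 0.0}
        assert res.p_value == 1.0

    def test_invariant_to_record_splitting(self):
        whole = s.annual_event_rate([2.0, 3.0], [1, 0], ["g", "g"])
        split = s.annual_event_rate([1.0, 1.0, 3.0], [0, 1, 0], ["g", "g", "g"])
        assert whole.rates["g"] == pytest.approx(split.rates["g"])

    def test_zero_person_time_rejected(self):
        with pytest.raises(ValueError):
            s.annual_event_rate([0.0, 0.0], [0, 0], ["a", "a"])

    def test_two_group_poisson_p(self):
        res = s.annual_event_rate(
            [1.0] * 40, [1] * 15 + [0] * 5 + [0] * 20, ["hi"] * 20 + ["lo"] * 20
        )
        assert res.p_value < 0.001


class TestKaplanMeier:
    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(2.0, 60)
        km = s.km_estimate(t, np.ones(60, dtype=bool))
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            ecdf = (t <= q).mean()
            assert km.at(q) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_two_deaths_of_two(self):
        km = s.km_estimate([1.0, 2.0], [1, 1])
        assert km.at(0.5) == 1.0
        assert km.at(1.0) == pytest.approx(0.5)
        assert km.at(2.0) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        km = s.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.at(3.0) == 1.0

    def test_exponential_data_tracks_closed_form(self):
        rng = np.random.default_rng(8)
        lam = 0.5
        t = rng.exponential(1 / lam, 4000)
        km = s.km_estimate(t, np.ones(4000, dtype=bool))
        for q in (0.5, 1.0, 2.0):
            assert km.at(q) == pytest.approx(math.exp(-lam * q), abs=0.03)


class TestLogrank:
    def test_extreme_separation(self):
        ta, ea = [1.0] * 20, [1] * 20
        tb, eb = [5.0] * 20, [0] * 20
        chi2, p = s.logrank_test(ta, ea, tb, eb)
        assert p < 1e-6 and chi2 > 20

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(1, 30), rng.exponential(2, 25)
        ea, eb = np.ones(30, bool), np.ones(25, bool)
        c1, p1 = s.logrank_test(ta, ea, tb, eb)
        c2, p2 = s.logrank_test(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2)
        assert p1 == pytest.approx(p2)

    def test_requires_events(self):
        with pytest.raises(ValueError, match="event"):
            s.logrank_test([1.0], [0], [2.0], [0])


@pytest.fixture(scope="module")
def cohort():
    return s.adjudicate_endpoints(s.generate_cohort(s.CohortSpec(n_patients=800, seed=17)))


class TestCox:
    def test_duplicated_covariate_rejected(self, cohort):
        df = cohort.copy()
        df["septal_copy"] = df["septal_pct_5sd"]
        with pytest.raises(s.CollinearityError, match="septal"):
            s.cox_fit(df, ["septal_pct_5sd", "septal_copy"])

    def test_constant_covariate_rejected(self, cohort):
        df = cohort.copy()
        df["constant"] = 1.0
        with pytest.raises(s.CollinearityError, match="constant"):
            s.cox_fit(df, ["constant", "lvef_pct"])

    def test_binary_two_group_exponential_rate_ratio(self):
        # Cox HR for a binary covariate converges to the rate ratio
        rng = np.random.default_rng(12)
        n = 5000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0, n) / np.where(x > 0, 0.6, 0.2)
        df = pd.DataFrame({"primary_time": t, "primary_event": True, "x": x})
        fit = s.cox_fit(df, ["x"], run_ph_test=False)
        assert fit.effect("x").hazard_ratio == pytest.approx(3.0, rel=0.05)

    def test_reports_wald_chi2_and_ph_diagnostic(self, cohort):
        fit = s.cox_fit(cohort, ["septal_pct_5sd"])
        eff = fit.effect("septal_pct_5sd")
        assert eff.chi2 > 0 and 0 <= eff.p <= 1
        assert eff.ci_lower < eff.hazard_ratio < eff.ci_upper
        assert "septal_pct_5sd" in fit.ph_test_p


class TestNri:
    def test_identity_is_zero(self):
        risks = np.array([0.1, 0.2, 0.3, 0.4])
        res = s.nri(risks, risks.copy(), [1, 0, 1, 0])
        assert res.nri == 0.0

    def test_maximum_is_two(self):
        base = np.array([0.5, 0.5, 0.5, 0.5])
        aug = np.array([0.9, 0.9, 0.1, 0.1])
        res = s.nri(base, aug, [1, 1, 0, 0])
        assert res.nri == pytest.approx(2.0)

    def test_hand_computed_example(self):
        # 4 events: 3 up / 1 down; 6 non-events: 2 up / 4 down
        base = np.full(10, 0.5)
        aug = np.array([0.6, 0.7, 0.8, 0.4, 0.6, 0.6, 0.3, 0.2, 0.1, 0.4])
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        res = s.nri(base, aug, y)
        assert res.nri == pytest.approx((3 - 1) / 4 + (4 - 2) / 6)
        assert res.nri == pytest.approx(0.8333, abs=1e-4)

    def test_antisymmetric_under_model_swap(self):
        rng = np.random.default_rng(2)
        base, aug = rng.random(50), rng.random(50)
        y = rng.random(50) < 0.3
        assert s.nri(base, aug, y).nri == pytest.approx(-s.nri(aug, base, y).nri)

    def test_all_tied_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            res = s.nri([0.1, 0.2], [0.1, 0.2], [1, 0])
        assert res.nri == 0.0
        assert any("tied" in r.message for r in caplog.records)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(6)
        y = rng.random(200) < 0.3
        base = np.clip(rng.random(200), 0.01, 0.99)
        aug = np.clip(base + np.where(y, 0.1, -0.1) + rng.normal(0, 0.1, 200), 0.01, 0.99)
        est = s.nri(base, aug, y)
        lo, hi = s.nri_bootstrap_ci(base, aug, y, n_boot=200, seed=1)
        assert lo < est.nri < hi


class TestIcc:
    def test_identical_readings_equal_one(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        res = s.icc(x)
        assert res.icc == pytest.approx(1.0)

    def test_matches_pingouin_two_way_random_absolute(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        subj = rng.normal(10, 3, 40)
        x = np.column_stack([subj + rng.normal(0, 1, 40), subj + 0.5 + rng.normal(0, 1, 40)])
        res = s.icc(x)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile(["a", "b"], 40),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci = row[[c for c in ref.columns if c.startswith("CI95")][0]]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert res.icc_ci[0] == pytest.approx(ci[0], abs=0.02)
        assert res.icc_ci[1] == pytest.approx(ci[1], abs=0.02)

    def test_variance_components_closed_form(self):
        rng = np.random.default_rng(13)
        n, s2_subj, s2_noise = 500, 9.0, 1.0
        subj = rng.normal(0, math.sqrt(s2_subj), n)
        x = subj[:, None] + rng.normal(0, math.sqrt(s2_noise), (n, 2))
        res = s.icc(x)
        assert res.icc == pytest.approx(s2_subj / (s2_subj + s2_noise), abs=0.02)

    def test_independent_readings_near_zero(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, (500, 2))
        assert abs(s.icc(x).icc) < 0.1

    def test_zero_between_subject_variance_rejected(self):
        with pytest.raises(ValueError, match="between-subject"):
            s.icc(np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]))


class TestBlandAltman:
    def test_identical_pairs(self):
        res = s.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.sd_diff == 0.0
        assert res.loa_lower == res.loa_upper == 0.0

    def test_constant_offset(self):
        res = s.bland_altman([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert res.bias == pytest.approx(2.0)
        assert res.sd_diff == 0.0

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(10, 2, 30), rng.normal(10, 2, 30)
        res = s.bland_altman(a, b)
        d = b - a
        assert res.bias == pytest.approx(d.mean())
        assert res.sd_diff == pytest.approx(d.std(ddof=1))
        assert res.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        pts = s.bland_altman_points(a, b)
        assert pts["difference"].to_numpy() == pytest.approx(d)
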