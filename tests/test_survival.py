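import numpy as np
import pandas as pd
import pytest

from concord.stats import DegenerateInputError
from concord.survival import (
    cox_fit,
    covariate_omission_scan,
    gap_sensitivity,
    km_logrank,
    threshold_analysis,
)


def surv_frame(time, event, **covs):
    return pd.DataFrame({"time_months": time, "event": event, **covs})


class TestKmLogrank:
    def test_no_deaths_curves_at_one(self):
        f = surv_frame([5.0, 8, 12, 20], [False] * 4, g=["a", "a", "b", "b"])
        res = km_logrank(f, "g")
        assert res.all_censored
        assert res.p_likelihood_ratio is None
        for curve in res.curves.values():
            assert np.allclose(curve["survival"], 1.0)

    def test_hand_computed_product_limit(self):
        # one group; deaths at t=2 (n at risk 6) and t=4 (n at risk 4);
        # censored at 3, 5, 6, 7.  S(2)=5/6, S(4)=5/6 * 3/4 = 0.625
        f = surv_frame(
            [2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
            [True, False, True, False, False, False],
            g=["a"] * 6,
        )
        res = km_logrank(f, "g")
        curve = res.curves["a"].set_index("timeline")["survival"]
        assert curve.loc[2.0] == pytest.approx(5 / 6)
        assert curve.loc[4.0] == pytest.approx(5 / 6 * 3 / 4)

    def test_curves_non_increasing_from_one(self, preset_frame):
        frame, _ = preset_frame
        res = km_logrank(frame, "status")
        for curve in res.curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] <= 1.0 + 1e-12
            assert np.all(np.diff(surv) <= 1e-12)

    def test_reports_all_three_pvalues(self, preset_frame):
        frame, _ = preset_frame
        res = km_logrank(frame, "mutual_gene_count")
        assert res.p_likelihood_ratio is not None
        assert res.p_score is not None
        assert res.p_wald is not None  # numeric trend covariate -> one term


class TestCoxFit:
    def test_two_group_exponential_rate_ratio(self):
        # closed-form oracle: exponential groups with rates 1 and 2 have
        # true hazard ratio exactly 2; estimate has SE(log HR) ~ sqrt(4/n)
        rng = np.random.default_rng(2024)
        n = 4000
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(1.0 / np.where(x > 0, 2.0, 1.0))
        fit = cox_fit(surv_frame(t, [True] * n, x=x), ["x"])
        term = fit.term("x")
        se = np.sqrt(4.0 / n)
        assert abs(term.coef - np.log(2.0)) < 3.5 * se
        assert term.ci_high / term.ci_low == pytest.approx(
            np.exp(2 * 1.959964 * se), rel=0.15
        )

    def test_zero_variance_covariate_rejected(self):
        f = surv_frame([1.0, 2, 3, 4], [True] * 4, x=[0.0, 0, 0, 0])
        with pytest.raises(DegenerateInputError, match="zero variance"):
            cox_fit(f, ["x"])

    def test_no_events_rejected(self):
        f = surv_frame([1.0, 2, 3], [False] * 3, x=[0.0, 1, 2])
        with pytest.raises(DegenerateInputError, match="no events"):
            cox_fit(f, ["x"])

    def test_categorical_reference_level(self, rng):
        n = 300
        g = rng.choice(["a", "b", "c"], n)
        t = rng.exponential(1.0, n)
        fit = cox_fit(
            surv_frame(t, [True] * n, g=g), ["g"], reference_levels={"g": "b"}
        )
        names = [t_.term for t_ in fit.terms]
        assert set(names) == {"g=a", "g=c"}
        assert fit.reference_levels == {"g": "b"}

    def test_missing_reference_level_rejected(self, rng):
        f = surv_frame([1.0, 2, 3, 4], [True] * 4, g=["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="absent"):
            cox_fit(f, ["g"], reference_levels={"g": "zzz"})

    def test_time_scale_invariance(self, preset_frame):
        frame, _ = preset_frame
        covs = ["age_at_diagnosis", "mutual_gene_count"]
        fit1 = cox_fit(frame, covs)
        doubled = frame.copy()
        doubled["time_months"] = doubled["time_months"] * 2.0
        fit2 = cox_fit(doubled, covs)
        for t1, t2 in zip(fit1.terms, fit2.terms):
            assert t1.hazard_ratio == pytest.approx(t2.hazard_ratio, rel=1e-6)
            assert t1.p == pytest.approx(t2.p, rel=1e-5, abs=1e-12)

    def test_ci_brackets_hr(self, preset_frame):
        frame, _ = preset_frame
        fit = cox_fit(frame, ["mutual_gene_count", "age_at_diagnosis"])
        for term in fit.terms:
            assert term.ci_low <= term.hazard_ratio <= term.ci_high
            assert term.hazard_ratio > 0


class TestThresholdAnalysis:
    def test_k1_equals_raw_count_on_binary_counts(self, rng):
        n = 400
        count = rng.integers(0, 2, n).astype(float)
        f = surv_frame(
            rng.exponential(10.0 / (1 + count)), [True] * n,
            mutual_gene_count=count, age=rng.normal(60, 10, n),
        )
        raw = cox_fit(f, ["age", "mutual_gene_count"])
        thr = threshold_analysis(f, "mutual_gene_count", 1, covariates=["age"])
        assert thr.term("mutual_gene_count_ge1").coef == pytest.approx(
            raw.term("mutual_gene_count").coef, abs=1e-8
        )

    def test_constant_indicator_rejected(self, rng):
        f = surv_frame(
            rng.exponential(1, 50), [True] * 50,
            mutual_gene_count=np.zeros(50), age=rng.normal(size=50),
        )
        with pytest.raises(DegenerateInputError, match="constant"):
            threshold_analysis(f, "mutual_gene_count", 2, covariates=["age"])

    def test_k_validation(self, preset_frame):
        frame, _ = preset_frame
        with pytest.raises(ValueError):
            threshold_analysis(frame, "mutual_gene_count", 0)


class TestGapSensitivity:
    def test_infinite_threshold_reproduces_full_fit(self, preset_frame):
        frame, _ = preset_frame
        covs = ["age_at_diagnosis", "pct_ctdna", "gap_months"]
        rows = gap_sensitivity(frame, [np.inf], covariates=covs)
        full = cox_fit(frame, [c for c in covs] + ["mutual_gene_count"])
        assert rows[0].p == pytest.approx(full.term("mutual_gene_count").p, abs=1e-10)
        assert rows[0].n == full.n

    def test_smaller_threshold_retains_fewer(self, preset_frame):
        frame, _ = preset_frame
        covs = ["age_at_diagnosis", "pct_ctdna"]
        rows = gap_sensitivity(frame, [6.0, 24.0, np.inf], covariates=covs)
        ns = [r.n for r in rows]
        assert ns[0] <= ns[1] <= ns[2]

    def test_nonpositive_threshold_rejected(self, preset_frame):
        frame, _ = preset_frame
        with pytest.raises(ValueError):
            gap_sensitivity(frame, [0.0])


class TestCovariateOmissionScan:
    def test_rows_cover_all_other_covariates(self, preset_frame):
        frame, _ = preset_frame
        covs = ["age_at_diagnosis", "pct_ctdna", "tmb", "mutual_gene_count"]
        full, rows = covariate_omission_scan(
            frame, "mutual_gene_count", covariates=covs
        )
        assert [r.omitted for r in rows] == ["age_at_diagnosis", "pct_ctdna", "tmb"]
        assert all(r.error is None for r in rows)

    def test_omitting_independent_covariate_barely_moves_target(self, rng):
        n = 1500
        x = rng.integers(0, 3, n).astype(float)
        z = rng.normal(size=n)  # independent of both x and the hazard
        t = rng.exponential(1.0 / np.exp(0.3 * x))
        f = surv_frame(t, [True] * n, x=x, z=z)
        full, rows = covariate_omission_scan(f, "x", covariates=["z", "x"])
        p_full = full.term("x").p
        p_omitted = rows[0].target_terms[0].p
        # both should detect the strong true effect equally well
        assert np.log10(max(p_omitted, 1e-300)) == pytest.approx(
            np.log10(max(p_full, 1e-300)), abs=1.0
        )
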