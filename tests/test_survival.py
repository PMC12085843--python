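"""Cox models, PH diagnostics, trend test, restricted cubic splines."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gidiet.config import SimulationConfig
from gidiet.simulate import simulate_outcomes
from gidiet.survival import test_proportional_hazards as schoenfeld_test  # noqa: import alias keeps pytest from collecting it
from gidiet.survival import (
    ModelSpec,
    fit_cox,
    fit_rcs,
    rcs_basis,
    subgroup_analysis,
    trend_test,
)


def exposure_cohort(n, rng, loghr=0.0, rate=0.1, horizon=10.0, binary=True):
    """Exponential survival data with one exposure column, no covariates."""
    x = (rng.random(n) < 0.5).astype(float) if binary else rng.normal(size=n)
    t = rng.exponential(1.0 / (rate * np.exp(loghr * x)))
    event = (t <= horizon).astype(int)
    return pd.DataFrame(
        {
            "x": x,
            "followup_years": np.minimum(t, horizon),
            "event_overall": event,
        }
    )


def spec_no_cov(exposure="x"):
    return ModelSpec(exposure, covariates=())


class TestFitCox:
    def test_two_group_exponential_matches_closed_form_mle(self, rng):
        # the exponential-rate-ratio MLE d1/T1 / (d0/T0) is the oracle
        df = exposure_cohort(50_000, rng, loghr=np.log(2.0), rate=0.05)
        fit = fit_cox(df, spec_no_cov())
        g1, g0 = df[df.x == 1], df[df.x == 0]
        mle = (g1.event_overall.sum() / g1.followup_years.sum()) / (
            g0.event_overall.sum() / g0.followup_years.sum()
        )
        hr = fit.summary.loc["x", "hr"]
        assert hr == pytest.approx(mle, rel=0.02)
        assert hr == pytest.approx(2.0, rel=0.06)
        lo, hi = fit.summary.loc["x", ["ci_low", "ci_high"]]
        assert lo < hr < hi

    def test_constant_exposure_is_an_error_not_a_silent_drop(self, rng):
        df = exposure_cohort(200, rng)
        df["x"] = 1.0
        with pytest.raises(ValueError, match="constant.*x"):
            fit_cox(df, spec_no_cov())

    def test_zero_events_rejected(self, rng):
        df = exposure_cohort(100, rng)
        df["event_overall"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, spec_no_cov())

    def test_collinear_covariates_named(self, rng):
        df = exposure_cohort(300, rng)
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(ValueError, match="collinear"):
            fit_cox(df, ModelSpec("x", covariates=("x2",)))

    def test_rescaling_exposure_preserves_likelihood(self, rng):
        df = exposure_cohort(2_000, rng, loghr=0.5, binary=False)
        a = fit_cox(df, spec_no_cov())
        df2 = df.assign(x=df.x * 3.0)
        b = fit_cox(df2, spec_no_cov())
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-6)
        assert a.summary.loc["x", "coef"] == pytest.approx(
            3.0 * b.summary.loc["x", "coef"], rel=1e-4
        )

    def test_categorical_exposure_uses_first_level_as_reference(self, small_cohort):
        fit = fit_cox(small_cohort, ModelSpec("digm_group", covariates=("age", "sex")))
        assert set(fit.exposure_terms) == {
            "digm_group[moderate]",
            "digm_group[high]",
        }


class TestProportionalHazards:
    def test_single_term_global_equals_term_test(self, rng):
        df = exposure_cohort(3_000, rng, loghr=0.3)
        fit = fit_cox(df, spec_no_cov())
        tbl = schoenfeld_test(fit)
        assert tbl.loc["GLOBAL", "p"] == pytest.approx(tbl.loc["x", "p"], abs=1e-9)

    def test_null_pvalues_roughly_uniform(self):
        ps = []
        for i in range(120):
            rng = np.random.default_rng(1000 + i)
            df = exposure_cohort(800, rng, loghr=0.0)
            fit = fit_cox(df, spec_no_cov())
            ps.append(schoenfeld_test(fit).loc["x", "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_time_varying_effect(self):
        # exposed hazard switches sign at t=2: a strong PH violation
        hits = 0
        for i in range(20):
            rng = np.random.default_rng(2000 + i)
            n, b = 4_000, 1.0
            x = (rng.random(n) < 0.5).astype(float)
            rate_early, rate_late = 0.2 * np.exp(b * x), 0.2 * np.exp(-b * x)
            t1 = rng.exponential(1.0 / rate_early)
            t = np.where(t1 <= 2.0, t1, 2.0 + rng.exponential(1.0 / rate_late))
            df = pd.DataFrame(
                {
                    "x": x,
                    "followup_years": np.minimum(t, 8.0),
                    "event_overall": (t <= 8.0).astype(int),
                }
            )
            fit = fit_cox(df, spec_no_cov())
            if schoenfeld_test(fit).loc["x", "p"] < 0.05 :
                hits += 1
        assert hits >= 16  # >= 80% power at this effect size


class TestTrend:
    def _grouped(self, rng, n=4_000, slope=0.0):
        g = rng.integers(0, 3, size=n)
        t = rng.exponential(1.0 / (0.1 * np.exp(slope * g)))
        df = pd.DataFrame(
            {
                "grp": pd.Categorical(
                    np.array(["low", "moderate", "high"])[g],
                    categories=["low", "moderate", "high"],
                    ordered=True,
                ),
                "followup_years": np.minimum(t, 10.0),
                "event_overall": (t <= 10.0).astype(int),
            }
        )
        return df

    def test_monotone_effect_gives_small_p(self, rng):
        df = self._grouped(rng, slope=0.4)
        assert trend_test(df, ModelSpec("grp", covariates=())) < 1e-6

    def test_affine_invariance_of_scores(self, rng):
        # shifting integer scores by a constant leaves the Wald p unchanged
        df = self._grouped(rng, slope=0.2)
        df["s0"] = df["grp"].cat.codes.astype(float)
        df["s1"] = df["s0"] + 1.0
        p0 = fit_cox(df, spec_no_cov("s0")).summary.loc["s0", "p"]
        p1 = fit_cox(df, spec_no_cov("s1")).summary.loc["s1", "p"]
        assert p0 == pytest.approx(p1, rel=1e-6)
        assert trend_test(df, ModelSpec("grp", covariates=())) == pytest.approx(
            p0, rel=1e-6
        )

    def test_too_few_levels_rejected(self, rng):
        df = self._grouped(rng)
        df["grp"] = pd.Categorical(
            np.where(df["grp"] == "low", "low", "high"), categories=["low", "high"]
        )
        with pytest.raises(ValueError, match=">= 3 levels"):
            trend_test(df, ModelSpec("grp", covariates=()))


class TestRcsBasis:
    def test_linear_tails_and_smoothness(self):
        knots = [-1.0, 0.0, 1.0, 2.0]
        x = np.linspace(-4, 5, 2001)
        basis = rcs_basis(x, knots)
        assert basis.shape == (2001, 3)
        # second differences vanish outside the boundary knots
        for j in range(1, 3):
            col = basis[:, j]
            d2 = np.diff(col, 2)
            left = x[1:-1] < -1.0
            right = x[1:-1] > 2.0
            assert np.allclose(d2[left], 0.0, atol=1e-9)
            assert np.allclose(d2[right], 0.0, atol=1e-9)
            assert np.abs(d2).max() > 1e-6  # genuinely nonlinear inside

    def test_span_matches_patsy_natural_spline(self, rng):
        # same knots, different parameterization: identical model fit
        patsy = pytest.importorskip("patsy")
        df = exposure_cohort(3_000, rng, binary=False)
        x = df["x"].to_numpy()
        knots = np.percentile(x, [5, 35, 65, 95])
        mine = rcs_basis(x, knots)
        theirs = patsy.dmatrix(
            "cr(x, knots=inner, lower_bound=lb, upper_bound=ub) - 1",
            {"x": x, "inner": knots[1:-1], "lb": knots[0], "ub": knots[-1]},
            return_type="dataframe",
        ).to_numpy()
        # column spaces agree: each basis reproduces the other by regression
        resid = mine - theirs @ np.linalg.lstsq(theirs, mine, rcond=None)[0]
        assert np.abs(resid).max() < 1e-8

        def ll(mat):
            work = df.copy()
            names = [f"b{j}" for j in range(mat.shape[1])]
            for j, nm in enumerate(names):
                work[nm] = mat[:, j]
            from lifelines import CoxPHFitter

            cph = CoxPHFitter().fit(
                work[names + ["followup_years", "event_overall"]],
                "followup_years",
                "event_overall",
            )
            return cph.log_likelihood_

        assert ll(mine) == pytest.approx(ll(theirs[:, 1:]), abs=1e-6)

    def test_tied_knots_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            rcs_basis(np.arange(10.0), [0.0, 0.0, 1.0, 2.0])


class TestFitRcs:
    def _cohort(self, rng, n=6_000, quadratic=0.0):
        x = rng.normal(size=n)
        lp = 0.3 * x + quadratic * x**2
        t = rng.exponential(1.0 / (0.08 * np.exp(lp)))
        return pd.DataFrame(
            {
                "x": x,
                "followup_years": np.minimum(t, 10.0),
                "event_overall": (t <= 10.0).astype(int),
            }
        )

    def test_reference_value_has_unit_hazard_ratio(self, rng):
        df = self._cohort(rng)
        res = fit_rcs(df, spec_no_cov(), reference=0.5)
        i = np.argmin(np.abs(res.curve["x"].to_numpy() - 0.5))
        # grid point nearest the reference: HR within interpolation error of 1
        assert res.curve["hr"].iloc[i] == pytest.approx(1.0, abs=0.02)
        assert res.reference == 0.5
        assert len(res.knots) == 4
        assert (np.diff(res.knots) > 0).all()

    def test_detects_strong_curvature(self, rng):
        df = self._cohort(rng, quadratic=0.4)
        res = fit_rcs(df, spec_no_cov())
        assert res.p_nonlinearity < 0.01

    def test_linear_truth_gives_moderate_p(self, rng):
        df = self._cohort(rng)
        res = fit_rcs(df, spec_no_cov())
        assert res.p_nonlinearity > 0.001  # single draw; full calibration elsewhere

    def test_degenerate_exposure_rejected(self, rng):
        df = self._cohort(rng, n=200)
        df["x"] = np.round(df["x"] * 0)  # constant
        with pytest.raises(ValueError, match="tied knots|degenerate"):
            fit_rcs(df, spec_no_cov())


class TestSubgroups:
    def test_identical_strata_give_identical_hrs(self, rng):
        df = exposure_cohort(2_000, rng, loghr=0.4)
        dup = pd.concat(
            [df.assign(stratum="a"), df.assign(stratum="b")], ignore_index=True
        )
        res = subgroup_analysis(dup, spec_no_cov(), by="stratum")
        assert res.per_stratum["a"].summary.loc["x", "hr"] == pytest.approx(
            res.per_stratum["b"].summary.loc["x", "hr"]
        )
        assert res.p_interaction > 0.99  # exactly homogeneous

    def test_zero_event_stratum_skipped_with_warning(self, rng):
        df = exposure_cohort(1_000, rng, loghr=0.0)
        df["stratum"] = np.where(np.arange(len(df)) < 500, "a", "b")
        df.loc[df["stratum"] == "b", "event_overall"] = 0
        df.loc[df["stratum"] == "b", "followup_years"] = 5.0
        with pytest.warns(UserWarning, match="no events"):
            res = subgroup_analysis(df, spec_no_cov(), by="stratum")
        assert res.skipped == ["b"]
        assert "a" in res.per_stratum

    def test_planted_heterogeneous_effect_detected(self):
        rng = np.random.default_rng(77)
        n = 12_000
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        x = rng.normal(size=n)
        b = np.where(sex == "male", -0.4, 0.0)
        t = rng.exponential(1.0 / (0.1 * np.exp(b * x)))
        df = pd.DataFrame(
            {
                "x": x,
                "sex": sex,
                "followup_years": np.minimum(t, 10.0),
                "event_overall": (t <= 10.0).astype(int),
            }
        )
        res = subgroup_analysis(df, spec_no_cov(), by="sex")
        assert res.p_interaction < 0.01
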