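"""The maximum-survivable-age estimator: exactness on log-linear input,
realism on hazard-integrated tables, delta-method CIs, series behaviour,
and record validation against estimated limits."""

import math

import numpy as np
import pytest

from msalimit import (
    DeathRecord,
    GompertzParams,
    InsufficientDataError,
    LogLinearFit,
    LogLinearMortality,
    NonProjectableFitError,
    ZeroLogError,
    check_records_against_msa,
    fit_loglinear_mortality,
    lifetable_from_deaths,
    make_gompertz_lifetable,
    make_improving_series,
    make_loglinear_q_table,
    msa_from_fit,
    msa_series,
    sample_deaths_from_table,
)


class TestExactness:
    def test_recovers_slope_intercept_exactly(self, loglinear_table):
        fit = fit_loglinear_mortality(loglinear_table, age_window=(40, 95))
        assert fit.slope == pytest.approx(0.1, abs=1e-9)
        assert fit.intercept == pytest.approx(math.log(1e-4), abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("window", [(40, 95), (50, 90), (20, 80), (60, 92)])
    def test_msa_window_independent_on_loglinear_input(self, loglinear_table, window):
        res = LogLinearMortality.from_lifetable(loglinear_table, age_window=window).fit()
        assert res.msa == pytest.approx(-math.log(1e-4) / 0.1, rel=1e-9)

    def test_zero_residual_fit_has_zero_ci_width(self, loglinear_table):
        res = LogLinearMortality.from_lifetable(loglinear_table).fit()
        lo, hi = res.msa_ci95
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "a1,b1,a2,b2",
        [(1e-4, 0.1, 2e-4, 0.1), (1e-4, 0.1, 1e-4, 0.12)],
    )
    def test_msa_decreasing_in_a_and_b(self, a1, b1, a2, b2):
        m1 = LogLinearMortality.from_lifetable(
            make_loglinear_q_table(GompertzParams(a1, b1))).fit().msa
        m2 = LogLinearMortality.from_lifetable(
            make_loglinear_q_table(GompertzParams(a2, b2))).fit().msa
        assert m2 < m1
        assert m1 == pytest.approx(-math.log(a1) / b1, rel=1e-9)
        assert m2 == pytest.approx(-math.log(a2) / b2, rel=1e-9)


class TestRealism:
    def test_gompertz_table_fit_quality_and_projection(self, gompertz_table):
        res = LogLinearMortality.from_lifetable(gompertz_table, age_window=(40, 95)).fit()
        assert res.r2 > 0.99
        # the log-linear projection lands near the hazard's unit crossing
        assert abs(res.msa - (-math.log(3e-5) / 0.1)) < 1.5

    def test_saturated_q_always_excluded(self, loglinear_table):
        res = LogLinearMortality.from_lifetable(loglinear_table, age_window=(40, 110)).fit()
        assert res.ages_used.max() <= 92  # q = 1 from age 93 on


class TestProjection:
    def _fit(self, **kw):
        base = dict(intercept=math.log(1e-4), slope=0.1, r2=1.0, se_slope=0.0,
                    se_intercept=0.0, cov_si=0.0, n_ages=50, age_window=(40, 95))
        base.update(kw)
        return LogLinearFit(**base)

    def test_ratio_projection(self):
        est = msa_from_fit(self._fit())
        assert est.msa == pytest.approx(92.1034, abs=1e-4)
        assert est.ci95 == (est.msa, est.msa)

    def test_delta_method_variance(self):
        fit = self._fit(se_intercept=0.2, se_slope=0.002, cov_si=-0.0003)
        est = msa_from_fit(fit)
        m = est.msa
        var = (1 / 0.1**2) * (0.2**2 + m**2 * 0.002**2 + 2 * m * -0.0003)
        half = 1.96 * math.sqrt(var)
        assert est.ci95 == pytest.approx((m - half, m + half))
        assert est.ci95[0] <= m <= est.ci95[1]

    def test_nonpositive_slope_not_projectable(self):
        with pytest.raises(NonProjectableFitError):
            msa_from_fit(self._fit(slope=-0.05))

    def test_decreasing_mortality_not_projectable_at_fit_time(self):
        ages = np.arange(40, 96)
        qx = 1e-3 * np.exp(-0.05 * (ages - 40))  # mortality falling with age
        with pytest.raises(NonProjectableFitError):
            LogLinearMortality(ages, qx).fit()


class TestZeroPolicy:
    def test_fail_policy_raises_on_zero_qx(self):
        ages = sample_deaths_from_table(
            make_loglinear_q_table(GompertzParams(1e-4, 0.1)), 200, seed=0
        )
        emp = lifetable_from_deaths(ages, max_age=110)
        assert np.any(emp.qx[(emp.ages >= 40) & (emp.ages <= 95)] == 0)
        with pytest.raises(ZeroLogError):
            LogLinearMortality.from_lifetable(emp, zero_policy="fail").fit()
        # drop policy fits the same table fine
        LogLinearMortality.from_lifetable(emp, zero_policy="drop").fit()


class TestSeries:
    def test_improving_series_msa_matches_closed_form(self):
        b = 0.1
        tables = make_improving_series(
            GompertzParams(1e-4, b), 0.01, range(1950, 1971), kind="loglinear"
        )
        series = msa_series(tables, age_window=(40, 90))
        assert not series.failures
        msas = np.array([e.msa for e in series.estimates])
        years = np.array([e.index_year for e in series.estimates])
        expected = (-np.log(1e-4) + -np.log(0.99) * (years - 1950)) / b
        np.testing.assert_allclose(msas, expected, rtol=1e-9)
        assert np.all(np.diff(msas) > 0)
        # per-year gain is -ln(1 - annual_decline)/b
        np.testing.assert_allclose(np.diff(msas), -math.log(0.99) / b, rtol=1e-9)

    def test_single_table_matches_scalar_pipeline(self, gompertz_table):
        series = msa_series([gompertz_table])
        scalar = LogLinearMortality.from_lifetable(gompertz_table).fit()
        assert len(series.estimates) == 1
        assert series.estimates[0].msa == scalar.msa
        assert series.median_r2 == scalar.r2

    def test_failures_recorded_not_dropped(self, gompertz_table):
        bad = LogLinearMortality(np.arange(40, 96), 1e-3 * np.exp(-0.05 * np.arange(56)))
        tables = [gompertz_table]
        series = msa_series(tables, age_window=(200, 210))  # no usable ages
        assert series.estimates == []
        assert len(series.failures) == 1
        assert "InsufficientData" in series.failures[0][2]

    def test_frame_has_contracted_columns(self, gompertz_table):
        frame = msa_series([gompertz_table]).to_frame()
        assert list(frame.columns) == [
            "population", "year", "msa", "ci_low", "ci_high",
            "slope", "intercept", "r2", "n_ages", "status",
        ]


class TestSummary:
    def test_summary_mentions_key_quantities(self, gompertz_table):
        res = LogLinearMortality.from_lifetable(gompertz_table).fit()
        text = res.summary()
        assert "MSA" in text and "R^2" in text and "slope" in text
        assert f"{res.msa:10.4f}" in text


class TestRecordCheck:
    def _estimates(self, years, msa=110.0):
        fit = LogLinearFit(math.log(1e-4), 0.1, 1.0, 0.0, 0.0, 0.0, 50, (40, 95))
        from msalimit import MSAEstimate

        return [MSAEstimate("SYN", y, msa, (msa, msa), fit) for y in years]

    def test_empty_records(self):
        check = check_records_against_msa([], self._estimates([1990]))
        assert (check.n_within, check.n_exceeding) == (0, 0)

    def test_record_above_limit_counts_as_exceeding(self):
        est = self._estimates([1990], msa=110.0)
        records = [DeathRecord("X1", 111.0, 1990, 6, "SYN")]
        check = check_records_against_msa(records, est)
        assert check.n_exceeding == 1
        assert check.margins["margin"].iloc[0] == pytest.approx(-1.0)

    def test_unmatched_records_reported(self):
        est = self._estimates([1990])
        records = [DeathRecord("X1", 111.0, 1950, 6, "SYN")]
        check = check_records_against_msa(records, est)
        assert check.unmatched == ["X1"]
        assert check.n_within == check.n_exceeding == 0

    def test_birth_cohort_matching(self):
        est = self._estimates([1880])
        records = [DeathRecord("X1", 109.5, 1989, 6, "SYN")]  # born 1880
        check = check_records_against_msa(records, est, matching="birth_cohort")
        assert check.n_within == 1

    def test_panel_checked_by_direct_enumeration(self):
        # records and limits share a mortality law whose projected limit
        # (-ln(a)/b ~ 115) sits above the supercentenarian threshold
        from msalimit import CountrySpec, PanelSpec, simulate_record_panel

        params = GompertzParams(1e-5, 0.1)
        lt = make_gompertz_lifetable(params, max_age=130)
        res = LogLinearMortality.from_lifetable(lt, age_window=(40, 95)).fit()
        years = range(1980, 2011)
        est = [
            type(res.as_estimate())(
                population_id="SYN", index_year=y, msa=res.msa, ci95=res.msa_ci95,
                fit=res.as_loglinear_fit())
            for y in years
        ]
        spec = PanelSpec(
            countries=(CountrySpec("SYN", params, tuple(years), 10.0),),
            threshold=110.0,
        )
        records = simulate_record_panel(spec, seed=8)
        check = check_records_against_msa(records, est)
        expected = sum(r.age_at_death > res.msa for r in records)
        assert check.n_exceeding == expected
        assert check.n_within + check.n_exceeding == len(records)
        # ages cluster below the limit: exceedances are a small fraction
        assert check.n_exceeding <= 0.05 * len(records)
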