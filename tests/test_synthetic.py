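"""Synthetic-data generators: closed-form Gompertz checks, the rounding
and age-cap operators, inverse-transform sampling, and record panels."""

import math
import warnings

import numpy as np
import pytest
from scipy import integrate, stats

from msalimit import (
    CountrySpec,
    GompertzParams,
    PanelSpec,
    ParameterError,
    apply_age_cap,
    apply_integer_rounding,
    lifetable_from_deaths,
    make_gompertz_lifetable,
    make_improving_series,
    make_loglinear_q_table,
    sample_death_ages,
    sample_deaths_from_table,
    simulate_record_panel,
)


class TestLogLinearQTable:
    def test_direct_evaluation(self, loglinear_table):
        assert loglinear_table.qx[0] == pytest.approx(1e-4, rel=1e-12)
        assert loglinear_table.qx[10] == pytest.approx(1e-4 * math.e, rel=1e-12)

    def test_q_saturates_at_closed_form_age(self, loglinear_table):
        crossing = -math.log(1e-4) / 0.1  # 92.103...
        saturated = loglinear_table.ages[loglinear_table.qx >= 1.0]
        assert saturated[0] == math.ceil(crossing)

    def test_lx_invariants(self, loglinear_table):
        assert loglinear_table.lx[0] == 100_000
        assert np.all(np.diff(loglinear_table.lx) <= 0)

    def test_saturating_a_rejected(self):
        with pytest.raises(ParameterError):
            make_loglinear_q_table(GompertzParams(1.5, 0.1))

    def test_makeham_rejected(self):
        with pytest.raises(ParameterError):
            make_loglinear_q_table(GompertzParams(1e-4, 0.1, c=1e-3))


class TestGompertzLifetable:
    def test_survival_closed_form(self, gompertz_table, realistic_params):
        a, b = realistic_params.a, realistic_params.b
        S80 = math.exp(-(a / b) * (math.exp(b * 80) - 1))
        assert gompertz_table.lx_at(80) / gompertz_table.radix == pytest.approx(S80, rel=1e-12)

    def test_small_b_limit_gives_constant_q(self):
        lt = make_gompertz_lifetable(GompertzParams(1e-3, 1e-9), max_age=50)
        expected = 1 - math.exp(-1e-3)
        np.testing.assert_allclose(lt.qx[:-1], expected, rtol=1e-6)

    def test_interval_q_below_integrated_hazard(self, gompertz_table, realistic_params):
        ages = gompertz_table.ages[:-1]
        dH = np.diff(realistic_params.cumulative_hazard(np.arange(gompertz_table.max_age + 2)))[:-1]
        assert np.all(gompertz_table.qx[:-1] <= dH)  # 1 - e^{-H} <= H


def _exact_table_from_lx(lx):
    """Exact toy table with the given survivor column (radix = lx[0])."""
    from msalimit import LifeTable

    lx = np.asarray(lx, float)
    qx = np.empty_like(lx)
    qx[:-1] = 1.0 - lx[1:] / lx[:-1]
    qx[-1] = 1.0
    return LifeTable(
        population_id="toy", index_year=0, table_type="cohort",
        ages=np.arange(lx.size), qx=qx, lx=lx, radix=lx[0], precision="exact",
    )


class TestRoundingOperator:
    def test_half_away_rule(self):
        lt = _exact_table_from_lx([100_000.0, 0.99, 0.50])
        rounded = apply_integer_rounding(lt)
        assert rounded.lx[1] == 1.0
        assert rounded.lx[2] == 1.0  # 0.50 -> 1, ties away from zero
        lt2 = _exact_table_from_lx([100_000.0, 0.99, 0.49])
        assert apply_integer_rounding(lt2).lx[2] == 0.0

    def test_radix_and_qx_untouched_and_original_unmodified(self, gompertz_table):
        before = gompertz_table.lx.copy()
        rounded = apply_integer_rounding(gompertz_table)
        assert rounded.lx[0] == 100_000
        np.testing.assert_array_equal(rounded.qx, gompertz_table.qx)
        np.testing.assert_array_equal(gompertz_table.lx, before)
        assert rounded.precision == "integer_rounded"

    def test_error_bounded_by_half(self, gompertz_table):
        rounded = apply_integer_rounding(gompertz_table)
        assert np.max(np.abs(rounded.lx - gompertz_table.lx)) <= 0.5

    def test_already_rounded_warns(self, gompertz_table):
        rounded = apply_integer_rounding(gompertz_table)
        with pytest.warns(UserWarning, match="already"):
            again = apply_integer_rounding(rounded)
        np.testing.assert_array_equal(again.lx, rounded.lx)


class TestAgeCap:
    def test_row_accounting_and_conservation(self, realistic_params):
        lt = make_gompertz_lifetable(realistic_params, max_age=120)
        capped = apply_age_cap(lt, 110)
        assert len(capped.ages) == 111
        assert capped.open_interval
        assert capped.qx[-1] == 1.0
        assert capped.lx_at(110) == lt.lx_at(110)

    def test_total_deaths_conserved(self, realistic_params):
        lt = make_gompertz_lifetable(realistic_params, max_age=120)
        capped = apply_age_cap(lt, 110)
        assert capped.dx().sum() == pytest.approx(capped.radix, rel=1e-12)
        assert lt.dx().sum() == pytest.approx(lt.radix, rel=1e-12)

    def test_cap_at_or_above_max_age_warns(self, gompertz_table):
        with pytest.warns(UserWarning, match="cap"):
            out = apply_age_cap(gompertz_table, 110)
        np.testing.assert_array_equal(out.lx, gompertz_table.lx)


class TestSampling:
    def test_truncation_contract(self, realistic_params):
        ages = sample_death_ages(realistic_params, 5000, threshold=110, seed=1)
        assert np.all(ages > 110)

    def test_seeded_determinism(self, realistic_params):
        a1 = sample_death_ages(realistic_params, 100, seed=42)
        a2 = sample_death_ages(realistic_params, 100, seed=42)
        np.testing.assert_array_equal(a1, a2)

    def test_mean_age_matches_numerical_integration(self, realistic_params):
        # E[X] = integral of S(x) dx for a nonnegative lifetime
        mean_true, _ = integrate.quad(realistic_params.survival, 0, 200)
        ages = sample_death_ages(realistic_params, 200_000, seed=7)
        se = ages.std(ddof=1) / math.sqrt(ages.size)
        assert abs(ages.mean() - mean_true) < 3 * se

    def test_truncated_sampling_matches_conditional_survival(self, realistic_params):
        # P(X > 111 | X > 110) = S(111)/S(110)
        ages = sample_death_ages(realistic_params, 100_000, threshold=110, seed=3)
        p_true = realistic_params.survival(111) / realistic_params.survival(110)
        p_hat = np.mean(ages > 111)
        se = math.sqrt(p_true * (1 - p_true) / ages.size)
        assert abs(p_hat - p_true) < 4 * se

    def test_table_sampling_support_and_determinism(self, loglinear_table):
        a1 = sample_deaths_from_table(loglinear_table, 1000, seed=5)
        a2 = sample_deaths_from_table(loglinear_table, 1000, seed=5)
        np.testing.assert_array_equal(a1, a2)
        assert a1.min() >= 0
        assert a1.max() < loglinear_table.max_age + 1

    def test_empirical_table_recovers_qx(self, loglinear_table):
        ages = sample_deaths_from_table(loglinear_table, 200_000, seed=11)
        emp = lifetable_from_deaths(ages, max_age=110)
        w = (emp.ages >= 60) & (emp.ages <= 80)
        np.testing.assert_allclose(emp.qx[w], loglinear_table.qx[w], rtol=0.25)


class TestRecordPanel:
    def _spec(self, **kw):
        params = GompertzParams(5e-5, 0.1)
        defaults = dict(
            countries=(
                CountrySpec("AAA", params, tuple(range(1990, 1995)), 5.0),
                CountrySpec("BBB", params, tuple(range(1995, 2000)), 5.0),
            ),
            threshold=110.0,
            seed=9,
        )
        defaults.update(kw)
        return PanelSpec(**defaults)

    def test_zero_count_year_is_empty(self):
        spec = self._spec(countries=(
            CountrySpec("AAA", GompertzParams(5e-5, 0.1), (1990,), 0.0),))
        assert simulate_record_panel(spec) == []

    def test_disjoint_coverage_pools_to_union(self):
        records = simulate_record_panel(self._spec(), seed=2)
        years = {r.death_year for r in records}
        assert years <= set(range(1990, 2000))
        assert {r.country for r in records} == {"AAA", "BBB"}
        assert all(r.age_at_death > 110 for r in records)

    def test_panel_determinism_and_fixed_counts(self):
        spec = self._spec(fixed_counts=True)
        r1 = simulate_record_panel(spec, seed=4)
        r2 = simulate_record_panel(spec, seed=4)
        assert r1 == r2
        per_year = {}
        for r in r1:
            per_year[(r.country, r.death_year)] = per_year.get((r.country, r.death_year), 0) + 1
        assert set(per_year.values()) == {5}

    def test_yaml_roundtrip(self, tmp_path):
        spec = self._spec()
        path = tmp_path / "panel.yaml"
        spec.to_yaml(path)
        assert PanelSpec.from_yaml(path) == spec


class TestImprovingSeries:
    def test_no_decline_means_identical_tables(self):
        series = make_improving_series(GompertzParams(5e-5, 0.1), 0.0, range(1900, 1910))
        for t in series[1:]:
            np.testing.assert_array_equal(t.qx, series[0].qx)
            np.testing.assert_array_equal(t.lx, series[0].lx)

    def test_old_age_survival_strictly_increasing(self, improving_series):
        lx100 = [t.lx_at(100) for t in improving_series]
        assert np.all(np.diff(lx100) > 0)

    def test_log_survival_near_linear_in_year(self, improving_series):
        years = np.array([t.index_year for t in improving_series], float)
        logs = np.log([t.lx_at(100) / t.radix for t in improving_series])
        res = stats.linregress(years, logs)
        assert res.rvalue**2 > 0.99

    def test_index_years_and_type(self, improving_series):
        assert [t.index_year for t in improving_series] == list(range(1950, 1981))
        assert all(t.table_type == "period" for t in improving_series)
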