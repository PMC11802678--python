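"""Baseline extrapolation, oxidative stability and threshold inversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxstab import tables
from oxstab.dose_response import (ExposureSeries, compute_oxs, critical_dose,
                                  fit_exponential_baseline,
                                  fit_polynomial_dose_response,
                                  invert_threshold)
from oxstab.errors import (DomainError, InsufficientDataError, NoRootError,
                           ValidationError)


def _series(zone, species):
    inx = tables.INJURY_INDEX_PCT[(zone, species)]
    return ExposureSeries(species, zone, tables.SUM_O3_PPM[zone],
                          tuple(inx[1:]))


def _loglin_oracle(x, y):
    """Closed-form log-linear OLS, independent of the fitting path."""
    x = np.asarray(x, float)
    ly = np.log(np.asarray(y, float))
    b = np.sum((x - x.mean()) * (ly - ly.mean())) / np.sum((x - x.mean()) ** 2)
    return np.exp(ly.mean() - b * x.mean()), b


class TestExponentialBaseline:
    def test_exact_model_class_recovered_to_machine_precision(self):
        x = (100.0, 400.0, 900.0, 1400.0, 1900.0)
        y = tuple(10.0 * np.exp(0.0008 * np.asarray(x)))
        fit = fit_exponential_baseline(ExposureSeries("s", "z", x, y))
        assert fit.a == pytest.approx(10.0, rel=1e-12)
        assert fit.b == pytest.approx(0.0008, rel=1e-12)
        assert fit.r == pytest.approx(1.0)

    @pytest.mark.parametrize("zone,species", list(tables.INJURY_INDEX_PCT))
    def test_matches_independent_normal_equations_oracle(self, zone, species):
        s = _series(zone, species)
        fit = fit_exponential_baseline(s)
        a, b = _loglin_oracle(s.sum_o3, s.inx)
        assert fit.a == pytest.approx(a, rel=1e-12)
        assert fit.b == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("zone,species", list(tables.INJURY_INDEX_PCT))
    def test_baselines_near_published_table(self, zone, species):
        """Refitted INX(0) agrees with the published baseline to within the
        propagation of the printed inputs' 1-decimal rounding (±0.1)."""
        fit = fit_exponential_baseline(_series(zone, species))
        assert fit.a == pytest.approx(
            tables.INJURY_INDEX_PCT[(zone, species)][0], abs=0.1)

    def test_domain_and_size_errors(self):
        with pytest.raises(DomainError):
            fit_exponential_baseline(
                ExposureSeries("s", "z", (1.0, 2.0, 3.0), (1.0, 0.0, 2.0)))
        with pytest.raises(InsufficientDataError):
            fit_exponential_baseline(
                ExposureSeries("s", "z", (1.0, 2.0), (1.0, 2.0)))


class TestOxS:
    @pytest.mark.parametrize("inx_n,inx_0,expected", [
        (48.4, 9.3, -0.39),   # deepest published decline, P. mugo FH
        (10.0, 10.0, 0.00),
        (25.0, 25.0, 0.00),
    ])
    def test_difference_in_decimal_form(self, inx_n, inx_0, expected):
        assert round(compute_oxs(inx_n, inx_0), 2) == expected

    def test_positive_values_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert compute_oxs(9.0, 10.0) == 0.0
        assert "clipped" in caplog.text

    @pytest.mark.parametrize("bad", [(-1, 50), (101, 50), (50, -1), (50, 101)])
    def test_range_validation(self, bad):
        with pytest.raises(ValidationError):
            compute_oxs(*bad)

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_always_within_unit_interval(self, inx_n, inx_0):
        assert -1.0 <= compute_oxs(inx_n, inx_0) <= 0.0


class TestPolynomialFit:
    def test_exact_linear_data(self):
        x = np.array([100.0, 500.0, 1000.0, 1500.0])
        fit = fit_polynomial_dose_response(x, -x / 10000.0, degree=1)
        assert fit.coefficients[0] == pytest.approx(-1e-4, rel=1e-9)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-12)

    def test_degree2_matches_normal_equations_oracle(self):
        x = np.asarray(tables.SUM_O3_PPM["FH"])
        y = np.asarray(tables.OXS[("FH", "Pinus mugo")][0])
        fit = fit_polynomial_dose_response(x, y, degree=2)
        design = np.column_stack([x ** 2, x, np.ones_like(x)])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.coefficients == pytest.approx(tuple(oracle), rel=1e-8)
        assert sum(fit.residuals) == pytest.approx(0.0, abs=1e-12)
        lo, hi = np.asarray(fit.ci_lower), np.asarray(fit.ci_upper)
        assert np.all(lo <= hi)

    def test_rank_error(self):
        with pytest.raises(InsufficientDataError):
            fit_polynomial_dose_response([1.0, 2.0], [0.0, -0.1], degree=2)


class TestInvertThreshold:
    def test_analytic_linear_root(self):
        x = np.array([10.0, 500.0, 900.0])
        fit = fit_polynomial_dose_response(x, -x / 1000.0, degree=1)
        dose, extrapolated = invert_threshold(fit, threshold=-0.05)
        assert dose == pytest.approx(50.0, abs=1e-6)
        assert not extrapolated

    def test_smallest_positive_crossing_against_grid_scan_oracle(self):
        x = np.asarray(tables.SUM_O3_PPM["ATE"])
        y = np.asarray(tables.OXS[("ATE", "Pinus mugo")][0])
        fit = fit_polynomial_dose_response(x, y, degree=2)
        dose, _ = invert_threshold(fit, threshold=-0.05)
        grid = np.arange(0.0, 2 * x.max(), 0.01)
        oracle = grid[np.flatnonzero(
            np.polyval(fit.coefficients, grid) <= -0.05)[0]]
        assert dose == pytest.approx(oracle, abs=0.01)
        # the published critical dose is the reference magnitude
        assert dose == pytest.approx(tables.OXS[("ATE", "Pinus mugo")][1],
                                     rel=0.10)

    def test_self_consistency_at_an_observed_point(self):
        x = np.asarray(tables.SUM_O3_PPM["FH"])
        y = np.asarray(tables.OXS[("FH", "Pinus mugo")][0])
        fit = fit_polynomial_dose_response(x, y, degree=2)
        target = float(np.polyval(fit.coefficients, x[3]))
        dose, _ = invert_threshold(fit, threshold=target)
        assert dose == pytest.approx(x[3], rel=1e-6)

    def test_no_crossing_raises(self):
        fit = fit_polynomial_dose_response(
            [1.0, 2.0, 3.0], [0.0, -0.001, -0.002], degree=1)
        with pytest.raises(NoRootError):
            invert_threshold(fit, threshold=-0.9)

    def test_extrapolation_flagged(self):
        x = np.array([10.0, 20.0, 30.0])
        fit = fit_polynomial_dose_response(x, -x / 1000.0, degree=1)
        dose, extrapolated = invert_threshold(fit, threshold=-0.05)
        assert extrapolated and dose == pytest.approx(50.0, rel=1e-6)

    @given(st.floats(1e-5, 5e-4), st.floats(-1e-8, -1e-9))
    def test_recovers_generating_dose_for_in_class_curves(self, b1, b2):
        """When the truth is a quadratic through the origin, fit + inversion
        return its analytic −0.05 crossing within 1 %."""
        x = np.linspace(100, 1800, 6)
        y = -(b1 * x - b2 * x ** 2)
        true_roots = np.roots([b2, -b1, 0.05])
        true = min(r.real for r in true_roots if r.real > 0 and abs(r.imag) < 1e-12)
        fit = fit_polynomial_dose_response(x, y, degree=2)
        try:
            dose, _ = invert_threshold(fit, threshold=-0.05)
        except NoRootError:
            assert true > 2 * x.max()
            return
        assert dose == pytest.approx(true, rel=0.01)


def test_critical_dose_chain_is_internally_consistent():
    res = critical_dose(_series("FH", "Abies alba"), degree=2)
    assert res["sum_o3_oxs"] > 0
    assert np.polyval(res["poly"].coefficients, res["sum_o3_oxs"]) == \
        pytest.approx(-0.05, abs=1e-9)
    assert all(-1.0 <= v <= 0.0 for v in res["oxs"])
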