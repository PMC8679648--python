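"""Experimental-data curation chain."""

import math

import numpy as np
import pytest

from polca.constants import MMHG_PER_BAR, PA_PER_BAR, R, bar_to_mmhg, mmhg_to_bar
from polca.expdata import (
    PropertySeries,
    adjust_hvap_temperature,
    aggregate_measurements,
    correct_single_temperature_value,
    fit_density_series,
    fit_vapor_pressure,
    gsolv_from_vapor_pressure,
    hvap_from_fit,
    pvap_at_reference,
)


# ---------------------------------------------------------------------------
# Density regression
# ---------------------------------------------------------------------------


def test_density_midpoint_of_line():
    s = PropertySeries.from_records("x", "rho",
                                    [(293.0, 800.0, "a", False), (303.0, 790.0, "a", False)])
    fits, slope, agg = fit_density_series(s, t_ref=298.0)
    assert fits[0].value_at_ref == pytest.approx(795.0)
    assert slope == pytest.approx(-1.0)


def test_density_isothermal_series_flagged():
    s = PropertySeries.from_records("x", "rho",
                                    [(298.0, 761.0, "a", False), (298.0, 761.4, "a", False)])
    fits, slope, agg = fit_density_series(s)
    assert math.isnan(fits[0].slope)
    assert fits[0].value_at_ref == pytest.approx(761.2)
    assert math.isnan(slope)


def test_density_flagged_outlier_excluded(rng):
    intercept, sl = 761.1, -0.92
    recs = [(t, intercept + sl * (t - 298.15), "a", False) for t in range(273, 324, 10)]
    recs.append((323.0, intercept + sl * (323 - 298.15) + 30.0, "a", True))  # flagged
    s = PropertySeries.from_records("x", "rho", recs)
    fits, slope, agg = fit_density_series(s)
    assert fits[0].value_at_ref == pytest.approx(intercept, abs=1e-9)
    assert slope == pytest.approx(sl, abs=1e-12)
    # the correction factor shifts single-temperature values onto the line
    v = correct_single_temperature_value(intercept + sl * (310 - 298.15), 310.0, slope)
    assert v == pytest.approx(intercept, abs=1e-9)


def test_all_points_excluded_raises():
    s = PropertySeries.from_records("x", "rho", [(298.0, 761.0, "a", True)])
    with pytest.raises(ValueError, match="excluded"):
        fit_density_series(s)


# ---------------------------------------------------------------------------
# Vapor pressure and enthalpy of vaporization
# ---------------------------------------------------------------------------


def test_vapor_pressure_exact_model_class():
    a, b = 17.0, -3031.6
    t = np.arange(268.0, 319.0, 10.0)
    p = np.exp(a + b / t)
    s = PropertySeries.from_records("x", "pvap",
                                    [(ti, pi, "src", False) for ti, pi in zip(t, p)],
                                    units="mmHg")
    fit = fit_vapor_pressure(s)[0]
    assert fit.a == pytest.approx(a, abs=1e-10)
    assert fit.b == pytest.approx(b, abs=1e-7)
    assert fit.r2 == pytest.approx(1.0)
    hv, t_mean = hvap_from_fit(fit)
    assert hv == pytest.approx(R * 3031.6 / 1000.0, abs=1e-9)
    assert hv == pytest.approx(25.2, abs=0.01)
    assert t_mean == pytest.approx(t.mean())


def test_vapor_pressure_two_points_interpolates():
    s = PropertySeries.from_records("x", "pvap",
                                    [(280.0, 100.0, "a", False), (300.0, 400.0, "a", False)],
                                    units="mmHg")
    fit = fit_vapor_pressure(s)[0]
    assert fit.r2 == pytest.approx(1.0)
    assert fit.pressure_mmhg(280.0) == pytest.approx(100.0)
    assert fit.pressure_mmhg(300.0) == pytest.approx(400.0)


def test_vapor_pressure_sources_fitted_independently():
    recs = [(270.0, 50.0, "a", False), (290.0, 200.0, "a", False),
            (280.0, 110.0, "b", False), (300.0, 420.0, "b", False)]
    s = PropertySeries.from_records("x", "pvap", recs, units="mmHg")
    fits = fit_vapor_pressure(s)
    assert {f.source for f in fits} == {"a", "b"}
    assert all(f.r2 == pytest.approx(1.0) for f in fits)


def test_vapor_pressure_rejects_nonpositive():
    s = PropertySeries.from_records("x", "pvap",
                                    [(280.0, -1.0, "a", False), (290.0, 2.0, "a", False)],
                                    units="bar")
    with pytest.raises(ValueError, match="non-positive"):
        fit_vapor_pressure(s)


def test_hvap_slope_linearity():
    from polca.expdata import VaporPressureFit

    f1 = VaporPressureFit(a=10.0, b=-2000.0, t_range=(280, 320), t_mean=300.0, r2=1.0)
    f2 = VaporPressureFit(a=10.0, b=-4000.0, t_range=(280, 320), t_mean=300.0, r2=1.0)
    assert hvap_from_fit(f2)[0] == pytest.approx(2 * hvap_from_fit(f1)[0])
    f0 = VaporPressureFit(a=10.0, b=0.0, t_range=(280, 320), t_mean=300.0, r2=1.0)
    assert hvap_from_fit(f0)[0] == 0.0


# ---------------------------------------------------------------------------
# Temperature corrections
# ---------------------------------------------------------------------------


def test_adjust_hvap_strategies():
    assert adjust_hvap_temperature(25.0, 281.3, "none")[0] == 25.0
    v, audit = adjust_hvap_temperature(25.0, 281.3, "heat-capacity-difference",
                                       delta_cp=0.0)
    assert v == 25.0 and audit["strategy"] == "heat-capacity-difference"
    # planted linear Delta H(T) with known derivative
    dhdt = -0.06
    dh_at_t = 25.2 - dhdt * (298.15 - 281.3)
    v, _ = adjust_hvap_temperature(dh_at_t, 281.3, "constant-correlation-derivative",
                                   dhdt=dhdt)
    assert v == pytest.approx(25.2, abs=1e-12)
    with pytest.raises(ValueError, match="unknown"):
        adjust_hvap_temperature(25.0, 281.3, "magic")


# ---------------------------------------------------------------------------
# Vapor pressure from boiling point; solvation free energy
# ---------------------------------------------------------------------------


def test_pvap_at_reference_degenerate_cases():
    assert pvap_at_reference(298.15, 40.0) == pytest.approx(1.01325)
    assert pvap_at_reference(350.0, 1e-12) == pytest.approx(1.01325)


def test_pvap_at_reference_closed_form():
    t_b, dh = 350.0, 40.0
    expected = 1.01325 * math.exp(-dh * 1000.0 / R * (1 / 298.15 - 1 / t_b))
    assert pvap_at_reference(t_b, dh) == pytest.approx(expected, rel=1e-12)
    assert pvap_at_reference(t_b, dh) < 1.01325  # below the boiling point


def test_gsolv_equal_concentration_reference():
    # choose p so the vapor molar concentration equals the liquid one
    rho, mw, t = 758.4, 162.38, 298.15
    c_liq = 1000.0 * rho / mw
    p_bar = c_liq * R * t / PA_PER_BAR
    assert gsolv_from_vapor_pressure(rho, mw, p_bar, t) == pytest.approx(0.0, abs=1e-12)


def test_gsolv_hexamethyldisiloxane_hand_value():
    val = gsolv_from_vapor_pressure(758.4, 162.38, 0.0555, 298.15)
    assert val == pytest.approx(-19.0, abs=0.1)


def test_gsolv_log_linear_in_pressure():
    base = gsolv_from_vapor_pressure(758.4, 162.38, 0.0555, 298.15)
    halved = gsolv_from_vapor_pressure(758.4, 162.38, 0.0555 / 2, 298.15)
    assert base - halved == pytest.approx(R * 298.15 * math.log(2) / 1000.0, rel=1e-12)
    assert base - halved == pytest.approx(1.718, abs=1e-3)
    with pytest.raises(ValueError):
        gsolv_from_vapor_pressure(758.4, 162.38, 0.0, 298.15)


# ---------------------------------------------------------------------------
# Aggregation and units
# ---------------------------------------------------------------------------


def test_aggregate_measurements():
    a = aggregate_measurements([5.0])
    assert a.mean == 5.0 and a.uncertainty is None and a.n == 1
    a = aggregate_measurements([1.0, 2.0, 3.0])
    assert a.mean == 2.0
    assert a.uncertainty == pytest.approx(2.0 / math.sqrt(3.0))
    a = aggregate_measurements([7.0, 7.0, 7.0, 7.0])
    assert a.uncertainty == 0.0
    with pytest.raises(ValueError):
        aggregate_measurements([])


def test_pressure_unit_round_trip():
    for p in [1e-3, 1.0, 760.0]:
        assert bar_to_mmhg(mmhg_to_bar(p)) == pytest.approx(p, rel=1e-12)
    assert mmhg_to_bar(MMHG_PER_BAR) == pytest.approx(1.0, rel=1e-12)


# ---------------------------------------------------------------------------
# Full curation chain on a planted model
# ---------------------------------------------------------------------------


def test_full_chain_recovers_planted_model():
    """rho(T) and p(T) generated from known models: the chain must recover
    rho(298), Delta H_vap(298) and a consistent Delta G_solv(298)."""
    rho_298, slope = 761.1, -0.92
    hvap = 25.2
    p298_mmhg = 600.0
    b = -hvap * 1000.0 / R
    a = math.log(p298_mmhg) - b / 298.15

    t = np.arange(273.0, 324.0, 5.0)
    s_rho = PropertySeries.from_records(
        "tms", "rho", [(ti, rho_298 + slope * (ti - 298.15), "lit", False) for ti in t])
    fits, mean_slope, agg = fit_density_series(s_rho)
    assert agg.mean == pytest.approx(rho_298, abs=1e-9)

    s_p = PropertySeries.from_records(
        "tms", "pvap", [(ti, math.exp(a + b / ti), "lit", False) for ti in t],
        units="mmHg")
    fit = fit_vapor_pressure(s_p)[0]
    hv, t_mean = hvap_from_fit(fit)
    assert hv == pytest.approx(hvap, abs=1e-9)

    p_bar = fit.pressure_bar(298.15)
    assert p_bar == pytest.approx(p298_mmhg / MMHG_PER_BAR, rel=1e-9)
    g = gsolv_from_vapor_pressure(agg.mean, 88.22, p_bar, 298.15)
    g_expected = (R * 298.15 / 1000.0
                  * math.log((p298_mmhg / MMHG_PER_BAR * PA_PER_BAR / (R * 298.15))
                             / (1000.0 * rho_298 / 88.22)))
    assert g == pytest.approx(g_expected, rel=1e-12)
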