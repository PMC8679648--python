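"""Curation of experimental property data.

Implements the analysis chain used to put literature data for
organosilicon liquids on a common footing at 298 K: per-source linear
temperature regression of densities, Clausius-Clapeyron-type vapor
pressure fits (ln p = A + B/T, p in mmHg), enthalpies of vaporization
from fitted slopes, temperature-correction strategies, vapor pressures
back-computed from normal boiling points, self-solvation free energies
from vapor pressure and density, and uncertainty aggregation (twice the
standard error of the mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import BAR_PER_ATM, MMHG_PER_BAR, PA_PER_BAR, R

T_REF = 298.15  # K; curation reference temperature


@dataclass
class PropertySeries:
    """One property of one compound: points (T, value) per literature source,
    with manual exclusion flags (no automatic outlier rejection)."""

    compound: str
    prop: str
    data: pd.DataFrame  # columns: T, value, source, excluded
    units: str = ""

    @classmethod
    def from_records(cls, compound, prop, records, units=""):
        df = pd.DataFrame(records, columns=["T", "value", "source", "excluded"])
        return cls(compound, prop, df, units)

    @classmethod
    def read_csv(cls, path, compound="", prop="", units=""):
        df = pd.read_csv(path)
        if "source" not in df:
            df["source"] = "unknown"
        if "excluded" not in df:
            df["excluded"] = False
        df["excluded"] = df["excluded"].astype(bool)
        return cls(compound, prop, df[["T", "value", "source", "excluded"]], units)

    @property
    def active(self) -> pd.DataFrame:
        out = self.data[~self.data.excluded]
        if out.empty:
            raise ValueError(f"all points of {self.compound}/{self.prop} are excluded")
        if (out["T"] <= 0).any():
            raise ValueError("non-positive temperatures")
        return out


@dataclass
class AggregateValue:
    """Mean with uncertainty = 2 x SEM; no uncertainty reported for n = 1."""

    mean: float
    uncertainty: float | None
    n: int
    sources: tuple[str, ...] = ()


def aggregate_measurements(values, sources=()) -> AggregateValue:
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no measurements to aggregate")
    if vals.size == 1:
        return AggregateValue(float(vals[0]), None, 1, tuple(sources))
    sem = np.std(vals, ddof=1) / math.sqrt(vals.size)
    return AggregateValue(float(np.mean(vals)), 2.0 * float(sem), int(vals.size), tuple(sources))


# ---------------------------------------------------------------------------
# Density
# ---------------------------------------------------------------------------


@dataclass
class DensityFit:
    source: str
    slope: float  # value per K
    intercept: float
    value_at_ref: float
    n: int
    r2: float | None


def fit_density_series(series: PropertySeries, t_ref: float = T_REF):
    """Per-source linear fits rho(T); evaluation at the reference temperature.

    Isothermal sources (zero temperature spread) contribute their mean with
    the slope flagged non-fittable (NaN).  The average slope across fittable
    sources doubles as a correction factor for single-temperature
    literature values.
    """
    fits: list[DensityFit] = []
    for src, grp in series.active.groupby("source"):
        t = grp["T"].to_numpy(float)
        v = grp["value"].to_numpy(float)
        if np.unique(t).size < 2:
            fits.append(DensityFit(src, float("nan"), float(np.mean(v)),
                                   float(np.mean(v)), len(v), None))
            continue
        res = stats.linregress(t, v)
        fits.append(
            DensityFit(src, res.slope, res.intercept,
                       res.intercept + res.slope * t_ref, len(v), res.rvalue**2)
        )
    slopes = [f.slope for f in fits if np.isfinite(f.slope)]
    mean_slope = float(np.mean(slopes)) if slopes else float("nan")
    agg = aggregate_measurements([f.value_at_ref for f in fits],
                                 sources=[f.source for f in fits])
    return fits, mean_slope, agg


def correct_single_temperature_value(value: float, t: float, mean_slope: float,
                                     t_ref: float = T_REF) -> float:
    """Shift a single-temperature literature value to the reference
    temperature using the average slope of the fitted sources."""
    return value + mean_slope * (t_ref - t)


# ---------------------------------------------------------------------------
# Vapor pressure
# ---------------------------------------------------------------------------


@dataclass
class VaporPressureFit:
    """ln p = A + B/T with p in mmHg and T in K."""

    a: float
    b: float  # K; slope of ln p vs 1/T
    t_range: tuple[float, float]
    t_mean: float
    r2: float
    source: str = ""

    def pressure_mmhg(self, t):
        return np.exp(self.a + self.b / np.asarray(t, dtype=float))

    def pressure_bar(self, t):
        return self.pressure_mmhg(t) / MMHG_PER_BAR


def fit_vapor_pressure(series: PropertySeries,
                       window: tuple[float, float] | None = None):
    """Fit each source's vapor pressure data independently to
    ln p = A + B/T (p converted to mmHg before fitting).

    ``window`` optionally restricts the fit to a temperature range centered
    near the reference temperature when enough points are available.
    """
    unit = (series.units or "mmHg").lower()
    to_mmhg = {"mmhg": 1.0, "bar": MMHG_PER_BAR, "pa": MMHG_PER_BAR / PA_PER_BAR,
               "kpa": MMHG_PER_BAR / PA_PER_BAR * 1e3, "atm": MMHG_PER_BAR * BAR_PER_ATM}
    if unit not in to_mmhg:
        raise ValueError(f"unknown pressure unit {series.units!r}")
    fits = []
    for src, grp in series.active.groupby("source"):
        t = grp["T"].to_numpy(float)
        p = grp["value"].to_numpy(float) * to_mmhg[unit]
        if window is not None:
            sel = (t >= window[0]) & (t <= window[1])
            if sel.sum() >= 2:
                t, p = t[sel], p[sel]
        if (p <= 0).any():
            raise ValueError("non-positive vapor pressures")
        if t.size < 2:
            continue
        res = stats.linregress(1.0 / t, np.log(p))
        fits.append(
            VaporPressureFit(
                a=res.intercept, b=res.slope,
                t_range=(float(t.min()), float(t.max())),
                t_mean=float(np.mean(t)), r2=res.rvalue**2, source=src,
            )
        )
    if not fits:
        raise ValueError("no source had two or more usable points")
    return fits


def hvap_from_fit(fit: VaporPressureFit) -> tuple[float, float]:
    """Enthalpy of vaporization from the Clausius-Clapeyron slope.

    Delta H_vap = -R B, in kJ/mol, tagged with the mean temperature of the
    fitted window (the value pertains to that temperature, not 298 K).
    """
    return -R * fit.b / 1000.0, fit.t_mean


def adjust_hvap_temperature(dh_at_t: float, t: float, strategy: str = "none",
                            t_ref: float = T_REF, *, dhdt: float | None = None,
                            delta_cp: float | None = None):
    """Shift an enthalpy of vaporization from T to the reference temperature.

    Strategies
    ----------
    none
        identity (data already at the reference temperature).
    constant-correlation-derivative
        Delta H(T_ref) = Delta H(T) + dH/dT * (T_ref - T) with ``dhdt`` in
        kJ/mol/K taken from a temperature-dependent correlation.
    heat-capacity-difference
        dH/dT approximated by Delta C_p = C_p(gas) - C_p(liquid), ``delta_cp``
        in kJ/mol/K.

    Returns (corrected value, audit record).
    """
    if strategy == "none":
        corrected = dh_at_t
    elif strategy == "constant-correlation-derivative":
        if dhdt is None:
            raise ValueError("strategy requires dhdt (kJ/mol/K)")
        corrected = dh_at_t + dhdt * (t_ref - t)
    elif strategy == "heat-capacity-difference":
        if delta_cp is None:
            raise ValueError("strategy requires delta_cp (kJ/mol/K)")
        corrected = dh_at_t + delta_cp * (t_ref - t)
    else:
        raise ValueError(f"unknown temperature-correction strategy {strategy!r}")
    audit = {"strategy": strategy, "T_from": t, "T_to": t_ref,
             "input": dh_at_t, "dhdt": dhdt, "delta_cp": delta_cp,
             "output": corrected}
    return corrected, audit


def pvap_at_reference(t_boil: float, dh_vap_kjmol: float, t_ref: float = T_REF) -> float:
    """Vapor pressure (bar) at the reference temperature from the normal
    boiling point, integrating Clausius-Clapeyron with constant Delta H_vap
    between p(T_b) = 1 atm and p(T_ref)."""
    if t_boil <= 0:
        raise ValueError("boiling point must be positive")
    exponent = -dh_vap_kjmol * 1000.0 / R * (1.0 / t_ref - 1.0 / t_boil)
    return BAR_PER_ATM * math.exp(exponent)


def gsolv_from_vapor_pressure(rho_kgm3: float, mw_gmol: float, p_bar: float,
                              t: float = T_REF) -> float:
    """Self-solvation free energy (kJ/mol) from vapor pressure and density.

    Delta G_solv = RT ln[ p M_W / (1000 rho R T) ]: the free energy of
    transferring a molecule from an ideal gas at the saturation
    concentration into its own liquid at the liquid molar concentration
    (equal-concentration reference); zero when the two concentrations
    coincide, more negative for lower vapor pressure.
    """
    if rho_kgm3 <= 0 or mw_gmol <= 0 or t <= 0:
        raise ValueError("density, molecular weight and temperature must be positive")
    if p_bar <= 0:
        raise ValueError("vapor pressure must be positive")
    c_gas = p_bar * PA_PER_BAR / (R * t)  # mol/m^3
    c_liq = 1000.0 * rho_kgm3 / mw_gmol  # mol/m^3
    return R * t / 1000.0 * math.log(c_gas / c_liq)
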