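"""Polarization corrections and MD-summary post-processing.

The force field is nonpolarizable; polarization enters as *post facto*
corrections built on the Onsager dielectric continuum picture:

* liquid-phase dipole enhancement from the gas-phase dipole, the static
  dielectric constant and the electronic (infinite-frequency) dielectric
  constant, with the cavity radius eliminated self-consistently;
* an additive polarization energy E_Pol = distortion + electronic terms,
  applied to enthalpies of vaporization and solvation free energies;
* a dielectric-constant correction replacing the model dipole by the real
  liquid dipole and adding the electronic response.

MD post-processing covers the dipole-fluctuation dielectric constant,
Einstein-relation self-diffusion, and finite-size extrapolation of D
versus inverse box length.

Units: dipoles in debye, polarizability volumes in Å³, energies kJ/mol,
temperatures K, box volumes nm³.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import DEBYE, DIPOLE_SQ_PER_ALPHA_KJMOL, EPS0, K_B, R

logger = logging.getLogger(__name__)


@dataclass
class ElectronicProperties:
    """Per-compound electronic inputs for the polarization calculus.

    eps_inf is always derived as n_D**2 (squared sodium-D refractive
    index); it is not an independent input, to avoid inconsistency.
    """

    mu_gas: float  # debye
    alpha: float  # polarizability volume, Å^3
    epsilon: float  # static dielectric constant
    n_d: float  # refractive index at the sodium D line
    compound: str = ""

    def __post_init__(self):
        if self.epsilon < 1 or self.n_d < 1:
            raise ValueError("dielectric constant and refractive index must be >= 1")

    @property
    def eps_inf(self) -> float:
        return self.n_d**2


@dataclass
class PolarizationResult:
    mu_liq: float  # debye
    distortion: float  # kJ/mol, >= 0
    electronic: float  # kJ/mol, <= 0
    total: float  # kJ/mol


@dataclass
class SimulationSummary:
    """Tabular MD outputs consumed by the correction calculus."""

    u_liq: float | None = None  # kJ/mol per mole of molecules
    u_gas: float | None = None  # kJ/mol
    temperature: float = 298.15  # K
    volume: float | None = None  # nm^3
    box_dipole: np.ndarray | None = None  # samples, debye (norm or components)
    msd_time: np.ndarray | None = None  # ps
    msd: np.ndarray | None = None  # nm^2
    box_lengths: np.ndarray | None = None  # nm


# ---------------------------------------------------------------------------
# Onsager continuum calculus
# ---------------------------------------------------------------------------


def liquid_dipole(props: ElectronicProperties) -> float:
    """Liquid-phase dipole from the Onsager continuum model.

    mu_liq = mu_gas * (2 eps + 1)(eps_inf + 2) / (3 (2 eps + eps_inf)),
    the self-consistent-cavity form in which the cavity radius has been
    eliminated; reduces to mu_gas when eps = eps_inf = 1 and grows
    monotonically with the static dielectric constant.
    """
    eps, eps_inf = props.epsilon, props.eps_inf
    if eps < 1 or eps_inf < 1:
        raise ValueError("dielectric constants must be >= 1")
    factor = (2 * eps + 1) * (eps_inf + 2) / (3.0 * (2 * eps + eps_inf))
    mu_liq = props.mu_gas * factor
    logger.debug(
        "liquid_dipole %s: mu_gas=%.4e C m, eps=%.3f, eps_inf=%.3f -> mu_liq=%.4e C m",
        props.compound, props.mu_gas * DEBYE, eps, eps_inf, mu_liq * DEBYE,
    )
    return mu_liq


def polarization_energy(props: ElectronicProperties, mu_liq: float | None = None) -> PolarizationResult:
    """E_Pol for a gas-to-liquid transfer: positive distortion energy plus
    negative electronic energy.

    distortion = (mu_liq - mu_gas)^2 / (2 alpha)
    electronic = -[(eps_inf - 1)^2 / ((2 eps_inf + 1)(eps_inf + 2))] mu_liq^2 / alpha
    """
    if props.alpha <= 0:
        raise ValueError("polarizability must be positive")
    if mu_liq is None:
        mu_liq = liquid_dipole(props)
    eps_inf = props.eps_inf
    scale = DIPOLE_SQ_PER_ALPHA_KJMOL / props.alpha
    distortion = 0.5 * (mu_liq - props.mu_gas) ** 2 * scale
    electronic = (
        -((eps_inf - 1) ** 2) / ((2 * eps_inf + 1) * (eps_inf + 2)) * mu_liq**2 * scale
    )
    logger.debug(
        "polarization_energy %s: distortion=%.6f kJ/mol, electronic=%.6f kJ/mol",
        props.compound, distortion, electronic,
    )
    return PolarizationResult(
        mu_liq=mu_liq,
        distortion=distortion,
        electronic=electronic,
        total=distortion + electronic,
    )


def enthalpy_of_vaporization(summary: SimulationSummary, e_pol: float = 0.0) -> float:
    """Delta H_vap = <U_gas> - <U_liq> + RT + E_pol, kJ/mol."""
    if summary.u_gas is None or summary.u_liq is None:
        raise ValueError("both gas- and liquid-phase average potential energies are required")
    rt = R * summary.temperature / 1000.0
    return summary.u_gas - summary.u_liq + rt + e_pol


def correct_dielectric(eps_simul: float, mu_liq: float, mu_model: float,
                       eps_inf: float) -> float:
    """Polarization-corrected dielectric constant.

    eps = eps_inf + (mu_liq / mu_model)^2 (eps_simul - 1): the fluctuation
    term is rescaled from the model dipole to the real liquid dipole and
    the purely electronic response (absent from a fixed-charge model) is
    added back.
    """
    if eps_simul < 1:
        raise ValueError("simulated dielectric constant must be >= 1")
    if mu_model <= 0:
        raise ValueError("model dipole moment must be positive")
    return eps_inf + (mu_liq / mu_model) ** 2 * (eps_simul - 1.0)


def correct_solvation_free_energy(dg_simul: float, e_pol: float) -> float:
    """Delta G_solv = Delta G_simul + E_pol (kJ/mol)."""
    return dg_simul + e_pol


# ---------------------------------------------------------------------------
# MD summary post-processing
# ---------------------------------------------------------------------------


def dielectric_from_box_dipole(m_samples, volume_nm3: float, temperature: float,
                               n_blocks: int = 5):
    """Dielectric constant from box-dipole fluctuations.

    eps = 1 + (<M^2> - <M>^2) / (3 eps0 V k_B T); M samples in debye,
    either scalar series per component or (n, 3) arrays.  Returns
    (eps, uncertainty) with a block-averaged standard error estimate.
    """
    m = np.asarray(m_samples, dtype=float)
    if volume_nm3 <= 0 or temperature <= 0:
        raise ValueError("volume and temperature must be positive")
    if m.shape[0] < 2:
        raise ValueError("at least two dipole samples are required")

    prefactor = DEBYE**2 / (3 * EPS0 * volume_nm3 * 1e-27 * K_B * temperature)

    def _eps(chunk):
        if chunk.ndim == 2:
            var = float(np.sum(np.mean(chunk**2, axis=0) - np.mean(chunk, axis=0) ** 2))
        else:
            var = float(np.var(chunk))
        return 1.0 + prefactor * var

    eps = _eps(m)
    blocks = np.array_split(m, n_blocks)
    vals = [_eps(b) for b in blocks if b.shape[0] >= 2]
    err = 2 * np.std(vals, ddof=1) / np.sqrt(len(vals)) if len(vals) >= 2 else np.nan
    return eps, err


def diffusion_from_msd(time_ps, msd_nm2, window: tuple[float, float] | None = None):
    """Einstein-relation self-diffusion: D = slope/6, converted to m^2/s.

    ``window`` selects a (t_min, t_max) fitting range in ps.  Returns
    (D, standard error of D).
    """
    t = np.asarray(time_ps, dtype=float)
    y = np.asarray(msd_nm2, dtype=float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, y = t[sel], y[sel]
    if t.size < 2:
        raise ValueError("fit window contains fewer than two points")
    res = stats.linregress(t, y)
    # nm^2/ps = 1e-18 m^2 / 1e-12 s = 1e-6 m^2/s
    return res.slope / 6.0 * 1e-6, res.stderr / 6.0 * 1e-6


def extrapolate_diffusion_infinite_box(box_lengths_nm, d_values):
    """Extrapolate D to infinite box size: intercept of D vs 1/L at 1/L = 0.

    Returns (D_inf, standard error of the intercept).
    """
    L = np.asarray(box_lengths_nm, dtype=float)
    D = np.asarray(d_values, dtype=float)
    if np.unique(L).size < 2:
        raise ValueError("at least two distinct box lengths are required")
    res = stats.linregress(1.0 / L, D)
    return res.intercept, res.intercept_stderr
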