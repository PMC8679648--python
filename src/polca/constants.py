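"""Physical constants and unit conversions used across the package.

Internal unit regime: lengths in nm, energies in kJ/mol, angles in degrees
at interfaces (radians internally), charges in elementary charge units,
dipoles in debye, polarizability volumes in Å³, pressures in bar at
interfaces (Eq-of-state fits run in mmHg, the convention of the vapor
pressure correlations).
"""

from __future__ import annotations

import scipy.constants as _sc

#: Molar gas constant, J mol^-1 K^-1.
R = 8.314462618

#: Boltzmann constant, J/K.
K_B = _sc.k

#: Vacuum permittivity, F/m.
EPS0 = _sc.epsilon_0

#: Avogadro's number.
N_A = _sc.N_A

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_KJMOL_NM = 138.935458

#: 1 debye in C m.
DEBYE = 1e-21 / _sc.c

#: Energy scale of mu^2 / alpha with mu in debye and alpha in Å^3,
#: expressed in kJ/mol: D^2 / (4 pi eps0 Å^3) * N_A.
DIPOLE_SQ_PER_ALPHA_KJMOL = DEBYE**2 / (4 * _sc.pi * EPS0 * 1e-30) * N_A / 1000.0

#: Pressure conversions.
BAR_PER_ATM = 1.01325
MMHG_PER_BAR = 750.062
PA_PER_BAR = 1e5


def mmhg_to_bar(p: float) -> float:
    return p / MMHG_PER_BAR


def bar_to_mmhg(p: float) -> float:
    return p * MMHG_PER_BAR


def bar_to_pa(p: float) -> float:
    return p * PA_PER_BAR
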