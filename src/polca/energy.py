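"""Classical potential-energy terms on explicit conformations.

Single-molecule evaluator: harmonic angles, Ryckaert-Bellemans torsions,
12-6 Lennard-Jones and Coulomb terms over non-excluded intramolecular
pairs.  No cutoff or periodicity — bulk simulation is delegated to an
external engine; this evaluator serves torsion scans and unit tests.

Dihedral convention: the Ryckaert-Bellemans series is evaluated with
cosine argument psi = phi - 180 degrees, so the trans conformation
(phi = 180) has cos(psi) = 1.  This matches the convention of the
topology-export dialect, so fitted coefficients round-trip through the
exported files unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_KJMOL_NM
from .forcefield import UATopology
from . import geometry


class OverlappingSitesError(ValueError):
    """Two non-excluded sites (nearly) coincide."""


def combine_lj(params_i: tuple[float, float], params_j: tuple[float, float]):
    """Lorentz-Berthelot combination: arithmetic-mean sigma, geometric-mean epsilon."""
    si, ei = params_i
    sj, ej = params_j
    if si < 0 or sj < 0 or ei < 0 or ej < 0:
        raise ValueError("negative Lennard-Jones parameters")
    return (0.5 * (si + sj), math.sqrt(ei * ej))


def rb_energy(phi_deg, coeffs) -> np.ndarray | float:
    """Ryckaert-Bellemans torsion energy, kJ/mol.

    E(phi) = sum_n C_n cos(psi)^n with psi = phi - 180 deg.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("non-finite torsion coefficients")
    phi = np.asarray(phi_deg, dtype=float)
    c = np.cos(np.radians(phi - 180.0))
    out = np.zeros_like(c)
    for n, C in enumerate(coeffs):
        out = out + C * c**n
    if np.ndim(phi_deg) == 0:
        return float(out)
    return out


def lj_pair(r: float, sigma: float, epsilon: float) -> float:
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def coulomb_pair(r: float, qi: float, qj: float,
                 ke: float = COULOMB_KJMOL_NM) -> float:
    return ke * qi * qj / r


@dataclass
class Conformation:
    """Site coordinates (nm) bound to a parent topology."""

    topology: UATopology
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_sites, 3):
            raise ValueError(
                f"coordinate count {self.coords.shape} does not match "
                f"{self.topology.n_sites} sites"
            )

    def check_constraints(self, tol: float = 1e-6) -> bool:
        for (i, j), r0 in zip(self.topology.bonds, self.topology.bond_lengths):
            if abs(geometry.measure_distance(self.coords, i, j) - r0) > tol:
                return False
        return True


def angle_energy(conf: Conformation) -> float:
    e = 0.0
    for (i, j, k), th0, kang in conf.topology.angles:
        th = math.radians(geometry.measure_angle(conf.coords, i, j, k))
        e += 0.5 * kang * (th - math.radians(th0)) ** 2
    return e


def torsion_energy(conf: Conformation) -> float:
    e = 0.0
    for quad, coeffs in conf.topology.torsions:
        phi = geometry.measure_dihedral(conf.coords, *quad)
        e += rb_energy(phi, coeffs)
    return e


def intramolecular_nonbonded(conf: Conformation, r_min: float = 1e-4):
    """(LJ, Coulomb) sums over all non-excluded intramolecular pairs, kJ/mol."""
    topo = conf.topology
    x = conf.coords
    e_lj = 0.0
    e_coul = 0.0
    n = topo.n_sites
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in topo.exclusions:
                continue
            r = geometry.measure_distance(x, i, j)
            if r < r_min:
                raise OverlappingSitesError(f"sites {i} and {j} overlap (r = {r:.2e} nm)")
            sij, eij = combine_lj((topo.sigma[i], topo.epsilon[i]),
                                  (topo.sigma[j], topo.epsilon[j]))
            if eij > 0.0:
                e_lj += lj_pair(r, sij, eij)
            e_coul += coulomb_pair(r, topo.charges[i], topo.charges[j])
    return e_lj, e_coul


def total_energy(conf: Conformation) -> dict[str, float]:
    """Component breakdown of the classical energy (bonds are rigid)."""
    e_lj, e_coul = intramolecular_nonbonded(conf)
    e_ang = angle_energy(conf)
    e_tor = torsion_energy(conf)
    return {
        "angle": e_ang,
        "torsion": e_tor,
        "lj": e_lj,
        "coulomb": e_coul,
        "total": e_ang + e_tor + e_lj + e_coul,
    }


def torsion_profile(
    topology: UATopology,
    dihedral: tuple[int, int, int, int],
    angles_deg=None,
    coords: np.ndarray | None = None,
):
    """Rigid-rotation energy profile about the central bond of ``dihedral``.

    Returns a record array-like dict of columns: angle (deg), E_total,
    E_torsion, E_LJ, E_Coulomb (kJ/mol).  Default grid: 12 points in 30
    degree steps over the full 360 degree range.
    """
    i, j, k, l = dihedral
    bondset = {tuple(sorted(b)) for b in topology.bonds}
    for a, b in ((i, j), (j, k), (k, l)):
        if tuple(sorted((a, b))) not in bondset:
            raise ValueError(f"dihedral atoms {dihedral} are not bonded in sequence")
    if angles_deg is None:
        angles_deg = np.arange(0.0, 360.0, 30.0)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if coords is None:
        coords = geometry.embed_topology(topology)
    rows = {"angle": [], "E_total": [], "E_torsion": [], "E_LJ": [], "E_Coulomb": []}
    phi0 = geometry.measure_dihedral(coords, i, j, k, l)
    for target in angles_deg:
        x = geometry.rotate_about_bond(coords, topology.bonds, j, k, target - phi0)
        conf = Conformation(topology, x)
        comp = total_energy(conf)
        rows["angle"].append(float(target))
        rows["E_total"].append(comp["total"])
        rows["E_torsion"].append(comp["torsion"])
        rows["E_LJ"].append(comp["lj"])
        rows["E_Coulomb"].append(comp["coulomb"])
    return {k_: np.array(v) for k_, v in rows.items()}


def write_profile(profile: dict, path) -> None:
    """Emit a profile table as delimited text."""
    import pandas as pd

    pd.DataFrame(profile).to_csv(path, index=False)
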