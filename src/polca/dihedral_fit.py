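"""Torsion parametrization: isolate the torsional target from a QM scan and
fit Ryckaert-Bellemans coefficients.

The QM scan provides total energies along a rigid rotation.  Classical
non-excluded LJ/Coulomb contributions along the scan and contributions
from dihedral classes that were already parametrized are subtracted; the
residual, shifted so its minimum is zero, is the fitting target for the
six-coefficient cosine series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import rb_energy


class ConditioningError(ValueError):
    """The cosine-power design matrix is rank-deficient."""


class DependencyError(ValueError):
    """The scan contains an unparametrized dihedral class other than the target."""


@dataclass
class TorsionScan:
    """A 360-degree dihedral energy scan.

    Parameters
    ----------
    angles_deg : array
        Dihedral grid; default protocol is 12 points in 30-degree steps.
    energies : array
        QM energies along the grid, kJ/mol.
    nonbonded : array, optional
        Classical non-excluded LJ+Coulomb energy along the scan (kJ/mol),
        to be subtracted.
    other_torsions : dict, optional
        ``class name -> (coefficients or None, angles along scan)`` for
        dihedral classes present in the scanned molecule other than the
        target.  ``None`` coefficients mark a class not yet fitted.
    """

    angles_deg: np.ndarray
    energies: np.ndarray
    nonbonded: np.ndarray | None = None
    other_torsions: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.angles_deg.shape != self.energies.shape:
            raise ValueError("angle grid and energies differ in length")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("non-finite scan energies")
        if self.nonbonded is not None:
            self.nonbonded = np.asarray(self.nonbonded, dtype=float)


def isolate_torsion_target(scan: TorsionScan) -> np.ndarray:
    """Residual profile = QM - classical nonbonded - already-fitted torsions,
    shifted so its minimum is zero."""
    residual = scan.energies.astype(float).copy()
    if scan.nonbonded is not None:
        residual = residual - scan.nonbonded
    for cls_name, (coeffs, angles) in scan.other_torsions.items():
        if coeffs is None:
            raise DependencyError(
                f"dihedral class {cls_name!r} appears in scan {scan.name!r} "
                "but has no fitted coefficients yet"
            )
        angles = np.asarray(angles, dtype=float)
        if angles.ndim == 1 and angles.shape == scan.angles_deg.shape:
            residual = residual - rb_energy(angles, coeffs)
        else:  # several symmetry-equivalent dihedrals of the same class
            for a in angles:
                residual = residual - rb_energy(np.asarray(a, dtype=float), coeffs)
    return residual - residual.min()


def rb_design_matrix(angles_deg: np.ndarray, mask=None) -> np.ndarray:
    c = np.cos(np.radians(np.asarray(angles_deg, dtype=float) - 180.0))
    cols = [c**n for n in range(6)]
    if mask is not None:
        cols = [col for n, col in enumerate(cols) if mask[n]]
    return np.column_stack(cols)


@dataclass
class RBFit:
    coefficients: np.ndarray  # C0..C5
    rms_residual: float
    rank: int
    n_points: int

    def __iter__(self):
        return iter(self.coefficients)


def fit_rb_coefficients(
    angles_deg,
    profile,
    mask: tuple[bool, ...] | None = None,
) -> RBFit:
    """Unweighted least-squares fit of the six-term cosine series.

    ``mask`` fixes chosen coefficients to zero (False entries) for
    reproduction studies; default fits use all six.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if angles_deg.size < 6:
        raise ValueError("at least 6 distinct angles are required")
    A = rb_design_matrix(angles_deg, mask)
    n_free = A.shape[1]
    rank = np.linalg.matrix_rank(A)
    if rank < n_free:
        raise ConditioningError(
            f"design matrix rank {rank} < {n_free}: scan angles give "
            "colliding cosine powers; use a denser or asymmetric grid"
        )
    sol, *_ = np.linalg.lstsq(A, profile, rcond=None)
    coeffs = np.zeros(6)
    if mask is None:
        coeffs[:] = sol
    else:
        coeffs[np.asarray(mask, dtype=bool)] = sol
    resid = profile - A @ sol
    return RBFit(
        coefficients=coeffs,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        rank=int(rank),
        n_points=int(angles_deg.size),
    )


def fit_scan(scan: TorsionScan, mask=None) -> RBFit:
    """Isolate the torsional target of a scan and fit coefficients."""
    residual = isolate_torsion_target(scan)
    return fit_rb_coefficients(scan.angles_deg, residual, mask=mask)
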