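"""Synthetic fixture generators with recorded ground truth.

Each generator is deterministic under its seed and writes the planted
parameters alongside the data so round-trip tests (and users validating an
analysis chain) can compare recovered values against truth.

Kinds
-----
torsion_scan
    12-point dihedral scan built from known Ryckaert-Bellemans
    coefficients plus an optional synthetic 1-5 classical contribution.
response_surface
    Quadratic property responses over a (sigma, epsilon) design grid.
property_series
    Density and vapor-pressure series from a planted linear rho(T) and a
    planted ln p = A + B/T model, with optional noise and an injected
    flagged outlier.
molecules
    Structured-text molecule specs from the internal registry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import rb_energy
from .graph import build_molecule
from .molspec import write_molecule_spec
from .optimize import DesignGrid

KINDS = ("torsion_scan", "response_surface", "property_series", "molecules")


def _write_truth(outdir: Path, truth: dict) -> None:
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def make_torsion_scan(seed: int, outdir: Path,
                      coeffs=(1.224, 3.672, 0.0, -4.895, 0.0, 0.0),
                      with_nonbonded: bool = True) -> dict:
    rng = np.random.default_rng(seed)
    angles = np.arange(0.0, 360.0, 30.0)
    torsion = rb_energy(angles, coeffs)
    if with_nonbonded:
        # smooth periodic stand-in for a 1-5 LJ+Coulomb contribution
        a, b = rng.uniform(0.5, 2.0, size=2)
        nonbonded = a * np.cos(np.radians(angles)) + b * np.cos(2 * np.radians(angles))
    else:
        nonbonded = np.zeros_like(angles)
    total = torsion + nonbonded
    df = pd.DataFrame({"angle_deg": angles, "energy_kjmol": total,
                       "nonbonded_kjmol": nonbonded})
    df.to_csv(outdir / "torsion_scan.csv", index=False)
    truth = {"kind": "torsion_scan", "seed": seed, "coefficients": list(coeffs),
             "with_nonbonded": with_nonbonded}
    _write_truth(outdir, truth)
    return truth


def make_response_surface(seed: int, outdir: Path,
                          sigma_levels=(0.5, 0.525, 0.55, 0.575, 0.6, 0.625),
                          epsilon_levels=(0.05, 0.075, 0.1, 0.125, 0.15, 0.175),
                          n_surfaces: int = 4) -> dict:
    rng = np.random.default_rng(seed)
    grid = DesignGrid(np.asarray(sigma_levels), np.asarray(epsilon_levels))
    coded = grid.coded_points
    # a shared interior minimum so the synthetic optimum is well defined
    xstar = rng.uniform(-0.6, 0.6, size=2)
    rows = {"sigma": grid.points[:, 0], "epsilon": grid.points[:, 1],
            "x1": coded[:, 0], "x2": coded[:, 1]}
    targets = {}
    surf_meta = {}
    for s in range(n_surfaces):
        scale = rng.uniform(0.5, 3.0)
        y0 = rng.uniform(10.0, 1000.0)
        y = y0 + scale * ((coded[:, 0] - xstar[0]) ** 2 + (coded[:, 1] - xstar[1]) ** 2)
        key = f"prop{s}"
        rows[key] = y
        targets[key] = y0
        surf_meta[key] = {"scale": scale, "target": y0}
    pd.DataFrame(rows).to_csv(outdir / "response_surface.csv", index=False)
    truth = {"kind": "response_surface", "seed": seed,
             "sigma_levels": list(map(float, sigma_levels)),
             "epsilon_levels": list(map(float, epsilon_levels)),
             "x_star_coded": [float(v) for v in xstar],
             "targets": targets, "surfaces": surf_meta}
    _write_truth(outdir, truth)
    return truth


def make_property_series(seed: int, outdir: Path,
                         rho_298: float = 761.1, rho_slope: float = -0.92,
                         hvap_kjmol: float = 25.2, p_298_mmhg: float = 600.0,
                         noise: float = 0.0, inject_outlier: bool = True) -> dict:
    """Density and vapor-pressure tables from planted models.

    Defaults emulate a light tetraalkylsilane: density ~761 kg/m^3 at
    298 K with a -0.92 kg/m^3/K slope, enthalpy of vaporization
    25.2 kJ/mol.  ln p = A + B/T with B = -1000 * hvap / R.
    """
    rng = np.random.default_rng(seed)
    t_rho = np.arange(273.0, 324.0, 10.0)
    rho = rho_298 + rho_slope * (t_rho - 298.15) + rng.normal(0, noise, t_rho.size)
    drec = [{"T": float(t), "value": float(v), "source": "planted", "excluded": False}
            for t, v in zip(t_rho, rho)]
    if inject_outlier:
        drec.append({"T": 323.0, "value": float(rho_298 + rho_slope * (323 - 298.15) + 25.0),
                     "source": "outlier", "excluded": True})
    pd.DataFrame(drec).to_csv(outdir / "density_series.csv", index=False)

    b = -1000.0 * hvap_kjmol / 8.314462618
    a = np.log(p_298_mmhg) - b / 298.15
    t_p = np.arange(268.0, 319.0, 10.0)
    p = np.exp(a + b / t_p) * np.exp(rng.normal(0, noise * 1e-4, t_p.size))
    prec = [{"T": float(t), "value": float(v), "source": "planted", "excluded": False}
            for t, v in zip(t_p, p)]
    pd.DataFrame(prec).to_csv(outdir / "vapor_pressure_series.csv", index=False)
    truth = {"kind": "property_series", "seed": seed, "rho_298": rho_298,
             "rho_slope": rho_slope, "hvap_kjmol": hvap_kjmol,
             "p_298_mmhg": p_298_mmhg, "lnp_a": float(a), "lnp_b": float(b),
             "noise": noise}
    _write_truth(outdir, truth)
    return truth


def make_molecules(seed: int, outdir: Path,
                   names=("tetramethylsilane", "trimethylsilanol",
                          "tetraethoxysilane", "dimethyldimethoxysilane")) -> dict:
    for name in names:
        g = build_molecule(name)
        write_molecule_spec(g, outdir / f"{name}.yaml")
    truth = {"kind": "molecules", "seed": seed, "names": list(names)}
    _write_truth(outdir, truth)
    return truth


def generate_fixtures(kind: str, seed: int, outdir) -> dict:
    """Dispatch fixture generation; deterministic under (kind, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "torsion_scan":
        return make_torsion_scan(seed, outdir)
    if kind == "response_surface":
        return make_response_surface(seed, outdir)
    if kind == "property_series":
        return make_property_series(seed, outdir)
    if kind == "molecules":
        return make_molecules(seed, outdir)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
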