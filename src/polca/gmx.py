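"""GROMACS-dialect topology and coordinate export, plus box packing.

Bonds are exported as constraints (they are rigid in this force field),
angles as harmonic terms (funct 1), torsions as Ryckaert-Bellemans
dihedrals (funct 3), with nrexcl = 3 and no 1-4 pairs section — pairs
separated by three bonds or fewer are fully excluded and no scaled 1-4
interaction is reintroduced.  Output is deterministic (byte-stable) for a
fixed input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .forcefield import UATopology
from . import geometry

#: masses of the united-atom site types, g/mol
SITE_MASSES = {
    "CH3": 15.035,
    "CH2": 14.027,
    "CH": 13.019,
    "C": 12.011,
    "Si": 28.086,
    "O_C": 15.999,
    "O_H": 15.999,
    "O_B": 15.999,
    "H_O": 1.008,
}


@dataclass
class ExportDialect:
    name: str = "gromacs"
    dihedral_funct: int = 3  # Ryckaert-Bellemans, cos argument phi - 180
    constraint_funct: int = 1
    exclusion_depth: int = 3


def molecular_weight(topology: UATopology) -> float:
    return sum(SITE_MASSES[l] for l in topology.labels)


def _atomtype_name(topology: UATopology, i: int) -> str:
    lab = topology.labels[i]
    if lab == "Si":
        return f"Si{topology.si_oxy_counts.get(i, 0)}"
    return lab.replace("_", "")


def write_itp(topology: UATopology, dialect: ExportDialect | None = None) -> str:
    """Molecule .itp text (moleculetype, atoms, constraints, angles,
    RB dihedrals)."""
    dialect = dialect or ExportDialect()
    rep = topology.validate()
    if not (rep["neutral"] and rep["complete"]):
        raise ValueError("refusing to export an unvalidated topology")
    name = topology.name or "MOL"
    lines = [
        "; generated by polca",
        "",
        "[ moleculetype ]",
        "; name  nrexcl",
        f"{name:<16s} {dialect.exclusion_depth}",
        "",
        "[ atoms ]",
        ";  nr  type  resnr  residue  atom  cgnr  charge      mass",
    ]
    for i, lab in enumerate(topology.labels):
        at = _atomtype_name(topology, i)
        lines.append(
            f"{i + 1:5d}  {at:<5s} {1:5d}  {name[:5]:<7s} {at:<5s} {i + 1:5d} "
            f"{topology.charges[i]:10.6f} {SITE_MASSES[lab]:9.4f}"
        )
    lines += ["", "[ constraints ]", ";  ai  aj  funct  length(nm)"]
    for (a, b), r0 in zip(topology.bonds, topology.bond_lengths):
        lines.append(f"{a + 1:5d} {b + 1:5d} {dialect.constraint_funct:5d} {r0:10.5f}")
    lines += ["", "[ angles ]", ";  ai  aj  ak  funct  theta0(deg)  k(kJ/mol/rad2)"]
    for (i, j, k), th0, kang in topology.angles:
        lines.append(f"{i + 1:5d} {j + 1:5d} {k + 1:5d} {1:5d} {th0:10.2f} {kang:10.2f}")
    lines += ["", "[ dihedrals ]", ";  ai  aj  ak  al  funct  C0..C5 (kJ/mol)"]
    for quad, coeffs in topology.torsions:
        idx = " ".join(f"{x + 1:5d}" for x in quad)
        cs = " ".join(f"{c:10.5f}" for c in coeffs)
        lines.append(f"{idx} {dialect.dihedral_funct:5d} {cs}")
    lines.append("")
    return "\n".join(lines)


def write_top(topology: UATopology, n_molecules: int = 1,
              dialect: ExportDialect | None = None) -> str:
    """System .top text with atomtypes (per-site LJ), defaults and the
    molecule count."""
    dialect = dialect or ExportDialect()
    seen = {}
    for i, lab in enumerate(topology.labels):
        at = _atomtype_name(topology, i)
        seen.setdefault(at, (SITE_MASSES[lab], topology.sigma[i], topology.epsilon[i]))
    lines = [
        "; generated by polca",
        "",
        "[ defaults ]",
        "; nbfunc  comb-rule  gen-pairs  fudgeLJ  fudgeQQ",
        "1         2          no         1.0      1.0",
        "",
        "[ atomtypes ]",
        "; name  mass      charge  ptype  sigma(nm)  epsilon(kJ/mol)",
    ]
    for at in sorted(seen):
        mass, sig, eps = seen[at]
        lines.append(f"{at:<6s} {mass:9.4f}  0.000   A  {sig:9.5f} {eps:9.5f}")
    lines += ["", f'#include "{topology.name or "MOL"}.itp"', "",
              "[ system ]", topology.name or "MOL", "",
              "[ molecules ]", f"{topology.name or 'MOL':<16s} {n_molecules}", ""]
    return "\n".join(lines)


def write_gromacs_topology(topology: UATopology, outdir,
                           n_molecules: int = 1,
                           dialect: ExportDialect | None = None) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = topology.name or "MOL"
    itp = outdir / f"{name}.itp"
    top = outdir / f"{name}.top"
    itp.write_text(write_itp(topology, dialect))
    top.write_text(write_top(topology, n_molecules, dialect))
    return {"itp": itp, "top": top}


def write_gro(coords_nm: np.ndarray, labels, box_nm: float, path,
              name: str = "MOL", title: str = "polca configuration") -> None:
    """GROMACS .gro coordinate file (fixed format, nm)."""
    coords_nm = np.asarray(coords_nm, dtype=float)
    n = coords_nm.shape[0]
    n_per_mol = len(labels)
    lines = [title, f"{n:5d}"]
    for i in range(n):
        mol = i // n_per_mol + 1
        lab = labels[i % n_per_mol].replace("_", "")[:5]
        x, y, z = coords_nm[i]
        lines.append(f"{mol:5d}{name[:5]:<5s}{lab:>5s}{(i % 99999) + 1:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{box_nm:10.5f}{box_nm:10.5f}{box_nm:10.5f}")
    lines.append("")
    Path(path).write_text("\n".join(lines))


class PackingError(RuntimeError):
    pass


def pack_box(topology: UATopology, count: int, box_nm: float, seed: int,
             min_dist: float = 0.25, max_attempts: int = 2000,
             path=None) -> np.ndarray:
    """Seeded random placement of rigid molecule copies in a cubic box.

    Each copy is randomly rotated and translated; a candidate placement is
    accepted only if every minimum-image inter-site distance to already
    placed molecules exceeds ``min_dist`` (nm).  Deterministic for a fixed
    seed.  A single molecule is centered in the box.
    """
    rng = np.random.default_rng(seed)
    base = geometry.embed_topology(topology)
    base = base - base.mean(axis=0)
    placed: list[np.ndarray] = []
    if count == 1:
        placed.append(base + box_nm / 2.0)
    else:
        all_sites = np.empty((0, 3))
        for _ in range(count):
            ok = False
            for _attempt in range(max_attempts):
                # random rotation via normalized quaternion
                q = rng.normal(size=4)
                q /= np.linalg.norm(q)
                w, x, y, z = q
                Rm = np.array([
                    [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                    [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                    [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
                ])
                cand = base @ Rm.T + rng.uniform(0.0, box_nm, size=3)
                if all_sites.shape[0]:
                    d = cand[:, None, :] - all_sites[None, :, :]
                    d -= box_nm * np.round(d / box_nm)
                    if np.min(np.linalg.norm(d, axis=-1)) < min_dist:
                        continue
                placed.append(cand)
                all_sites = np.vstack([all_sites, cand % box_nm])
                ok = True
                break
            if not ok:
                raise PackingError(
                    f"could not place molecule {len(placed) + 1}/{count} after "
                    f"{max_attempts} attempts (box {box_nm} nm, min_dist {min_dist} nm)"
                )
    coords = np.vstack([p % box_nm for p in placed])
    if path is not None:
        write_gro(coords, topology.labels, box_nm, path, name=(topology.name or "MOL")[:5])
    return coords
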