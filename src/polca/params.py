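"""Parameter set: charge rules, bonded terms, Lennard-Jones tables.

The shipped defaults mirror the published organosilicate tables; everything
is loaded from a human-editable YAML file so users can override, e.g., the
carried-over alkane constants.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class MissingParameterError(KeyError):
    """A bonded or nonbonded term has no table entry."""


def _norm_key(parts: tuple[str, ...]) -> tuple[str, ...]:
    """Canonical orientation of a bond/angle/torsion type tuple."""
    return min(parts, parts[::-1])


@dataclass
class ParameterSet:
    charges: dict[str, float]
    bonds: dict[tuple[str, str], float]
    angles: dict[tuple[str, str, str], tuple[float, float]]
    torsions: dict[tuple[str, str, str, str], tuple[float, ...]]
    lj: dict[str, tuple[float, float]]
    alkane_lj: dict[str, tuple[float, float]]
    si_sigma_scaling_per_oxy: float = 0.05
    source: str = "builtin"

    # -- loading ----------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict, source: str = "dict") -> "ParameterSet":
        bonds = {_norm_key(tuple(k.split("-"))): float(v) for k, v in d["bonds"].items()}
        angles = {
            _norm_key(tuple(k.split("-"))): (float(v[0]), float(v[1]))
            for k, v in d["angles"].items()
        }
        torsions = {
            _norm_key(tuple(k.split("-"))): tuple(float(x) for x in v)
            for k, v in d["torsions"].items()
        }
        lj = {k: (float(v[0]), float(v[1])) for k, v in d["lj"].items()}
        alkane = {k: (float(v[0]), float(v[1])) for k, v in d.get("alkane_lj", {}).items()}
        ps = cls(
            charges={k: float(v) for k, v in d["charges"].items()},
            bonds=bonds,
            angles=angles,
            torsions=torsions,
            lj=lj,
            alkane_lj=alkane,
            si_sigma_scaling_per_oxy=float(d.get("si_sigma_scaling_per_oxy", 0.05)),
            source=source,
        )
        ps.validate()
        return ps

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), source=str(path))

    @classmethod
    def default(cls) -> "ParameterSet":
        ref = importlib.resources.files("polca.data").joinpath("parameters.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()), source="builtin")

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for name, (sigma, eps) in {**self.lj, **self.alkane_lj}.items():
            if name == "H_O":
                continue
            if sigma <= 0 or eps <= 0:
                raise ValueError(f"non-positive LJ parameters for {name}")

    # -- lookups ----------------------------------------------------------
    def bond_length(self, key: tuple[str, str]) -> float:
        try:
            return self.bonds[_norm_key(key)]
        except KeyError:
            raise MissingParameterError(f"no bond length for {'-'.join(key)}") from None

    def angle_params(self, key: tuple[str, str, str]) -> tuple[float, float]:
        try:
            return self.angles[_norm_key(key)]
        except KeyError:
            raise MissingParameterError(f"no angle parameters for {'-'.join(key)}") from None

    def torsion_coeffs(self, key: tuple[str, str, str, str]) -> tuple[float, ...]:
        try:
            return self.torsions[_norm_key(key)]
        except KeyError:
            raise MissingParameterError(f"no torsion coefficients for {'-'.join(key)}") from None

    def si_sigma(self, k: int) -> float:
        """Sigma of a Si atom with k oxygenated substituents.

        Values inside the table (k = 0..4) are returned verbatim; the
        per-substituent scaling rule is used only beyond the table.
        """
        name = f"Si^{k}"
        if name in self.lj:
            return self.lj[name][0]
        return self.scaled_si_sigma(k)

    def scaled_si_sigma(self, k: int) -> float:
        """Sigma from the scaling law: sigma(Si^k) = sigma(Si^0)*(1 - 0.05 k)."""
        sigma0 = self.lj["Si^0"][0]
        return sigma0 * (1.0 - self.si_sigma_scaling_per_oxy * k)

    def lj_for_site(self, label: str, si_oxy_count: int | None = None) -> tuple[float, float]:
        if label == "Si":
            if si_oxy_count is None:
                raise MissingParameterError("Si site requires its oxygenated-substituent count")
            name = f"Si^{si_oxy_count}"
            if name in self.lj:
                return self.lj[name]
            return (self.scaled_si_sigma(si_oxy_count), self.lj["Si^0"][1])
        if label in self.lj:
            return self.lj[label]
        if label in ("CH3", "CH2", "CH", "C"):
            if label not in self.alkane_lj:
                raise MissingParameterError(
                    f"alkane LJ constants for {label} are not configured; supply them "
                    "in the parameter file under 'alkane_lj'"
                )
            return self.alkane_lj[label]
        raise MissingParameterError(f"no LJ parameters for site type {label}")
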