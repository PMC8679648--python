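"""Molecular graphs and united-atom perception.

A :class:`MoleculeGraph` is a light wrapper around :class:`networkx.Graph`
holding element symbols on nodes.  All-atom graphs (explicit hydrogens) are
collapsed to united-atom (UA) graphs in which each aliphatic CH_x group is a
single site; hydroxyl hydrogens stay explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

SUPPORTED_ELEMENTS = {"C", "H", "O", "Si"}

#: UA site labels.
UA_CARBON_LABELS = {3: "CH3", 2: "CH2", 1: "CH", 0: "C"}


class ScopeError(ValueError):
    """Molecule falls outside the supported organosilicate chemistry."""


class MalformedMoleculeError(ValueError):
    """Input graph violates basic structural invariants."""


@dataclass
class MoleculeGraph:
    """Chemical graph: atoms (element, index), bonds, optional coordinates.

    Parameters
    ----------
    elements : sequence of str
        Element symbol per atom, indexed 0..n-1.  For united-atom graphs the
        "element" of a collapsed carbon is still ``C``; the UA label lives in
        ``labels``.
    bonds : iterable of (int, int)
        Unordered pairs of atom indices.
    coordinates : mapping int -> (x, y, z), optional
        Cartesian coordinates in nm.
    labels : mapping int -> str, optional
        UA site labels (CH3, CH2, CH, C, Si, O_C, O_H, O_B, H_O); present
        only on united-atom graphs.
    name : str
    """

    elements: list[str]
    bonds: list[tuple[int, int]]
    coordinates: dict[int, tuple[float, float, float]] | None = None
    labels: dict[int, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.elements)
        for i, j in self.bonds:
            if i == j:
                raise MalformedMoleculeError(f"atom {i} bonded to itself")
            if not (0 <= i < n and 0 <= j < n):
                raise MalformedMoleculeError(f"bond ({i},{j}) references missing atom")
        for el in self.elements:
            if el not in SUPPORTED_ELEMENTS:
                raise ScopeError(f"unsupported element {el!r}")
        if n > 1 and not nx.is_connected(self.to_networkx()):
            raise MalformedMoleculeError("molecule graph is not connected")

    # -- graph views ------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el, label=self.labels.get(i))
        g.add_edges_from(self.bonds)
        return g

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def is_united_atom(self) -> bool:
        return bool(self.labels)


def perceive_united_atoms(graph: MoleculeGraph) -> MoleculeGraph:
    """Collapse an explicit-hydrogen graph into a united-atom graph.

    Aliphatic hydrogens are merged into the adjacent carbon, which becomes a
    CH_x site; hydrogens bonded to oxygen are retained as explicit ``H_O``
    sites.  Heavy-atom connectivity is preserved.

    Raises
    ------
    ScopeError
        If a hydrogen is bonded to silicon (SiH_x species are out of scope).
    MalformedMoleculeError
        If a hydrogen has a valence other than one.
    """
    h_count = {i: 0 for i, el in enumerate(graph.elements) if el != "H"}
    keep_h: list[int] = []
    for i, el in enumerate(graph.elements):
        if el != "H":
            continue
        nbrs = graph.neighbors(i)
        if len(nbrs) != 1:
            raise MalformedMoleculeError(
                f"hydrogen {i} bonded to {len(nbrs)} atoms (expected exactly 1)"
            )
        parent = nbrs[0]
        pel = graph.elements[parent]
        if pel == "Si":
            raise ScopeError(f"hydrogen {i} bonded to Si {parent}: SiH_x out of scope")
        if pel == "C":
            h_count[parent] += 1
        elif pel == "O":
            keep_h.append(i)
        else:
            raise MalformedMoleculeError(f"hydrogen {i} bonded to hydrogen {parent}")

    # Re-index the retained atoms.
    kept = [i for i, el in enumerate(graph.elements) if el != "H"] + keep_h
    kept.sort()
    remap = {old: new for new, old in enumerate(kept)}
    elements = [graph.elements[i] for i in kept]
    bonds = sorted(
        {
            (min(remap[a], remap[b]), max(remap[a], remap[b]))
            for a, b in graph.bonds
            if a in remap and b in remap
        }
    )
    labels: dict[int, str] = {}
    for old in kept:
        new = remap[old]
        el = graph.elements[old]
        if el == "C":
            x = h_count[old]
            if x > 3:
                raise MalformedMoleculeError(f"carbon {old} carries {x} hydrogens")
            labels[new] = UA_CARBON_LABELS[x]
        elif el == "Si":
            labels[new] = "Si"
        elif el == "O":
            labels[new] = "O"  # refined by atom typing
        else:  # retained hydroxyl hydrogen
            labels[new] = "H_O"
    coords = None
    if graph.coordinates:
        coords = {remap[i]: graph.coordinates[i] for i in kept if i in graph.coordinates}
    return MoleculeGraph(elements, bonds, coords, labels, graph.name)


# ---------------------------------------------------------------------------
# Programmatic all-atom molecule builders for the compounds used in
# parametrization and validation.
# ---------------------------------------------------------------------------


class _Builder:
    def __init__(self, name: str):
        self.name = name
        self.elements: list[str] = []
        self.bonds: list[tuple[int, int]] = []

    def add(self, element: str, bond_to: int | None = None) -> int:
        self.elements.append(element)
        idx = len(self.elements) - 1
        if bond_to is not None:
            self.bonds.append((bond_to, idx))
        return idx

    def methyl(self, attach: int) -> int:
        c = self.add("C", attach)
        for _ in range(3):
            self.add("H", c)
        return c

    def ethyl(self, attach: int) -> int:
        c1 = self.add("C", attach)
        self.add("H", c1)
        self.add("H", c1)
        c2 = self.add("C", c1)
        for _ in range(3):
            self.add("H", c2)
        return c1

    def methoxy(self, attach: int) -> int:
        o = self.add("O", attach)
        self.methyl(o)
        return o

    def ethoxy(self, attach: int) -> int:
        o = self.add("O", attach)
        self.ethyl(o)
        return o

    def hydroxyl(self, attach: int) -> int:
        o = self.add("O", attach)
        self.add("H", o)
        return o

    def build(self) -> MoleculeGraph:
        return MoleculeGraph(self.elements, self.bonds, name=self.name)


def build_silane(
    name: str,
    methyl: int = 0,
    ethyl: int = 0,
    methoxy: int = 0,
    ethoxy: int = 0,
    hydroxyl: int = 0,
) -> MoleculeGraph:
    """Build an all-atom tetrahedrally substituted silane."""
    if methyl + ethyl + methoxy + ethoxy + hydroxyl != 4:
        raise ScopeError("silicon must carry exactly 4 substituents")
    b = _Builder(name)
    si = b.add("Si")
    for _ in range(methyl):
        b.methyl(si)
    for _ in range(ethyl):
        b.ethyl(si)
    for _ in range(methoxy):
        b.methoxy(si)
    for _ in range(ethoxy):
        b.ethoxy(si)
    for _ in range(hydroxyl):
        b.hydroxyl(si)
    return b.build()


def build_hexamethyldisiloxane() -> MoleculeGraph:
    b = _Builder("hexamethyldisiloxane")
    si1 = b.add("Si")
    o = b.add("O", si1)
    si2 = b.add("Si", o)
    for _ in range(3):
        b.methyl(si1)
    for _ in range(3):
        b.methyl(si2)
    return b.build()


def build_alkane(n: int, name: str = "") -> MoleculeGraph:
    """Linear alkane C_n H_{2n+2} with explicit hydrogens."""
    b = _Builder(name or f"n-alkane-C{n}")
    prev = None
    for k in range(n):
        c = b.add("C", prev)
        n_h = 3 if k in (0, n - 1) else 2
        if n == 1:
            n_h = 4
        for _ in range(n_h):
            b.add("H", c)
        prev = c
    return b.build()


#: Registry of named compounds (abbreviations follow common usage:
#: Met = methyl, Eth = ethyl, SiOMet/SiOEth = alkoxysilanes, ...-SiOH silanols).
_REGISTRY = {
    "tetramethylsilane": dict(methyl=4),
    "ethyltrimethylsilane": dict(methyl=3, ethyl=1),
    "diethyldimethylsilane": dict(methyl=2, ethyl=2),
    "triethylmethylsilane": dict(methyl=1, ethyl=3),
    "tetraethylsilane": dict(ethyl=4),
    "trimethylsilanol": dict(methyl=3, hydroxyl=1),
    "triethylsilanol": dict(ethyl=3, hydroxyl=1),
    "tetramethoxysilane": dict(methoxy=4),
    "tetraethoxysilane": dict(ethoxy=4),
    "trimethylethoxysilane": dict(methyl=3, ethoxy=1),
    "dimethylethylethoxysilane": dict(methyl=2, ethyl=1, ethoxy=1),
    "methyldiethylethoxysilane": dict(methyl=1, ethyl=2, ethoxy=1),
    "triethylethoxysilane": dict(ethyl=3, ethoxy=1),
    "methoxytrimethylsilane": dict(methyl=3, methoxy=1),
    "dimethyldimethoxysilane": dict(methyl=2, methoxy=2),
}

ALIASES = {
    "Met4Si": "tetramethylsilane",
    "Eth4Si": "tetraethylsilane",
    "Met3SiOH": "trimethylsilanol",
    "Eth3SiOH": "triethylsilanol",
    "Met6Si2O": "hexamethyldisiloxane",
    "SiOMet4": "tetramethoxysilane",
    "SiOEth4": "tetraethoxysilane",
    "M3SiOE": "trimethylethoxysilane",
    "M2ESiOE": "dimethylethylethoxysilane",
    "ME2SiOE": "methyldiethylethoxysilane",
    "E3SiOE": "triethylethoxysilane",
}


def available_molecules() -> list[str]:
    return sorted(_REGISTRY) + ["hexamethyldisiloxane"]


def build_molecule(name: str) -> MoleculeGraph:
    """Build a named all-atom molecule from the internal registry."""
    key = ALIASES.get(name, name)
    if key == "hexamethyldisiloxane":
        return build_hexamethyldisiloxane()
    if key not in _REGISTRY:
        raise KeyError(
            f"unknown molecule {name!r}; available: {', '.join(available_molecules())}"
        )
    return build_silane(key, **_REGISTRY[key])
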