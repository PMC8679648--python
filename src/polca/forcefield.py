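"""United-atom typing, charge assignment and topology generation.

The pipeline is: all-atom graph -> united-atom perception -> atom typing
(O_H / O_C / O_B oxygens, Si with its oxygenated-substituent count k,
CH_x context) -> point charges (tabulated substituent charges, bespoke Si
charge closing neutrality) -> bonded terms (rigid bond constraints,
harmonic angles, Ryckaert-Bellemans torsions) -> Lennard-Jones parameters
(with the 5%-per-oxygenated-substituent sigma reduction on Si) -> exclusion
list (all pairs separated by three bonds or fewer; no 1-4 pair
interactions are retained).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from .graph import MoleculeGraph, MalformedMoleculeError, ScopeError, perceive_united_atoms
from .params import MissingParameterError, ParameterSet

logger = logging.getLogger(__name__)

#: site label -> bonded-term type class
_TYPE_CLASS = {
    "CH3": "C",
    "CH2": "C",
    "CH": "C",
    "C": "C",
    "Si": "Si",
    "O_C": "O_C",
    "O_H": "O_H",
    "O_B": "O_B",
    "H_O": "H",
}


def type_class(label: str) -> str:
    return _TYPE_CLASS[label]


@dataclass
class UATopology:
    """Fully parametrized united-atom topology."""

    name: str
    labels: list[str]  # site label per index
    bonds: list[tuple[int, int]]
    charges: list[float]
    sigma: list[float]  # nm
    epsilon: list[float]  # kJ/mol
    bond_lengths: list[float]  # nm, constraint length per bond
    angles: list[tuple[tuple[int, int, int], float, float]]  # (ijk, theta0 deg, k)
    torsions: list[tuple[tuple[int, int, int, int], tuple[float, ...]]]
    exclusions: set[tuple[int, int]]
    si_oxy_counts: dict[int, int] = field(default_factory=dict)
    graph: MoleculeGraph | None = None

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    @property
    def net_charge(self) -> float:
        return sum(self.charges)

    def torsion_class(self, quad: tuple[int, int, int, int]) -> tuple[str, ...]:
        return tuple(type_class(self.labels[i]) for i in quad)

    def validate(self) -> dict:
        """Neutrality and parameter-completeness report."""
        report = {
            "net_charge": self.net_charge,
            "neutral": abs(self.net_charge) <= 1e-12,
            "n_sites": self.n_sites,
            "n_constraints": len(self.bonds),
            "n_angles": len(self.angles),
            "n_torsions": len(self.torsions),
            "n_exclusions": len(self.exclusions),
            "complete": len(self.sigma) == self.n_sites == len(self.charges),
        }
        return report


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------


def assign_atom_types(ua: MoleculeGraph) -> MoleculeGraph:
    """Classify oxygens (O_H / O_C / O_B) and annotate Si oxy-substituent counts.

    Returns a new united-atom graph whose ``labels`` are fully refined.
    CH_x labels are already fixed by perception; context (Si-adjacent,
    alkoxy-adjacent, chain) is resolved during charge assignment.
    """
    if not ua.is_united_atom():
        raise MalformedMoleculeError("atom typing requires a united-atom graph")
    labels = dict(ua.labels)
    for i, el in enumerate(ua.elements):
        if el != "O":
            continue
        nbrs = ua.neighbors(i)
        if len(nbrs) != 2:
            raise ScopeError(f"oxygen {i} has valence {len(nbrs)} (expected 2)")
        nbr_labels = sorted(labels[j] if labels[j] != "O" else "O" for j in nbrs)
        nbr_els = sorted(ua.elements[j] for j in nbrs)
        if nbr_els == ["Si", "Si"]:
            labels[i] = "O_B"
        elif nbr_els == ["H", "Si"]:
            labels[i] = "O_H"
        elif nbr_els == ["C", "Si"]:
            labels[i] = "O_C"
        else:
            raise ScopeError(
                f"oxygen {i} with neighbors {nbr_labels} is outside scope "
                "(supported: Si-O-H, Si-O-C, Si-O-Si)"
            )
    for i, el in enumerate(ua.elements):
        if el == "Si" and len(ua.neighbors(i)) != 4:
            raise ScopeError(f"silicon {i} has {len(ua.neighbors(i))} substituents (expected 4)")
    out = MoleculeGraph(ua.elements, ua.bonds, ua.coordinates, labels, ua.name)
    return out


def si_oxy_counts(typed: MoleculeGraph) -> dict[int, int]:
    """Count oxygen-containing substituent groups k for every Si atom."""
    counts = {}
    for i, el in enumerate(typed.elements):
        if el == "Si":
            counts[i] = sum(1 for j in typed.neighbors(i) if typed.elements[j] == "O")
    return counts


# ---------------------------------------------------------------------------
# Charges
# ---------------------------------------------------------------------------


def assign_charges(typed: MoleculeGraph, params: ParameterSet | None = None) -> list[float]:
    """Assign point charges; silicon closes neutrality.

    Substituent charges are the rounded tabulated values; each silicon then
    receives the (full-precision) charge closing the neutrality of its own
    substituent atoms.  For multi-silicon molecules every non-Si atom is
    attributed to the silicon(s) it reaches without crossing another Si; a
    bridging O_B, reachable from both its silicons, is split equally.
    """
    params = params or ParameterSet.default()
    cr = params.charges
    labels = typed.labels
    molecule_has_oxygen = any(el == "O" for el in typed.elements)

    charges = [0.0] * typed.n_atoms
    si_atoms = [i for i, el in enumerate(typed.elements) if el == "Si"]
    if not si_atoms:
        return charges  # pure alkane fragment: all sites neutral

    for i, el in enumerate(typed.elements):
        lab = labels[i]
        if lab in ("O_C", "O_H", "O_B", "H_O"):
            charges[i] = cr[lab]
        elif lab in ("CH3", "CH2", "CH", "C"):
            nbr_labels = {labels[j] for j in typed.neighbors(i)}
            if "Si" in nbr_labels:
                if molecule_has_oxygen:
                    key = f"{lab}_Si_oxygenated"
                    if key not in cr:
                        raise MissingParameterError(
                            f"no charge rule for {lab} bonded to Si in an oxygenated molecule"
                        )
                    charges[i] = cr[key]
                else:
                    charges[i] = cr["CHx_Si_alkylsilane"]
            elif "O_C" in nbr_labels:
                charges[i] = cr["CHx_O_C"]
            else:
                charges[i] = cr["CHx_chain"]
        logger.debug("charge %s[%d] (%s) = %+.4f", typed.name, i, lab, charges[i])

    # Attribute every non-Si atom to its "owning" silicon(s): BFS from each
    # Si that does not pass through other silicons.
    g = typed.to_networkx()
    owners: dict[int, list[int]] = {i: [] for i in range(typed.n_atoms)}
    for si in si_atoms:
        seen = {si}
        stack = [si]
        while stack:
            u = stack.pop()
            for v in g.neighbors(u):
                if v in seen or typed.elements[v] == "Si":
                    continue
                seen.add(v)
                owners[v].append(si)
                stack.append(v)
    residual = 0.0
    per_si = {si: 0.0 for si in si_atoms}
    for i in range(typed.n_atoms):
        if typed.elements[i] == "Si":
            continue
        own = owners[i]
        if not own:
            residual += charges[i]
            continue
        for si in own:
            per_si[si] += charges[i] / len(own)
    if abs(residual) > 1e-12:
        raise ScopeError(
            f"charged atoms not attributable to any silicon (residual {residual:+.4f} e)"
        )
    for si in si_atoms:
        charges[si] = -per_si[si]
        logger.debug("charge %s[%d] (Si, bespoke) = %+.6f", typed.name, si, charges[si])
    return charges


# ---------------------------------------------------------------------------
# Bonded terms
# ---------------------------------------------------------------------------


def enumerate_angles(bonds: list[tuple[int, int]], n: int) -> list[tuple[int, int, int]]:
    adj = {i: set() for i in range(n)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    out = []
    for j in range(n):
        for i, k in itertools.combinations(sorted(adj[j]), 2):
            out.append((i, j, k))
    return out


def enumerate_torsions(bonds: list[tuple[int, int]], n: int) -> list[tuple[int, int, int, int]]:
    adj = {i: set() for i in range(n)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    out = []
    for j, k in bonds:
        for i in sorted(adj[j] - {k}):
            for l in sorted(adj[k] - {j, i}):
                quad = (i, j, k, l)
                if quad[::-1] < quad:
                    quad = quad[::-1]
                out.append(quad)
    return sorted(set(out))


def assign_bonded_terms(typed: MoleculeGraph, params: ParameterSet | None = None):
    """Map every bond, angle and proper torsion to its table parameters."""
    params = params or ParameterSet.default()
    labels = typed.labels
    cls = lambda i: type_class(labels[i])

    bond_lengths = [params.bond_length((cls(a), cls(b))) for a, b in typed.bonds]
    angles = []
    for (i, j, k) in enumerate_angles(typed.bonds, typed.n_atoms):
        th0, kang = params.angle_params((cls(i), cls(j), cls(k)))
        angles.append(((i, j, k), th0, kang))
    torsions = []
    for quad in enumerate_torsions(typed.bonds, typed.n_atoms):
        coeffs = params.torsion_coeffs(tuple(cls(x) for x in quad))
        torsions.append((quad, coeffs))
    return bond_lengths, angles, torsions


# ---------------------------------------------------------------------------
# Lennard-Jones
# ---------------------------------------------------------------------------


def assign_lj(typed: MoleculeGraph, params: ParameterSet | None = None):
    """Per-site sigma (nm) and epsilon (kJ/mol)."""
    params = params or ParameterSet.default()
    counts = si_oxy_counts(typed)
    sigma, epsilon = [], []
    for i in range(typed.n_atoms):
        s, e = params.lj_for_site(typed.labels[i], counts.get(i))
        sigma.append(s)
        epsilon.append(e)
    return sigma, epsilon


# ---------------------------------------------------------------------------
# Exclusions and assembly
# ---------------------------------------------------------------------------


def build_exclusions(bonds: list[tuple[int, int]], n: int, depth: int = 3) -> set[tuple[int, int]]:
    """All unordered pairs separated by ``depth`` bonds or fewer."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(bonds)
    excl = set()
    lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=depth))
    for i, dists in lengths.items():
        for j, d in dists.items():
            if i < j and 1 <= d <= depth:
                excl.add((i, j))
    return excl


def build_topology(graph: MoleculeGraph, params: ParameterSet | None = None) -> UATopology:
    """Full pipeline from an (all-atom or united-atom) graph to a topology."""
    params = params or ParameterSet.default()
    ua = graph if graph.is_united_atom() else perceive_united_atoms(graph)
    typed = assign_atom_types(ua)
    charges = assign_charges(typed, params)
    bond_lengths, angles, torsions = assign_bonded_terms(typed, params)
    sigma, epsilon = assign_lj(typed, params)
    excl = build_exclusions(typed.bonds, typed.n_atoms)
    topo = UATopology(
        name=typed.name,
        labels=[typed.labels[i] for i in range(typed.n_atoms)],
        bonds=list(typed.bonds),
        charges=charges,
        sigma=sigma,
        epsilon=epsilon,
        bond_lengths=bond_lengths,
        angles=angles,
        torsions=torsions,
        exclusions=excl,
        si_oxy_counts=si_oxy_counts(typed),
        graph=typed,
    )
    rep = topo.validate()
    if not rep["neutral"]:
        raise ScopeError(
            f"{typed.name or 'molecule'}: no neutrality solution, net charge "
            f"{rep['net_charge']:+.3e} e"
        )
    return topo
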