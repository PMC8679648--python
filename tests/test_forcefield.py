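"""Topology generation: united-atom perception, typing, charges, bonded
terms, Lennard-Jones assignment, exclusions."""

import math

import numpy as np
import pytest

from polca import (
    MalformedMoleculeError,
    MoleculeGraph,
    ScopeError,
    MissingParameterError,
    build_molecule,
    build_topology,
    perceive_united_atoms,
)
from polca.forcefield import (
    assign_atom_types,
    assign_charges,
    assign_lj,
    build_exclusions,
    si_oxy_counts,
)
from polca.graph import build_alkane, build_silane


# ---------------------------------------------------------------------------
# United-atom perception
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "graph, expected_labels",
    [
        (build_alkane(2, "ethane"), ["CH3", "CH3"]),
        (
            build_molecule("trimethylsilanol"),
            ["Si", "O", "H_O", "CH3", "CH3", "CH3"],
        ),
        (
            build_molecule("tetraethoxysilane"),
            ["Si"] + ["O"] * 4 + ["CH2"] * 4 + ["CH3"] * 4,
        ),
    ],
)
def test_perceive_united_atoms_site_counts(graph, expected_labels):
    ua = perceive_united_atoms(graph)
    assert sorted(ua.labels.values()) == sorted(expected_labels)
    # heavy-atom connectivity preserved: same number of heavy-heavy bonds
    heavy_bonds_aa = sum(
        1 for a, b in graph.bonds if graph.elements[a] != "H" and graph.elements[b] != "H"
    )
    heavy_bonds_ua = sum(
        1 for a, b in ua.bonds if ua.elements[a] != "H" and ua.elements[b] != "H"
    )
    assert heavy_bonds_aa == heavy_bonds_ua


def test_hydrogen_on_silicon_rejected():
    g = MoleculeGraph(["Si", "H", "C", "H", "H", "H", "C", "H", "H", "H",
                       "C", "H", "H", "H"],
                      [(0, 1), (0, 2), (2, 3), (2, 4), (2, 5), (0, 6), (6, 7),
                       (6, 8), (6, 9), (0, 10), (10, 11), (10, 12), (10, 13)])
    with pytest.raises(ScopeError, match="SiH"):
        perceive_united_atoms(g)


def test_bridging_hydrogen_rejected():
    g = MoleculeGraph(["C", "H", "C", "H", "H", "H", "H", "H", "H"],
                      [(0, 1), (2, 1), (0, 3), (0, 4), (0, 5), (2, 6), (2, 7), (2, 8)])
    with pytest.raises(MalformedMoleculeError, match="bonded to 2"):
        perceive_united_atoms(g)


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------


def test_typing_examples():
    tmos = assign_atom_types(perceive_united_atoms(build_molecule("tetramethoxysilane")))
    counts = si_oxy_counts(tmos)
    assert list(counts.values()) == [4]

    hmdso = assign_atom_types(perceive_united_atoms(build_molecule("hexamethyldisiloxane")))
    assert sorted(si_oxy_counts(hmdso).values()) == [1, 1]
    assert sum(1 for l in hmdso.labels.values() if l == "O_B") == 1

    tes_ol = assign_atom_types(perceive_united_atoms(build_molecule("triethylsilanol")))
    labs = list(tes_ol.labels.values())
    assert si_oxy_counts(tes_ol) and list(si_oxy_counts(tes_ol).values()) == [1]
    assert labs.count("O_H") == 1 and labs.count("CH2") == 3 and labs.count("CH3") == 3


def test_typing_rejects_ether_oxygen():
    # dimethyl ether: O bonded to two carbons but no silicon
    g = MoleculeGraph(["O", "C", "H", "H", "H", "C", "H", "H", "H"],
                      [(0, 1), (1, 2), (1, 3), (1, 4), (0, 5), (5, 6), (5, 7), (5, 8)])
    with pytest.raises(ScopeError, match="oxygen"):
        assign_atom_types(perceive_united_atoms(g))


def test_typing_invariant_under_reindexing(params, rng):
    base = build_molecule("dimethyldimethoxysilane")
    topo = build_topology(base, params)
    ref = sorted(zip(topo.labels, np.round(topo.charges, 10), topo.sigma))
    perm = rng.permutation(base.n_atoms)
    inv = np.argsort(perm)
    g2 = MoleculeGraph(
        [base.elements[perm[i]] for i in range(base.n_atoms)],
        [(int(inv[a]), int(inv[b])) for a, b in base.bonds],
        name="permuted",
    )
    topo2 = build_topology(g2, params)
    assert sorted(zip(topo2.labels, np.round(topo2.charges, 10), topo2.sigma)) == ref


# ---------------------------------------------------------------------------
# Charges
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "name, q_si",
    [
        ("tetramethylsilane", 0.96),
        ("hexamethyldisiloxane", 1.40),
        ("tetraethoxysilane", 1.72),
        ("trimethylethoxysilane", 1.39),
    ],
)
def test_silicon_charge_closes_neutrality(topologies, name, q_si):
    topo = topologies(name)
    si_charges = [topo.charges[i] for i, l in enumerate(topo.labels) if l == "Si"]
    assert si_charges == pytest.approx([q_si] * len(si_charges), abs=1e-12)
    assert abs(topo.net_charge) <= 1e-12


def test_ethyl_on_oxygenated_silicon_charge_split(topologies):
    """An ethyl substituent next to Si in an oxygenated molecule: the
    Si-adjacent CH2 carries -0.27 and its terminal CH3 is neutral."""
    topo = topologies("triethylethoxysilane")
    g = topo.graph
    for i, lab in enumerate(topo.labels):
        if lab != "CH2":
            continue
        nbr_labels = {topo.labels[j] for j in g.neighbors(i)}
        if "Si" in nbr_labels:
            assert topo.charges[i] == pytest.approx(-0.27)
        elif "O_C" in nbr_labels:
            assert topo.charges[i] == pytest.approx(0.25)


# Reference point charges from continuum-solvent quantum calculations
# (DDEC partitioning) for the eleven parametrization compounds; one value
# per non-empty entry: (Si, CH3-Si, CH2-Si, CH3-CH2Si, O, H, CHx-O, CH3-CH2O).
DDEC_REFERENCE = {
    "tetramethylsilane": dict(si=0.960, ch3_si=-0.240),
    "tetraethylsilane": dict(si=0.975, ch2_si=-0.2875, ch3_ch2si=0.0438),
    "trimethylsilanol": dict(si=1.451, ch3_si=-0.329, o=-0.908, h=0.444),
    "triethylsilanol": dict(si=1.237, ch2_si=-0.333, ch3_ch2si=0.0605, o=-0.849, h=0.4295),
    "hexamethyldisiloxane": dict(si=1.458, ch3_si=-0.3335, o=-0.915),
    "tetramethoxysilane": dict(si=1.852, o=-0.719, chx_o=0.256),
    "tetraethoxysilane": dict(si=1.878, o=-0.758, chx_o=0.326, ch3_ch2o=-0.0375),
    "trimethylethoxysilane": dict(si=1.390, ch3_si=-0.320, o=-0.678, chx_o=0.294,
                                  ch3_ch2o=-0.046),
    "dimethylethylethoxysilane": dict(si=1.329, ch3_si=-0.319, ch2_si=-0.332,
                                      ch3_ch2si=0.0583, o=-0.664, chx_o=0.2915,
                                      ch3_ch2o=-0.0448),
    "methyldiethylethoxysilane": dict(si=1.258, ch3_si=-0.309, ch2_si=-0.3282,
                                      ch3_ch2si=0.0519, o=-0.645, chx_o=0.289,
                                      ch3_ch2o=-0.0404),
    "triethylethoxysilane": dict(si=1.194, ch2_si=-0.322, ch3_ch2si=0.0554,
                                 o=-0.638, chx_o=0.287, ch3_ch2o=-0.0432),
}


def model_charge_entries(topo):
    """Force-field charges grouped by the reference-table columns."""
    g = topo.graph
    out = {}
    for i, lab in enumerate(topo.labels):
        nbrs = {topo.labels[j] for j in g.neighbors(i)}
        q = topo.charges[i]
        if lab == "Si":
            out["si"] = q
        elif lab in ("O_C", "O_H", "O_B"):
            out["o"] = q
        elif lab == "H_O":
            out["h"] = q
        elif lab == "CH3" and "Si" in nbrs:
            out["ch3_si"] = q
        elif lab == "CH2" and "Si" in nbrs:
            out["ch2_si"] = q
        elif "O_C" in nbrs:
            out["chx_o"] = q
        elif lab == "CH3" and "CH2" in nbrs:
            # terminal methyl: behind a CH2 that is bonded to Si or to O_C
            parent = next(j for j in g.neighbors(i) if topo.labels[j] == "CH2")
            parent_nbrs = {topo.labels[j] for j in g.neighbors(parent)}
            out["ch3_ch2si" if "Si" in parent_nbrs else "ch3_ch2o"] = q
    return out


def charge_rmsd(topologies):
    devs = []
    for name, ref in DDEC_REFERENCE.items():
        entries = model_charge_entries(topologies(name))
        for key, ref_q in ref.items():
            devs.append(entries[key] - ref_q)
    return math.sqrt(np.mean(np.square(devs))), len(devs)


def test_charge_rmsd_against_quantum_reference(topologies):
    rmsd, n = charge_rmsd(topologies)
    assert n == 49
    assert rmsd <= 0.05


# ---------------------------------------------------------------------------
# Bonded terms
# ---------------------------------------------------------------------------


def test_bonded_term_examples(params, topologies):
    assert params.bond_length(("Si", "C")) == 0.1875
    assert params.angle_params(("Si", "O_B", "Si")) == (149.5, 61.3)

    topo = topologies("tetraethylsilane")
    assert topo.n_sites == 9
    assert len(topo.bonds) == 8
    assert len(topo.angles) == 10
    classes = [tuple(sorted((topo.labels[i], topo.labels[k]))) + (topo.labels[j],)
               for (i, j, k), _, _ in topo.angles]
    assert sum(1 for c in classes if c[2] == "Si") == 6  # C-Si-C
    assert len(topo.torsions) == 12
    assert all(topo.torsion_class(q) in [("C", "C", "Si", "C"), ("C", "Si", "C", "C")]
               for q, _ in topo.torsions)


def test_missing_bonded_parameter_names_the_tuple(params):
    with pytest.raises(MissingParameterError, match="C-C-C-C"):
        params.torsion_coeffs(("C", "C", "C", "C"))


# ---------------------------------------------------------------------------
# Lennard-Jones
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "name, sigma_si",
    [
        ("tetramethylsilane", 0.580),
        ("trimethylsilanol", 0.551),
        ("dimethyldimethoxysilane", 0.522),
        ("tetramethoxysilane", 0.464),
    ],
)
def test_silicon_sigma_by_oxy_count(topologies, name, sigma_si):
    topo = topologies(name)
    i = topo.labels.index("Si")
    assert topo.sigma[i] == sigma_si
    assert topo.epsilon[i] == 0.108


def test_sigma_scaling_law_reproduces_table(params):
    for k, sigma in enumerate([0.580, 0.551, 0.522, 0.493, 0.464]):
        assert round(params.scaled_si_sigma(k), 3) == sigma


def test_hydroxyl_hydrogen_has_no_lj(topologies):
    topo = topologies("trimethylsilanol")
    i = topo.labels.index("H_O")
    assert topo.sigma[i] == 0.0 and topo.epsilon[i] == 0.0


def test_missing_alkane_constants_hard_error(params):
    import dataclasses

    bare = dataclasses.replace(params, alkane_lj={})
    typed = assign_atom_types(perceive_united_atoms(build_molecule("tetramethylsilane")))
    with pytest.raises(MissingParameterError, match="alkane"):
        assign_lj(typed, bare)


# ---------------------------------------------------------------------------
# Exclusions and full topology
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n", [4, 5, 6, 8])
def test_exclusion_count_on_path_graph(n):
    bonds = [(i, i + 1) for i in range(n - 1)]
    excl = build_exclusions(bonds, n)
    assert len(excl) == (n - 1) + (n - 2) + (n - 3)
    assert (0, 3) in excl  # 1-4 pairs are excluded
    if n > 4:
        assert (0, 4) not in excl


def test_tetramethylsilane_topology(topologies):
    topo = topologies("tetramethylsilane")
    assert topo.n_sites == 5
    assert abs(topo.net_charge) <= 1e-12
    assert len(topo.torsions) == 0
    # every pair is within 3 bonds: fully excluded
    assert len(topo.exclusions) == 10


def test_methoxy_terminal_carbons_are_1_5_pair(topologies):
    topo = topologies("dimethyldimethoxysilane")
    g = topo.graph
    methoxy_c = [i for i, lab in enumerate(topo.labels)
                 if lab == "CH3" and "O_C" in {topo.labels[j] for j in g.neighbors(i)}]
    assert len(methoxy_c) == 2
    pair = tuple(sorted(methoxy_c))
    assert pair not in topo.exclusions


def test_every_site_fully_assigned(topologies):
    for name in ["tetramethylsilane", "triethylsilanol", "tetraethoxysilane",
                 "hexamethyldisiloxane", "dimethylethylethoxysilane"]:
        topo = topologies(name)
        assert len(topo.charges) == len(topo.sigma) == len(topo.epsilon) == topo.n_sites
        assert abs(topo.net_charge) <= 1e-12
        rep = topo.validate()
        assert rep["neutral"] and rep["complete"]


def test_silane_requires_four_substituents():
    with pytest.raises(ScopeError):
        build_silane("bad", methyl=3)
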