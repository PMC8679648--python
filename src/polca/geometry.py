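"""Cartesian geometry utilities: internal-coordinate embedding, measures,
and rigid rotation about a bond.

The embedder builds a deterministic 3D conformation of a united-atom
topology from its constraint lengths and equilibrium angles using the
natural-extension-reference-frame (NeRF) construction, with staggered
default dihedrals.  It serves single-molecule torsion scans and file
export; it is not an energy minimizer.
"""

from __future__ import annotations

import math

import numpy as np
import networkx as nx

_DEF_ANGLE = 109.471  # tetrahedral default, deg


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Position a new atom D given chain A-B-C, bond r = |CD|,
    angle theta = B-C-D and dihedral phi = A-B-C-D."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:  # collinear reference; pick any perpendicular
        probe = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        n = np.cross(probe, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(phi),
            r * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_distance(x: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(x[i] - x[j]))


def measure_angle(x: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in degrees."""
    u = x[i] - x[j]
    v = x[k] - x[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


def measure_dihedral(x: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral i-j-k-l in degrees, IUPAC convention, range (-180, 180]."""
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
    return ang


def rotate_about_bond(x: np.ndarray, bonds, j: int, k: int, delta_deg: float) -> np.ndarray:
    """Rotate all atoms on the k-side of bond j-k by delta about the bond axis."""
    g = nx.Graph()
    g.add_nodes_from(range(len(x)))
    g.add_edges_from(bonds)
    g.remove_edge(j, k)
    side = nx.node_connected_component(g, k) - {k}
    axis = x[k] - x[j]
    axis = axis / np.linalg.norm(axis)
    # rotating the k-side by +delta about the j->k axis must increase the
    # measured i-j-k-l dihedral by +delta
    t = -math.radians(delta_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    Rm = np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)
    out = x.copy()
    for a in side:
        out[a] = x[k] + Rm @ (x[a] - x[k])
    return out


def embed_topology(topology, seed: int | None = None) -> np.ndarray:
    """Deterministic 3D coordinates (nm) for a united-atom topology.

    Bond lengths come from the constraint table, angles from the harmonic
    equilibrium values (tetrahedral default when a triple has no entry),
    dihedrals staggered at 180/60/-60 degrees by sibling order.
    """
    n = topology.n_sites
    bonds = topology.bonds
    blen = {tuple(sorted(b)): l for b, l in zip(bonds, topology.bond_lengths)}
    ang = {}
    for (i, j, k), th0, _ in topology.angles:
        ang[(i, j, k)] = th0
        ang[(k, j, i)] = th0

    adj = {i: [] for i in range(n)}
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)

    x = np.zeros((n, 3))
    placed: list[int] = []
    parent: dict[int, int] = {}

    order = list(nx.bfs_tree(nx.Graph(bonds), 0).nodes()) if n > 1 else [0]
    for idx, atom in enumerate(order):
        if idx == 0:
            x[atom] = 0.0
        elif idx == 1:
            p = next(a for a in adj[atom] if a in placed)
            parent[atom] = p
            x[atom] = x[p] + np.array([blen[tuple(sorted((p, atom)))], 0.0, 0.0])
        else:
            p = next(a for a in adj[atom] if a in placed)
            parent[atom] = p
            gp = parent.get(p)
            if gp is None:
                gp = next(a for a in adj[p] if a in placed and a != atom)
            ggp = parent.get(gp)
            if ggp is None or ggp == p:
                cand = [a for a in adj[gp] if a in placed and a not in (p, atom)]
                ggp = cand[0] if cand else None
            r = blen[tuple(sorted((p, atom)))]
            theta = ang.get((gp, p, atom), _DEF_ANGLE)
            siblings = [a for a in adj[p] if a in placed and a not in (gp, atom)]
            phi = [180.0, 60.0, -60.0, 120.0][len(siblings) % 4]
            if ggp is None:
                # only two reference atoms exist; fabricate an off-axis anchor
                anchor = x[gp] + np.array([0.0, 1.0, 0.0])
                x[atom] = place_atom(anchor, x[gp], x[p], r, theta, phi)
            else:
                x[atom] = place_atom(x[ggp], x[gp], x[p], r, theta, phi)
        placed.append(atom)
    return x
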