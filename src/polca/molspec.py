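"""Structured-text molecule specifications (YAML): name, atoms, bonds,
optional coordinates.  Round-trips losslessly through write/read."""

from __future__ import annotations

from pathlib import Path

import yaml

from .graph import MoleculeGraph, SUPPORTED_ELEMENTS


def read_molecule_spec(path_or_text) -> MoleculeGraph:
    """Read a molecule spec from a YAML file path or a YAML string."""
    p = Path(str(path_or_text))
    try:
        is_file = p.is_file()
    except OSError:
        is_file = False
    text = p.read_text() if is_file else str(path_or_text)
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "atoms" not in doc or "bonds" not in doc:
        raise ValueError("molecule spec must contain 'atoms' and 'bonds'")
    elements = [str(a) for a in doc["atoms"]]
    for el in elements:
        if el not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unknown element {el!r} in molecule spec")
    bonds = []
    n = len(elements)
    for pair in doc["bonds"]:
        i, j = int(pair[0]), int(pair[1])
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"dangling bond index in pair ({i}, {j})")
        bonds.append((i, j))
    coords = None
    if "coordinates" in doc and doc["coordinates"] is not None:
        coords = {k: tuple(float(v) for v in xyz)
                  for k, xyz in enumerate(doc["coordinates"])}
    return MoleculeGraph(elements, bonds, coords, name=str(doc.get("name", "")))


def write_molecule_spec(graph: MoleculeGraph, path=None) -> str:
    doc = {
        "name": graph.name,
        "atoms": list(graph.elements),
        "bonds": [[int(i), int(j)] for i, j in graph.bonds],
    }
    if graph.coordinates:
        doc["coordinates"] = [
            [float(c) for c in graph.coordinates[i]] for i in range(graph.n_atoms)
        ]
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
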