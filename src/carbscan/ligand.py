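"""Ligand chemistry templates, centered on compound 1:
1-methylenesulfamide-1,2-dicarba-closo-dodecaborane.

The molecule is a 12-vertex closo-carborane icosahedron (two adjacent CH
vertices C1/C2, ten BH vertices B3-B12) carrying a methylene-linked
sulfamide: C1-CH2(C3)-NH(N1)-SO2(S,O1,O2)-NH2(N2). The terminal sulfamide
nitrogen N2 is the zinc-binding anchor. Each cage vertex bears one exo
hydrogen; B-H hydrogens are hydridic (partner of dihydrogen bonds).

Ideal cage geometry is generated from the golden-ratio icosahedron scaled
to a typical cage edge of 1.78 A, so fixtures and hydrogen placement have
a physically sensible reference conformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyError

__all__ = ["LigandTemplate", "load_ligand_template", "COMPOUND1"]

_PHI = (1.0 + math.sqrt(5.0)) / 2.0
_CAGE_EDGE = 1.78  # A, typical B-B bond length in icosahedral carboranes


def _icosahedron_vertices() -> np.ndarray:
    """12 vertices of a unit-edge-2 icosahedron (cyclic (0, +-1, +-phi))."""
    v = []
    for a, b in [(1, _PHI), (1, -_PHI), (-1, _PHI), (-1, -_PHI)]:
        v.append((0.0, a, b))
        v.append((a, b, 0.0))
        v.append((b, 0.0, a))
    return np.array(v)


def _cage_geometry() -> tuple[np.ndarray, list[tuple[int, int]]]:
    verts = _icosahedron_vertices() * (_CAGE_EDGE / 2.0)
    n = len(verts)
    d = np.linalg.norm(verts[:, None, :] - verts[None, :, :], axis=-1)
    edge = d[d > 1e-9].min()
    bonds = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if abs(d[i, j] - edge) < 0.2
    ]
    return verts, bonds


@dataclass(frozen=True)
class LigandTemplate:
    """Topology + parameters of a rigid polyatomic ligand.

    ``atom_names`` are the canonical labels; ``aliases`` maps deposited
    (file) names onto canonical ones (a bijection on the heavy atoms).
    """

    name: str
    atom_names: tuple[str, ...]
    elements: dict[str, str]
    bonds: tuple[tuple[str, str], ...]
    charges: dict[str, float]
    vdw_types: dict[str, str]
    ideal_coordinates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    aliases: dict[str, str] = field(default_factory=dict)
    hydrogen_parents: dict[str, str] = field(default_factory=dict)

    @property
    def heavy_atom_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.atom_names if self.elements[n] != "H")

    @property
    def cage_atom_names(self) -> tuple[str, ...]:
        return tuple(
            n for n in self.atom_names if self.elements[n] in ("B", "C") and _is_cage(n)
        )

    def cage_neighbors(self, atom: str) -> list[str]:
        out = []
        for a, b in self.bonds:
            if a == atom and _is_cage(b):
                out.append(b)
            elif b == atom and _is_cage(a):
                out.append(a)
        return out

    def canonical_name(self, deposited: str) -> str:
        return self.aliases.get(deposited, deposited)

    def formal_charge(self) -> float:
        return sum(self.charges.values())

    def validate(self) -> None:
        cage = [n for n in self.heavy_atom_names if _is_cage(n)]
        if len(cage) != 12:
            raise TopologyError(f"cage has {len(cage)} vertices, expected 12")
        for v in cage:
            nb = self.cage_neighbors(v)
            if len(nb) != 5:
                raise TopologyError(
                    f"cage vertex {v} has {len(nb)} cage neighbors, expected 5"
                )
        n_carbon = sum(1 for v in cage if self.elements[v] == "C")
        if n_carbon != 2:
            raise TopologyError(f"cage has {n_carbon} carbon vertices, expected 2")
        if abs(self.formal_charge()) > 1e-9:
            raise TopologyError(
                f"template charges sum to {self.formal_charge():.4f}, expected 0"
            )


_CAGE_LABELS = frozenset(
    {"C1", "C2"} | {f"B{i}" for i in range(3, 13)}
)


def _is_cage(name: str) -> bool:
    return name in _CAGE_LABELS


def _build_compound1() -> LigandTemplate:
    verts, edge_idx = _cage_geometry()

    # Label assignment: C1 is vertex 0; its five neighbors are C2 and B3-B6
    # (the vertices bonded to C1); the remaining six are B7-B12, with B12
    # antipodal to C1 (the vertex used for displacement metrics).
    adj = {i: set() for i in range(12)}
    for i, j in edge_idx:
        adj[i].add(j)
        adj[j].add(i)
    c1 = 0
    nbrs = sorted(adj[c1])
    antipode = max(range(12), key=lambda i: np.linalg.norm(verts[i] - verts[c1]))
    c2 = nbrs[0]
    labels: dict[int, str] = {c1: "C1", c2: "C2", antipode: "B12"}
    b = 3
    for i in nbrs[1:]:
        labels[i] = f"B{b}"
        b += 1
    for i in range(12):
        if i not in labels:
            labels[i] = f"B{b}"
            b += 1

    coords: dict[str, np.ndarray] = {labels[i]: verts[i] for i in range(12)}
    bonds: list[tuple[str, str]] = [
        tuple(sorted((labels[i], labels[j]))) for i, j in edge_idx
    ]

    # Substituent chain off C1: methylene C3, sulfamide N1-S(=O1)(=O2)-N2.
    centroid = verts.mean(axis=0)
    u = coords["C1"] - centroid
    u = u / np.linalg.norm(u)
    # pick a perpendicular for chain zig-zag
    p = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(p) < 1e-6:
        p = np.cross(u, [0.0, 1.0, 0.0])
    p = p / np.linalg.norm(p)

    def step(origin: np.ndarray, direction: np.ndarray, length: float) -> np.ndarray:
        return origin + direction / np.linalg.norm(direction) * length

    coords["C3"] = step(coords["C1"], u, 1.52)
    coords["N1"] = step(coords["C3"], u * 0.5 + p * 0.85, 1.47)
    coords["S"] = step(coords["N1"], u * 0.6 - p * 0.75, 1.62)
    q = np.cross(u, p)
    coords["O1"] = step(coords["S"], q * 0.9 + u * 0.2, 1.43)
    coords["O2"] = step(coords["S"], -q * 0.9 + u * 0.2, 1.43)
    coords["N2"] = step(coords["S"], u * 0.45 + p * 0.85, 1.60)

    bonds += [
        ("C1", "C3"),
        ("C3", "N1"),
        ("N1", "S"),
        ("O1", "S"),
        ("O2", "S"),
        ("N2", "S"),
    ]

    heavy = (
        "C1", "C2", "B3", "B4", "B5", "B6", "B7", "B8", "B9", "B10", "B11",
        "B12", "C3", "N1", "S", "O1", "O2", "N2",
    )
    elements = {n: ("B" if n.startswith("B") else n[0]) for n in heavy}
    elements["S"] = "S"

    # Hydrogens: one exo H per cage vertex except C1 (substituted), two on
    # the methylene, one on N1, two on the terminal sulfamide N2.
    hydrogens = (
        ["H2"]
        + [f"H{i}" for i in range(3, 13)]
        + ["H31", "H32", "HN1", "HN21", "HN22"]
    )
    h_parent = {"H2": "C2", "H31": "C3", "H32": "C3", "HN1": "N1",
                "HN21": "N2", "HN22": "N2"}
    for i in range(3, 13):
        h_parent[f"H{i}"] = f"B{i}"

    # Partial charges: group-based, hydridic B-H (H negative), protic N-H
    # (H positive), summing exactly to the formal charge 0. See
    # data/forcefield.yaml for the parameter conventions.
    charges: dict[str, float] = {
        "C1": -0.18, "C2": -0.12, "H2": 0.14,
        "C3": 0.08, "H31": 0.06, "H32": 0.06,
        "N1": -0.62, "HN1": 0.34,
        "S": 1.30, "O1": -0.58, "O2": -0.58,
        "N2": -0.88, "HN21": 0.39, "HN22": 0.39,
    }
    for i in range(3, 13):
        charges[f"B{i}"] = 0.10
        charges[f"H{i}"] = -0.08

    vdw_types: dict[str, str] = {}
    for n in heavy:
        e = elements[n]
        vdw_types[n] = {"B": "B", "C": "C", "N": "N", "O": "O", "S": "S"}[e]
    for h in hydrogens:
        parent = h_parent[h]
        if parent.startswith("B"):
            vdw_types[h] = "HB"  # hydridic
        elif elements[parent] == "N":
            vdw_types[h] = "HP"  # protic
        else:
            vdw_types[h] = "H"

    all_elements = dict(elements)
    for h in hydrogens:
        all_elements[h] = "H"

    tmpl = LigandTemplate(
        name="compound1",
        atom_names=tuple(list(heavy) + hydrogens),
        elements=all_elements,
        bonds=tuple(sorted(set(bonds))),
        charges=charges,
        vdw_types=vdw_types,
        ideal_coordinates=coords,
        # Deposited atom names for this chemistry match the canonical
        # labels; the table exists so alternative naming schemes can be
        # registered without touching code paths.
        aliases={n: n for n in heavy},
        hydrogen_parents=h_parent,
    )
    tmpl.validate()
    return tmpl


COMPOUND1 = _build_compound1()

_REGISTRY = {"compound1": COMPOUND1}


def load_ligand_template(name: str) -> LigandTemplate:
    """Look up a bundled ligand template by identifier.

    ``"compound1"`` is the methylenesulfamide carborane inhibitor.
    """
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise TopologyError(
            f"unknown ligand template {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
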