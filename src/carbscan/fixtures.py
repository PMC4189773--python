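"""Synthetic test systems with known ground truth.

Generates small "active sites": 5-20 residues built from ideal internal
geometry (z-matrix construction), arranged around a rigid ligand (the
carborane-sulfamide compound-1 template or a unit point charge), with an
optional zinc ion. Every fixture is written to a PDB file and re-read
through the public I/O path, so the parser and writer are exercised on
every use, and comes with exhaustively computed ground truth: all
environment-ligand heavy-atom distances, expected contact sets at any
cutoff, expected polar classes, and closed-form per-residue Coulomb
energies for the point-charge probe.

Everything is deterministic under the seed.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import FixtureSpecError
from .io import read_structure, write_structure
from .ligand import COMPOUND1, LigandTemplate
from .model import Atom, Residue, Structure

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "make_toy_complex",
    "make_homolog_pair",
    "make_minimization_fixture",
    "build_residue",
    "PROBE_TEMPLATE",
]

#: Single positive unit point charge used for closed-form energy oracles.
#: Its LJ type has epsilon = 0, so its interaction is pure Coulomb.
PROBE_TEMPLATE = LigandTemplate(
    name="point_probe",
    atom_names=("PX",),
    elements={"PX": "N"},
    bonds=(),
    charges={"PX": 1.0},
    vdw_types={"PX": "HW"},
)


# ---------------------------------------------------------------------------
# Ideal-geometry residue construction (z-matrix)


def _extend(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """NeRF placement: new atom bonded to ``c`` with angle at c to b and
    dihedral about the b-c axis relative to a."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        ref = np.array([0.0, 0.0, 1.0]) if abs(bc[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        n = np.cross(ref, bc)
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d = np.array(
        [-bond * math.cos(theta),
         bond * math.sin(theta) * math.cos(phi),
         bond * math.sin(theta) * math.sin(phi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


# (atom, ref_a, ref_b, ref_c, bond, angle, dihedral); refs are prior atoms.
_SIDECHAIN_ZMAT: dict[str, tuple[tuple[str, str, str, str, float, float, float], ...]] = {
    "GLY": (),
    "ALA": (),
    "SER": (("OG", "N", "CA", "CB", 1.42, 110.5, 180.0),),
    "CYS": (("SG", "N", "CA", "CB", 1.81, 114.0, 180.0),),
    "THR": (("OG1", "N", "CA", "CB", 1.43, 109.5, 180.0),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, 60.0)),
    "VAL": (("CG1", "N", "CA", "CB", 1.52, 110.5, 180.0),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, 60.0)),
    "LEU": (("CG", "N", "CA", "CB", 1.53, 116.0, 180.0),
            ("CD1", "CA", "CB", "CG", 1.52, 110.5, 180.0),
            ("CD2", "CA", "CB", "CG", 1.52, 110.5, 60.0)),
    "ILE": (("CG1", "N", "CA", "CB", 1.53, 110.5, 180.0),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, 60.0),
            ("CD1", "CA", "CB", "CG1", 1.52, 113.0, 180.0)),
    "MET": (("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
            ("SD", "CA", "CB", "CG", 1.80, 112.7, 180.0),
            ("CE", "CB", "CG", "SD", 1.79, 100.9, 180.0)),
    "ASN": (("CG", "N", "CA", "CB", 1.52, 112.6, 180.0),
            ("OD1", "CA", "CB", "CG", 1.23, 120.8, 0.0),
            ("ND2", "CA", "CB", "CG", 1.33, 116.4, 180.0)),
    "ASP": (("CG", "N", "CA", "CB", 1.52, 112.6, 180.0),
            ("OD1", "CA", "CB", "CG", 1.25, 118.4, 0.0),
            ("OD2", "CA", "CB", "CG", 1.25, 118.4, 180.0)),
    "GLN": (("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 112.6, 180.0),
            ("OE1", "CB", "CG", "CD", 1.23, 120.8, 0.0),
            ("NE2", "CB", "CG", "CD", 1.33, 116.4, 180.0)),
    "GLU": (("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 112.6, 180.0),
            ("OE1", "CB", "CG", "CD", 1.25, 118.4, 0.0),
            ("OE2", "CB", "CG", "CD", 1.25, 118.4, 180.0)),
    "LYS": (("CG", "N", "CA", "CB", 1.52, 111.0, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 111.0, 180.0),
            ("CE", "CB", "CG", "CD", 1.52, 111.0, 180.0),
            ("NZ", "CG", "CD", "CE", 1.49, 111.0, 180.0)),
    "ARG": (("CG", "N", "CA", "CB", 1.52, 111.0, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 111.0, 180.0),
            ("NE", "CB", "CG", "CD", 1.46, 111.5, 180.0),
            ("CZ", "CG", "CD", "NE", 1.33, 124.0, 180.0),
            ("NH1", "CD", "NE", "CZ", 1.33, 120.0, 0.0),
            ("NH2", "CD", "NE", "CZ", 1.33, 120.0, 180.0)),
    "HIS": (("CG", "N", "CA", "CB", 1.50, 113.8, 180.0),
            ("ND1", "CA", "CB", "CG", 1.38, 122.7, 90.0),
            ("CD2", "CA", "CB", "CG", 1.36, 129.7, 270.0),
            ("CE1", "CB", "CG", "ND1", 1.32, 105.6, 180.0),
            ("NE2", "CB", "CG", "CD2", 1.37, 107.2, 180.0)),
    "PHE": (("CG", "N", "CA", "CB", 1.50, 113.8, 180.0),
            ("CD1", "CA", "CB", "CG", 1.39, 120.8, 90.0),
            ("CD2", "CA", "CB", "CG", 1.39, 120.8, 270.0),
            ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0)),
    "TYR": (("CG", "N", "CA", "CB", 1.50, 113.8, 180.0),
            ("CD1", "CA", "CB", "CG", 1.39, 120.8, 90.0),
            ("CD2", "CA", "CB", "CG", 1.39, 120.8, 270.0),
            ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
            ("OH", "CD1", "CE1", "CZ", 1.38, 120.0, 180.0)),
    "TRP": (("CG", "N", "CA", "CB", 1.50, 113.8, 180.0),
            ("CD1", "CA", "CB", "CG", 1.37, 127.0, 90.0),
            ("CD2", "CA", "CB", "CG", 1.43, 126.6, 270.0),
            ("NE1", "CB", "CG", "CD1", 1.38, 110.1, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.41, 107.2, 180.0),
            ("CE3", "CD1", "CG", "CD2", 1.40, 133.9, 180.0),
            ("CZ2", "CG", "CD2", "CE2", 1.40, 122.4, 180.0),
            ("CZ3", "CG", "CD2", "CE3", 1.39, 118.6, 180.0),
            ("CH2", "CD2", "CE2", "CZ2", 1.37, 117.5, 0.0)),
    "PRO": (("CG", "N", "CA", "CB", 1.49, 104.0, 30.0),
            ("CD", "CA", "CB", "CG", 1.50, 105.0, 325.0)),
}


def build_residue(
    name: str, chain_id: str = "A", number: int = 1
) -> Residue:
    """One amino acid with ideal internal geometry, CA at the origin.

    The side chain extends roughly along +y (the CB direction), so the
    residue can be aimed at a ligand by rotating +y onto the desired
    approach vector.
    """
    if name not in _SIDECHAIN_ZMAT:
        raise FixtureSpecError(f"no fixture geometry for residue {name!r}")
    coords: dict[str, np.ndarray] = {}
    coords["CA"] = np.zeros(3)
    coords["N"] = np.array([-1.458, 0.0, 0.0])
    t = math.radians(111.0)
    coords["C"] = 1.525 * np.array([-math.cos(t), math.sin(t), 0.0])
    coords["O"] = _extend(coords["N"], coords["CA"], coords["C"], 1.231, 120.5, 0.0)
    if name != "GLY":
        coords["CB"] = _extend(coords["C"], coords["N"], coords["CA"], 1.53, 110.5, 237.5)
    for atom, ra, rb, rc, bond, ang, dih in _SIDECHAIN_ZMAT[name]:
        coords[atom] = _extend(coords[ra], coords[rb], coords[rc], bond, ang, dih)

    # rotate so the CA->CB (or CA->C for GLY) direction is +y
    ref = coords.get("CB", coords["C"]) - coords["CA"]
    ref = ref / np.linalg.norm(ref)
    target = np.array([0.0, 1.0, 0.0])
    v = np.cross(ref, target)
    s, c = np.linalg.norm(v), float(np.dot(ref, target))
    if s > 1e-10:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    else:
        R = np.eye(3) if c > 0 else -np.eye(3)
    atoms = []
    for an, p in coords.items():
        el = "S" if an.startswith("S") else an[0]
        atoms.append(Atom(name=an, element=el, position=R @ p))
    return Residue(chain_id=chain_id, number=number, name=name, atoms=atoms)


# ---------------------------------------------------------------------------
# Toy complexes


@dataclass
class FixtureSpec:
    """Recipe for a deterministic toy active site.

    ``residue_names`` is cycled to fill ``n_residues``. ``approach_gaps``
    sets each residue's nearest heavy-atom distance to the ligand
    (default drawn uniformly in [3.3, 4.6] A, straddling the 4 A contact
    cutoff). Engineered features: ``exact_contacts``
    pins a named residue atom at an exact distance from a ligand atom;
    ``sole_contact_residue`` moves every other residue 50+ A away;
    ``clash_distance`` pulls residue 0 in until its nearest ligand
    approach equals the given value; ``substitutions`` is used by
    :func:`make_homolog_pair`.
    """

    seed: int = 0
    n_residues: int = 8
    residue_names: tuple[str, ...] = (
        "SER", "THR", "LEU", "ASN", "VAL", "GLN", "TRP", "HIS",
    )
    ligand: str = "compound1"  # compound1 | point_probe
    approach_gaps: Optional[tuple[float, ...]] = None
    metal: bool = False
    metal_offset: float = 2.0
    exact_contacts: tuple[tuple[int, str, str, float], ...] = ()
    sole_contact_residue: Optional[int] = None
    clash_distance: Optional[float] = None
    substitutions: tuple[tuple[int, str], ...] = ()
    chain_id: str = "A"


@dataclass
class GroundTruth:
    """Exhaustive reference data computed independently of the analysis code.

    ``distances`` maps ((chain, resnum, icode, protein_atom), ligand_atom)
    to the heavy-atom distance, computed by a plain double loop over the
    re-read coordinates.
    """

    distances: dict[tuple[tuple, str], float] = field(default_factory=dict)
    residue_names: dict[tuple, str] = field(default_factory=dict)
    elements: dict[tuple[tuple, str], str] = field(default_factory=dict)
    ligand_elements: dict[str, str] = field(default_factory=dict)
    probe_energies: dict[tuple, float] = field(default_factory=dict)

    def contacts(self, cutoff: float = 4.0) -> set[tuple[tuple, str, str]]:
        return {
            (rk, pa, la)
            for ((rk, pa), la), d in self.distances.items()
            if d <= cutoff + 1e-9
        }

    def polar_contacts(
        self, cutoff: float = 4.0, polar_cutoff: float = 3.1, metal_cutoff: float = 2.5
    ) -> set[tuple[tuple, str, str]]:
        polar = {"N", "O", "S"}
        out = set()
        for ((rk, pa), la), d in self.distances.items():
            if d > cutoff + 1e-9:
                continue
            if self.residue_names[rk] == "ZN":
                if d <= metal_cutoff + 1e-9:
                    out.add((rk, pa, la))
            elif (
                self.elements[(rk, pa)] in polar
                and self.ligand_elements[la] in polar
                and d <= polar_cutoff + 1e-9
            ):
                out.add((rk, pa, la))
        return out


def _ligand_residue(spec: FixtureSpec) -> Residue:
    if spec.ligand == "compound1":
        atoms = [
            Atom(name=n, element=COMPOUND1.elements[n],
                 position=COMPOUND1.ideal_coordinates[n].copy())
            for n in COMPOUND1.heavy_atom_names
        ]
        return Residue(chain_id="L", number=900, name="LIG", atoms=atoms)
    if spec.ligand == "point_probe":
        return Residue(
            chain_id="L", number=900, name="PRB",
            atoms=[Atom(name="PX", element="N", position=np.zeros(3))],
        )
    raise FixtureSpecError(f"unknown ligand kind {spec.ligand!r}")


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (deterministic spherical lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_toy_complex(
    spec: FixtureSpec, out_dir: Optional[str] = None
) -> tuple[Structure, GroundTruth]:
    """Build, serialize, re-read, and measure a toy complex.

    The returned structure has passed through PDB write + read (so all
    coordinates carry 3-decimal precision); the ground truth is computed
    from the re-read coordinates by plain double loops.
    """
    rng = np.random.default_rng(spec.seed)
    if not (1 <= spec.n_residues <= 50):
        raise FixtureSpecError("n_residues must be in [1, 50]")
    lig = _ligand_residue(spec)
    lig_center = np.mean([a.position for a in lig.atoms], axis=0)

    names = [spec.residue_names[i % len(spec.residue_names)]
             for i in range(spec.n_residues)]
    for idx, newname in spec.substitutions:
        if not (0 <= idx < spec.n_residues):
            raise FixtureSpecError(f"substitution at missing residue index {idx}")
        names[idx] = newname

    dirs = _fibonacci_directions(max(spec.n_residues, 2))
    if spec.approach_gaps is not None:
        gaps = list(spec.approach_gaps)
        if len(gaps) != spec.n_residues:
            raise FixtureSpecError("approach_gaps length != n_residues")
    else:
        gaps = list(rng.uniform(3.3, 4.6, size=spec.n_residues))

    lig_xyz = np.array([a.position for a in lig.atoms])
    residues: list[Residue] = []
    for i, nm in enumerate(names):
        res = build_residue(nm, chain_id=spec.chain_id, number=i + 1)
        u = dirs[i]
        # aim the side chain (+y in local frame) back toward the ligand
        y = np.array([0.0, 1.0, 0.0])
        v = np.cross(y, -u)
        s, c = np.linalg.norm(v), float(np.dot(y, -u))
        if s > 1e-10:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        else:
            R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        shift = lig_center + u * 12.0
        for a in res.atoms:
            a.position = R @ a.position + shift
        # slide along the approach axis until the nearest heavy-atom
        # separation from the ligand equals the requested gap
        for _ in range(4):
            cur = min(
                float(np.min(np.linalg.norm(lig_xyz - a.position, axis=1)))
                for a in res.atoms
            )
            if abs(cur - gaps[i]) < 1e-6:
                break
            for a in res.atoms:
                a.position = a.position - u * (cur - gaps[i])
        residues.append(res)

    if spec.sole_contact_residue is not None:
        j = spec.sole_contact_residue
        if not (0 <= j < len(residues)):
            raise FixtureSpecError("sole_contact_residue out of range")
        for i, res in enumerate(residues):
            if i == j:
                continue
            u = dirs[i]
            for a in res.atoms:
                a.position = a.position + u * 200.0

    if spec.clash_distance is not None:
        res = residues[0]
        lig_xyz = np.array([a.position for a in lig.atoms])
        cur = min(
            float(np.min(np.linalg.norm(lig_xyz - a.position, axis=1)))
            for a in res.atoms
        )
        u = dirs[0]
        for a in res.atoms:
            a.position = a.position - u * (cur - spec.clash_distance)

    for idx, atom_name, lig_atom_name, dist in spec.exact_contacts:
        res = residues[idx]
        at = res.atom(atom_name)
        la = lig.atom(lig_atom_name)
        if at is None or la is None:
            raise FixtureSpecError(
                f"exact contact references missing atom {atom_name}/{lig_atom_name}"
            )
        direction = at.position - la.position
        n = np.linalg.norm(direction)
        direction = direction / n if n > 1e-9 else dirs[idx]
        target = la.position + direction * dist
        delta = target - at.position
        for a in res.atoms:
            a.position = a.position + delta

    structure = Structure(residues=list(residues), source_id=f"toy-seed{spec.seed}")
    if spec.metal:
        # Zn near the sulfamide anchor (N2) or at a fixed offset from probe
        anchor = lig.atom("N2") or lig.atoms[0]
        direction = anchor.position - lig_center
        n = np.linalg.norm(direction)
        direction = direction / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
        zn_pos = anchor.position + direction * spec.metal_offset
        structure.residues.append(
            Residue(chain_id="M", number=500, name="ZN",
                    atoms=[Atom(name="ZN", element="ZN", position=zn_pos)])
        )
    structure.residues.append(lig)

    # check for unrequested overlap
    all_xyz = structure.coordinates()
    d = np.linalg.norm(all_xyz[:, None] - all_xyz[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if spec.clash_distance is None and float(d.min()) < 0.8:
        raise FixtureSpecError(
            f"unrequested atomic overlap (min distance {d.min():.2f} A); "
            "adjust placement distances"
        )

    # serialize through the public I/O path
    if out_dir is None:
        out_dir = tempfile.mkdtemp(prefix="carbscan_fixture_")
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, f"toy_seed{spec.seed}.pdb")
    write_structure(structure, path, format="pdb")
    reread = read_structure(path, format="pdb")

    gt = GroundTruth()
    lig_res = next(r for r in reread.residues if r.name in ("LIG", "PRB"))
    for la in lig_res.atoms:
        gt.ligand_elements[la.name] = la.element
    for r in reread.residues:
        if r.name in ("LIG", "PRB"):
            continue
        gt.residue_names[r.key] = r.name
        for a in r.atoms:
            if a.is_hydrogen:
                continue
            gt.elements[(r.key, a.name)] = a.element
            for la in lig_res.atoms:
                if la.is_hydrogen:
                    continue
                gt.distances[((r.key, a.name), la.name)] = float(
                    np.linalg.norm(a.position - la.position)
                )
    if spec.ligand == "point_probe":
        gt.probe_energies = _probe_energies(reread, lig_res)
    return reread, gt


def _probe_energies(s: Structure, probe_res: Residue) -> dict[tuple, float]:
    """Closed-form per-residue Coulomb energies for the +1 probe.

    Independent arithmetic over the bundled charge table with the default
    distance-dependent dielectric eps(r) = 4r: E = sum 332.0637*q/(4 d^2).
    The probe's LJ epsilon is zero, so there is no vdW term.
    """
    import yaml
    from importlib import resources

    ref = resources.files("carbscan").joinpath("data/forcefield.yaml")
    raw = yaml.safe_load(ref.read_text())
    charges = {
        rn: {an: float(v["charge"]) for an, v in atoms.items()}
        for rn, atoms in raw["residues"].items()
    }
    kcoul = float(raw["coulomb_constant"])
    kdie = float(raw["dielectric"]["k"])
    px = probe_res.atoms[0].position
    out: dict[tuple, float] = {}
    for r in s.residues:
        if r.key == probe_res.key:
            continue
        table = charges.get(r.name)
        if table is None:
            continue
        e = 0.0
        for a in r.atoms:
            qa = table.get(a.name)
            if qa is None:
                continue
            d = float(np.linalg.norm(a.position - px))
            e += kcoul * qa * 1.0 / (kdie * d * d)
        out[r.key] = e
    return out


# ---------------------------------------------------------------------------
# Homolog pairs


def _random_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Seeded proper rotation (QR with det correction) and translation."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20.0, 20.0, size=3)
    return q, t


def make_homolog_pair(
    spec: FixtureSpec, out_dir: Optional[str] = None
) -> tuple[Structure, Structure, list[tuple[int, str, str]], tuple[np.ndarray, np.ndarray]]:
    """A template complex and a transformed, substituted apo homolog.

    Structure A is a toy complex (protein + ligand + optional Zn);
    structure B is A's protein (and metal) with ``spec.substitutions``
    applied at the same anchor placements, rigidly moved by a seeded
    proper transform. Returns (A, B, substitution list, (R, t)) where
    substitutions are (residue number, name in A, name in B).
    """
    base_spec = FixtureSpec(
        **{**spec.__dict__, "substitutions": ()}
    )
    a, _gt = make_toy_complex(base_spec, out_dir=out_dir)

    sub_spec = FixtureSpec(**spec.__dict__)
    b_full, _ = make_toy_complex(sub_spec, out_dir=out_dir)

    subs: list[tuple[int, str, str]] = []
    for idx, newname in spec.substitutions:
        old = spec.residue_names[idx % len(spec.residue_names)]
        if old == newname:
            continue
        subs.append((idx + 1, old, newname))

    rng = np.random.default_rng(spec.seed + 10_000)
    rot, trans = _random_transform(rng)
    b = Structure(source_id=f"homolog-seed{spec.seed}")
    for r in b_full.residues:
        if r.name in ("LIG", "PRB"):
            continue  # apo target
        nr = r.copy()
        for at in nr.atoms:
            at.position = rot @ at.position + trans
        b.residues.append(nr)

    if out_dir is None:
        out_dir = tempfile.mkdtemp(prefix="carbscan_homolog_")
    os.makedirs(out_dir, exist_ok=True)
    path_a = os.path.join(out_dir, f"homolog_a_seed{spec.seed}.pdb")
    path_b = os.path.join(out_dir, f"homolog_b_seed{spec.seed}.pdb")
    write_structure(a, path_a, format="pdb")
    write_structure(b, path_b, format="pdb")
    return (
        read_structure(path_a),
        read_structure(path_b),
        subs,
        (rot, trans),
    )


# ---------------------------------------------------------------------------
# Minimization fixtures


def make_minimization_fixture(
    kind: str, seed: int = 0
) -> dict:
    """Analytic minimization test systems.

    ``harmonic``: isotropic 3-D well, known center. ``lj_dimer``: one
    movable atom against a fixed one, optimum at 2^(1/6)*sigma.
    ``cluster``: 5 movable LJ atoms from a seeded start (no analytic
    optimum; compare against a weaker reference optimizer).
    Returns a dict with ``objective`` (x -> (E, grad)), ``x0``, and where
    known ``optimum`` / ``optimum_separation`` / ``sigma`` / ``epsilon``.
    """
    rng = np.random.default_rng(seed)
    if kind == "harmonic":
        center = rng.uniform(-5.0, 5.0, size=3)
        k = float(rng.uniform(1.0, 10.0))

        def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
            d = x - center
            return k * float(d @ d), 2.0 * k * d

        return {
            "objective": objective,
            "x0": center + rng.uniform(-3.0, 3.0, size=3),
            "optimum": center,
            "k": k,
        }
    if kind == "lj_dimer":
        sigma, epsilon = 3.4, 0.5
        fixed = np.zeros(3)

        def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
            dv = x - fixed
            r = float(np.linalg.norm(dv))
            sr6 = (sigma / r) ** 6
            e = 4.0 * epsilon * (sr6 * sr6 - sr6)
            de = 4.0 * epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            return e, de * dv / r

        x0 = np.array([sigma * 1.35, 0.0, 0.0]) + rng.normal(scale=0.05, size=3)
        return {
            "objective": objective,
            "x0": x0,
            "optimum_separation": sigma * 2.0 ** (1.0 / 6.0),
            "sigma": sigma,
            "epsilon": epsilon,
            "fixed": fixed,
        }
    if kind == "cluster":
        sigma, epsilon = 3.4, 0.5
        n = 5
        # seeded start: perturbed simplex-ish arrangement, no overlaps
        base = rng.uniform(-1.0, 1.0, size=(n, 3)) * 2.0
        base += np.arange(n)[:, None] * np.array([2.2, 0.6, -0.4])

        def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
            p = x.reshape(n, 3)
            e = 0.0
            g = np.zeros_like(p)
            for i in range(n):
                for j in range(i + 1, n):
                    dv = p[i] - p[j]
                    r = max(float(np.linalg.norm(dv)), 1e-6)
                    sr6 = (sigma / r) ** 6
                    e += 4.0 * epsilon * (sr6 * sr6 - sr6)
                    de = 4.0 * epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
                    gv = de * dv / r
                    g[i] += gv
                    g[j] -= gv
            return e, g.ravel()

        return {
            "objective": objective,
            "x0": base.ravel(),
            "n_atoms": n,
            "sigma": sigma,
            "epsilon": epsilon,
        }
    raise FixtureSpecError(f"unknown minimization fixture kind {kind!r}")
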