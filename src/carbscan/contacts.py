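"""Protein-ligand contact enumeration, classification, and dihydrogen bonds.

A contact is any (protein-or-metal heavy atom, ligand heavy atom) pair at
Euclidean distance <= cutoff (default 4.0 A, inclusive). Classes:

- ``metal_coordination``: protein-side atom is a flagged metal within the
  metal cutoff (default 2.5 A — keeps the Zn-N anchor bond, excludes the
  longer Zn...S/O approaches);
- ``polar``: both atoms in {N, O, S} within the polar cutoff (default
  3.1 A, which cleanly separates hydrogen-bond-range pairs from
  van-der-Waals-range N/O pairs);
- ``vdw``: everything else within the contact cutoff.

Dihydrogen bonds pair a protic hydrogen (on N, O, S, or an aromatic
carbon) with a hydridic hydrogen (on boron) at H...H <= 2.4 A with both
X-H...H angles >= 90 deg — the standard crystallographic criteria for
boron-cluster H...H contacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import SelectionError, TopologyError
from .model import Atom, AtomSelection, Residue, Structure, select_atoms

__all__ = [
    "ContactRecord",
    "DihydrogenBond",
    "enumerate_contacts",
    "classify_contacts",
    "detect_dihydrogen_bonds",
    "contact_residue_sets",
    "write_contact_table",
    "read_contact_table",
    "DEFAULT_CUTOFF",
    "POLAR_CUTOFF",
    "METAL_CUTOFF",
    "DIHYDROGEN_CUTOFF",
]

DEFAULT_CUTOFF = 4.0
POLAR_CUTOFF = 3.1
METAL_CUTOFF = 2.5
DIHYDROGEN_CUTOFF = 2.4
_POLAR_ELEMENTS = frozenset({"N", "O", "S"})

#: Aromatic ring carbons able to act as weak C-H donors.
_AROMATIC_CARBONS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
}


@dataclass(frozen=True)
class ContactRecord:
    """One protein-atom/ligand-atom pair within the contact cutoff."""

    chain_id: str
    residue_number: int
    residue_name: str
    protein_atom: str
    ligand_atom: str
    distance: float
    contact_class: str = ""  # metal_coordination | polar | vdw


@dataclass(frozen=True)
class DihydrogenBond:
    """A protic-H / hydridic-H pair satisfying distance + angle criteria."""

    protic_residue: tuple[str, int, str]
    protic_H: str
    donor_atom: str
    hydridic_residue: tuple[str, int, str]
    hydridic_H: str
    acceptor_atom: str
    hh_distance: float
    donor_angle: float
    acceptor_angle: float


def _ligand_keys(s: Structure, ligand_sel: AtomSelection) -> set[tuple]:
    return {r.key for r, _ in select_atoms(s, ligand_sel)}


def enumerate_contacts(
    s: Structure,
    ligand_sel: AtomSelection,
    cutoff: float = DEFAULT_CUTOFF,
    include_waters: bool = False,
) -> list[ContactRecord]:
    """All heavy-atom protein/metal-ligand pairs with distance <= cutoff.

    Hydrogens are excluded on both sides; waters are excluded by default.
    Records are sorted by residue number then distance, distances rounded
    to 2 decimals (matching contact-table conventions).
    """
    lig_pairs = [
        (r, a) for r, a in select_atoms(s, ligand_sel) if not a.is_hydrogen
    ]
    if not lig_pairs:
        raise SelectionError("ligand selection matched no heavy atoms")
    lig_res_keys = {r.key for r, _ in lig_pairs}

    env_pairs: list[tuple[Residue, Atom]] = []
    for r in s.residues:
        if r.key in lig_res_keys:
            continue
        if r.is_water and not include_waters:
            continue
        for a in r.atoms:
            if not a.is_hydrogen:
                env_pairs.append((r, a))
    if not env_pairs:
        return []

    lig_xyz = np.array([a.position for _, a in lig_pairs])
    env_xyz = np.array([a.position for _, a in env_pairs])
    tree = cKDTree(env_xyz)
    records: list[ContactRecord] = []
    for (lr, la), lx in zip(lig_pairs, lig_xyz):
        for j in tree.query_ball_point(lx, cutoff + 1e-9):
            er, ea = env_pairs[j]
            d = float(np.linalg.norm(env_xyz[j] - lx))
            if d <= cutoff + 1e-9:
                records.append(
                    ContactRecord(
                        chain_id=er.chain_id,
                        residue_number=er.number,
                        residue_name=er.name,
                        protein_atom=ea.name,
                        ligand_atom=la.name,
                        distance=round(d, 2),
                    )
                )
    records.sort(key=lambda c: (c.residue_number, c.distance, c.protein_atom, c.ligand_atom))
    return records


def classify_contacts(
    contacts: Sequence[ContactRecord],
    s: Structure,
    polar_cutoff: float = POLAR_CUTOFF,
    metal_cutoff: float = METAL_CUTOFF,
) -> list[ContactRecord]:
    """Fill contact classes; a pure function of elements, distance, metal flag."""
    metal_keys = {r.key for r in s.metals}
    elem: dict[tuple, str] = {}
    for r, a in s.atoms():
        elem[(r.key, a.name)] = a.element
    res_by_key = {r.key: r for r in s.residues}
    # protein atom element lookup needs (chain, number) -> residue
    by_chain_num: dict[tuple[str, int], Residue] = {
        (r.chain_id, r.number): r for r in s.residues
    }

    out: list[ContactRecord] = []
    lig_elem: dict[str, str] = {}
    for r, a in s.atoms():
        lig_elem.setdefault(a.name, a.element)
    for c in contacts:
        pres = by_chain_num.get((c.chain_id, c.residue_number))
        if pres is None:
            raise TopologyError(f"contact references unknown residue {c.residue_number}")
        pa = pres.atom(c.protein_atom)
        p_elem = pa.element if pa is not None else "C"
        l_elem = lig_elem.get(c.ligand_atom, "C")
        if pres.key in metal_keys and c.distance <= metal_cutoff + 1e-9:
            cls = "metal_coordination"
        elif (
            p_elem in _POLAR_ELEMENTS
            and l_elem in _POLAR_ELEMENTS
            and c.distance <= polar_cutoff + 1e-9
        ):
            cls = "polar"
        else:
            cls = "vdw"
        out.append(
            ContactRecord(
                chain_id=c.chain_id,
                residue_number=c.residue_number,
                residue_name=c.residue_name,
                protein_atom=c.protein_atom,
                ligand_atom=c.ligand_atom,
                distance=c.distance,
                contact_class=cls,
            )
        )
    return out


def _bonded_heavy(res: Residue, h: Atom) -> Optional[Atom]:
    """Nearest heavy atom in the same residue (the H's covalent parent)."""
    best, best_d = None, 1.6  # generous X-H bond ceiling
    for a in res.atoms:
        if a.is_hydrogen:
            continue
        d = float(np.linalg.norm(a.position - h.position))
        if d < best_d:
            best, best_d = a, d
    return best


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosv = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def detect_dihydrogen_bonds(
    s: Structure,
    ligand_sel: AtomSelection,
    cutoff: float = DIHYDROGEN_CUTOFF,
    min_angle: float = 90.0,
) -> list[DihydrogenBond]:
    """Protic-H...hydridic-H pairs between environment and boron cage.

    Requires hydrogens on both the ligand (B-H) and the protein; raises a
    clear error pointing to ``prep.add_hydrogens`` when the cage bears none.
    """
    lig_pairs = select_atoms(s, ligand_sel)
    lig_res_keys = {r.key for r, _ in lig_pairs}
    hydridic: list[tuple[Residue, Atom, Atom]] = []
    for r, a in lig_pairs:
        if not a.is_hydrogen:
            continue
        parent = _bonded_heavy(r, a)
        if parent is not None and parent.element == "B":
            hydridic.append((r, a, parent))
    if not hydridic:
        raise TopologyError(
            "no hydridic B-H hydrogens on the ligand; run prep.add_hydrogens first"
        )

    protic: list[tuple[Residue, Atom, Atom]] = []
    for r in s.residues:
        if r.key in lig_res_keys:
            continue
        for a in r.atoms:
            if not a.is_hydrogen:
                continue
            parent = _bonded_heavy(r, a)
            if parent is None:
                continue
            if parent.element in _POLAR_ELEMENTS or (
                parent.element == "C"
                and parent.name in _AROMATIC_CARBONS.get(r.name, frozenset())
            ):
                protic.append((r, a, parent))

    bonds: list[DihydrogenBond] = []
    for pr, ph, pdon in protic:
        for hr, hh, hacc in hydridic:
            d = float(np.linalg.norm(ph.position - hh.position))
            if d > cutoff + 1e-9:
                continue
            ang_d = _angle(pdon.position, ph.position, hh.position)
            ang_a = _angle(hacc.position, hh.position, ph.position)
            if ang_d >= min_angle and ang_a >= min_angle:
                bonds.append(
                    DihydrogenBond(
                        protic_residue=pr.key,
                        protic_H=ph.name,
                        donor_atom=pdon.name,
                        hydridic_residue=hr.key,
                        hydridic_H=hh.name,
                        acceptor_atom=hacc.name,
                        hh_distance=round(d, 2),
                        donor_angle=round(ang_d, 1),
                        acceptor_angle=round(ang_a, 1),
                    )
                )
    bonds.sort(key=lambda b: b.hh_distance)
    return bonds


def contact_residue_sets(
    complexes: Sequence[tuple[str, Structure, AtomSelection]],
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Compare contacting residues across several complexes.

    Rows are the union of contacting residues (metals included); one column
    per complex with '' (absent), 'x' (contact), or 'P' (has a polar or
    metal-coordination contact) — the bold-residue convention of published
    contact-comparison tables.
    """
    if len(complexes) < 2:
        raise ValueError("need at least two complexes to compare")
    columns: dict[str, dict[tuple[int, str], str]] = {}
    for label, s, sel in complexes:
        recs = classify_contacts(enumerate_contacts(s, sel, cutoff), s)
        col: dict[tuple[int, str], str] = {}
        for c in recs:
            key = (c.residue_number, c.residue_name)
            mark = "P" if c.contact_class in ("polar", "metal_coordination") else "x"
            if col.get(key) != "P":
                col[key] = mark if col.get(key) != "P" else "P"
            if mark == "P":
                col[key] = "P"
        columns[label] = col
    all_rows = sorted({k for col in columns.values() for k in col})
    data = {
        label: [col.get(k, "") for k in all_rows] for label, col in columns.items()
    }
    index = [f"{name}{num}" if name not in ("ZN",) else name for num, name in all_rows]
    return pd.DataFrame(data, index=index)


_TABLE_COLUMNS = [
    "residue_number",
    "residue_name",
    "protein_atom",
    "ligand_atom",
    "distance",
    "contact_class",
]


def write_contact_table(contacts: Sequence[ContactRecord], path) -> None:
    """Write classified contacts as a TSV with stable ordering."""
    df = pd.DataFrame(
        [
            {
                "residue_number": c.residue_number,
                "residue_name": c.residue_name,
                "protein_atom": c.protein_atom,
                "ligand_atom": c.ligand_atom,
                "distance": f"{c.distance:.2f}",
                "contact_class": c.contact_class or "vdw",
            }
            for c in contacts
        ],
        columns=_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_contact_table(path) -> list[ContactRecord]:
    """Read back a TSV written by :func:`write_contact_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"distance": float})
    return [
        ContactRecord(
            chain_id="",
            residue_number=int(row.residue_number),
            residue_name=str(row.residue_name),
            protein_atom=str(row.protein_atom),
            ligand_atom=str(row.ligand_atom),
            distance=float(row.distance),
            contact_class=str(row.contact_class),
        )
        for row in df.itertuples()
    ]
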