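"""Structure preparation: hydrogens, glycine truncation, ligand grafting.

Hydrogen placement uses ideal sp3/sp2 geometry with standard X-H bond
lengths; cage B-H/C-H hydrogens point radially outward from the cage
centroid (B-H = 1.19 A). Heavy atoms are never moved. Glycine truncation
removes side-chain atoms beyond C-beta and replaces them with an H-alpha
along the old C-alpha -> C-beta direction. Grafting transfers a template's
ligand (plus metal and named bridging waters) into a homologous target
after a rigid superposition of the binding sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import PairingError, TopologyError
from .ligand import COMPOUND1, LigandTemplate
from .model import (
    Atom,
    AtomSelection,
    Residue,
    Structure,
    select_atoms,
)
from .superpose import RigidTransform, kabsch_fit, superpose_structures
from . import topology as topo

__all__ = [
    "add_hydrogens",
    "truncate_to_glycine",
    "GraftRecipe",
    "graft_ligand",
    "binding_site_substitutions",
]

logger = logging.getLogger(__name__)

_TET_HALF = math.radians(109.471 / 2.0)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length direction")
    return v / n


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(u, ref))


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about unit axis."""
    axis = _unit(axis)
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * np.dot(axis, v) * (1.0 - math.cos(angle))
    )


def _sp3_1h(parent: np.ndarray, nbrs: Sequence[np.ndarray], bl: float) -> list[np.ndarray]:
    d = -sum(_unit(n - parent) for n in nbrs)
    return [parent + _unit(d) * bl]


def _sp3_2h(parent: np.ndarray, nbrs: Sequence[np.ndarray], bl: float) -> list[np.ndarray]:
    u1, u2 = (_unit(n - parent) for n in nbrs[:2])
    bis = -_unit(u1 + u2)
    perp = _unit(np.cross(u1, u2))
    return [
        parent + _unit(bis * math.cos(_TET_HALF) + s * perp * math.sin(_TET_HALF)) * bl
        for s in (+1.0, -1.0)
    ]


def _sp3_3h(
    parent: np.ndarray, nbrs: Sequence[np.ndarray], bl: float,
    stagger_ref: Optional[np.ndarray] = None,
) -> list[np.ndarray]:
    axis = -_unit(nbrs[0] - parent)
    if stagger_ref is not None:
        perp = stagger_ref - nbrs[0]
        perp = perp - np.dot(perp, axis) * axis
        perp = -_unit(perp) if np.linalg.norm(perp) > 1e-6 else _any_perpendicular(axis)
    else:
        perp = _any_perpendicular(axis)
    tet = math.radians(180.0 - 109.471)
    base = _rotate(axis, np.cross(axis, perp), tet)
    return [
        parent + _rotate(base, axis, k * 2.0 * math.pi / 3.0) * bl for k in range(3)
    ]


def _sp2_1h(parent: np.ndarray, nbrs: Sequence[np.ndarray], bl: float) -> list[np.ndarray]:
    d = -sum(_unit(n - parent) for n in nbrs[:2])
    return [parent + _unit(d) * bl]


def _sp2_2h(
    parent: np.ndarray, center: np.ndarray, plane_ref: np.ndarray, bl: float
) -> list[np.ndarray]:
    """Two in-plane H on a planar NH2 bonded to sp2 ``center``."""
    u = _unit(center - parent)
    normal = np.cross(u, plane_ref - center)
    if np.linalg.norm(normal) < 1e-6:
        normal = _any_perpendicular(u)
    normal = _unit(normal)
    return [
        parent + _rotate(-u, normal, s * math.radians(60.0)) * bl for s in (+1.0, -1.0)
    ]


def _hydroxyl(
    parent: np.ndarray,
    nbr: np.ndarray,
    nbr_ref: Optional[np.ndarray],
    bl: float,
    acceptors: Sequence[np.ndarray],
) -> list[np.ndarray]:
    """Rotatable O-H/S-H: pick the staggered position nearest an acceptor."""
    axis = _unit(parent - nbr)
    if nbr_ref is not None:
        perp = nbr_ref - nbr
        perp = perp - np.dot(perp, axis) * axis
        perp = _unit(perp) if np.linalg.norm(perp) > 1e-6 else _any_perpendicular(axis)
    else:
        perp = _any_perpendicular(axis)
    tet = math.radians(180.0 - 109.471)
    base = _rotate(axis, np.cross(axis, perp), tet)
    candidates = [
        parent + _rotate(base, axis, ang) * bl
        for ang in (math.pi, math.pi / 3.0, -math.pi / 3.0)
    ]
    if len(acceptors):
        acc = np.asarray(acceptors)
        scores = [np.min(np.linalg.norm(acc - c, axis=1)) for c in candidates]
        return [candidates[int(np.argmin(scores))]]
    return [candidates[0]]


def _acceptor_positions(s: Structure, exclude_key: tuple) -> np.ndarray:
    """N/O/S heavy atoms outside one residue (H-bond acceptor candidates)."""
    out = [
        a.position
        for r, a in s.atoms()
        if r.key != exclude_key and not a.is_hydrogen and a.element in ("N", "O", "S")
    ]
    return np.asarray(out) if out else np.zeros((0, 3))


def _place_residue_hydrogens(
    s: Structure, res: Residue, prev_c: Optional[Atom]
) -> list[Atom]:
    """Ideal-geometry hydrogens for one standard amino acid."""
    name = res.name
    added: list[Atom] = []
    existing = {a.name for a in res.atoms}

    def pos(atom_name: str) -> Optional[np.ndarray]:
        a = res.atom(atom_name)
        return a.position if a is not None else None

    def add(h_name: str, p: np.ndarray) -> None:
        if h_name not in existing:
            added.append(Atom(name=h_name, element="H", position=p))
            existing.add(h_name)

    # Backbone amide H (not for proline). The preceding residue's carbonyl
    # C defines the amide plane only when an actual peptide bond exists;
    # otherwise fall back to the in-residue bisector of CA and C.
    n, ca, c, o = pos("N"), pos("CA"), pos("C"), pos("O")
    if name != "PRO" and n is not None and ca is not None and "H" not in existing:
        bonded_prev = (
            prev_c is not None
            and np.linalg.norm(prev_c.position - n) < 1.8
        )
        if bonded_prev:
            nbrs = [ca, prev_c.position]
        elif c is not None:
            nbrs = [ca, c]
        else:
            nbrs = None
        if nbrs is not None:
            add("H", _sp2_1h(n, nbrs, topo.XH_BOND_LENGTHS["N"])[0])

    # H-alpha (two for glycine).
    if ca is not None and n is not None and c is not None:
        bl = topo.XH_BOND_LENGTHS["C"]
        if name == "GLY":
            if "HA2" not in existing and "HA3" not in existing:
                h2, h3 = _sp3_2h(ca, [n, c], bl)
                add("HA2", h2)
                add("HA3", h3)
        else:
            cb = pos("CB")
            if cb is not None and "HA" not in existing:
                add("HA", _sp3_1h(ca, [n, c, cb], bl)[0])

    specs = list(topo.HYDROGEN_SPECS.get(name, ()))
    # His tautomer: protonate the ring nitrogen with the nearest acceptor.
    if name == "HIS":
        acc = _acceptor_positions(s, res.key)
        choice = "NE2"
        if len(acc):
            cand = {}
            for nname in ("ND1", "NE2"):
                p = pos(nname)
                if p is not None:
                    cand[nname] = float(np.min(np.linalg.norm(acc - p, axis=1)))
            if cand and min(cand.values()) < 3.6:
                choice = min(cand, key=cand.get)
        h_name = "HD1" if choice == "ND1" else "HE2"
        specs.append(((h_name,), choice, "sp2_1h"))

    for h_names, parent_name, rule in specs:
        p = pos(parent_name)
        if p is None:
            logger.warning("residue %s %s missing %s; hydrogens skipped",
                           name, res.number, parent_name)
            continue
        if all(h in existing for h in h_names):
            continue
        nbr_names = topo.heavy_neighbors(name, parent_name)
        nbrs = [pos(nn) for nn in nbr_names]
        nbrs = [x for x in nbrs if x is not None]
        parent_el = "S" if parent_name.startswith("S") else parent_name[0]
        bl = topo.XH_BOND_LENGTHS.get(parent_el, 1.09)
        try:
            if rule == "sp3_1h" and len(nbrs) >= 3:
                placed = _sp3_1h(p, nbrs, bl)
            elif rule == "sp3_2h" and len(nbrs) >= 2:
                placed = _sp3_2h(p, nbrs, bl)
            elif rule == "sp3_3h" and len(nbrs) >= 1:
                nbr0 = nbr_names[0]
                ref_names = [x for x in topo.heavy_neighbors(name, nbr0) if x != parent_name]
                ref = pos(ref_names[0]) if ref_names else None
                placed = _sp3_3h(p, nbrs, bl, stagger_ref=ref)
            elif rule == "sp2_1h" and len(nbrs) >= 2:
                placed = _sp2_1h(p, nbrs, bl)
            elif rule == "sp2_2h" and len(nbrs) >= 1:
                center = nbrs[0]
                ref_names = [x for x in topo.heavy_neighbors(name, nbr_names[0]) if x != parent_name]
                ref = pos(ref_names[0]) if ref_names else p + _any_perpendicular(_unit(center - p))
                placed = _sp2_2h(p, center, ref, bl)
            elif rule == "hydroxyl" and len(nbrs) >= 1:
                ref_names = [x for x in topo.heavy_neighbors(name, nbr_names[0]) if x != parent_name]
                ref = pos(ref_names[0]) if ref_names else None
                placed = _hydroxyl(p, nbrs[0], ref, bl, _acceptor_positions(s, res.key))
            else:
                logger.warning("cannot place %s on %s %s (rule %s, %d neighbors)",
                               h_names, name, res.number, rule, len(nbrs))
                continue
        except ValueError:
            logger.warning("degenerate geometry placing %s on %s %s",
                           h_names, name, res.number)
            continue
        for h_name, hp in zip(h_names, placed):
            add(h_name, hp)
    return added


def _place_ligand_hydrogens(res: Residue, template: LigandTemplate) -> list[Atom]:
    """Cage hydrogens radial from the centroid; chain hydrogens by rules."""
    added: list[Atom] = []
    existing = {a.name for a in res.atoms}
    cage = [res.atom(n) for n in template.cage_atom_names]
    cage = [a for a in cage if a is not None]
    if len(cage) < 12:
        raise TopologyError(
            f"ligand residue {res.key} has {len(cage)}/12 cage vertices"
        )
    centroid = np.mean([a.position for a in cage], axis=0)

    def add(h_name: str, p: np.ndarray) -> None:
        if h_name not in existing:
            added.append(Atom(name=h_name, element="H", position=p))
            existing.add(h_name)

    def pos(n: str) -> Optional[np.ndarray]:
        a = res.atom(n)
        return a.position if a is not None else None

    for h_name, parent_name in template.hydrogen_parents.items():
        pa = res.atom(template.canonical_name(parent_name)) or res.atom(parent_name)
        if pa is None:
            continue
        bl = topo.XH_BOND_LENGTHS.get(pa.element, 1.09)
        if parent_name in template.cage_atom_names:
            add(h_name, pa.position + _unit(pa.position - centroid) * bl)
        elif parent_name == "C3":
            nbrs = [pos("C1"), pos("N1")]
            nbrs = [x for x in nbrs if x is not None]
            if len(nbrs) == 2 and h_name in ("H31", "H32"):
                h1, h2 = _sp3_2h(pa.position, nbrs, bl)
                add("H31", h1)
                add("H32", h2)
        elif parent_name == "N1":
            nbrs = [pos("C3"), pos("S")]
            nbrs = [x for x in nbrs if x is not None]
            if len(nbrs) == 2:
                add(h_name, _sp2_1h(pa.position, nbrs, bl)[0])
        elif parent_name == "N2":
            sp = pos("S")
            o1 = pos("O1")
            if sp is not None and o1 is not None:
                h1, h2 = _sp2_2h(pa.position, sp, o1, bl)
                if h_name == "HN21":
                    add("HN21", h1)
                else:
                    add("HN22", h2)
    return added


def add_hydrogens(
    s: Structure,
    ligand_templates: Optional[dict[str, LigandTemplate]] = None,
) -> Structure:
    """Return a copy of ``s`` with ideal-geometry hydrogens added.

    Existing hydrogens are preserved; heavy atoms never move. Residues with
    unknown topology (other than waters/metals) are skipped with a warning.
    ``ligand_templates`` maps residue names to ligand topologies; residues
    with 12 cage-labelled atoms default to the compound-1 template.
    """
    ligand_templates = dict(ligand_templates or {})
    out = s.copy()
    prev_c_by_chain: dict[str, Optional[Atom]] = {}
    for res in out.residues:
        prev_c = prev_c_by_chain.get(res.chain_id)
        if res.is_water or res.is_metal:
            pass
        elif res.is_amino_acid:
            res.atoms.extend(_place_residue_hydrogens(out, res, prev_c))
        elif res.name in ligand_templates:
            res.atoms.extend(_place_ligand_hydrogens(res, ligand_templates[res.name]))
        elif {n for n in COMPOUND1.cage_atom_names} <= {a.name for a in res.atoms}:
            res.atoms.extend(_place_ligand_hydrogens(res, COMPOUND1))
        else:
            logger.warning("no topology for residue %s %s; hydrogens skipped",
                           res.name, res.number)
        c = res.atom("C")
        prev_c_by_chain[res.chain_id] = c if res.is_amino_acid else None
    return out


_GLY_KEEP = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})


def truncate_to_glycine(s: Structure, residue_key: tuple[str, int] | tuple[str, int, str]) -> Structure:
    """Replace one residue's side chain with glycine's H-alpha pair.

    Backbone atoms (and their coordinates) are untouched; the new HA2 sits
    along the old C-alpha -> C-beta direction at standard C-H length and an
    existing HA is renamed HA3. All other residues are returned unchanged.
    """
    if len(residue_key) == 2:
        residue_key = (residue_key[0], residue_key[1], "")
    out = s.copy()
    res = out.find_residue(*residue_key)
    if res is None:
        raise TopologyError(f"no residue {residue_key}")
    if not res.is_amino_acid:
        raise TypeError(f"residue {residue_key} ({res.name}) is not a standard amino acid")
    if res.name == "GLY":
        logger.info("residue %s is already glycine; no-op", (residue_key,))
        return out
    ca = res.atom("CA")
    cb = res.atom("CB")
    if ca is None:
        raise TopologyError(f"residue {residue_key} lacks CA")
    kept = [a for a in res.atoms if a.name in _GLY_KEEP]
    if cb is not None:
        direction = _unit(cb.position - ca.position)
        kept.append(
            Atom(name="HA2", element="H",
                 position=ca.position + direction * topo.XH_BOND_LENGTHS["C"])
        )
    for a in kept:
        if a.name == "HA":
            a.name = "HA3"
    res.atoms = kept
    res.name = "GLY"
    return out


@dataclass
class GraftRecipe:
    """Inputs for template-based ligand transfer into a homologous site."""

    template_complex: Structure
    target_protein: Structure
    fit_selection: AtomSelection
    ligand_selection: AtomSelection
    transfer_metal: bool = True
    water_numbers: tuple[int, ...] = ()
    spatial_pairing: bool = False
    clash_cutoff: float = 1.5


def _spatial_fit(
    target: Structure, template: Structure, sel: AtomSelection, max_dist: float = 2.5
) -> RigidTransform:
    """Fit template onto target pairing selected atoms by nearest neighbor."""
    t_atoms = [a.position for _, a in select_atoms(target, sel)]
    m_atoms = [a.position for _, a in select_atoms(template, sel)]
    if len(t_atoms) < 3 or len(m_atoms) < 3:
        raise PairingError("spatial pairing needs >= 3 atoms on both sides")
    t_xyz = np.asarray(t_atoms)
    ref, mov = [], []
    for p in m_atoms:
        d = np.linalg.norm(t_xyz - p, axis=1)
        j = int(np.argmin(d))
        if d[j] <= max_dist:
            ref.append(t_xyz[j])
            mov.append(p)
    if len(ref) < 3:
        raise PairingError("spatial pairing found < 3 partners within range")
    return kabsch_fit(np.asarray(ref), np.asarray(mov))


def graft_ligand(recipe: GraftRecipe) -> tuple[Structure, dict]:
    """Transfer the template's ligand (+ metal, named waters) onto the target.

    Returns the modeled complex and a provenance record (fit RMSD, applied
    transform, clash list). Grafted atoms closer than ``clash_cutoff`` to a
    target heavy atom are reported as clashes (warning, not fatal — the
    relaxation stage resolves them).
    """
    template = recipe.template_complex
    target = recipe.target_protein
    if recipe.spatial_pairing:
        tr = _spatial_fit(target, template, recipe.fit_selection)
        fit_rmsd = float("nan")
        n_fit = -1
    else:
        result = superpose_structures(target, template, recipe.fit_selection)
        tr, fit_rmsd, n_fit = result.transform, result.rmsd, result.n_atoms

    transferred: list[Residue] = []
    lig_keys = {r.key for r, _ in select_atoms(template, recipe.ligand_selection)}
    for r in template.residues:
        take = False
        if r.key in lig_keys:
            take = True
        elif recipe.transfer_metal and r.is_metal and not target.metals:
            take = True
        elif r.is_water and r.number in recipe.water_numbers:
            take = True
        if take:
            nr = r.copy()
            for a in nr.atoms:
                a.position = tr.apply(a.position)
            transferred.append(nr)
    if not any(r.key in lig_keys for r in transferred):
        raise TopologyError("ligand selection matched nothing in the template")

    out = target.copy()
    # avoid residue-key collisions with the target
    used = {r.key for r in out.residues}
    for nr in transferred:
        while nr.key in used:
            nr.number += 1000
        used.add(nr.key)
        out.residues.append(nr)

    target_xyz = np.array(
        [a.position for r, a in target.atoms() if not a.is_hydrogen]
    )
    clashes: list[tuple[str, float]] = []
    for nr in transferred:
        for a in nr.atoms:
            if a.is_hydrogen or not len(target_xyz):
                continue
            d = float(np.min(np.linalg.norm(target_xyz - a.position, axis=1)))
            if d < recipe.clash_cutoff:
                clashes.append((f"{nr.name}{nr.number}:{a.name}", round(d, 2)))
    if clashes:
        logger.warning("grafted atoms with close target contacts: %s", clashes)
    provenance = {
        "fit_rmsd": fit_rmsd,
        "n_fit_atoms": n_fit,
        "transform": tr,
        "clashes": clashes,
        "transferred": [r.key for r in transferred],
    }
    return out, provenance


def binding_site_substitutions(
    a: Structure,
    b: Structure,
    site_sel: Optional[AtomSelection] = None,
    fit_sel: Optional[AtomSelection] = None,
    pair_cutoff: float = 2.5,
) -> tuple[list[tuple[int, str, str]], list[tuple[str, int, str]]]:
    """Residue identity differences between two homologous sites.

    Pairs site residues of ``a`` with residues of ``b`` by nearest C-alpha
    after a C-alpha superposition (author numbering may differ between
    isoenzymes). Returns (substitutions, unmatched): substitutions are
    (residue number in a, name in a, name in b) for paired positions with
    differing names; unmatched site residues are listed, never dropped.
    """
    ca_sel = AtomSelection.make(atom_names=["CA"])
    fit = superpose_structures(a, b, fit_sel or ca_sel)

    b_cas: list[tuple[Residue, np.ndarray]] = [
        (r, fit.transform.apply(at.position))
        for r, at in select_atoms(b, ca_sel)
    ]
    if not b_cas:
        raise PairingError("no C-alpha atoms in structure b")
    b_xyz = np.array([p for _, p in b_cas])

    subs: list[tuple[int, str, str]] = []
    unmatched: list[tuple[str, int, str]] = []
    for r in a.residues:
        if site_sel is not None and not site_sel.matches_residue(r):
            continue
        if not r.is_amino_acid:
            continue
        ca = r.atom("CA")
        if ca is None:
            continue
        d = np.linalg.norm(b_xyz - ca.position, axis=1)
        j = int(np.argmin(d))
        if d[j] > pair_cutoff:
            unmatched.append(r.key)
            continue
        partner = b_cas[j][0]
        if partner.name != r.name:
            subs.append((r.number, r.name, partner.name))
    return subs, unmatched
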