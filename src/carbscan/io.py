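"""Reading and writing macromolecular structures (PDB and mmCIF).

Parsing is delegated to gemmi; this module converts between gemmi's model
and the package's :class:`~carbscan.model.Structure`, applies the
alternate-location policy, and reduces anisotropic displacement records to
their isotropic equivalent (B_eq = 8*pi^2 * trace(U)/3), since summary ADP
statistics are reported on the isotropic scale.
"""

from __future__ import annotations

import math
import os
from typing import Optional

import gemmi
import numpy as np

from .errors import FormatError, ParseError, SelectionError
from .model import Atom, AtomSelection, Residue, Structure, select_atoms

__all__ = [
    "read_structure",
    "write_structure",
    "structure_stats",
]

_EIGHT_PI2 = 8.0 * math.pi**2


def _iso_adp(atom: gemmi.Atom) -> float:
    """Isotropic-equivalent B-factor; from the aniso tensor when present."""
    if atom.aniso.nonzero():
        u_eq = (atom.aniso.u11 + atom.aniso.u22 + atom.aniso.u33) / 3.0
        return _EIGHT_PI2 * u_eq
    return atom.b_iso


def _apply_altloc_policy(atoms: list[Atom], keep_all: bool) -> list[Atom]:
    """Default policy: per atom name keep the highest-occupancy altloc
    (ties broken by alphabetically first tag); blanks always kept."""
    if keep_all:
        return atoms
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
            continue
        b = best[a.name]
        if (a.occupancy, _tag_rank(a.altloc)) > (b.occupancy, _tag_rank(b.altloc)):
            best[a.name] = a
    return [best[n] for n in order]


def _tag_rank(tag: str) -> float:
    # Higher rank wins ties; alphabetically earlier tags rank higher.
    if not tag:
        return 0.0
    return -ord(tag[0])


def read_structure(
    path: str | os.PathLike,
    format: str = "auto",
    keep_all_altlocs: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from extension/content).
    keep_all_altlocs:
        When False (default) only the highest-occupancy alternate location
        per atom name is retained; ties go to the alphabetically first tag.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Detect)
        else:
            raise FormatError(f"unknown format {format!r}; use pdb, mmcif or auto")
    except FormatError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with location info
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise ParseError(f"{path}: no atom records found")

    st.setup_entities()
    out = Structure(source_id=st.name or os.path.basename(path))
    model = st[0]
    for chain in model:
        for res in chain:
            atoms: list[Atom] = []
            for at in res:
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name.upper(),
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        adp=_iso_adp(at),
                        altloc=at.altloc if at.altloc != "\0" else "",
                    )
                )
            atoms = _apply_altloc_policy(atoms, keep_all_altlocs)
            icode = res.seqid.icode.strip()
            out.residues.append(
                Residue(
                    chain_id=chain.name,
                    number=res.seqid.num,
                    name=res.name.strip().upper(),
                    atoms=atoms,
                    insertion_code=icode,
                )
            )
    out.validate()
    return out


def write_structure(s: Structure, path: str | os.PathLike, format: str = "auto") -> None:
    """Write ``s`` as PDB (fixed-column) or mmCIF.

    Round-trips through :func:`read_structure` preserving atom names,
    numbering, occupancies, ADPs and coordinates to 3 decimals.
    """
    if s.n_atoms() == 0:
        raise ValueError("refusing to write an empty structure")
    path = os.fspath(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    if fmt not in ("pdb", "mmcif", "cif"):
        raise FormatError(f"unknown format {format!r}; use pdb or mmcif")

    st = gemmi.Structure()
    st.name = s.source_id or "carbscan"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in s.residues:
        ch = chains.get(r.chain_id)
        if ch is None:
            ch = gemmi.Chain(r.chain_id or "A")
            chains[r.chain_id] = ch
            model.add_chain(ch)
            ch = model[-1]
            chains[r.chain_id] = ch
        gres = gemmi.Residue()
        gres.name = r.name
        gres.seqid = gemmi.SeqId(r.number, r.insertion_code or " ")
        if not r.is_amino_acid:
            gres.het_flag = "H"
        else:
            gres.het_flag = "A"
        for a in r.atoms:
            gat = gemmi.Atom()
            gat.name = a.name
            gat.element = gemmi.Element(a.element.capitalize())
            gat.pos = gemmi.Position(*a.position)
            gat.occ = a.occupancy
            gat.b_iso = a.adp
            gat.altloc = a.altloc or "\0"
            gres.add_atom(gat)
        ch.add_residue(gres)
    st.add_model(model)
    st.setup_entities()
    try:
        if fmt == "pdb":
            st.write_pdb(path)
        else:
            st.make_mmcif_document().write_file(path)
    except Exception as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def structure_stats(s: Structure, sel: Optional[AtomSelection] = None) -> dict:
    """Summary record: atom count, residue count, water count, mean ADP.

    The mean ADP is the unweighted arithmetic mean of per-atom
    isotropic-equivalent ADPs over the selected atoms.
    """
    pairs = select_atoms(s, sel)
    if not pairs:
        raise SelectionError("selection matched no atoms; mean ADP undefined")
    residues = {r.key for r, _ in pairs}
    mean_adp = float(np.mean([a.adp for _, a in pairs]))
    return {
        "atom_count": len(pairs),
        "residue_count": len(residues),
        "water_count": len(s.waters),
        "mean_adp": mean_adp,
    }
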