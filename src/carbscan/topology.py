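"""Residue topology tables: heavy-atom connectivity and hydrogen rules.

Hydrogen specs are (hydrogen names, parent heavy atom, geometry rule):

- ``sp3_1h`` : parent has three heavy neighbors; one H opposite their sum
- ``sp3_2h`` : methylene-type; two H completing a tetrahedron
- ``sp3_3h`` : methyl / ammonium; three staggered H
- ``sp2_1h`` : planar center with two neighbors; one in-plane H
- ``sp2_2h`` : planar NH2 (amide/guanidinium); two in-plane H
- ``hydroxyl``: single rotatable H (O-H or S-H), oriented toward the
  nearest acceptor among staggered positions

Default protonation: Asp/Glu deprotonated, Lys/Arg protonated, His neutral
with the tautomer chosen by a nearest-acceptor heuristic at placement time
(the ``HIS_TAUTOMER_H`` alternatives below).
"""

from __future__ import annotations

__all__ = [
    "BACKBONE_BONDS",
    "SIDECHAIN_BONDS",
    "HYDROGEN_SPECS",
    "HIS_TAUTOMER_H",
    "XH_BOND_LENGTHS",
    "residue_bonds",
    "heavy_neighbors",
]

BACKBONE_BONDS: tuple[tuple[str, str], ...] = (
    ("N", "CA"),
    ("CA", "C"),
    ("C", "O"),
    ("C", "OXT"),
)

SIDECHAIN_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "ALA": (("CA", "CB"),),
    "ARG": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")),
    "ASN": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "ASP": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "CYS": (("CA", "CB"), ("CB", "SG")),
    "GLN": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")),
    "GLU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")),
    "GLY": (),
    "HIS": (("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")),
    "ILE": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "LEU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "LYS": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")),
    "MET": (("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PHE": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")),
    "PRO": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "SER": (("CA", "CB"), ("CB", "OG")),
    "THR": (("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")),
    "TRP": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")),
    "TYR": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")),
    "VAL": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")),
}

# (hydrogen names, parent atom, rule); backbone H and HA are added
# programmatically (HA2/HA3 for glycine). PRO has no backbone amide H.
HYDROGEN_SPECS: dict[str, tuple[tuple[tuple[str, ...], str, str], ...]] = {
    "ALA": ((("HB1", "HB2", "HB3"), "CB", "sp3_3h"),),
    "ARG": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HG2", "HG3"), "CG", "sp3_2h"),
            (("HD2", "HD3"), "CD", "sp3_2h"),
            (("HE",), "NE", "sp2_1h"),
            (("HH11", "HH12"), "NH1", "sp2_2h"),
            (("HH21", "HH22"), "NH2", "sp2_2h")),
    "ASN": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HD21", "HD22"), "ND2", "sp2_2h")),
    "ASP": ((("HB2", "HB3"), "CB", "sp3_2h"),),
    "CYS": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HG",), "SG", "hydroxyl")),
    "GLN": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HG2", "HG3"), "CG", "sp3_2h"),
            (("HE21", "HE22"), "NE2", "sp2_2h")),
    "GLU": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HG2", "HG3"), "CG", "sp3_2h")),
    "GLY": (),
    "HIS": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HD2",), "CD2", "sp2_1h"),
            (("HE1",), "CE1", "sp2_1h")),
    "ILE": ((("HB",), "CB", "sp3_1h"),
            (("HG12", "HG13"), "CG1", "sp3_2h"),
            (("HG21", "HG22", "HG23"), "CG2", "sp3_3h"),
            (("HD11", "HD12", "HD13"), "CD1", "sp3_3h")),
    "LEU": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HG",), "CG", "sp3_1h"),
            (("HD11", "HD12", "HD13"), "CD1", "sp3_3h"),
            (("HD21", "HD22", "HD23"), "CD2", "sp3_3h")),
    "LYS": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HG2", "HG3"), "CG", "sp3_2h"),
            (("HD2", "HD3"), "CD", "sp3_2h"),
            (("HE2", "HE3"), "CE", "sp3_2h"),
            (("HZ1", "HZ2", "HZ3"), "NZ", "sp3_3h")),
    "MET": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HG2", "HG3"), "CG", "sp3_2h"),
            (("HE1", "HE2", "HE3"), "CE", "sp3_3h")),
    "PHE": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HD1",), "CD1", "sp2_1h"),
            (("HD2",), "CD2", "sp2_1h"),
            (("HE1",), "CE1", "sp2_1h"),
            (("HE2",), "CE2", "sp2_1h"),
            (("HZ",), "CZ", "sp2_1h")),
    "PRO": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HG2", "HG3"), "CG", "sp3_2h"),
            (("HD2", "HD3"), "CD", "sp3_2h")),
    "SER": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HG",), "OG", "hydroxyl")),
    "THR": ((("HB",), "CB", "sp3_1h"),
            (("HG1",), "OG1", "hydroxyl"),
            (("HG21", "HG22", "HG23"), "CG2", "sp3_3h")),
    "TRP": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HD1",), "CD1", "sp2_1h"),
            (("HE1",), "NE1", "sp2_1h"),
            (("HE3",), "CE3", "sp2_1h"),
            (("HZ2",), "CZ2", "sp2_1h"),
            (("HZ3",), "CZ3", "sp2_1h"),
            (("HH2",), "CH2", "sp2_1h")),
    "TYR": ((("HB2", "HB3"), "CB", "sp3_2h"),
            (("HD1",), "CD1", "sp2_1h"),
            (("HD2",), "CD2", "sp2_1h"),
            (("HE1",), "CE1", "sp2_1h"),
            (("HE2",), "CE2", "sp2_1h"),
            (("HH",), "OH", "hydroxyl")),
    "VAL": ((("HB",), "CB", "sp3_1h"),
            (("HG11", "HG12", "HG13"), "CG1", "sp3_3h"),
            (("HG21", "HG22", "HG23"), "CG2", "sp3_3h")),
}

#: Neutral-His tautomer hydrogens: exactly one of these is placed, chosen
#: by the nearest-acceptor heuristic (default NE2 when neither wins).
HIS_TAUTOMER_H: dict[str, tuple[str, str]] = {
    "HD1": ("ND1", "sp2_1h"),
    "HE2": ("NE2", "sp2_1h"),
}

#: Standard X-H bond lengths in Angstrom, keyed by parent element.
XH_BOND_LENGTHS: dict[str, float] = {
    "C": 1.09,
    "N": 1.01,
    "O": 0.96,
    "S": 1.34,
    "B": 1.19,
}


def residue_bonds(resname: str) -> tuple[tuple[str, str], ...]:
    """All intra-residue heavy-atom bonds (backbone + side chain)."""
    if resname not in SIDECHAIN_BONDS:
        return ()
    return BACKBONE_BONDS + SIDECHAIN_BONDS[resname]


def heavy_neighbors(resname: str, atom_name: str) -> tuple[str, ...]:
    """Heavy atoms bonded to ``atom_name`` within the residue template."""
    out = []
    for a, b in residue_bonds(resname):
        if a == atom_name:
            out.append(b)
        elif b == atom_name:
            out.append(a)
    return tuple(out)
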