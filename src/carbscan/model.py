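"""Core structural containers: atoms, residues, structures, selections.

The hierarchy is deliberately simple — an ordered list of residues each
holding an ordered list of atoms — because every analysis in this package
(superposition, contact enumeration, energy decomposition) walks residues
and atoms linearly. Coordinates are in Angstrom, residue numbering follows
the author (deposited) numbering throughout, and ranges are inclusive.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "AtomSelection",
    "METAL_ELEMENTS",
    "WATER_NAMES",
    "STANDARD_AMINO_ACIDS",
    "parse_selection",
]

#: Elements flagged as metals when they constitute a single-atom residue.
METAL_ELEMENTS = frozenset(
    {"ZN", "MG", "MN", "FE", "CU", "NI", "CO", "CA", "NA", "K", "HG", "CD"}
)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)


@dataclass
class Atom:
    """One atom: label, element, position (Angstrom), occupancy, isotropic ADP."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    adp: float = 0.0
    altloc: str = ""
    charge: Optional[float] = None
    vdw_type: Optional[str] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")
        self.element = self.element.upper()

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def copy(self) -> "Atom":
        a = _copy.copy(self)
        a.position = self.position.copy()
        return a


@dataclass
class Residue:
    """A residue (amino acid, ligand, water, or metal ion) with ordered atoms."""

    chain_id: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_amino_acid(self) -> bool:
        return self.name in STANDARD_AMINO_ACIDS

    @property
    def is_metal(self) -> bool:
        return len(self.atoms) == 1 and self.atoms[0].element in METAL_ELEMENTS

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def copy(self) -> "Residue":
        return Residue(
            chain_id=self.chain_id,
            number=self.number,
            name=self.name,
            atoms=[a.copy() for a in self.atoms],
            insertion_code=self.insertion_code,
        )


@dataclass
class Structure:
    """Ordered collection of residues with provenance.

    Metals are single-atom residues of metallic elements; waters are residues
    named HOH/WAT. Every atom is reachable through exactly one residue.
    """

    residues: list[Residue] = field(default_factory=list)
    source_id: str = ""

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def metals(self) -> list[Residue]:
        return [r for r in self.residues if r.is_metal]

    @property
    def waters(self) -> list[Residue]:
        return [r for r in self.residues if r.is_water]

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def find_residue(
        self, chain_id: str, number: int, insertion_code: str = ""
    ) -> Optional[Residue]:
        for r in self.residues:
            if r.key == (chain_id, number, insertion_code):
                return r
        return None

    def residues_named(self, name: str) -> list[Residue]:
        return [r for r in self.residues if r.name == name]

    def copy(self) -> "Structure":
        return Structure(
            residues=[r.copy() for r in self.residues], source_id=self.source_id
        )

    def coordinates(self) -> np.ndarray:
        """All atom positions as an (N, 3) array in residue/atom order."""
        if self.n_atoms() == 0:
            return np.zeros((0, 3))
        return np.array([a.position for _, a in self.atoms()])

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            if r.key in seen:
                raise ValueError(f"duplicate residue key {r.key}")
            seen.add(r.key)
            names: set[tuple[str, str]] = set()
            for a in r.atoms:
                k = (a.name, a.altloc)
                if k in names:
                    raise ValueError(
                        f"duplicate atom name {a.name!r} (altloc {a.altloc!r}) in {r.key}"
                    )
                names.add(k)


@dataclass(frozen=True)
class AtomSelection:
    """Declarative atom filter; all clauses must match (logical AND).

    ``residue_ranges`` are inclusive (author numbering). An empty selection
    matches every atom. Applying a selection twice equals applying it once.
    """

    chains: Optional[frozenset[str]] = None
    residue_ranges: Optional[tuple[tuple[int, int], ...]] = None
    residue_names: Optional[frozenset[str]] = None
    atom_names: Optional[frozenset[str]] = None
    elements: Optional[frozenset[str]] = None
    include_hydrogens: bool = True

    @staticmethod
    def make(
        chains: Optional[Iterable[str]] = None,
        residue_ranges: Optional[Iterable[tuple[int, int]]] = None,
        residue_names: Optional[Iterable[str]] = None,
        atom_names: Optional[Iterable[str]] = None,
        elements: Optional[Iterable[str]] = None,
        include_hydrogens: bool = True,
    ) -> "AtomSelection":
        return AtomSelection(
            chains=frozenset(chains) if chains is not None else None,
            residue_ranges=tuple(sorted(tuple(r) for r in residue_ranges))
            if residue_ranges is not None
            else None,
            residue_names=frozenset(n.upper() for n in residue_names)
            if residue_names is not None
            else None,
            atom_names=frozenset(n.upper() for n in atom_names)
            if atom_names is not None
            else None,
            elements=frozenset(e.upper() for e in elements)
            if elements is not None
            else None,
            include_hydrogens=include_hydrogens,
        )

    def matches_residue(self, r: Residue) -> bool:
        if self.chains is not None and r.chain_id not in self.chains:
            return False
        if self.residue_ranges is not None and not any(
            lo <= r.number <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.residue_names is not None and r.name not in self.residue_names:
            return False
        return True

    def matches_atom(self, a: Atom) -> bool:
        if not self.include_hydrogens and a.is_hydrogen:
            return False
        if self.atom_names is not None and a.name.upper() not in self.atom_names:
            return False
        if self.elements is not None and a.element not in self.elements:
            return False
        return True


def select_atoms(
    s: Structure, sel: Optional[AtomSelection] = None
) -> list[tuple[Residue, Atom]]:
    """Atoms of ``s`` matching ``sel`` in deterministic residue/atom order.

    A selection naming a chain absent from the structure yields an empty
    result (not an error). ``sel=None`` selects everything.
    """
    if sel is None:
        sel = AtomSelection()
    out: list[tuple[Residue, Atom]] = []
    for r in s.residues:
        if not sel.matches_residue(r):
            continue
        for a in r.atoms:
            if sel.matches_atom(a):
                out.append((r, a))
    return out


_RANGE_RE = re.compile(r"^(-?\d+)-(-?\d+)$")
_NUM_RE = re.compile(r"^-?\d+$")

#: Common atom-name tokens accepted by the string selection mini-language.
_ATOM_TOKENS = {"CA", "CB", "N", "C", "O", "CG", "OG", "OG1", "NE2", "OE1", "ZN"}


def parse_selection(text: str) -> AtomSelection:
    """Parse the CLI selection mini-language, e.g. ``"ca,4-261"``.

    Comma-separated tokens: ``N-M`` → inclusive residue range; a bare integer
    → single-residue range; a 3-letter residue code (e.g. ``THR``) → residue
    name; anything else → atom name (``ca`` means the C-alpha atom ``CA``).
    """
    ranges: list[tuple[int, int]] = []
    resnames: list[str] = []
    atnames: list[str] = []
    chains: list[str] = []
    for raw in text.split(","):
        tok = raw.strip()
        if not tok:
            continue
        m = _RANGE_RE.match(tok)
        if m:
            ranges.append((int(m.group(1)), int(m.group(2))))
            continue
        if _NUM_RE.match(tok):
            n = int(tok)
            ranges.append((n, n))
            continue
        up = tok.upper()
        if up.startswith("CHAIN:"):
            chains.append(up.split(":", 1)[1])
        elif len(up) == 3 and (up in STANDARD_AMINO_ACIDS or up in WATER_NAMES):
            resnames.append(up)
        else:
            atnames.append(up)
    return AtomSelection.make(
        chains=chains or None,
        residue_ranges=ranges or None,
        residue_names=resnames or None,
        atom_names=atnames or None,
    )
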