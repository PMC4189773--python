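"""Least-squares rigid-body superposition and deviation analysis.

The fit is the classical Kabsch solution: center both point sets, take the
SVD of the covariance matrix, and correct the sign of the smallest singular
direction so that the rotation is proper (det +1, reflections excluded).
Structure-level pairing is by (chain, residue number, insertion code, atom
name); atoms present on only one side are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateGeometryError, PairingError
from .model import AtomSelection, Structure, select_atoms

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "kabsch_fit",
    "rmsd",
    "superpose_structures",
    "per_residue_deviation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        R = self.rotation
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) not allowed")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int


def kabsch_fit(ref: np.ndarray, mov: np.ndarray) -> RigidTransform:
    """Proper rotation + translation minimizing ||R @ mov + t - ref||^2.

    Requires at least 3 non-collinear point pairs. Reflections are excluded
    by construction (determinant correction on the SVD).
    """
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise PairingError(
            f"point sets must be matching (N, 3) arrays; got {ref.shape} vs {mov.shape}"
        )
    n = ref.shape[0]
    if n < 3:
        raise PairingError(f"need >= 3 point pairs for a determined fit, got {n}")
    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    H = (mov - cm).T @ (ref - cr)
    U, S, Vt = np.linalg.svd(H)
    # Collinear/degenerate sets leave the rotation about the line undetermined.
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise DegenerateGeometryError("point set is (nearly) collinear; fit underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return RigidTransform(R, t)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation of paired coordinates (no fitting)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise PairingError(f"coordinate lists must match; got {a.shape} vs {b.shape}")
    if a.shape[0] == 0:
        raise PairingError("empty coordinate lists")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _paired_coordinates(
    ref: Structure, mov: Structure, sel: Optional[AtomSelection]
) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    """Pair atoms by (chain, number, icode, atom name) under ``sel``."""
    def index(s: Structure) -> dict[tuple, np.ndarray]:
        out: dict[tuple, np.ndarray] = {}
        for r, a in select_atoms(s, sel):
            key = (r.chain_id, r.number, r.insertion_code, a.name)
            if key in out:
                raise PairingError(f"ambiguous pairing: duplicate atom key {key}")
            out[key] = a.position
        return out

    ri = index(ref)
    mi = index(mov)
    keys = [k for k in ri if k in mi]
    dropped = (len(ri) - len(keys)) + (len(mi) - len(keys))
    if dropped:
        logger.info("superposition pairing dropped %d unmatched atoms", dropped)
    ra = np.array([ri[k] for k in keys]).reshape(-1, 3)
    ma = np.array([mi[k] for k in keys]).reshape(-1, 3)
    return ra, ma, keys


def superpose_structures(
    ref: Structure, mov: Structure, sel: Optional[AtomSelection] = None
) -> SuperpositionResult:
    """Fit ``mov`` onto ``ref`` over the selection and report the RMSD.

    The returned transform maps any coordinates of ``mov`` into the frame
    of ``ref`` — e.g. to carry a ligand along without refitting.
    """
    ra, ma, keys = _paired_coordinates(ref, mov, sel)
    if len(keys) < 3:
        raise PairingError(f"only {len(keys)} paired atoms; need >= 3")
    tr = kabsch_fit(ra, ma)
    return SuperpositionResult(transform=tr, rmsd=rmsd(ra, tr.apply(ma)), n_atoms=len(keys))


def per_residue_deviation(
    ref: Structure,
    mov: Structure,
    sel: Optional[AtomSelection] = None,
    fit_sel: Optional[AtomSelection] = None,
) -> dict[tuple[str, int, str], float]:
    """Per-residue deviation (A) after superposing on ``fit_sel``.

    ``sel`` names the reported atoms (typically C-alpha); for residues with
    several selected atoms, the mean per-atom distance is reported. Residues
    present in only one structure are omitted with a warning.
    """
    fit = superpose_structures(ref, mov, fit_sel)
    ra, ma, keys = _paired_coordinates(ref, mov, sel)
    if len(keys) == 0:
        return {}
    moved = fit.transform.apply(ma)
    dist = np.linalg.norm(ra - moved, axis=1)
    out: dict[tuple[str, int, str], list[float]] = {}
    for k, d in zip(keys, dist):
        out.setdefault((k[0], k[1], k[2]), []).append(float(d))
    return {rk: float(np.mean(v)) for rk, v in out.items()}
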