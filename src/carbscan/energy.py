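"""Classical nonbonded interaction-energy model with per-residue breakdown.

The ligand-environment interaction energy (the quantity written dG_int'
in computational mutagenesis work) is evaluated as a pairwise-additive sum
of Coulomb and Lennard-Jones terms over all (ligand atom, residue atom)
pairs:

    E_pair = 332.0637 * q_i * q_j / (eps(r) * r)
             + 4 * eps_ij * [(sigma_ij / r)^12 - (sigma_ij / r)^6]

with Lorentz-Berthelot combination (arithmetic sigma, geometric epsilon)
and, by default, a distance-dependent dielectric eps(r) = 4r that mimics
solvent screening in an open binding site. No cutoff is applied: the
intended systems are active-site-scale. Parameters ship in
``data/forcefield.yaml``; see that file for conventions.

This model is a desk-scale classical surrogate for hybrid QM/MM
interaction free energies: it preserves ranks, additivity and geometry
sensitivity, not absolute kcal/mol magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ParameterizationError
from .ligand import COMPOUND1, LigandTemplate
from .model import Atom, Residue, Structure

__all__ = [
    "ForceFieldParameters",
    "EnergyBreakdown",
    "load_default_forcefield",
    "assign_parameters",
    "pair_energy",
    "interaction_energy",
    "COULOMB_CONSTANT",
]

COULOMB_CONSTANT = 332.0637  # kcal*A/(mol*e^2)


@dataclass(frozen=True)
class ForceFieldParameters:
    """Nonbonded parameter tables: LJ types, per-(residue, atom) charges."""

    vdw_types: dict[str, tuple[float, float]]  # type -> (epsilon, sigma)
    residue_params: dict[str, dict[str, tuple[float, str]]]
    dielectric_model: str = "distance_dependent"  # or "constant"
    dielectric_k: float = 4.0
    coulomb_constant: float = COULOMB_CONSTANT

    @staticmethod
    def from_file(path) -> "ForceFieldParameters":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return ForceFieldParameters._from_dict(raw)

    @staticmethod
    def _from_dict(raw: dict) -> "ForceFieldParameters":
        vdw = {
            t: (float(v["epsilon"]), float(v["sigma"]))
            for t, v in raw["vdw_types"].items()
        }
        for t, (eps, sig) in vdw.items():
            if eps < 0 or sig <= 0:
                raise ValueError(f"invalid LJ parameters for type {t}")
        res = {
            rn: {an: (float(v["charge"]), str(v["type"])) for an, v in atoms.items()}
            for rn, atoms in raw["residues"].items()
        }
        die = raw.get("dielectric", {})
        return ForceFieldParameters(
            vdw_types=vdw,
            residue_params=res,
            dielectric_model=die.get("model", "distance_dependent"),
            dielectric_k=float(die.get("k", 4.0)),
            coulomb_constant=float(raw.get("coulomb_constant", COULOMB_CONSTANT)),
        )

    def epsilon_of_r(self, r: float) -> float:
        if self.dielectric_model == "distance_dependent":
            return self.dielectric_k * r
        return self.dielectric_k


def load_default_forcefield() -> ForceFieldParameters:
    """The parameter set bundled with the package."""
    ref = resources.files("carbscan").joinpath("data/forcefield.yaml")
    with resources.as_file(ref) as path:
        return ForceFieldParameters.from_file(path)


def assign_parameters(
    s: Structure,
    ff: Optional[ForceFieldParameters] = None,
    ligand_templates: Optional[dict[str, LigandTemplate]] = None,
) -> Structure:
    """Return a copy of ``s`` with charge and vdW type set on every atom.

    Ligand residues are parameterized from their templates (resname ->
    template; residues containing the full carborane cage default to the
    compound-1 template). Unparameterized atoms are collected and reported
    together in a single :class:`ParameterizationError`.
    """
    ff = ff or load_default_forcefield()
    ligand_templates = dict(ligand_templates or {})
    out = s.copy()
    offenders: list[str] = []
    cage_names = set(COMPOUND1.cage_atom_names)
    for res in out.residues:
        tmpl: Optional[LigandTemplate] = ligand_templates.get(res.name)
        if tmpl is None and cage_names <= {a.name for a in res.atoms}:
            tmpl = COMPOUND1
        if tmpl is not None:
            for a in res.atoms:
                cn = tmpl.canonical_name(a.name)
                if cn in tmpl.charges:
                    a.charge = tmpl.charges[cn]
                    a.vdw_type = tmpl.vdw_types[cn]
                else:
                    offenders.append(f"{res.name}{res.number}:{a.name}")
            continue
        table = ff.residue_params.get(res.name)
        if table is None and res.is_water:
            table = ff.residue_params.get("HOH")
        if table is None:
            offenders.extend(f"{res.name}{res.number}:{a.name}" for a in res.atoms)
            continue
        for a in res.atoms:
            entry = table.get(a.name)
            if entry is None and res.is_water and a.element == "O":
                entry = table.get("O")
            if entry is None:
                offenders.append(f"{res.name}{res.number}:{a.name}")
            else:
                a.charge, a.vdw_type = entry
    if offenders:
        raise ParameterizationError(offenders)
    return out


def _lj_params(ff: ForceFieldParameters, ti: str, tj: str) -> tuple[float, float]:
    ei, si = ff.vdw_types[ti]
    ej, sj = ff.vdw_types[tj]
    return math.sqrt(ei * ej), 0.5 * (si + sj)


def pair_energy(
    i: Atom, j: Atom, ff: Optional[ForceFieldParameters] = None
) -> float:
    """Nonbonded pair energy in kcal/mol; symmetric in its arguments."""
    ff = ff or load_default_forcefield()
    if i.charge is None or j.charge is None or i.vdw_type is None or j.vdw_type is None:
        raise ParameterizationError(
            [a.name for a in (i, j) if a.charge is None or a.vdw_type is None]
        )
    r = float(np.linalg.norm(i.position - j.position))
    if r < 1e-9:
        raise ZeroDivisionError("coincident atoms: pair energy singular at r=0")
    elec = ff.coulomb_constant * i.charge * j.charge / (ff.epsilon_of_r(r) * r)
    eps, sig = _lj_params(ff, i.vdw_type, j.vdw_type)
    sr6 = (sig / r) ** 6
    vdw = 4.0 * eps * (sr6 * sr6 - sr6)
    return elec + vdw


@dataclass
class EnergyBreakdown:
    """Per-residue interaction-energy components, kcal/mol.

    ``per_residue`` maps residue key -> (electrostatic, vdw, total); the
    grand total equals the sum of per-residue totals by construction.
    """

    per_residue: dict[tuple, tuple[float, float, float]] = field(default_factory=dict)
    residue_names: dict[tuple, str] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(v[2] for v in self.per_residue.values()))

    @property
    def electrostatic(self) -> float:
        return float(sum(v[0] for v in self.per_residue.values()))

    @property
    def vdw(self) -> float:
        return float(sum(v[1] for v in self.per_residue.values()))


def interaction_energy(
    ligand_atoms: Sequence[Atom],
    environment: Structure,
    ff: Optional[ForceFieldParameters] = None,
) -> EnergyBreakdown:
    """Ligand-environment interaction energy decomposed per residue.

    ``ligand_atoms`` and the atoms of ``environment`` must be disjoint
    sets; every (ligand atom, residue atom) pair contributes (no cutoff).
    """
    ff = ff or load_default_forcefield()
    lig_ids = {id(a) for a in ligand_atoms}
    for r, a in environment.atoms():
        if id(a) in lig_ids:
            raise ValueError(
                f"ligand atom {a.name} also present in environment residue {r.key}"
            )
    lq = np.array([a.charge for a in ligand_atoms], dtype=float)
    lx = np.array([a.position for a in ligand_atoms])
    if np.any(np.isnan(lq)):
        raise ParameterizationError([a.name for a in ligand_atoms if a.charge is None])
    leps = np.array([ff.vdw_types[a.vdw_type][0] for a in ligand_atoms])
    lsig = np.array([ff.vdw_types[a.vdw_type][1] for a in ligand_atoms])

    out = EnergyBreakdown()
    for res in environment.residues:
        if not res.atoms:
            continue
        rq = np.array([a.charge if a.charge is not None else np.nan for a in res.atoms])
        if np.any(np.isnan(rq)):
            raise ParameterizationError(
                [f"{res.name}{res.number}:{a.name}" for a in res.atoms if a.charge is None]
            )
        rx = np.array([a.position for a in res.atoms])
        reps = np.array([ff.vdw_types[a.vdw_type][0] for a in res.atoms])
        rsig = np.array([ff.vdw_types[a.vdw_type][1] for a in res.atoms])

        d = np.linalg.norm(lx[:, None, :] - rx[None, :, :], axis=-1)
        if np.any(d < 1e-9):
            raise ZeroDivisionError(
                f"coincident ligand/environment atoms in residue {res.key}"
            )
        if ff.dielectric_model == "distance_dependent":
            elec = ff.coulomb_constant * np.outer(lq, rq) / (ff.dielectric_k * d * d)
        else:
            elec = ff.coulomb_constant * np.outer(lq, rq) / (ff.dielectric_k * d)
        eps = np.sqrt(np.outer(leps, reps))
        sig = 0.5 * (lsig[:, None] + rsig[None, :])
        sr6 = (sig / d) ** 6
        vdw = 4.0 * eps * (sr6 * sr6 - sr6)
        e, v = float(elec.sum()), float(vdw.sum())
        out.per_residue[res.key] = (e, v, e + v)
        out.residue_names[res.key] = res.name
    return out
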