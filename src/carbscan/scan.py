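"""Virtual glycine scan and end-to-end analysis pipelines.

The glycine scan quantifies each binding-site side chain's contribution
to ligand binding: residue by residue, the side chain is truncated to
glycine and the ligand-environment interaction energy dG_int' recomputed.
The reported value is the side-chain contribution

    ddG_int' = dG_int'(glycine mutant) - dG_int'(wild type)

with interaction energies negative-favorable, so a positive ddG_int'
means the side chain favors binding (strong contributors plot as positive
bars). The default mode
is rigid (no re-relaxation after truncation) — deterministic and standard
for computational alanine/glycine scanning; ``relaxed`` re-relaxes the
movable set for each mutant.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import __about__
from .contacts import (
    classify_contacts,
    detect_dihydrogen_bonds,
    enumerate_contacts,
    write_contact_table,
)
from .energy import (
    EnergyBreakdown,
    ForceFieldParameters,
    assign_parameters,
    interaction_energy,
    load_default_forcefield,
)
from .errors import TopologyError
from .io import read_structure, write_structure
from .ligand import COMPOUND1, LigandTemplate
from .model import AtomSelection, Residue, Structure, select_atoms
from .prep import GraftRecipe, add_hydrogens, binding_site_substitutions, graft_ligand, truncate_to_glycine
from .relax import MinimizerSettings, relax_binding_site
from .superpose import superpose_structures

__all__ = [
    "ScanResult",
    "PipelineConfig",
    "glycine_scan",
    "run_caii_analysis",
    "run_caix_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """Per-residue ddG_int' (kcal/mol) with scan metadata."""

    values: dict[tuple, float] = field(default_factory=dict)
    residue_names: dict[tuple, str] = field(default_factory=dict)
    wild_type_total: float = 0.0
    mode: str = "rigid"
    energy_model: str = "carbscan-nonbonded"

    def ranked(self) -> list[tuple[tuple, str, float]]:
        """Residues sorted by descending side-chain contribution."""
        return sorted(
            (
                (k, self.residue_names.get(k, "?"), v)
                for k, v in self.values.items()
            ),
            key=lambda kv: -kv[2],
        )


def _split_ligand(
    s: Structure, ligand_sel: AtomSelection
) -> tuple[list, Structure]:
    """(ligand atoms, environment structure without the ligand residues)."""
    lig_keys = {r.key for r, _ in select_atoms(s, ligand_sel)}
    if not lig_keys:
        raise TopologyError("ligand selection matched nothing")
    lig_atoms = [a for r, a in s.atoms() if r.key in lig_keys]
    env = Structure(
        residues=[r for r in s.residues if r.key not in lig_keys],
        source_id=s.source_id,
    )
    return lig_atoms, env


def glycine_scan(
    complex_structure: Structure,
    residues: Sequence[tuple],
    ligand_sel: AtomSelection,
    ff: Optional[ForceFieldParameters] = None,
    mode: str = "rigid",
    movable_residues: Optional[Sequence[tuple]] = None,
    settings: Optional[MinimizerSettings] = None,
    ligand_templates: Optional[dict[str, LigandTemplate]] = None,
) -> ScanResult:
    """Scan the listed residues (keys) by truncation to glycine.

    The complex must be protonated; parameters are assigned internally.
    Residues already glycine report exactly 0. Mutations are independent:
    the wild-type complex is restored between residues, and the result
    does not depend on scan order.
    """
    if mode not in ("rigid", "relaxed"):
        raise ValueError(f"unknown scan mode {mode!r}")
    ff = ff or load_default_forcefield()
    keys = [tuple(k) if len(k) == 3 else (k[0], k[1], "") for k in residues]
    param = assign_parameters(complex_structure, ff, ligand_templates)
    lig_atoms, env = _split_ligand(param, ligand_sel)
    wt = interaction_energy(lig_atoms, env, ff)

    result = ScanResult(mode=mode, wild_type_total=wt.total)
    for key in keys:
        res = complex_structure.find_residue(*key)
        if res is None:
            raise TopologyError(f"scan residue {key} not in structure")
        result.residue_names[key] = res.name
        if res.name == "GLY":
            result.values[key] = 0.0
            continue
        if key not in wt.per_residue:
            logger.info("scan residue %s has no contact with the ligand selection", key)
        mutant = truncate_to_glycine(complex_structure, key)
        if mode == "relaxed":
            mutant = assign_parameters(mutant, ff, ligand_templates)
            movable = list(movable_residues or []) or [key]
            mutant, _ = relax_binding_site(
                mutant, movable, ff, settings, ligand_templates
            )
        else:
            mutant = assign_parameters(mutant, ff, ligand_templates)
        m_lig, m_env = _split_ligand(mutant, ligand_sel)
        mut = interaction_energy(m_lig, m_env, ff)
        result.values[key] = mut.total - wt.total
    return result


@dataclass
class PipelineConfig:
    """Inputs and knobs for the end-to-end analyses.

    Structures may be given as paths (read at run time) or in-memory
    objects. Residue lists are residue keys (chain, number[, icode]).
    """

    complex_path: Optional[str] = None
    complex_structure: Optional[Structure] = None
    template_path: Optional[str] = None
    template_structure: Optional[Structure] = None
    target_path: Optional[str] = None
    target_structure: Optional[Structure] = None
    ligand_resname: str = "LIG"
    fit_selection: Optional[AtomSelection] = None
    movable_residues: tuple = ()
    scanned_residues: tuple = ()
    contact_cutoff: float = 4.0
    relax: bool = True
    scan_mode: str = "rigid"
    keep_waters: tuple[int, ...] = ()
    output_dir: str = "carbscan_out"
    ligand_templates: dict[str, LigandTemplate] = field(default_factory=dict)

    def ligand_selection(self) -> AtomSelection:
        return AtomSelection.make(residue_names=[self.ligand_resname])

    def resolve_complex(self) -> Structure:
        if self.complex_structure is not None:
            return self.complex_structure
        if self.complex_path:
            return read_structure(self.complex_path)
        raise ValueError("config has neither complex_path nor complex_structure")

    def resolve_template(self) -> Structure:
        if self.template_structure is not None:
            return self.template_structure
        if self.template_path:
            return read_structure(self.template_path)
        raise ValueError("config has neither template_path nor template_structure")

    def resolve_target(self) -> Structure:
        if self.target_structure is not None:
            return self.target_structure
        if self.target_path:
            return read_structure(self.target_path)
        raise ValueError("config has neither target_path nor target_structure")

    def templates(self) -> dict[str, LigandTemplate]:
        t = dict(self.ligand_templates)
        t.setdefault(self.ligand_resname, COMPOUND1)
        return t


def _write_manifest(outdir: str, payload: dict) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def _scan_table(path: str, scans: dict[str, ScanResult]) -> None:
    labels = sorted(scans)
    keys = sorted({k for s in scans.values() for k in s.values},
                  key=lambda k: (k[0], k[1]))
    with open(path, "w") as fh:
        fh.write("residue\tname\t" + "\t".join(f"ddG_{l}" for l in labels) + "\n")
        for k in keys:
            name = next(
                (s.residue_names.get(k) for s in scans.values() if k in s.residue_names),
                "?",
            )
            cells = [
                f"{s.values[k]:.4f}" if k in s.values else ""
                for s in (scans[l] for l in labels)
            ]
            fh.write(f"{k[0]}{k[1]}\t{name}\t" + "\t".join(cells) + "\n")


def _default_scan_residues(
    s: Structure, ligand_sel: AtomSelection, cutoff: float
) -> list[tuple]:
    """All standard residues with any heavy-atom contact <= cutoff."""
    recs = enumerate_contacts(s, ligand_sel, cutoff)
    out = []
    for c in recs:
        for r in s.residues:
            if (r.chain_id, r.number) == (c.chain_id, c.residue_number):
                if r.is_amino_acid and r.key not in out:
                    out.append(r.key)
    return out


def run_caii_analysis(config: PipelineConfig) -> dict:
    """Contact + dihydrogen-bond + glycine-scan report for one complex.

    Emits a contact TSV, a dihydrogen-bond list, a polar/vdW summary and
    glycine-scan bar data under ``config.output_dir``; returns the bundle.
    """
    s = config.resolve_complex()
    ligand_sel = config.ligand_selection()
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)

    contacts = classify_contacts(
        enumerate_contacts(s, ligand_sel, config.contact_cutoff), s
    )
    write_contact_table(contacts, os.path.join(outdir, "contacts.tsv"))
    n_polar = sum(1 for c in contacts if c.contact_class == "polar")
    n_metal = sum(1 for c in contacts if c.contact_class == "metal_coordination")

    prot = add_hydrogens(s, config.templates())
    dihydrogen = detect_dihydrogen_bonds(prot, ligand_sel)
    with open(os.path.join(outdir, "dihydrogen_bonds.tsv"), "w") as fh:
        fh.write("donor_residue\tdonor\tprotic_H\thydridic_H\tacceptor\thh_distance\t"
                 "donor_angle\tacceptor_angle\n")
        for b in dihydrogen:
            fh.write(
                f"{b.protic_residue[0]}{b.protic_residue[1]}\t{b.donor_atom}\t"
                f"{b.protic_H}\t{b.hydridic_H}\t{b.acceptor_atom}\t"
                f"{b.hh_distance:.2f}\t{b.donor_angle:.1f}\t{b.acceptor_angle:.1f}\n"
            )

    scanned = list(config.scanned_residues) or _default_scan_residues(
        s, ligand_sel, config.contact_cutoff
    )
    scan = None
    if scanned:
        scan = glycine_scan(
            prot, scanned, ligand_sel,
            mode=config.scan_mode,
            movable_residues=config.movable_residues or None,
            ligand_templates=config.templates(),
        )
        _scan_table(os.path.join(outdir, "glycine_scan.tsv"), {"complex": scan})

    _write_manifest(outdir, {
        "tool": "carbscan", "version": __about__.__version__,
        "analysis": "single-complex", "source": s.source_id,
        "cutoff": config.contact_cutoff,
        "n_contacts": len(contacts), "n_polar": n_polar, "n_metal": n_metal,
        "n_dihydrogen_bonds": len(dihydrogen),
        "scanned_residues": [list(k) for k in scanned],
        "scan_mode": config.scan_mode,
    })
    return {
        "contacts": contacts,
        "dihydrogen_bonds": dihydrogen,
        "scan": scan,
        "summary": {"n_polar": n_polar, "n_metal": n_metal,
                    "n_contacts": len(contacts)},
        "output_dir": outdir,
    }


def run_caix_pipeline(config: PipelineConfig) -> dict:
    """Template-based modeling of a homologous complex plus comparison.

    Grafts the template's ligand (and named bridging waters) into the
    target, relaxes the movable set, and reports: the modeled complex
    file, its contact table, the binding-site substitution list, glycine
    scans of both complexes side by side, and the ligand displacement
    between the grafted and relaxed pose (measured at the cage antipode
    B12 when present).
    """
    template = config.resolve_template()
    target = config.resolve_target()
    ligand_sel = config.ligand_selection()
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)

    recipe = GraftRecipe(
        template_complex=template,
        target_protein=target,
        fit_selection=config.fit_selection or AtomSelection.make(atom_names=["CA"]),
        ligand_selection=ligand_sel,
        water_numbers=tuple(config.keep_waters),
    )
    modeled, provenance = graft_ligand(recipe)
    grafted_pose = {
        a.name: a.position.copy()
        for r, a in select_atoms(modeled, ligand_sel)
    }

    modeled = add_hydrogens(modeled, config.templates())
    relax_info = None
    if config.relax and config.movable_residues:
        ff = load_default_forcefield()
        param = assign_parameters(modeled, ff, config.templates())
        movable = list(config.movable_residues)
        # the grafted ligand moves too
        movable += [r.key for r, _ in select_atoms(modeled, ligand_sel)]
        movable = list(dict.fromkeys(movable))
        param, relax_info = relax_binding_site(
            param, movable, ff, ligand_templates=config.templates()
        )
        modeled = param

    model_path = os.path.join(outdir, "modeled_complex.pdb")
    write_structure(modeled, model_path, format="pdb")

    contacts = classify_contacts(
        enumerate_contacts(modeled, ligand_sel, config.contact_cutoff), modeled
    )
    write_contact_table(contacts, os.path.join(outdir, "model_contacts.tsv"))

    site_numbers = sorted({c.residue_number for c in contacts})
    site_sel = AtomSelection.make(
        residue_ranges=[(n, n) for n in site_numbers]
    ) if site_numbers else None
    subs, unmatched = binding_site_substitutions(
        template, target, site_sel=None, fit_sel=recipe.fit_selection
    )

    # displacement of the relaxed pose vs the grafted pose
    probe_atom = "B12" if "B12" in grafted_pose else next(iter(grafted_pose))
    relaxed_pose = {
        a.name: a.position for r, a in select_atoms(modeled, ligand_sel)
    }
    displacement = float(
        np.linalg.norm(relaxed_pose[probe_atom] - grafted_pose[probe_atom])
    )

    scans: dict[str, ScanResult] = {}
    template_prot = add_hydrogens(template, config.templates())
    t_scanned = _default_scan_residues(template_prot, ligand_sel, config.contact_cutoff)
    if t_scanned:
        scans["template"] = glycine_scan(
            template_prot, t_scanned, ligand_sel, mode=config.scan_mode,
            ligand_templates=config.templates(),
        )
    m_scanned = list(config.scanned_residues) or _default_scan_residues(
        modeled, ligand_sel, config.contact_cutoff
    )
    if m_scanned:
        scans["model"] = glycine_scan(
            modeled, m_scanned, ligand_sel, mode=config.scan_mode,
            ligand_templates=config.templates(),
        )
    if scans:
        _scan_table(os.path.join(outdir, "glycine_scan.tsv"), scans)
        if "model" in scans:
            ranked = scans["model"].ranked()
            top = [f"{n}{k[1]}" for k, n, _v in ranked[:3]]
            logger.info("top model scan contributors: %s", top)

    _write_manifest(outdir, {
        "tool": "carbscan", "version": __about__.__version__,
        "analysis": "template-graft-pipeline",
        "template": template.source_id, "target": target.source_id,
        "fit_rmsd": provenance["fit_rmsd"],
        "clashes": provenance["clashes"],
        "relax": relax_info,
        "displacement_atom": probe_atom,
        "ligand_displacement": displacement,
        "substitutions": subs, "unmatched_site_residues": unmatched,
    })
    return {
        "modeled_complex": modeled,
        "model_path": model_path,
        "provenance": provenance,
        "relax_info": relax_info,
        "contacts": contacts,
        "substitutions": subs,
        "unmatched": unmatched,
        "scans": scans,
        "ligand_displacement": displacement,
        "displacement_atom": probe_atom,
        "output_dir": outdir,
    }
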