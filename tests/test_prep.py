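"""Hydrogen placement, glycine truncation, grafting, substitutions."""

import math

import numpy as np
import pytest

from carbscan import (
    AtomSelection,
    COMPOUND1,
    FixtureSpec,
    GraftRecipe,
    add_hydrogens,
    binding_site_substitutions,
    graft_ligand,
    make_homolog_pair,
    make_toy_complex,
    truncate_to_glycine,
)
from carbscan.errors import TopologyError
from carbscan.fixtures import build_residue
from carbscan.model import Structure

LIG_SEL = AtomSelection.make(residue_names=["LIG"])
CA_SEL = AtomSelection.make(atom_names=["CA"])


def test_hydrogens_never_move_heavy_atoms(toy_complex):
    s, _ = toy_complex
    prot = add_hydrogens(s)
    heavy0 = np.array([a.position for _, a in s.atoms() if not a.is_hydrogen])
    heavy1 = np.array([a.position for _, a in prot.atoms() if not a.is_hydrogen])
    assert np.array_equal(heavy0, heavy1)


def test_ligand_cage_hydrogens_radial_and_counted(toy_complex):
    s, _ = toy_complex
    prot = add_hydrogens(s)
    lig = next(r for r in prot.residues if r.name == "LIG")
    hydrogens = [a for a in lig.atoms if a.is_hydrogen]
    # 10 B-H + 1 cage C-H + 2 methylene + 1 amide NH + 2 sulfamide NH2
    assert len(hydrogens) == 16
    cage_pos = np.array([
        lig.atom(n).position for n in COMPOUND1.cage_atom_names
    ])
    centroid = cage_pos.mean(axis=0)
    for i in range(3, 13):
        h = lig.atom(f"H{i}")
        b = lig.atom(f"B{i}")
        bl = float(np.linalg.norm(h.position - b.position))
        assert bl == pytest.approx(1.19, abs=0.01)
        radial = b.position - centroid
        bond = h.position - b.position
        cosang = np.dot(radial, bond) / (
            np.linalg.norm(radial) * np.linalg.norm(bond)
        )
        assert math.degrees(math.acos(min(1.0, cosang))) < 5.0


def test_glycine_gets_backbone_and_two_alpha_hydrogens():
    gly = build_residue("GLY", number=1)
    s = Structure(residues=[gly])
    prot = add_hydrogens(s)
    names = {a.name for a in prot.residues[0].atoms}
    assert {"H", "HA2", "HA3"} <= names


def test_add_hydrogens_is_idempotent(toy_complex):
    s, _ = toy_complex
    once = add_hydrogens(s)
    twice = add_hydrogens(once)
    assert twice.n_atoms() == once.n_atoms()


def test_placed_hydrogen_bond_lengths_are_standard(toy_complex):
    s, _ = toy_complex
    prot = add_hydrogens(s)
    expected = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34, "B": 1.19}
    for r in prot.residues:
        for a in r.atoms:
            if not a.is_hydrogen:
                continue
            parent = min(
                (x for x in r.atoms if not x.is_hydrogen),
                key=lambda x: np.linalg.norm(x.position - a.position),
            )
            bl = float(np.linalg.norm(parent.position - a.position))
            assert bl == pytest.approx(expected[parent.element], abs=0.02)


def test_truncate_trp_to_glycine_bookkeeping(toy_complex):
    s, _ = toy_complex
    trp = next(r for r in s.residues if r.name == "TRP")
    out = truncate_to_glycine(s, trp.key)
    mutant = out.find_residue(*trp.key)
    assert mutant.name == "GLY"
    assert {a.name for a in mutant.atoms if not a.is_hydrogen} == {"N", "CA", "C", "O"}
    assert mutant.atom("HA2") is not None
    for bb in ("N", "CA", "C", "O"):
        assert np.array_equal(mutant.atom(bb).position, trp.atom(bb).position)
    # everything else untouched
    for r0 in s.residues:
        if r0.key == trp.key:
            continue
        r1 = out.find_residue(*r0.key)
        for a0, a1 in zip(r0.atoms, r1.atoms):
            assert np.array_equal(a0.position, a1.position)


def test_truncate_glycine_is_a_noop_and_errors(toy_complex):
    s, _ = toy_complex
    trp = next(r for r in s.residues if r.name == "TRP")
    once = truncate_to_glycine(s, trp.key)
    again = truncate_to_glycine(once, trp.key)
    assert again.n_atoms() == once.n_atoms()
    lig = next(r for r in s.residues if r.name == "LIG")
    with pytest.raises(TypeError):
        truncate_to_glycine(s, lig.key)
    with pytest.raises(TopologyError):
        truncate_to_glycine(s, ("Z", 999))


def test_truncating_many_residues_is_order_independent(toy_complex):
    s, _ = toy_complex
    keys = [r.key for r in s.residues if r.is_amino_acid][:4]
    seq = s
    for k in keys:
        seq = truncate_to_glycine(seq, k)
    rev = s
    for k in reversed(keys):
        rev = truncate_to_glycine(rev, k)
    assert [(r.name, len(r.atoms)) for r in seq.residues] == \
        [(r.name, len(r.atoms)) for r in rev.residues]


def test_self_graft_reproduces_pose_exactly(toy_complex):
    s, _ = toy_complex
    apo = Structure(residues=[r.copy() for r in s.residues if r.name != "LIG"])
    recipe = GraftRecipe(
        template_complex=s, target_protein=apo,
        fit_selection=CA_SEL, ligand_selection=LIG_SEL,
    )
    modeled, prov = graft_ligand(recipe)
    assert prov["fit_rmsd"] < 1e-12
    lig0 = np.array([a.position for r in s.residues if r.name == "LIG"
                     for a in r.atoms])
    lig1 = np.array([a.position for r in modeled.residues if r.name == "LIG"
                     for a in r.atoms])
    np.testing.assert_allclose(lig1, lig0, atol=1e-10)


def test_graft_onto_rotated_target_recovers_engineered_pose(toy_complex):
    """In-memory rotated target: grafted ligand lands on the engineered
    coordinates to 1e-8 (constructed oracle)."""
    s, _ = toy_complex
    rng = np.random.default_rng(31)
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(size=3) * 15.0
    target = Structure(residues=[
        r.copy() for r in s.residues if r.name != "LIG"
    ])
    for r in target.residues:
        for a in r.atoms:
            a.position = R @ a.position + t
    modeled, prov = graft_ligand(GraftRecipe(
        template_complex=s, target_protein=target,
        fit_selection=CA_SEL, ligand_selection=LIG_SEL,
    ))
    assert prov["fit_rmsd"] < 1e-9
    for r0 in s.residues:
        if r0.name != "LIG":
            continue
        grafted = next(r for r in modeled.residues if r.name == "LIG")
        for a0, a1 in zip(r0.atoms, grafted.atoms):
            np.testing.assert_allclose(
                a1.position, R @ a0.position + t, atol=1e-8
            )


def test_graft_reports_clashes_without_failing(toy_complex, caplog):
    s, _ = toy_complex
    apo = Structure(residues=[r.copy() for r in s.residues if r.name != "LIG"])
    lig = next(r for r in s.residues if r.name == "LIG")
    clasher = apo.residues[0].copy()
    clasher.number = 99
    offset = lig.atoms[0].position - clasher.atoms[0].position
    for a in clasher.atoms:
        a.position = a.position + offset + np.array([0.5, 0.0, 0.0])
    apo.residues.append(clasher)
    _, prov = graft_ligand(GraftRecipe(
        template_complex=s, target_protein=apo,
        fit_selection=CA_SEL, ligand_selection=LIG_SEL,
    ))
    assert prov["clashes"]


def test_substitutions_structure_vs_itself_is_empty(toy_complex):
    s, _ = toy_complex
    subs, unmatched = binding_site_substitutions(s, s)
    assert subs == [] and unmatched == []


def test_substitutions_recover_engineered_differences(tmp_path):
    spec = FixtureSpec(
        seed=13, metal=True,
        substitutions=((0, "ALA"), (3, "GLY"), (5, "HIS")),
    )
    a, b, engineered, _tr = make_homolog_pair(spec, out_dir=str(tmp_path))
    subs, unmatched = binding_site_substitutions(a, b)
    assert unmatched == []
    assert sorted(subs) == sorted(engineered)


def test_unmatched_site_residue_is_listed_not_dropped(toy_complex):
    s, _ = toy_complex
    other = Structure(residues=[r.copy() for r in s.residues])
    # move one residue's CA far away so it cannot pair
    lost = next(r for r in other.residues if r.number == 5)
    for a in lost.atoms:
        a.position = a.position + np.array([80.0, 0.0, 0.0])
    subs, unmatched = binding_site_substitutions(
        s, other,
        site_sel=AtomSelection.make(residue_ranges=[(5, 5)]),
        fit_sel=AtomSelection.make(
            atom_names=["CA"], residue_ranges=[(1, 4), (6, 8)]
        ),
    )
    assert subs == []
    assert [k[1] for k in unmatched] == [5]
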