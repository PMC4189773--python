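"""Virtual glycine scan: oracles, invariants, and pipeline plumbing."""

import numpy as np
import pytest

import carbscan.scan as scan_mod
from carbscan import (
    AtomSelection,
    FixtureSpec,
    PipelineConfig,
    add_hydrogens,
    assign_parameters,
    glycine_scan,
    make_homolog_pair,
    make_toy_complex,
    run_caii_analysis,
    run_caix_pipeline,
    truncate_to_glycine,
)
from carbscan.energy import interaction_energy
from carbscan.model import Structure

LIG_SEL = AtomSelection.make(residue_names=["LIG"])


@pytest.fixture(scope="module")
def protonated(tmp_path_factory):
    out = tmp_path_factory.mktemp("scan")
    s, _ = make_toy_complex(FixtureSpec(seed=2), out_dir=str(out))
    return add_hydrogens(s)


def test_scanning_glycine_gives_exact_zero(tmp_path):
    s, _ = make_toy_complex(
        FixtureSpec(seed=6, residue_names=("GLY", "SER", "THR")),
        out_dir=str(tmp_path),
    )
    prot = add_hydrogens(s)
    gly_keys = [r.key for r in prot.residues if r.name == "GLY"]
    assert gly_keys
    result = glycine_scan(prot, gly_keys, LIG_SEL)
    for k in gly_keys:
        assert result.values[k] == 0.0


def test_sole_contact_residue_equals_pair_energy_oracle(tmp_path, ff):
    """With one residue as the only interaction partner, its ddG equals a
    naive per-atom pair-sum recomputation over wild type vs mutant."""
    s, _ = make_toy_complex(
        FixtureSpec(seed=5, sole_contact_residue=1), out_dir=str(tmp_path)
    )
    prot = add_hydrogens(s)
    key = [r.key for r in prot.residues if r.is_amino_acid][1]
    result = glycine_scan(prot, [key], LIG_SEL)

    def naive_total(struct):
        param = assign_parameters(struct, ff)
        lig = [(a.charge, ff.vdw_types[a.vdw_type], a.position)
               for r, a in param.atoms() if r.name == "LIG"]
        total = 0.0
        for r in param.residues:
            if r.name == "LIG":
                continue
            for a in r.atoms:
                ea, sa = ff.vdw_types[a.vdw_type]
                for q, (eb, sb), p in lig:
                    d = float(np.linalg.norm(a.position - p))
                    total += 332.0637 * a.charge * q / (4.0 * d * d)
                    eps = (ea * eb) ** 0.5
                    sig = 0.5 * (sa + sb)
                    total += 4 * eps * ((sig / d) ** 12 - (sig / d) ** 6)
        return total

    expected = naive_total(truncate_to_glycine(prot, key)) - naive_total(prot)
    assert result.values[key] == pytest.approx(expected, rel=1e-9, abs=1e-12)


def test_distant_residue_contributes_nothing(tmp_path):
    s, _ = make_toy_complex(
        FixtureSpec(seed=5, sole_contact_residue=1), out_dir=str(tmp_path)
    )
    prot = add_hydrogens(s)
    far_key = [r.key for r in prot.residues if r.is_amino_acid][3]
    result = glycine_scan(prot, [far_key], LIG_SEL)
    assert abs(result.values[far_key]) < 1e-6


def test_scan_is_order_independent(protonated):
    keys = [r.key for r in protonated.residues if r.is_amino_acid]
    forward = glycine_scan(protonated, keys, LIG_SEL)
    backward = glycine_scan(protonated, list(reversed(keys)), LIG_SEL)
    for k in keys:
        assert forward.values[k] == backward.values[k]


def test_scan_leaves_complex_bit_identical(protonated):
    before = [
        (r.key, r.name, a.name, a.position.copy())
        for r, a in protonated.atoms()
    ]
    keys = [r.key for r in protonated.residues if r.is_amino_acid]
    glycine_scan(protonated, keys, LIG_SEL)
    after = [(r.key, r.name, a.name, a.position) for r, a in protonated.atoms()]
    assert len(before) == len(after)
    for (k0, n0, an0, p0), (k1, n1, an1, p1) in zip(before, after):
        assert (k0, n0, an0) == (k1, n1, an1)
        assert np.array_equal(p0, p1)


def test_rigid_scan_costs_n_plus_one_energy_evaluations(protonated, monkeypatch):
    calls = {"n": 0}
    real = scan_mod.interaction_energy

    def counting(*args, **kwargs):
        calls["n"] += 1
        return real(*args, **kwargs)

    monkeypatch.setattr(scan_mod, "interaction_energy", counting)
    keys = [r.key for r in protonated.residues if r.is_amino_acid]
    n_non_gly = sum(
        1 for r in protonated.residues if r.is_amino_acid and r.name != "GLY"
    )
    glycine_scan(protonated, keys, LIG_SEL)
    assert calls["n"] == n_non_gly + 1


def test_relaxed_mode_runs_and_differs(tmp_path, ff):
    from carbscan import MinimizerSettings

    s, _ = make_toy_complex(
        FixtureSpec(seed=9, n_residues=3, residue_names=("SER", "VAL", "ASN")),
        out_dir=str(tmp_path),
    )
    prot = add_hydrogens(s)
    key = [r.key for r in prot.residues if r.is_amino_acid][0]
    rigid = glycine_scan(prot, [key], LIG_SEL, mode="rigid")
    relaxed = glycine_scan(
        prot, [key], LIG_SEL, mode="relaxed",
        settings=MinimizerSettings(max_iterations=150),
    )
    assert relaxed.mode == "relaxed"
    assert np.isfinite(relaxed.values[key])
    assert relaxed.values[key] != rigid.values[key]


def test_single_complex_pipeline_bundle(tmp_path):
    s, _ = make_toy_complex(FixtureSpec(seed=2), out_dir=str(tmp_path / "fx"))
    cfg = PipelineConfig(
        complex_structure=s, ligand_resname="LIG",
        output_dir=str(tmp_path / "out"),
    )
    bundle = run_caii_analysis(cfg)
    assert (tmp_path / "out" / "contacts.tsv").exists()
    assert (tmp_path / "out" / "manifest.json").exists()
    assert bundle["summary"]["n_contacts"] == len(bundle["contacts"])
    assert bundle["scan"] is not None and bundle["scan"].values


def test_contacts_only_report_when_no_residues_scanned(tmp_path):
    s, _ = make_toy_complex(FixtureSpec(seed=2), out_dir=str(tmp_path / "fx"))
    # a far-away probe ligand yields no scanned residues
    cfg = PipelineConfig(
        complex_structure=s, ligand_resname="LIG",
        contact_cutoff=0.5,  # nothing within range
        output_dir=str(tmp_path / "out"),
    )
    bundle = run_caii_analysis(cfg)
    assert bundle["scan"] is None
    assert bundle["contacts"] == []


def test_template_graft_pipeline_end_to_end(tmp_path):
    spec = FixtureSpec(
        seed=21, metal=True,
        substitutions=((1, "ALA"), (4, "SER")),
    )
    a, b, subs, _tr = make_homolog_pair(spec, out_dir=str(tmp_path / "fx"))
    cfg = PipelineConfig(
        template_structure=a, target_structure=b,
        ligand_resname="LIG",
        fit_selection=AtomSelection.make(atom_names=["CA"]),
        movable_residues=tuple(
            r.key for r in b.residues if r.is_amino_acid
        ),
        relax=False,  # keep the unit test fast; relaxation tested elsewhere
        output_dir=str(tmp_path / "out"),
    )
    bundle = run_caix_pipeline(cfg)
    assert sorted(bundle["substitutions"]) == sorted(subs)
    assert bundle["displacement_atom"] == "B12"
    assert bundle["ligand_displacement"] == pytest.approx(0.0, abs=1e-6)
    assert (tmp_path / "out" / "modeled_complex.pdb").exists()
    assert (tmp_path / "out" / "model_contacts.tsv").exists()
    assert "template" in bundle["scans"] and "model" in bundle["scans"]


def test_self_graft_control_matches_template_contacts(tmp_path):
    s, _ = make_toy_complex(
        FixtureSpec(seed=2, metal=True), out_dir=str(tmp_path / "fx")
    )
    apo = Structure(residues=[r.copy() for r in s.residues if r.name != "LIG"])
    cfg = PipelineConfig(
        template_structure=s, target_structure=apo,
        ligand_resname="LIG",
        fit_selection=AtomSelection.make(atom_names=["CA"]),
        relax=False,
        output_dir=str(tmp_path / "out"),
    )
    bundle = run_caix_pipeline(cfg)
    assert bundle["ligand_displacement"] == pytest.approx(0.0, abs=1e-9)
    from carbscan import classify_contacts, enumerate_contacts

    ref = classify_contacts(enumerate_contacts(s, LIG_SEL, 4.0), s)
    got = {(c.residue_number, c.protein_atom, c.ligand_atom, c.distance)
           for c in bundle["contacts"]}
    assert got == {(c.residue_number, c.protein_atom, c.ligand_atom, c.distance)
                   for c in ref}
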