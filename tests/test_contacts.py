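"""Contact enumeration/classification and dihydrogen-bond detection."""

import numpy as np
import pytest

from carbscan import (
    AtomSelection,
    FixtureSpec,
    classify_contacts,
    contact_residue_sets,
    detect_dihydrogen_bonds,
    enumerate_contacts,
    make_toy_complex,
    write_contact_table,
)
from carbscan.contacts import read_contact_table
from carbscan.errors import SelectionError, TopologyError
from carbscan.model import Atom, Residue, Structure

from conftest import make_structure, simple_residue

LIG_SEL = AtomSelection.make(residue_names=["LIG"])


def _brute_force_contacts(s, lig_name, cutoff):
    """Independent all-pairs double loop (the oracle)."""
    out = set()
    lig = [r for r in s.residues if r.name == lig_name]
    env = [r for r in s.residues if r.name != lig_name and not r.is_water]
    for lr in lig:
        for la in lr.atoms:
            if la.element in ("H", "D"):
                continue
            for er in env:
                for ea in er.atoms:
                    if ea.element in ("H", "D"):
                        continue
                    d = float(np.linalg.norm(la.position - ea.position))
                    if d <= cutoff + 1e-9:
                        out.add(((er.chain_id, er.number), ea.name, la.name))
    return out


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("cutoff", [3.5, 4.0])
def test_enumeration_matches_all_pairs_oracle(seed, cutoff, tmp_path):
    s, _ = make_toy_complex(
        FixtureSpec(seed=seed, metal=bool(seed % 2)), out_dir=str(tmp_path)
    )
    recs = enumerate_contacts(s, LIG_SEL, cutoff)
    got = {((c.chain_id, c.residue_number), c.protein_atom, c.ligand_atom)
           for c in recs}
    assert got == _brute_force_contacts(s, "LIG", cutoff)


def test_records_are_sorted_and_rounded(toy_complex):
    s, _ = toy_complex
    recs = enumerate_contacts(s, LIG_SEL, 4.0)
    assert recs == sorted(
        recs, key=lambda c: (c.residue_number, c.distance, c.protein_atom,
                             c.ligand_atom)
    )
    for c in recs:
        assert round(c.distance, 2) == c.distance


def test_inclusive_cutoff_boundary():
    lig = simple_residue("LIG", "L", 900, [("N2", "N", (0.0, 0.0, 0.0))])
    near = simple_residue("GLY", "A", 1, [("N", "N", (4.00, 0.0, 0.0))])
    far = simple_residue("GLY", "A", 2, [("N", "N", (0.0, 4.01, 0.0))])
    s = make_structure(near, far, lig)
    recs = enumerate_contacts(s, LIG_SEL, 4.0)
    assert [(c.residue_number, c.distance) for c in recs] == [(1, 4.00)]


def test_empty_ligand_selection_raises(toy_complex):
    s, _ = toy_complex
    with pytest.raises(SelectionError):
        enumerate_contacts(s, AtomSelection.make(residue_names=["XXX"]))


def _zn_fixture():
    lig = simple_residue("LIG", "L", 900, [
        ("N2", "N", (0.0, 0.0, 1.87)),
        ("S", "S", (0.0, 0.0, 3.47)),
        ("O2", "O", (1.4, 0.0, 2.71)),   # 3.05 A from the Zn at the origin
        ("N1", "N", (-1.2, 0.5, 3.2)),
        ("C3", "C", (-1.5, 0.2, 4.6)),
    ])
    zn = Residue(chain_id="M", number=500, name="ZN",
                 atoms=[Atom(name="ZN", element="ZN",
                             position=np.zeros(3))])
    thr = simple_residue("THR", "A", 200, [
        ("OG1", "O", (-2.0, 2.0, 2.0)),  # ~3.02 from N1 below
        ("CB", "C", (-3.2, 2.5, 2.7)),
    ])
    # place OG1 exactly 3.02 A from N1 along the current direction
    og1 = thr.atom("OG1")
    n1 = lig.atom("N1")
    u = og1.position - n1.position
    og1.position = n1.position + u / np.linalg.norm(u) * 3.02
    his = simple_residue("HIS", "A", 96, [
        ("NE2", "N", (0.0, 3.14, 0.0)),  # 3.14 from N2 -> vdw (beyond polar cutoff)
        ("CE1", "C", (0.9, 3.9, 0.6)),
    ])
    return make_structure(zn, thr, his, lig)


def test_classification_thresholds_follow_the_bolding_pattern():
    """Zn-N at 1.87 is coordination; Zn-O at 3+ A, N-N at 3.14 are vdW;
    O-N at 3.02 is polar — the distance pattern of the contact table."""
    s = _zn_fixture()
    recs = classify_contacts(enumerate_contacts(s, LIG_SEL, 4.0), s)
    by_pair = {(c.protein_atom, c.ligand_atom): c.contact_class for c in recs}
    assert by_pair[("ZN", "N2")] == "metal_coordination"
    assert by_pair[("ZN", "S")] == "vdw"
    assert by_pair[("ZN", "O2")] == "vdw"
    assert by_pair[("OG1", "N1")] == "polar"
    assert by_pair[("NE2", "N2")] == "vdw"
    assert by_pair.get(("CB", "C3"), "vdw") == "vdw"


def test_classification_is_order_independent():
    s = _zn_fixture()
    recs = enumerate_contacts(s, LIG_SEL, 4.0)
    direct = classify_contacts(recs, s)
    shuffled = classify_contacts(list(reversed(recs)), s)
    assert {(c.protein_atom, c.ligand_atom, c.contact_class) for c in direct} \
        == {(c.protein_atom, c.ligand_atom, c.contact_class) for c in shuffled}


def _dihydrogen_fixture(hh_distance, bent=False):
    """Constructed N-H ... H-B geometry with controllable distance/angle."""
    b_pos = np.array([0.0, 0.0, 0.0])
    hb = np.array([1.19, 0.0, 0.0])
    if bent:
        hp = hb + np.array([0.0, hh_distance, 0.0])
        # donor on the same side as the hydridic H: N-H...H angle < 90
        n_pos = hp + 1.01 * np.array([0.5, -0.866, 0.0])
    else:
        hp = hb + np.array([hh_distance, 0.0, 0.0])
        n_pos = hp + np.array([1.01, 0.0, 0.0])
    lig = simple_residue("LIG", "L", 900, [("B7", "B", b_pos)])
    lig.atoms.append(Atom(name="H7", element="H", position=hb))
    trp = simple_residue("TRP", "A", 5, [("NE1", "N", n_pos)])
    trp.atoms.append(Atom(name="HE1", element="H", position=hp))
    return make_structure(trp, lig)


def test_dihydrogen_bond_detected_at_2p3_linear():
    s = _dihydrogen_fixture(2.3)
    bonds = detect_dihydrogen_bonds(s, LIG_SEL)
    assert len(bonds) == 1
    b = bonds[0]
    assert b.hh_distance == pytest.approx(2.3, abs=0.01)
    assert b.donor_atom == "NE1" and b.acceptor_atom == "B7"
    assert b.donor_angle > 170 and b.acceptor_angle > 170


def test_dihydrogen_bond_cutoff_and_angle_criteria():
    assert detect_dihydrogen_bonds(_dihydrogen_fixture(2.5), LIG_SEL) == []
    bent = _dihydrogen_fixture(2.0, bent=True)
    # the protic N-H points perpendicular to the H...H vector: angle < 90
    assert detect_dihydrogen_bonds(bent, LIG_SEL) == []


def test_dihydrogen_requires_ligand_hydrogens(toy_complex):
    s, _ = toy_complex  # heavy atoms only
    with pytest.raises(TopologyError, match="add_hydrogens"):
        detect_dihydrogen_bonds(s, LIG_SEL)


def test_dihydrogen_symmetric_under_equivalent_vertex_relabeling():
    s = _dihydrogen_fixture(2.3)
    lig = next(r for r in s.residues if r.name == "LIG")
    lig.atoms[0].name = "B9"
    lig.atoms[1].name = "H9"
    bonds = detect_dihydrogen_bonds(s, LIG_SEL)
    assert len(bonds) == 1 and bonds[0].acceptor_atom == "B9"


def test_contact_residue_set_comparison(toy_complex):
    s, _ = toy_complex
    df = contact_residue_sets([("a", s, LIG_SEL), ("b", s, LIG_SEL)])
    assert list(df["a"]) == list(df["b"])
    assert len(df) > 0

    s2 = _zn_fixture()
    df2 = contact_residue_sets([("x", s, LIG_SEL), ("y", s2, LIG_SEL)])
    assert "THR200" in df2.index
    assert df2.loc["THR200", "x"] == "" and df2.loc["THR200", "y"] == "P"


def test_contact_table_round_trip(tmp_path, toy_complex):
    s, _ = toy_complex
    recs = classify_contacts(enumerate_contacts(s, LIG_SEL, 4.0), s)
    path = tmp_path / "contacts.tsv"
    write_contact_table(recs, path)
    back = read_contact_table(path)
    assert [
        (c.residue_number, c.residue_name, c.protein_atom, c.ligand_atom,
         c.distance, c.contact_class)
        for c in recs
    ] == [
        (c.residue_number, c.residue_name, c.protein_atom, c.ligand_atom,
         c.distance, c.contact_class)
        for c in back
    ]


def test_contact_table_empty_is_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    write_contact_table([], path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("residue_number")
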