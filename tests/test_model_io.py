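"""Structure containers, selections, and PDB/mmCIF round trips."""

import numpy as np
import pytest

from carbscan import (
    AtomSelection,
    FixtureSpec,
    make_toy_complex,
    read_structure,
    structure_stats,
    write_structure,
)
from carbscan.errors import FormatError, ParseError, SelectionError
from carbscan.model import Atom, Residue, Structure, parse_selection, select_atoms

from conftest import make_structure, simple_residue


@pytest.fixture()
def three_residue_structure():
    r1 = simple_residue("SER", "A", 1, [
        ("N", "N", (0, 0, 0)), ("CA", "C", (1.458, 0, 0)),
        ("C", "C", (2.0, 1.4, 0)), ("O", "O", (1.5, 2.5, 0)),
        ("CB", "C", (2.1, -0.7, 1.1)), ("OG", "O", (3.4, -0.4, 1.6)),
    ])
    r2 = simple_residue("GLY", "A", 2, [
        ("N", "N", (3.3, 1.5, 0.2)), ("CA", "C", (4.1, 2.6, 0.5)),
        ("C", "C", (5.5, 2.3, 1.0)), ("O", "O", (6.0, 1.2, 0.9)),
    ])
    hoh = simple_residue("HOH", "W", 101, [("O", "O", (8.0, 8.0, 8.0))])
    for r, adp in zip((r1, r2, hoh), (10.0, 14.0, 30.0)):
        for a in r.atoms:
            a.adp = adp
            a.occupancy = 1.0
    return make_structure(r1, r2, hoh)


@pytest.mark.parametrize("fmt,ext", [("pdb", ".pdb"), ("mmcif", ".cif")])
def test_round_trip_preserves_atoms_coordinates_numbering(
    three_residue_structure, tmp_path, fmt, ext
):
    path = tmp_path / f"toy{ext}"
    write_structure(three_residue_structure, str(path), format=fmt)
    back = read_structure(str(path), format=fmt)
    assert back.n_atoms() == three_residue_structure.n_atoms()
    for (r0, a0), (r1, a1) in zip(
        three_residue_structure.atoms(), back.atoms()
    ):
        assert (r0.key, a0.name) == (r1.key, a1.name)
        assert r0.name == r1.name
        np.testing.assert_allclose(a0.position, a1.position, atol=1.5e-3)
        assert a1.occupancy == pytest.approx(a0.occupancy, abs=0.01)
        assert a1.adp == pytest.approx(a0.adp, abs=0.01)


def test_double_round_trip_is_exact(three_residue_structure, tmp_path):
    p1 = tmp_path / "a.pdb"
    p2 = tmp_path / "b.pdb"
    write_structure(three_residue_structure, str(p1))
    s1 = read_structure(str(p1))
    write_structure(s1, str(p2))
    s2 = read_structure(str(p2))
    for (_, a1), (_, a2) in zip(s1.atoms(), s2.atoms()):
        assert np.array_equal(a1.position, a2.position)


def test_empty_file_is_a_parse_error(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("")
    with pytest.raises(ParseError):
        read_structure(str(p))


def test_missing_file_and_unknown_format_errors(tmp_path):
    with pytest.raises(ParseError):
        read_structure(str(tmp_path / "nope.pdb"))
    p = tmp_path / "x.pdb"
    p.write_text("ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00           N\n")
    with pytest.raises(FormatError):
        read_structure(str(p), format="xyzzy")


def test_altloc_policy_keeps_highest_occupancy(tmp_path):
    res = Residue(chain_id="A", number=1, name="SER", atoms=[
        Atom(name="OG", element="O", position=np.array([0.0, 0.0, 0.0]),
             occupancy=0.4, altloc="A"),
        Atom(name="OG", element="O", position=np.array([1.0, 0.0, 0.0]),
             occupancy=0.6, altloc="B"),
        Atom(name="CB", element="C", position=np.array([0.5, 1.0, 0.0])),
    ])
    s = make_structure(res)
    p = tmp_path / "alt.pdb"
    write_structure(s, str(p))
    default = read_structure(str(p))
    (og,) = [a for _, a in default.atoms() if a.name == "OG"]
    assert og.altloc == "B" and og.occupancy == pytest.approx(0.6, abs=0.01)
    keep = read_structure(str(p), keep_all_altlocs=True)
    assert sum(1 for _, a in keep.atoms() if a.name == "OG") == 2


def test_altloc_tie_goes_to_alphabetically_first_tag(tmp_path):
    res = Residue(chain_id="A", number=1, name="SER", atoms=[
        Atom(name="OG", element="O", position=np.array([0.0, 0.0, 0.0]),
             occupancy=0.5, altloc="B"),
        Atom(name="OG", element="O", position=np.array([1.0, 0.0, 0.0]),
             occupancy=0.5, altloc="A"),
    ])
    p = tmp_path / "tie.pdb"
    write_structure(make_structure(res), str(p))
    s = read_structure(str(p))
    (og,) = [a for _, a in s.atoms() if a.name == "OG"]
    assert og.altloc == "A"


def test_select_atoms_is_idempotent_and_ordered(toy_complex):
    s, _ = toy_complex
    sel = AtomSelection.make(elements=["N", "O"])
    first = select_atoms(s, sel)
    again = [
        (r, a) for (r, a) in first
        if sel.matches_residue(r) and sel.matches_atom(a)
    ]
    assert [(r.key, a.name) for r, a in first] == [
        (r.key, a.name) for r, a in again
    ]
    # deterministic residue/atom order
    keys = [(r.key, a.name) for r, a in first]
    assert keys == sorted(keys, key=lambda k: keys.index(k))


def test_empty_selection_matches_everything(toy_complex):
    s, _ = toy_complex
    assert len(select_atoms(s, AtomSelection())) == s.n_atoms()
    assert len(select_atoms(s, None)) == s.n_atoms()


def test_selection_for_absent_names_or_chain_is_empty(toy_complex):
    s, _ = toy_complex
    assert select_atoms(s, AtomSelection.make(residue_names=["ARG", "MET"])) == []
    assert select_atoms(s, AtomSelection.make(chains=["Z"])) == []


def test_calpha_range_selection_counts_residues(toy_complex):
    s, _ = toy_complex
    sel = AtomSelection.make(atom_names=["CA"], residue_ranges=[(1, 4)])
    got = select_atoms(s, sel)
    expect = [r for r in s.residues if 1 <= r.number <= 4 and r.atom("CA")]
    assert len(got) == len(expect)


def test_structure_stats_mean_adp():
    r = simple_residue("GLY", "A", 1, [("N", "N", (0, 0, 0)),
                                       ("CA", "C", (1.5, 0, 0))])
    r.atoms[0].adp = 4.0
    r.atoms[1].adp = 6.0
    s = make_structure(r)
    rec = structure_stats(s)
    assert rec["mean_adp"] == pytest.approx(5.0)
    assert rec["atom_count"] == 2 and rec["residue_count"] == 1

    single = structure_stats(s, AtomSelection.make(atom_names=["N"]))
    assert single["mean_adp"] == pytest.approx(4.0)


def test_structure_stats_water_count_and_empty_selection(three_residue_structure):
    rec = structure_stats(three_residue_structure)
    assert rec["water_count"] == len(
        [r for r in three_residue_structure.residues if r.name == "HOH"]
    ) == 1
    with pytest.raises(SelectionError):
        structure_stats(three_residue_structure,
                        AtomSelection.make(residue_names=["TRP"]))


def test_parse_selection_mini_language():
    sel = parse_selection("ca,4-261")
    assert sel.atom_names == frozenset({"CA"})
    assert sel.residue_ranges == ((4, 261),)
    sel2 = parse_selection("THR,200")
    assert sel2.residue_names == frozenset({"THR"})
    assert sel2.residue_ranges == ((200, 200),)


def test_metal_and_water_flags(toy_complex):
    s, _ = toy_complex
    zn = Residue(chain_id="M", number=500, name="ZN",
                 atoms=[Atom(name="ZN", element="ZN",
                             position=np.zeros(3))])
    s2 = Structure(residues=s.residues + [zn])
    assert [r.name for r in s2.metals] == ["ZN"]
    assert all(r.name == "HOH" for r in s2.waters)


def test_duplicate_residue_key_rejected():
    r1 = simple_residue("GLY", "A", 1, [("N", "N", (0, 0, 0))])
    r2 = simple_residue("ALA", "A", 1, [("N", "N", (5, 0, 0))])
    s = make_structure(r1, r2)
    with pytest.raises(ValueError, match="duplicate residue"):
        s.validate()


def test_atom_invariants_enforced():
    with pytest.raises(ValueError):
        Atom(name="X", element="C", position=np.array([np.inf, 0, 0]))
    with pytest.raises(ValueError):
        Atom(name="X", element="C", position=np.zeros(3), occupancy=1.5)
    with pytest.raises(ValueError):
        Atom(name="X", element="", position=np.zeros(3))
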