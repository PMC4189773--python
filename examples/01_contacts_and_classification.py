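"""Enumerate and classify protein-ligand contacts on a synthetic active site.

Builds a small toy site around the carborane-sulfamide ligand (with a
catalytic zinc), lists every heavy-atom contact within 4.0 A, and marks
each as metal coordination, polar, or van der Waals — the same analysis a
crystal-structure contact table reports.
"""

import tempfile

from carbscan import (
    AtomSelection,
    FixtureSpec,
    classify_contacts,
    enumerate_contacts,
    make_toy_complex,
)

spec = FixtureSpec(seed=2, metal=True)
structure, truth = make_toy_complex(spec, out_dir=tempfile.mkdtemp())
ligand = AtomSelection.make(residue_names=["LIG"])

contacts = classify_contacts(enumerate_contacts(structure, ligand, 4.0), structure)
print(f"{len(contacts)} contacts within 4.0 A "
      f"(ground truth: {len(truth.contacts(4.0))})\n")
print("res   protein  ligand  dist   class")
for c in contacts:
    print(f"{c.residue_name}{c.residue_number:<4} {c.protein_atom:<8} "
          f"{c.ligand_atom:<7} {c.distance:.2f}   {c.contact_class}")

n_special = sum(1 for c in contacts
                if c.contact_class in ("polar", "metal_coordination"))
print(f"\n{n_special} polar/coordination contacts (the 'bold rows'); "
      "the rest are van der Waals packing around the hydrophobic cage.")
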