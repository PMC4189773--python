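"""Rigid-body superposition and per-residue deviation analysis.

Superposes a structure onto a rigidly moved, locally perturbed copy and
reports the overall C-alpha RMSD plus the residue with the largest
displacement — the analysis used to compare two crystal forms of the same
protein and localize a shifted loop.
"""

import tempfile

import numpy as np

from carbscan import (
    AtomSelection,
    FixtureSpec,
    make_toy_complex,
    per_residue_deviation,
    superpose_structures,
)

structure, _ = make_toy_complex(FixtureSpec(seed=3), out_dir=tempfile.mkdtemp())

# a rigidly moved copy with residue 4 pushed 0.74 A sideways
moved = structure.copy()
rng = np.random.default_rng(0)
from scipy.spatial.transform import Rotation
R = Rotation.random(rng=rng).as_matrix()
t = np.array([8.0, -3.0, 5.0])
for r in moved.residues:
    for a in r.atoms:
        a.position = R @ a.position + t
for a in next(r for r in moved.residues if r.number == 4).atoms:
    a.position = a.position + R @ np.array([0.74, 0.0, 0.0])

ca = AtomSelection.make(atom_names=["CA"])
fit_sel = AtomSelection.make(atom_names=["CA"],
                             residue_ranges=[(1, 3), (5, 8)])
result = superpose_structures(structure, moved, fit_sel)
print(f"C-alpha fit over {result.n_atoms} unperturbed residues: "
      f"RMSD {result.rmsd:.3f} A (rigid motion removed)")

dev = per_residue_deviation(structure, moved, ca, fit_sel)
worst = max(dev, key=dev.get)
print("\nper-residue deviation after the fit:")
for key in sorted(dev):
    print(f"  residue {key[1]}: {dev[key]:.3f} A")
print(f"\nlargest deviation at residue {worst[1]} ({dev[worst]:.3f} A) — "
      "the engineered local shift, recovered against the rigid background.")
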