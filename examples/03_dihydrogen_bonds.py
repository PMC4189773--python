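"""Detect a dihydrogen bond between a protic N-H and a hydridic B-H.

closo-carborane cages carry hydridic hydrogens on their B-H vertices;
these can accept weak 'dihydrogen bonds' from protic donors (N-H, O-H,
aromatic C-H). The standard geometric criteria are an H...H distance of
at most 2.4 A with both X-H...H angles at least 90 degrees. This example
constructs a near-linear N-H...H-B approach at the published 2.3 A
distance and shows the detector finding exactly that pair.
"""

import numpy as np

from carbscan import AtomSelection, detect_dihydrogen_bonds
from carbscan.model import Atom, Residue, Structure

b = np.zeros(3)
h_b = np.array([1.19, 0.0, 0.0])          # B-H bond, 1.19 A
h_n = h_b + np.array([2.3, 0.0, 0.0])     # H...H = 2.3 A, head-on
n = h_n + np.array([1.01, 0.0, 0.0])      # N-H bond, 1.01 A

lig = Residue(chain_id="L", number=900, name="LIG", atoms=[
    Atom(name="B7", element="B", position=b),
    Atom(name="H7", element="H", position=h_b),
])
trp = Residue(chain_id="A", number=5, name="TRP", atoms=[
    Atom(name="NE1", element="N", position=n),
    Atom(name="HE1", element="H", position=h_n),
])
structure = Structure(residues=[trp, lig])

bonds = detect_dihydrogen_bonds(
    structure, AtomSelection.make(residue_names=["LIG"])
)
for bd in bonds:
    print(f"{bd.donor_atom}-{bd.protic_H} ... {bd.hydridic_H}-{bd.acceptor_atom}: "
          f"H...H {bd.hh_distance:.2f} A, "
          f"angles {bd.donor_angle:.0f} deg / {bd.acceptor_angle:.0f} deg")
print("\nA 2.3 A head-on approach passes both criteria; pushing the pair to"
      " 2.5 A or bending the donor below 90 degrees would reject it.")
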