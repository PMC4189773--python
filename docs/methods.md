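# Methods

This note documents the models, conventions and numerical choices behind
carbscan: a package for analyzing and modeling complexes of carbonic
anhydrase (CA) isoenzymes with carborane-sulfamide inhibitors, centered
on 1-methylenesulfamide-1,2-dicarba-*closo*-dodecaborane ("compound 1").

## Structures and I/O

Structures are a flat hierarchy (residues holding atoms) read and written
through gemmi in PDB and mmCIF. Conventions:

- Coordinates in Å; author residue numbering everywhere; ranges inclusive.
- Alternate locations: by default, per atom name only the
  highest-occupancy conformer is kept (ties go to the alphabetically
  first tag). Distance analysis needs one position per atom; a flag
  retains all conformers. Occupancy weighting of summary statistics is
  not attempted — mean ADPs are plain arithmetic means over the selected
  atoms.
- Anisotropic displacement records are reduced to the isotropic
  equivalent B_eq = 8π²·tr(U)/3 at read time.
- Hydrogens absent from deposited files are tolerated everywhere except
  dihydrogen-bond detection and energy evaluation, which require
  `prep.add_hydrogens` first.

## The compound-1 template

The ligand is a 12-vertex icosahedral *closo*-carborane (two adjacent CH
vertices C1/C2, ten BH vertices B3–B12; every vertex has exactly five
cage neighbors) carrying a methylene-linked sulfamide
C1–CH2–NH–SO2–NH2. Ideal geometry is generated from the golden-ratio
icosahedron scaled to a 1.78 Å cage edge; B12 is the vertex antipodal to
C1 and serves as the displacement probe for pose comparisons. The
template carries partial charges (hydridic B–H hydrogens slightly
negative, protic N–H hydrogens positive, net charge exactly 0) and vdW
types, plus an atom-name aliasing table for deposited files whose labels
differ from the canonical ones (identity until a differing deposition is
registered).

## Superposition

Rigid fits use the closed-form Kabsch solution (SVD of the covariance
matrix with determinant correction; reflections excluded by
construction). Pairing between structures is by (chain, residue number,
insertion code, atom name); unmatched atoms are dropped with a logged
count. Nearly collinear point sets raise a rank-deficiency error rather
than returning an arbitrary rotation. Per-residue deviation reports the
mean paired-atom distance per residue after a fit on a separate
selection, which localizes loop shifts against a rigid background.

For cross-form inhibitor comparisons the cage RMSD is measured in the
protein frame (fit on Cα, measure on the 12 cage atoms without
refitting), i.e. it reports the positional shift of the inhibitor, not
the internal agreement of the cages.

## Contacts and dihydrogen bonds

A contact is any (protein-or-metal heavy atom, ligand heavy atom) pair at
≤ 4.0 Å (inclusive); waters are excluded by default and distances are
reported to 2 decimals. Classification is a pure function of elements,
distance and the metal flag:

- metal coordination: metal partner within 2.5 Å (keeps a Zn–N anchor
  bond near 1.9 Å, excludes 3 Å Zn⋯S/O approaches);
- polar: both atoms in {N, O, S} within 3.1 Å — the threshold separates
  hydrogen-bond-range pairs (≤ 3.02 Å in the reference complex) from
  van-der-Waals-range N/O pairs (≥ 3.14 Å);
- van der Waals: everything else in range.

Dihydrogen bonds pair a protic hydrogen (parent N/O/S or aromatic
carbon) with a hydridic hydrogen (parent B) at H⋯H ≤ 2.4 Å with both
X–H⋯H angles ≥ 90° — the standard crystallographic criteria for boron
cluster H⋯H contacts. Hydrogen parents are identified as the nearest
heavy atom within 1.6 Å.

## Structure preparation

Hydrogens are placed by ideal geometry: sp³ completions (tetrahedral
angles), in-plane sp² placements, staggered methyls, and rotatable
hydroxyls oriented toward the nearest acceptor among staggered
positions. Standard X–H lengths: C–H 1.09, N–H 1.01, O–H 0.96, S–H 1.34,
B–H 1.19 Å; cage hydrogens point radially outward from the cage
centroid. Protonation defaults: Asp/Glu deprotonated, Lys/Arg
protonated, His neutral with the tautomer chosen by a nearest-acceptor
heuristic (Nε–H when neither nitrogen has an acceptor within 3.6 Å).
Backbone amide hydrogens use the preceding residue's carbonyl carbon
only when an actual peptide bond exists (N⋯C < 1.8 Å); isolated residues
fall back to the in-residue bisector. Heavy atoms never move.

Glycine truncation removes all side-chain atoms beyond Cα, adds an Hα
along the old Cα→Cβ direction at 1.09 Å, renames an existing Hα to HA3,
and leaves the backbone and all other residues bit-identical. No
re-minimization happens at truncation time (standard computational
glycine/alanine scanning); relaxation is a separate, opt-in stage.

Grafting transfers a template's ligand — plus the metal if the target
lacks one, and explicitly named bridging waters — into a homologous
target after a rigid fit of the binding sites (key-based pairing by
default, nearest-Cα spatial pairing as an option for isoenzymes with
shifted numbering). Grafted atoms closer than 1.5 Å to target heavy
atoms are reported as clashes but do not abort: the relaxation stage
resolves them. Binding-site substitution listing pairs residues by
nearest Cα within 2.5 Å after superposition (author numbering may differ
between isoenzymes) and reports identity differences; unpairable site
residues are listed separately, never dropped.

## Energy model

The ligand-environment interaction energy ΔG_int′ is a pairwise-additive
classical nonbonded sum over all (ligand atom, residue atom) pairs:

    E = 332.0637·q_i·q_j / (ε(r)·r) + 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶]

with Lorentz–Berthelot combination and a distance-dependent dielectric
ε(r) = 4r as the default solvent screening (a constant-dielectric mode
exists). No cutoff is applied; intended systems are active-site-scale
(tens of residues). Units are fixed: kcal/mol, Å, elementary charges,
Coulomb constant 332.0637 kcal·Å/(mol·e²).

Parameters ship in `src/carbscan/data/forcefield.yaml`: element-class
Lennard-Jones parameters of Amber/OPLS-like magnitude and group-based
partial charges balanced so each residue's canonical atom set sums
exactly to its formal charge. This is the package's own minimal,
internally consistent set, adequate for rank-level and property-based
analysis; it is not a transcription of any single published force field,
and boron-cage parameters (σ ≈ 3.6 Å, small ε, hydridic hydrogens)
follow the magnitudes used in published carborane parameterization work.

This classical surrogate replaces the hybrid quantum-mechanical
treatment such complexes receive in high-accuracy studies. It preserves
additivity, geometry sensitivity, and side-chain ranking; it does not
reproduce quantitative QM/MM kcal/mol values, charge transfer, or
polarization, and no claim is made that scan magnitudes transfer to
experiment.

## FIRE relaxation

Geometry relaxation uses the Fast Inertial Relaxation Engine with the
original published parameters (f_inc 1.1, f_dec 0.5, α_start 0.1,
f_α 0.99, N_min 5), semi-implicit Euler integration with unit masses,
dt_init 0.02 (cap 10·dt_init), and convergence at max force component
≤ 0.05 kcal/mol/Å or 5,000 iterations. The minimizer returns the
lowest-energy configuration visited, so the reported energy never
exceeds the initial one even if the last step overshot. Non-finite
energies at the start raise an input error (callers must pre-separate
catastrophic clashes); non-finite mid-run steps back off to the best
configuration and shrink the step.

Because the energy model is nonbonded-only, covalent geometry of movable
atoms is maintained by harmonic restraints on 1-2 (bond, k = 300
kcal/mol/Å²) and 1-3 (geminal, k = 60 kcal/mol/Å²) distances at their
input values; a 1-3 distance restraint at fixed bond lengths is
equivalent to an angle restraint and keeps gradients simple. Bonds are
detected by covalent radii within residues, plus peptide C–N and
disulfide SG–SG links across residues — close inter-residue approaches
are clashes, not bonds. Nonbonded terms exclude 1-2/1-3 pairs; only
pairs with at least one movable atom enter the objective, and frozen
atoms are bit-identical in the output. Annealing/thermostat protocols
are out of scope: relaxation is minimization only.

## Virtual glycine scan

For each scanned residue independently: truncate to glycine, recompute
ΔG_int′, restore the wild type. The reported side-chain contribution is

    ΔΔG_int′ = ΔG_int′(glycine mutant) − ΔG_int′(wild type)

with interaction energies negative-favorable, so a positive ΔΔG_int′
means the side chain stabilizes the bound ligand and strong contributors
plot as positive bars. A residue that is already glycine reports exactly
0. The default mode is rigid (no re-relaxation after truncation):
deterministic, n+1 energy evaluations for n residues, and standard for
computational mutagenesis scans; `relaxed` mode re-relaxes the movable
set per mutant. Scanned residues default to every amino acid with any
heavy-atom contact ≤ 4 Å.

The end-to-end modeling pipeline (template graft → hydrogens →
relaxation → contact table → substitution list → paired scans) also
reports the ligand displacement between the grafted and relaxed pose,
measured at cage atom B12.

## Synthetic fixtures

The generator builds small active sites with exhaustively known ground
truth so that every stage is testable without downloads:

- Residues are constructed from ideal internal geometry (z-matrix /
  NeRF placement, including the aromatic ring systems) and aimed at the
  ligand along well-separated spherical directions, each slid along its
  approach axis until its nearest heavy-atom distance to the ligand
  equals a controlled gap — by default uniform in [3.3, 4.6] Å,
  straddling the 4 Å contact cutoff so fixtures exercise both sides of
  the threshold at crystallographic contact distances.
- Engineered features: an atom pinned at an exact distance from a named
  ligand atom (e.g. a Ser Oγ at 2.74 Å from the sulfamide nitrogen, the
  hydrogen-bond distance observed in the reference complex), a
  sole-contact residue (all others moved 200 Å away, far enough that
  screened residual interactions drop below 10⁻⁶ kcal/mol), a
  controlled steric clash, engineered homolog substitutions, and an
  optional Zn²⁺ placed on the sulfamide anchor axis.
- Every fixture is written to PDB and re-read through the public I/O
  path, so parser and writer are exercised on each use; coordinates
  therefore carry 3-decimal file precision, and oracles that require
  10⁻⁸ agreement (transform recovery, graft pose) are run on in-memory
  copies instead.
- Ground truth (all environment-ligand heavy-atom distances, contact
  sets at any cutoff, polar classes, closed-form Coulomb energies for a
  +1 point probe with zero LJ well depth) is computed by plain double
  loops over the re-read coordinates, independent of the analysis code
  paths.
- Everything is deterministic under the seed; identical seeds produce
  byte-identical files.

What the fixtures do not emulate: real protein folds, chain continuity,
crystallographic noise, alternate conformations, or solvent networks.
Passing tests therefore demonstrate algorithmic correctness (geometry,
enumeration, classification, energy arithmetic, minimization,
bookkeeping), not biological realism of any particular pose.

## Reference-data checks and problem sizes

The acceptance tests that recompute published crystallographic values
(superposition RMSDs, the 39-row contact table, water count, inhibitor
mean ADP) run on the deposited entries when present under
`data/structures/`; the coordinate files are not bundled. All other
acceptance checks are property-based at desk scale: 10 random transforms
plus a 10,000-rotation brute-force oracle for the rigid fit, 100 seeded
fixtures for contact enumeration, 5 seeds each for the analytic FIRE
minima, and a 10-residue homolog pair with six engineered substitutions
for the end-to-end pipeline. These sizes keep the full suite and the
acceptance script in the low tens of seconds on one CPU while leaving
every check statistically meaningful.

## Known limitations

- The energy surrogate is fixed-charge and unpolarized; zinc
  coordination is represented electrostatically (formal +2 charge, small
  LJ radius), not by ligand-field or bonded terms.
- Hydrogen placement is single-conformer ideal geometry; no rotamer or
  network optimization beyond the nearest-acceptor hydroxyl/His rules.
- Relaxation maintains covalent geometry by restraints rather than a
  bonded force field; torsional preferences are not modeled.
- Scan values are rank-level indicators under the package's own energy
  model, not predictions of experimental ΔΔG or inhibition constants.
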