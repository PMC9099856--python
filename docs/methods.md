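# Methods

`bindspace` re-implements, as a tested library, the analysis layer used in
ensemble-docking studies of ligand binding to the serotonin transporter's
allosteric vestibule: binding-space parameterization of scored pose sets,
geometric interaction fingerprinting, Metropolis Monte Carlo torsional
search with interaction monitoring, electrostatic complementarity on the
solvent-accessible surface, a component-structured binding free-energy
estimate, and the statistics that relate computed energies to measured
potencies. Docking itself is out of scope: pose sets come either from
files (SDF / multi-model PDB) or from the synthetic generators described
below.

## Structures and perception

Coordinates are in Å, energies in kcal/mol, partial charges in elementary
units; indexing is 0-based. Bonds are perceived where the interatomic
distance is at most the sum of covalent radii plus 0.45 Å; rings are a
minimum cycle basis of the bond graph and are flagged planar when no
member deviates more than 0.15 Å from the best-fit plane. Rotatable bonds
are acyclic single bonds between non-terminal heavy atoms, excluding
amide C–N. Both tolerances are arguments, with the common literature
defaults above.

Receptor pharmacophore tags come from residue-name templates (Asp/Glu
carboxylate oxygens anionic; Arg guanidinium and Lys NZ cationic;
Phe/Tyr/Trp/His side-chain rings aromatic; backbone O and polar side
chains as acceptors; N–H and O–H as donors). Ligand tags come from
element and bond environment (quaternary/protonated N cationic; O
acceptors; N/O–H donors; planar all-carbon rings aromatic). Standard
protonation states are assumed (Asp/Glu deprotonated, Arg/Lys protonated,
His neutral); structures without explicit polar hydrogens are accepted,
but donors then skip the angle check, with a warning.

Partial charges are taken from the input when present (an SDF
`partial_charges` field); otherwise a small built-in per-residue table
spreads the formal charge over the charged group and places modest
dipoles on polar backbone/side-chain atoms. This is a point-charge
description throughout — no multipoles, no polarization.

The active site is the set of residues with any heavy atom within 6 Å of
the template ligand's heavy atoms, the usual docking-grid convention; in
pipeline commands that analyse a whole ensemble the site is the union
over all poses.

## Interaction detection

Typed ligand–receptor contacts use explicit geometric windows, all
configurable (`InteractionCriteria`):

| kind           | criterion (defaults)                                         |
|----------------|--------------------------------------------------------------|
| H-bond         | donor–acceptor ≤ 3.5 Å and D–H…A ≥ 120°; strong ≤ 3.0 Å, ≥ 150° |
| salt bridge    | cation-group centre to anion O ≤ 4.0 Å                       |
| π–π            | ring-centroid distance ≤ 5.0 Å; parallel ≤ 30°, edge ≥ 60° interplanar |
| cation–π       | cation centre to ring centroid ≤ 5.0 Å                       |

A salt bridge is reported *in addition to* an H-bond when both hold (a
charged amine can satisfy both simultaneously on a carboxylate); π
geometries between 30° and 60° are reported as parallel with a
`displaced` flag. The guanidinium cation centre is the mean of the three
nitrogens; ring centroids are heavy-atom means with best-fit-plane
normals. The detector is tested against an independently written
all-pairs enumeration for exact record-set equality.

Ensemble contact profiles report, per residue, the fraction of poses with
at least one typed record (`typed_only`, default) or any heavy-atom pair
within 4.0 Å (`any_contact`); both modes are exposed because relative
occurrence plots in the literature rarely state which convention they
use.

## Ensemble binding space

A scored pose set is reduced to the 80 most favourable (lowest-ΔG) poses,
the retention count used in ensemble docking of transporter ligands, then
summarized by: mean and sample SD of ΔG; the mode as the centre of the
most populated 0.5 kcal/mol bin anchored at the minimum (the bin rule is
our choice — only the statistic itself is standard); the range; the mean
pairwise heavy-atom rmsd *without* superposition (binding-mode
displacement: poses live in one receptor frame); and a sensitivity score,
defined here as range over the mean pairwise *superposed* rmsd — score
variability attributable to conformational adjustment. The exact
sensitivity formula of the property-space literature is not public, so
ours is an explicit stand-in, recorded in every output.

Clustering is greedy leader clustering in input order on non-superposed
rmsd (deterministic, O(nk)); the representative is the medoid of the most
populated cluster, ties broken by lower ΔG then lower index (whether the
original method used medoid or best-scored member is unstated; the medoid
is the more robust default). Orientation classification projects each
pose onto a ligand axis (cationic amine N → aromatic-ring centroid) and
labels it after the nearer of two reference poses when within 40°,
otherwise `intermediate`.

## Monte Carlo torsional search

The Boltzmann-jump protocol: at each step the rotatable bonds are
perturbed by zero-mean normal draws rescaled so the per-move rms is
exactly 60° (a distribution-width reading is selectable with
`exact_rms=False`), the smaller fragment rotating about each bond axis;
the conformer is then relaxed by exactly 20 steepest-descent iterations;
and the post-minimization energy is accepted or rejected against the
current energy by the Metropolis criterion at 1000 K
(p = exp(−ΔE/RT), R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹). Rejected proposals
restore the previous conformer. The receptor is rigid and this is
asserted every step. Monitored pairs (e.g. amine ↔ carboxylate oxygens,
ring ↔ ring) are recorded as centroid distances after every step, the
marker used to read bond stability off a trajectory.

The energy model is deliberately minimal — per-element Lennard-Jones,
Coulomb with a distance-dependent dielectric (ε = 4r, conversion constant
332.06 kcal Å mol⁻¹ e⁻²), and a 3-fold torsion term averaged over
substituent pairs so it is invariant to atom relabeling. Intramolecular
pairs closer than three bonds are excluded. Absolute energies are not
comparable to any published force field; only the protocol's behaviour
(acceptance law, minimization contract, monitoring) is the point.
Minimization operates in torsion space (the ligand's internal geometry is
rigid except for rotations about rotatable bonds) with a numeric gradient
and backtracking line search, which guarantees the energy is
non-increasing over the 20 iterations. A consequence of torsion-only
moves is that the fragment on the larger side of every rotor never moves;
for the toy ligand the aromatic system is that anchor, so its monitored
ring distance is constant unless receptor motion is supplied externally.

## Electrostatic complementarity

The ligand solvent-accessible surface is sampled Shrake–Rupley style: a
golden-spiral lattice (default 256 points/atom) on each atom's expanded
sphere (r_vdW + 1.4 Å probe), discarding points inside any neighbour's
expanded sphere; each surviving point carries the area weight
4π(r+probe)²/points-per-atom. Ligand and protein electrostatic potentials
are evaluated at every point from point charges with ε = 1
(units kcal mol⁻¹ e⁻¹). The local score is

    EC(x) = 1 − |ESP_L + ESP_P| / max(|ESP_L|, |ESP_P|, k)

with both potentials first clamped to ±cap; the global score is the
area-weighted mean over the ligand surface. Defaults k = 5 and cap = 12.
The magnitude bars are part of this implementation by construction: only
with them does the expression give +1 for perfectly complementary and −1
for identical clashing potentials. The unit system in which k and cap are
interpreted is a declared convention of the point-charge ESP; both are
configurable.

## Binding free-energy estimate

`estimate_dg` preserves the term inventory of empirical ΔG functions
while making every coefficient an explicit, configurable default
(`DGParams`); no published calibration is reproduced and the total is a
ranking device, not an affinity prediction:

- intermolecular Lennard-Jones and Coulomb from the MC energy model;
- H-bond rewards: −1.0 per strong H-bond, −0.5 per weak, −1.0 per salt
  bridge (the salt bridge reinforces at the strong level);
- Born-like polar desolvation: Σ 166·s·q²·buried/r_Born over atoms with
  |q| ≥ 0.25, r_Born = covalent radius + 0.5 Å, buried fraction from the
  per-atom SAS free vs in complex. The screening factor
  s = 1/ε_interior − 1/ε_water (defaults 20 and 78.5) expresses that
  burial moves a charge from water into a protein *interface*, not into
  vacuum; with a low interior dielectric a contact ion pair would come
  out net unfavourable, contradicting the term's role;
- +0.6 per buried (fraction > 0.5) donor/acceptor with no H-bond record;
- nonpolar solvation: −0.025 kcal mol⁻¹ Å⁻² of buried ligand SAS;
- internal strain: ligand internal energy of the pose minus its
  torsionally relaxed value (never negative);
- entropy: +0.65 kcal/mol per rotor whose moving fragment has a heavy
  atom within 4.5 Å of the receptor (a frozen degree of freedom).

The estimator's contract, enforced by test, is monotonicity: over
generator-built complexes in which favourable contacts are planted one at
a time (nothing → salt bridge → + parallel π stack → + H-bond), the total
strictly decreases.

## Statistics

Activity correlation regresses log10(IC50) on ΔG by ordinary least
squares (the log transform is the pharmacological convention and can be
disabled) and reports the Pearson r; n ≥ 3 and non-degenerate variance
are required. Group comparisons (e.g. the two binding orientations) use
the two-sided Welch unequal-variance t-test. One calibration note: a
correctly computed 95% CI misses the true slope ~1 time in 20, and the
derandomized recovery tests assert coverage at that nominal rate rather
than demanding 20/20.

## Synthetic data: what it emulates and what it does not

The generators stand in for a docking engine's output with *known ground
truth*:

- `make_toy_pocket`: residues (default roster Glu494, Asp328, Arg104,
  Phe335, Phe556, Thr497, Gln332 — the pharmacophoric cast of the
  transporter's allosteric vestibule, not its geometry) built from ideal
  internal-coordinate templates with polar hydrogens only, placed on a
  cylindrical shell with their key groups aimed at the site axis,
  seeded rolls, and ≥ 2.5 Å inter-residue separation.
- `make_toy_ligand("mdma_like")`: a methylenedioxyphenyl ring system plus
  an N-methyl aminium chain — one cation, one aromatic ring, two ring
  oxygens, 3 rotatable bonds, net +1.
- `plant_pose_ensemble`: poses scattered around cluster centres on the
  site axis, with per-state ΔG drawn from stated normals (defaults
  −7.1 ± 0.9 and −6.3 ± 0.6 kcal/mol for the two states), an orientation
  mix enforced by axis alignment, and per-residue interaction frequencies
  planted as *exact counts*: the quota poses are placed so the typed
  criterion holds (translation for distance-only kinds, rotation for
  H-bonds — which therefore overrides those poses' orientation labels),
  and the others are verified against the detector to miss every targeted
  residue, with bounded retries. Recovery tolerances therefore test the
  detector, not sampling noise. Infeasible targets (frequencies summing
  above 1, geometric conflicts) raise a spec error.
- `make_mc_system` / `make_graded_poses`: seeded searches for clash-free
  complexes with a planted salt bridge + aromatic contact (and, for the
  graded set, 0–3 contacts switched off by minimal rotations about the
  shared amine anchor). Steric screening uses the Lennard-Jones term
  itself: a flat distance floor would reject legitimate tight salt
  bridges while admitting strongly repulsive carbon contacts.

What the toys do not have: protein folds, backbone context beyond single
residues, water, ions, induced fit, nonpolar hydrogens, or realistic
charge distributions. Passing tests therefore demonstrate that the
*analysis layer* — detection, statistics, protocol physics, scoring
structure — behaves correctly on inputs with known truth; they say
nothing about docking accuracy or real-transporter energetics.

## Numerical choices and degenerate inputs

Pair distances below 0.1 Å are clamped with a warning (capped repulsion);
ESP charges closer than 0.01 Å to a surface point contribute as if at
that range. Single-pose ensembles omit SD/rmsd fields; a rigid ensemble
(zero conformational rmsd) leaves the sensitivity score undefined rather
than infinite. Ties: retention filter by input order (stable sort), mode
bin by lowest bin, cluster representative by lower ΔG then lower index.
Altloc handling keeps the first conformer; insertion codes are ignored;
multi-model receptor PDBs use the first model.

Default problem sizes used by the test suite and pipeline examples —
ensembles of 90–200 poses, pockets of 2–7 residues (≈ 30–90 atoms), MC
runs of tens of steps in tests with the 1000-step default reserved for
production runs — were chosen so every statistical check runs at full
strength (10⁴ Metropolis trials, 20-seed recovery sweeps) on a single
CPU.

## Known limitations

- Torsion-space minimization cannot relieve bond-length/angle strain and
  never moves the ligand as a rigid body; the MC explores conformer
  space, not pose space.
- The EC units are a convention; global EC values saturate quickly for
  small, formally charged ligands in charged toy pockets.
- The ΔG estimator's coefficients are sane-magnitude defaults; only
  orderings (more favourable planted contacts → lower total) are
  meaningful, not absolute values.
- Receptor flexibility is out of scope; monitored receptor–receptor
  distances are only meaningful when receptor motion is supplied
  externally.
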