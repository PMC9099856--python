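# bindspace

Ensemble binding-space analysis for protein–ligand pose sets: interaction
fingerprinting, pose-set statistics and clustering, Metropolis Monte
Carlo torsional search, electrostatic complementarity, and a
component-structured binding free-energy estimate — with seeded synthetic
generators that stand in for a docking engine.

## The problem

Ensemble docking of a flexible, cationic ligand (the motivating case is
an MDMA-like amphetamine binding the allosteric vestibule of the human
serotonin transporter) produces dozens of scored poses across several
receptor conformations. Turning that cloud of solutions into science
requires a reproducible analysis layer:

- **Binding space.** Retain the 80 most favourable poses, characterize
  their ΔG distribution (mean, SD, binned mode, range), their
  *sensitivity* (range over mean superposed rmsd — how much the score
  moves when only the conformation does), their *binding-mode
  displacement* (mean pairwise rmsd in the receptor frame), cluster them
  (greedy leader) and extract the representative pose of the most
  populated cluster, and classify each pose between two reference
  orientations (serotonin-like vs escitalopram-like).
- **Interaction fingerprints.** Detect H-bonds (weak/strong: 3.5 Å/120°
  vs 3.0 Å/150°), salt bridges (≤ 4.0 Å), π–π (ring centroids ≤ 5 Å,
  parallel/edge by interplanar angle) and cation–π contacts, and report
  per-residue relative occurrences over the ensemble.
- **Monte Carlo stability.** Boltzmann-jump search at 1000 K — random
  torsional perturbation with an exact per-move rms of 60°, 20
  minimization steps, Metropolis acceptance p = exp(−ΔE/RT) — while
  monitoring contact distances (amine↔carboxylate, ring↔ring) along the
  trajectory.
- **Surface electrostatics.** Shrake–Rupley sampling of the ligand SAS
  and the local complementarity score
  EC = 1 − |ESP_L + ESP_P| / max(|ESP_L|, |ESP_P|, k), with k = 5 and
  potentials capped at ±12, integrated area-weighted over the surface.
- **ΔG structure and validation.** An estimator with the standard term
  inventory (LJ + Coulomb, H-bond rewards, Born-like polar desolvation,
  lost-H-bond penalties, nonpolar solvation, internal strain, entropic
  rotor freezing), plus OLS correlation of ΔG with log10(IC50) and Welch
  t-tests between orientation groups.

Every stochastic piece is seeded; every cutoff is a configurable
parameter with its default documented in `docs/methods.md`.

## Worked example

Generate a synthetic study — a seven-residue toy pocket (anionic,
cationic, aromatic and H-bonding residues on a cylindrical shell) and 90
poses of an MDMA-like ligand with planted structure (contact frequencies
0.6 on Glu494 and 0.3 on Phe335; ΔG per receptor state from
N(−7.1, 0.9²) and N(−6.3, 0.6²) kcal/mol) — then analyse it:

```bash
bindspace simulate --seed 3 --n-poses 90 --out-prefix demo
bindspace interactions --receptor demo_pocket.pdb --poses demo_poses.sdf \
    --out records.csv --profile-out profile.csv
bindspace ensemble --poses demo_poses.sdf --out binding_space.json
bindspace mc --seed 1 --steps 20
```

`profile.csv` recovers the planted interaction frequencies exactly —
the detector, not sampling noise, is what is being exercised:

```
chain,resnum,resname,occurrence,n_poses,mode
A,335,PHE,0.3,90,typed_only
A,494,GLU,0.6,90,typed_only
A,556,PHE,0.3333333333333333,90,typed_only
```

(Phe556 picks up incidental stacking contacts from poses planted on
other residues — only planted residues are frequency-controlled.)

`binding_space.json` holds the ensemble parameterization after the
top-80 retention filter:

```json
{
 "n_poses": 80,
 "mean_dg": -6.92959625,
 "sd_dg": 0.8675617757807718,
 "mode_dg": -6.4246,
 "range_dg": 4.0258,
 "sensitivity_score": 22.502521296737996,
 "mean_pairwise_rmsd": 5.8183081327435575,
 "per_state_counts": {"open": 40, "occluded": 40}
}
```

Read: 90 poses were filtered to the 80 best; their ΔG spread (range
4.03 kcal/mol around a mean of −6.93) sits on a large binding-mode
displacement (5.8 Å mean pairwise rmsd — the ensemble genuinely explores
the site rather than re-finding one pose), and both receptor states
contribute equally to the retained set.

`mc_trajectory.csv` logs, per Boltzmann step, the proposed and
post-minimization energies, the Metropolis decision, and the monitored
contact distances; the amine–Glu494 distance staying within ~3.6 Å marks
a salt bridge that survives the 1000 K perturbations:

```
step,proposed_energy,post_min_energy,accepted,energy,amine-GLU494,ring-PHE335
0,-0.872889904155485,-7.198532593658673,True,-7.198532593658673,3.593298069693971,3.930453791805544
...
19,-2.463723441331293,-7.198452156187599,True,-7.198452156187599,3.5909329260513525,3.930453791805544
```

The same operations are importable as a library
(`bindspace.ensemble.binding_space_summary`,
`bindspace.interactions.detect_interactions`, `bindspace.mc.run_mc`,
`bindspace.ec.compute_ec`, `bindspace.dg.estimate_dg`,
`bindspace.stats.fit_dg_activity`, …), which is the intended interface
for anything beyond one-off runs.

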