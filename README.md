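# armflex

Analysis toolkit for the collective bend/twist dynamics of α-solenoid
proteins (ARM-repeat architectures) and their peptide interfaces, exercised
end-to-end on synthetic solenoid fixtures with analytically known ground
truth.

The pipeline mirrors a standard MD/normal-mode characterization workflow:

1. **structio** — structure/trajectory data model, multi-model PDB I/O,
   Kabsch superposition, per-frame RMSD and per-atom RMSF.
2. **synthetic** — idealized 10-repeat, 3-helix-per-repeat Cα solenoid
   built from an exact screw transform; sinusoidal hinge-bend and
   per-repeat-twist trajectories with seeded Gaussian noise; a bound
   extended pseudo-peptide whose salt-bridge / hydrogen-bond / hydrophobic
   contacts follow an exact per-frame schedule.
3. **clustering** — reference-structure clustering: randomly sample a
   reference from the merged trajectories, remove everything within an RMSD
   cutoff *d* (default 2.5 Å), repeat until empty, then assign all frames
   to their nearest reference and tabulate per-trajectory frequencies (the
   convergence diagnostic).
4. **enm** — Cα anisotropic elastic-network Hessian, the 87 lowest-frequency
   normal modes (modes 1–6 rigid), entropy-based degree of collectivity,
   and mode displacement on a mass-weighted-RMS grid of ±3.0 Å at 0.1 Å
   steps (61 conformations per mode) with a restraint-energy screen.
5. **covariance** — PCA of the Cα displacement covariance, normal-mode /
   principal-component overlap, residue cross-correlation maps (DCCM), and
   pseudo-trajectory merging.
6. **geometry** — radius of curvature through three anchor atoms
   (circumradius; reduces to d²/(2√(d²−m²)) for the isoceles arrangement)
   and inter-repeat H3 helix-axis angles/torsions, per structure or per
   frame.
7. **interactions** — interface contact detection with inclusive criteria
   (donor–acceptor ≤ 3.5 Å; D–H–A deviation from linearity ≤ 60°; closest
   side-chain carbons ≤ 4.0 Å) and per-contact occupancy with the ≥ 50%
   report filter.
8. **cli** — stage subcommands plus a deterministic full-pipeline runner.

## Command line

```sh
armflex generate --seed 1 --out fixtures/          # synthetic fixture set + ground truth JSON
armflex cluster --d 2.5 --seed 0 fixtures/traj_*.pdb
armflex modes --n 87 --cutoff 10 fixtures/solenoid.pdb
armflex pca fixtures/traj_0.pdb
armflex dccm fixtures/traj_0.pdb
armflex geometry --annotation fixtures/ground_truth.json fixtures/traj_0.pdb
armflex contacts --ensemble fixtures/complex_ensemble.pdb
armflex run --seed 1 --out report/                 # all stages, manifest + log
```

All inputs and outputs are plain text (PDB, CSV, JSON, YAML). Trajectories
are interchanged as multi-model PDB.

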