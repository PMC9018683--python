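# ssnmrpipe

A tested, reusable pipeline for solid-state NMR structure work on protein
assemblies:

- **Synthetic data** (`ssnmrpipe.synthetic`) — ideal-helix models, perturbed
  multi-model bundles, cross-peak lists generated from a structure under an
  isotope labeling scheme (with controllable shift degeneracy and noise),
  trajectory ensembles with scheduled contacts, and two-state Markov series —
  every artifact comes with ground truth for recovery testing.
- **Labeling** (`ssnmrpipe.labeling`) — sparse ¹³C labeling schemes
  (U-¹³C₆ built in; 2-¹³C-/1,6-¹³C-glucose shipped as editable,
  literature-derived data tables) and pair observability for CC/NC
  correlation experiments.
- **Peak assignment** (`ssnmrpipe.assignment`) — shift matching within
  tolerance, unambiguity criteria applied in a fixed order (unique match,
  single intra-residue possibility, single sequential possibility, single
  spin-system-corroborated possibility), a homolog distance filter (default
  9 Å), an ambiguity cap (≤ 3 surviving possibilities), and audited
  region re-inspection against a newer structure.
- **Restraints** (`ssnmrpipe.restraints`) — classification by sequence
  separation (0 intra / 1 sequential / 2–4 medium / ≥5 long; the
  |i−j| = 4 boundary is configurable via `medium_max`), bound conversion
  (intra 1.5–6.5 Å, inter 2.0–7.2 Å), category tables, per-residue counts,
  and violation statistics with r⁻⁶ pooling for ambiguous groups.
  I/O: lossless native TSV, XPLOR/CNS NOE `assign` tables (read/write,
  OR-groups), minimal NMR-STAR v3 restraint loops (read), TALOS-style
  torsion prediction tables (read).
- **Bundle analytics** (`ssnmrpipe.bundle`) — Kabsch superposition and RMSD
  (global, pairwise-bundle, regional with global-fit-then-local-evaluate
  convention), hydrogen-bond detection, atom distances, and helical
  filament construction from per-subunit twist/rise.
- **Density docking** (`ssnmrpipe.docking`) — Gaussian-blurred simulated
  density (FWHM = resolution), masked about-mean cross-correlation, and a
  global rigid-body search over random quaternion rotations and uniform
  translations. Self-contained MRC2014 map read/write.
- **Trajectory analytics** (`ssnmrpipe.trajectory`) — contact occupancy
  (pooled double-sum over simulations and interfaces; per-simulation
  averaging behind a flag), RMSF, pairwise distance maps, TICA
  (symmetrized time-lagged covariances, variance-floor regularization),
  and 2-D free-energy surfaces with minimax-path barrier estimation.

## CLI

One entry point with per-stage subcommands; every stage writes its
artifacts plus a `manifest.json` into the run directory and is
deterministic for a fixed seed:

```sh
ssnmrpipe simulate --n-res 60 --seed 1 --out run/sim
ssnmrpipe assign --peaks run/sim/peaks.tsv --shifts run/sim/shifts.tsv \
    --homolog run/sim/model.pdb --truth run/sim/truth.json --out run/assign
ssnmrpipe tabulate --restraints run/assign/restraints.tsv --out run/tab
ssnmrpipe validate --bundle run/sim/bundle.pdb \
    --restraints run/assign/restraints.tsv --out run/val
ssnmrpipe rmsd --bundle run/sim/bundle.pdb --selection "resid 6-55 and backbone"
ssnmrpipe build-filament --protomer run/sim/model.pdb --twist -162.1 --rise 27.6
ssnmrpipe dock --model run/sim/model.pdb --resolution 9 --seed 1
ssnmrpipe occupancy --traj run/traj1.pdb --traj run/traj2.pdb --pairs 3:17
ssnmrpipe tica --features run/features.tsv --lag 1
ssnmrpipe fes --projections run/tica/projections.tsv
```

A TOML config file can supply per-command defaults
(`ssnmrpipe --config cfg.toml simulate`); explicit flags override it.
Exit codes: 0 success, 2 config error, 3 missing input, 4 internal.

Selections use a small grammar: `clause ("and" clause)*` where a clause is
`all`, `backbone`, `heavy`, `sidechain`, `resid RANGE...` (e.g.
`resid 6-165`), `name NAME...`, or `chain ID...`.

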