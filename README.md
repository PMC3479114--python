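# pullkit

Analysis toolkit for constant-velocity pulling (steered-MD-style) trajectories
of protein domains, built around the question of how destabilizing point
mutations lower a domain's mechanical resistance. The motivating system is
the von Willebrand factor A2 domain, whose ADAMTS13 cleavage site is buried
until tension undocks the C-terminal helix α6 from the hydrophobic core it
shields; type 2A von Willebrand disease mutations weaken that packing and
lower the force at which the core becomes solvent-exposed.

The package provides, as composable library modules plus a CLI:

- **structure_io** (`pullkit.structure`) — PDB and multi-model-PDB reading and
  writing (via biotite), a plain-text `xyz-frames` trajectory dialect,
  residue/atom selections in author numbering, and whitespace-separated
  nonbonded parameter tables.
- **geometry** (`pullkit.geometry`) — Kabsch superposition, RMSD time series
  with separate fit/measure selections, RMSF profiles against an iteratively
  refined mean structure, the B-factor relation RMSF = √(3B/8π²), and
  length-preserving running averages.
- **surface** (`pullkit.surface`) — Shrake–Rupley SASA with a deterministic
  spiral point set, a separable compute/context occlusion split, and SASA time
  series.
- **contacts** (`pullkit.contacts`) — side-chain center-of-mass contacts
  (≤ 6 Å, inclusive), the native-contact rule (present in ≥ 60% of force-free
  frames of at least one run), and the anchor-defined buried-core selection.
- **energetics** (`pullkit.energetics`) — switched 12-6 Lennard-Jones and
  truncated Coulomb side-chain interaction energies (switch 10–12 Å,
  332.0636 kcal·Å/(mol·e²)), and mutant−WT energy differencing.
- **secstruct** (`pullkit.secstruct`) — simplified DSSP (Kabsch–Sander H-bond
  energies, H/G/E/T/C classes) for unfolding timelines.
- **pulling_sim** (`pullkit.pulling`) — the synthetic-data generator: a
  Gō-model bead chain whose buried core is shielded by a terminal strap,
  BAOAB Langevin dynamics at 300 K (2 fs step, 1 ps⁻¹ damping), and the
  pulling protocol: a dummy point moving at 5 Å/ns drags the last bead
  through a 2 kcal/mol/Å² spring, reported as F = k·extension
  (1 kcal/mol/Å = 69.479 pN). Also a scripted-trajectory builder with exact
  ground truth.
- **unfolding_analysis** (`pullkit.unfolding`) — rupture events: core exposure
  = first SASA sample strictly above 50 Å², force peak = maximum of the
  20-ps-smoothed force within a 400 ps window centered on the exposure.
- **stats_compare** (`pullkit.stats`) — replicate mean ± SEM, one-tailed
  pooled-variance Student t, significance classes (p ≤ 0.05 significant,
  ≤ 0.10 marginal).

## Worked example

```bash
pullkit run-pipeline --out-dir demo --seed 1
```

simulates three wild-type and three mutant pulling replicates of the bundled
toy domain (the mutant's core contact wells are scaled ×0.5), derives the
buried core from native contacts of three force-free runs, detects each run's
exposure event and windowed force peak, and prints:

```
MUT 275 ± 5 pN vs WT 467 ± 11 pN, one-tailed p = 0.0000 (significant)
```

i.e. the destabilized mutant's core becomes solvent-exposed at a
significantly lower force peak than wild type — the synthetic analogue of the
weakened mechanical resistance of disease mutants. Per-run force and
core-SASA series (TSV) and a full JSON report land in `demo/`.

The same stages are available separately:

```bash
pullkit simulate --out-dir run1 --seed 7 --duration 3.5   # one pulling run
pullkit analyze-pull --run-dir run1                        # rupture event JSON
pullkit plot --run-dir run1                                # force/SASA panel
pullkit compare --group-a 292,310,275 --group-b 458,440,475 --direction less
```

## xyz-frames format

One block per frame: a header line `<n_atoms> <time_ps>`, then one line per
atom `<element> <x> <y> <z>` (Å, 6 decimals). Frames are concatenated in time
order; the topology comes from the accompanying structure.
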