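# Methods

## Problem and observables

A mechanically loaded protein domain resists unfolding until tension undocks
a terminal structural element from the hydrophobic core it buries; the force
at which the core becomes solvent-exposed is the experimentally meaningful
"rupture force" of that first event. pullkit implements the corresponding
analysis chain for constant-velocity pulling trajectories:

1. **Core definition.** A contact exists between two residues when their
   side-chain centers of mass are within 6 Å (boundary inclusive; "side
   chain" means heavy atoms from Cβ outward, with Cα standing in for
   glycine). A contact of the anchor residue is *native* when present in at
   least 60% of the frames of at least one force-free run; the core is the
   anchor plus the union of its native partners over replicate runs.
   Sequence neighbours (i±1) are excluded so covalently enforced proximity
   does not enter the core. Distances at the inclusive boundary carry a 1 nÅ
   tolerance to absorb center-of-mass rounding.
2. **Exposure detection.** The core's SASA (Shrake–Rupley, probe 1.4 Å,
   side-chain atoms of the core residues shaded by the whole protein) is
   evaluated per frame; the exposure time is the first sample *strictly*
   above 50 Å², on the raw (unsmoothed) series. A series that starts above
   threshold reports its first sample; one that never crosses raises a
   distinct no-event error.
3. **Force peak.** The applied force is F = k·extension of the virtual
   spring (k = 2 kcal/mol/Å²; reported both in kcal/mol/Å and in pN at
   69.479 pN per kcal/mol/Å). The rupture peak is the maximum of the
   20-ps-running-averaged force within a 400 ps window *centered* on the
   exposure time (the window's anchoring is a documented choice; it is
   configurable). Ties break to the earliest sample.
4. **Replicate comparison.** Groups of replicate peaks are summarized as
   mean ± SEM (n−1 standard deviation over √n) and contrasted with a
   one-tailed pooled-variance Student t-test (direction: mutant < wild
   type); p ≤ 0.05 is significant, 0.05 < p ≤ 0.10 marginally significant.
   No multiple-testing correction is applied — contrasts are reported per
   comparison, matching the replicate-triplet study design this pipeline
   serves.

## Numerical components

**SASA.** Shrake–Rupley with a deterministic golden-angle spiral point set
(960 points by default; 240 for per-frame series, where the ~1% quadrature
error is far below the thermal fluctuation of the signal). The computed
selection and the occluding context are independent, so a buried group's
exposure can be asked for while the whole structure still shades it. Radii
come from a bundled per-element table (Bondi-style) and can be overridden by
a parameter file.

**Superposition.** Kabsch via SVD with a determinant guard (only proper
rotations), optional weights, and an explicit collinearity check. RMSF
profiles align frames to an iteratively refined mean structure (two passes;
pass count configurable, zero passes for fixtures with no net rigid motion).
Per-segment RMSD fits on the segment itself, so it measures internal
deformation; fitting on a separate immobile selection measures displacement.

**Running averages** span `round(width/spacing)` samples centered on each
sample (the extra sample trailing for even counts), truncated at the edges so
length is preserved.

**Nonbonded energies.** 12-6 Lennard-Jones (ε, r_min per atom;
Lorentz–Berthelot combination) and Coulomb (332.0636 kcal·Å/(mol·e²),
dielectric 1 by default), both multiplied by the cubic-in-r² switching
function that is 1 below 10 Å, 0 above 12 Å and C¹-continuous between.
Electrostatics are switched truncation by design: the trajectories this
package analyses are solvent-free and desk-scale, so a lattice sum would add
cost without meaning. `vs_system` scope equals `vs_protein` plus an
identically zero solvent term and is recorded as such. 1-2/1-3 bonded pairs
are excluded via the topology where one exists; the averaging stride is
every saved frame.

**Secondary structure.** Simplified DSSP: Kabsch–Sander electrostatic H-bond
energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN), bond called below
−0.5 kcal/mol, amide H built geometrically (1.01 Å along the bisector) when
absent. Two consecutive i→i+4 turns give H, i→i+3 give G, mutual or offset
bridge patterns give E, isolated turns T, else C, with priority H > G > E > T.
β-bulges and the bend class are not handled — the goal is an unfolding
timeline, not DSSP parity.

## The synthetic generator

The generator emulates, at desk scale, replicate equilibrium and
constant-velocity pulling runs of a folded domain whose buried core is
shielded by a terminal element. It is a Gō-type bead chain (default 36 beads
of 110 amu): a spherical-cup body (radius 7 Å, Saff–Kuijlaars spiral path, a
65° polar opening), a five-bead core cluster threaded mid-chain (tetrahedron
around the anchor, one edge facing the opening), and a four-bead terminal
strap docked across the opening directly above the core pair — the
terminal-helix analogue. Chain order within the core places the anchor's two
upward-facing partners outside its i±1 neighbourhood, so the native-contact
rule recovers exactly the designed core.

Bond rest lengths and contact minima equal the built distances, making the
construction a potential minimum. Attractive wells (depth ε, default
4 kcal/mol) go on all pairs within 7.5 Å of the built geometry — wider than
the 6 Å analysis rule, so near-miss pairs (e.g. anchor-to-wall at ~7 Å) are
restrained at their native distance without ever counting as contacts; this
keeps the cluster from wandering and the occupancy statistics sharp.
Body/core contacts are twice as deep as strap-involving ones
(`scaffold_scale = 2`), making strap undocking the designed first rupture —
the same ordering the terminal-helix mechanism shows. Everything else repels
through a WCA wall at 3.8 Å. A "mutant" scales the wells touching the
designated core beads (×0.5 by default), weakening exactly the packing a
core point mutation weakens, and scales the beads' analysis-side LJ ε in
step.

Dynamics are BAOAB Langevin (300 K, friction 1 ps⁻¹, 2 fs step, snapshots
every 10 ps), chosen for accurate configurational sampling at this step
size; with friction → 0 it reduces exactly to velocity Verlet, which the
energy-conservation test exploits. The fixed first bead is pinned by zeroing
its force and velocity. The dummy point starts at the pulled (last) bead and
moves at 5 Å/ns along the initial fixed→pulled axis; the spring force
−k(x_pulled − x_dummy) acts on the pulled bead only. Default run length is
3.5 ns (17.5 Å of dummy travel): in the default geometry the strap undocks
and the core exposes at ~1.4–2.1 ns across seeds and well depths, so the
event is comfortably inside every run while keeping a full replicate study
in the minutes range on one CPU. The same seed yields bit-identical
trajectories (chunked Gaussian noise from a seeded generator feeding a
deterministic compiled integrator).

What the generator does **not** emulate: atomistic packing and side-chain
rotamers, explicit solvent and its friction anisotropy, secondary-structure
mechanics (the strap is a strap, not a helix), and the ~50,000-atom scale of
the runs it stands in for. Tests passing on this model validate the
*analysis* — detection, windowing, contact rules, statistics — not any
quantitative force scale of a real protein; the simulated peak forces
(hundreds of pN at these loading rates) are model quantities.

## Design choices on genuinely open points

- **Window anchoring**: the 400 ps force-peak window is centered on the
  exposure time; a leading or trailing window is a CLI/API override.
- **Threshold semantics**: strict `>` on raw SASA; the smoothed series is
  used only for the force maximum.
- **Core SASA scope**: side-chain atoms of core residues, whole-protein
  context. All-atom SASA is available through the same API.
- **RMSF reference**: iterative mean structure (2 passes) rather than
  first-frame alignment — stabler profiles on short windows.
- **Fit selections**: whole-molecule RMSD fits on all Cα (or all beads);
  per-segment RMSD fits on the segment itself.
- **Student rather than Welch t**: pooled variance matches the n = 3
  replicate design the pipeline serves.
- **Spring constant units**: the pulling spring is 2 kcal/mol/Å²
  (kcal/mol alone is not a stiffness; Hooke's law fixes the dimension).
- **Insertion codes** are rejected, first altlocs kept: the analysis targets
  single-conformer trajectories, not crystallographic heterogeneity.

## Limitations

- `native_contacts` keys partners by residue number; multi-chain systems
  with duplicated numbering should be analysed per chain.
- The simplified DSSP has no β-bulge or bend handling and will fragment
  irregular sheets more than DSSP proper.
- The energetics module computes interaction energies, not free energies;
  solvent screening beyond a uniform dielectric is out of scope.
- Automatic segmentation of the full unfolding cascade is not attempted; the
  secondary-structure timeline reports it qualitatively.
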