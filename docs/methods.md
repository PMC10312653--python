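# Methods

## The model

`coilslab` implements a coarse-grained (CG) framework for studying whether
coiled-coil (CC) domains alone can drive liquid-liquid phase separation
(LLPS) of proteins.  In the stickers-and-spacers picture, each *coil
segment* is a sticker — a helical, heptad-organized domain that binds coils
of the same type on other chains — and each *linker segment* is an inert
spacer.  Two multivalency axes are tunable:

- **polymeric multivalency** — the number of coil segments per chain
  (2-coil-1-linker, 3-coil-2-linker, 4-coil-3-linker, ...);
- **multimeric multivalency** — how many partners one coil engages at once
  (dimer-, trimer-, or tetramer-forming coils).

### Coarse-graining

One bead per residue, centered on the C-alpha position.  All beads share a
mass of 109 amu (average residue mass), a diameter sigma = 0.47 nm, and the
GROMACS unit system (nm, ps, kJ/mol, amu, K).  Chains are built as ideal
alpha-helical traces (rise 0.15 nm/residue, twist 100 degrees/residue,
helix radius 0.23 nm); the equilibrium bond length (~0.383 nm), pseudo-bond
angle (~90.4 degrees) and pseudo-torsion (~+50 degrees) are measured off
that ideal trace, so the bonded equilibria and the builder are consistent
by construction.

### Energetics

- Bonds: harmonic, k = 5000 kJ/mol/nm^2 in coils.
- Angles: harmonic in the angle, k = 150 kJ/mol/rad^2 in coils.
- Torsions: periodic proper dihedrals, V = k (1 + cos(m*phi - phi_s)) with
  m = 1 and k = 20 kJ/mol in coils, minimized at the helical +50 degrees.
- Linkers use the same equilibria with all force constants divided by 100,
  which lets them relax into disordered conformations while coils stay
  helical.  The coil constants were calibrated so that an isolated
  32-residue coil retains >= 90% helical pseudo-torsions at 293 K (shipped
  as a test; the routine check runs a 10 ns window of the 100 ns
  calibration criterion).
- Nonbonded: Lennard-Jones, truncated and shifted to zero at 1.1 nm.
  Sticky beads of coils with the same `coil_type_id` on *different* chains
  attract with the coil sticky strength epsilon_coil (5.5 kJ/mol for
  dimer-forming coils; 4.5 / 4.0 kJ/mol for trimer- / tetramer-forming
  coils, where the lower strengths prevent aberrantly large multimers).  Every
  other pair — linker beads, backbone beads, cross-type sticky pairs, and
  all intrachain sticky pairs — interacts with a weak excluded-volume
  epsilon of 0.1 kJ/mol.  First and second bonded neighbors (1-2, 1-3) are
  excluded from nonbonded terms.

The trimer-forming strength is not independently documented, only that it
was lowered relative to the dimer value for the same reason as the
tetramer strength.  We calibrate it against the multimer census (a dilute
box of 3-coil proteins): 4.0 kJ/mol leaves trimer-mode systems
monomer/dimer-dominated, 5.0 kJ/mol tips them into stable pairwise dimers,
and 4.5 kJ/mol yields a trimer-dominated census — so 4.5 kJ/mol is the
default, exposed in the force-field config.

### Multimer-driving bead layout

How a coil's maximum valence is enforced is a genuinely open design point;
we enforce it geometrically through the angular coverage of sticky
positions on the helix surface.  With a 100 degrees/residue twist, heptad
position p in heptad k sits at an angle of 100p - 20k degrees around the
helix axis:

- dimer: positions (a, d) = (0, 3) — the classic narrow interface stripe
  (10 sticky beads on a 32-residue coil);
- trimer: positions (0, 3, 4) — widens the interface into a contiguous
  ~100 degree arc that one partner cannot fully bury, leaving attraction
  exposed for a third helix;
- tetramer: positions (0, 2, 3, 5) — two opposed sticky faces, allowing
  partners on both sides of the helix.

Combined with excluded volume, wider angular coverage permits more
simultaneous partners.  Specificity is imperfect by construction (isotropic
pair potentials cannot enforce exact valence), which reproduces the
framework's characteristic behavior: dimer-forming coils are dominated by
dimers but not exclusively; trimer- and tetramer-forming coils produce
mixtures.

### Interaction scheme

The *maximally specific* scheme is the only one implemented: attraction
exists solely between sticky beads of coils carrying the same type id on
different chains.  Each architecture assigns every coil position its own
type (coil 1 binds only coil 1 of other chains, etc.), and all intrachain
coil-coil attraction is disabled.

## Dynamics engine

Desk-scale Langevin dynamics with a BAOAB splitting: friction 0.2 1/ps,
COM translational velocity removed every 10 steps, dt 20-25 fs.  At zero
friction the scheme reduces to velocity Verlet, which is how energy
conservation is tested (drift < 0.1% over 1e4 steps).  Forces are the
exact analytic gradient (verified against central finite differences to
1e-5 relative).  Neighbor lists use a cell list with a 0.3 nm Verlet skin,
rebuilt whenever any bead has moved more than half the skin, so no eligible
pair within the 1.1 nm cutoff is ever missed — the same concern that
motivates the very strict Verlet-buffer tolerance (1e-7) written into the
exported run files, since density inhomogeneity in phase-separated boxes
makes default buffer estimates unsafe.  Steepest-descent minimization uses
the protocol's defaults (force tolerance 50 kJ/mol/nm, initial step 2 pm,
adaptive).  Overlapping beads produce force-capped, finite dynamics; a
non-finite potential aborts the run and returns the last valid frame.

Semi-isotropic NPT is *not* re-implemented.  The slab-forming compression
is approximated at desk scale by staged rescaling of the box z-length and
of molecule centers (molecules move rigidly, so bonds are never strained),
with short 150 K Langevin relaxation between stages and a final
minimization; the final z-length is exactly the requested fraction of the
initial one.  At-scale runs use the exported NPT files on an external
engine (Parrinello-Rahman, z-only coupling, 1 bar, compressibility 3e-4
1/bar, tau 5 ps).

## Slab protocol

The pipeline mirrors the standard direct-coexistence recipe: single-chain
NVT runs provide a pool of equilibrated conformations; five are chosen at
random from the equilibrated portion; copies are packed at random rigid
placements with a 1.0 nm inter-chain tolerance into 25x25x100 nm under a
standardized coil budget of 450 coils (so 2-/3-coil proteins place exactly
450 and the 4-coil protein places 448 in 112 copies); the box is
compressed along z to 10-20% of its length, expanded to z = 150 nm with
molecules unwrapped and the slab recentered, equilibrated in NVT, then run
in production.  Exported bundles carry every stage's settings (dt 20 fs
for NPT/NVT at 200 ns; production 20 us at dt 25 fs; temperatures 253,
273, 293, 313 K; three replicates with distinct seeds; mdrun -rdd 1.6 nm
in the manifest).

Equilibration is detected from center-window and combined edge-window
density series: the earliest time from which every subsequent
sliding window (10 samples) has a fitted linear slope whose total change
is below 2% of the series mean, for both series.  The numeric criterion is
a package choice (no standard exists); both the window and tolerance are
arguments.  Desk-scale pipelines fall back to discarding the first half of
production when counting noise in small boxes defeats the slope test.

## Analyses

- **Density profiles**: number density in 2 nm z-slices, time-averaged,
  replicate mean +- population sd.  Conservation (sum of density times
  slice volume = mean bead count) holds to 1e-9 relative.
- **Coexistence densities**: dense = mean over 70-80 nm; dilute = mean
  over 1-35 plus 115-150 nm (windows rescale proportionally for other box
  lengths).  Binodal points whose dense and dilute mean +- sd intervals
  overlap are flagged melted and omitted.
- **Molecular clusters**: two molecules are linked when any inter-molecular
  bead pair is within 0.9 nm (minimum image); clusters are single-linkage
  connected components, accumulated over equilibrated frames and normalized
  by cluster count.
- **Multimer census**: coils i, j on different chains are bound when at
  least 3 attraction-eligible sticky-bead pairs (same coil type) are within
  0.9 nm; an n-mer is a connected component of n coils; fractions are
  computed over coil instances and time-averaged.  The same-type
  restriction matters: raw proximity contacts between non-interacting
  coils of different types would artificially merge multimers.
- **LLPS call**: both markers required — dense/dilute ratio >= 10 and a
  largest cluster holding >= 90% of the proteins.  The thresholds quantify
  "sharp density transition" and "nearly all proteins" and are exposed as
  arguments.
- **Validation metrics**: mass-weighted radius of gyration; RMSD with
  optimal (Kabsch) superposition; KL divergence between Gaussian KDEs
  (Scott's rule, 2048-point trapezoidal quadrature over the joint range
  plus three bandwidths, q clamped at 1e-12 with a warning).  The KDE/KL
  machinery is validated against the closed-form Gaussian result
  (KL = dmu^2 / 2 sigma^2).

## Desk-scale study conditions

Full-scale slab runs (450 coils, 20 us, triplicate, four temperatures) are
cluster-scale jobs; this package runs the same pipeline at sizes chosen for
a single CPU and states them explicitly:

- **Multimer census**: 8 copies of the 3-coil protein (24 coils) in a
  22 nm cubic box at 293 K, dt 25 fs; 2 ns discarded, 10 ns analyzed,
  frames every 0.25 ns.  Concentration is the main control on the
  dimer-trimer balance (mass action); the chosen dilution (0.0023
  coils/nm^3) puts dimer-mode systems in the dimer-dominated regime that
  the framework is designed to show.  Multimer exchange at this binding
  strength is slower than the analysis window, so compositions carry
  cluster-level noise: with 24 coils one dimer is ~8% of composition, and
  independent runs scatter by roughly ten percentage points.
- **Slab coexistence**: 6 copies of the 3-coil protein (18 coils) packed
  into 10x10x40 nm, compressed to 15%, expanded to z = 40 nm, 0.5 ns NVT,
  6 ns production; frames are recentered on the slab's center of mass
  (circular mean under periodic boundaries) and the analysis windows are
  the 150 nm-convention windows rescaled to the box.  Desk-scale slabs
  cannot melt within nanoseconds — detaching a multi-coil chain crosses a
  barrier of tens of kT — so high-temperature miniatures measure slab
  annealing, not evaporation; coexistence at temperature is an at-scale
  (exported-run) observable.

These miniatures preserve the protocol's structure and the model's
qualitative physics (temperature destabilizes the slab; higher multimer
valence compacts it) but not its quantitative binodals: dense-phase
densities at desk scale carry large finite-size fluctuations, and
melting temperatures shift with system size.  Passing desk-scale checks
therefore demonstrates mechanism and implementation correctness, not
at-scale phase boundaries.

## Synthetic fixtures

The fixtures module generates ground-truth data with no physics: slab
density fields (uniform placement at prescribed dense/dilute densities),
cluster arrangements with exact composition (straight bead rods, spacing
chosen so intra-chain beads never bridge clusters), and density time
series with known equilibration behavior.  They emulate the *geometry* of
analysis inputs (densities, contacts, stability) but none of the dynamics,
so they validate the analysis stack, not the model.

## Known limitations

- No residue-specific chemistry; linkers are purely inert.
- No parallel/antiparallel orientation specificity between coils.
- Coils are held helical regardless of multimerization state (no
  folding-upon-binding free-energy cost).
- Multimer valence control is geometric and imperfect; tetramer-forming
  systems in particular produce trimer/tetramer mixtures.
- The internal engine is for desk-scale work; it is single-threaded and
  does not implement a barostat.
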