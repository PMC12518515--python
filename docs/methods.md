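# Methods

## Scope and model overview

`eesim` is a forward simulation of epidural electrical stimulation (EES) of
the rat lumbosacral cord. Nothing is fitted to data: a parametric synthetic
anatomy generates the study conditions, a quasi-static field solver maps
electrode currents to extracellular potentials, compartmental axon models
convert potentials to recruitment thresholds, and a statistics layer reduces
thresholds to the quantities of interest (threshold, saturation, selectivity
index) with bootstrap uncertainty. Absolute thresholds depend strongly on
geometric detail that a parametric anatomy cannot reproduce; the simulation
is therefore read *directionally* (dorsal vs ventral, mode vs mode), and the
test suite asserts directions and structural/analytic identities, not
absolute milliamp values.

## Synthetic anatomy

Coordinates: x lateral, y dorsoventral (+y dorsal), z rostro-caudal
(+z caudal), lengths in mm. Segments L2–S1 have lengths 3.3, 2.8, 2.7, 2.8,
2.4, 2.7 mm. Cross sections are concentric elliptic cylinders running the
full grid; defaults (half axes in mm) follow the ~3 mm diameter of the rat
lumbar cord: white matter (1.5, 1.25), CSF (1.8, 1.55), dura (2.0, 1.75),
epidural fat (2.6, 2.4), vertebral bone (3.4, 3.2), saline bath to the
grounded grid boundary (default margin 4 mm, trimmed in the desk presets).
The gray-matter butterfly is the union of a wide lateral ellipse
(0.95, 0.42) and a tall central ellipse (0.35, 0.95). The dura is 0.2 mm
thick so the default 0.1 mm and the desk-scale 0.2 mm grids both resolve it;
a voxel size coarser than the dura is a hard error. All of these are config
parameters (`SpinalCordSpec`), not constants.

Roots are discrete rootlet bundles (default 3 per segment per side, radius
0.18 mm) leaving the cord at ±30° from the dorsoventral axis and running
caudally through the CSF at ~90% of the CSF half-axes, labeled as
anisotropic root tissue with tangent fiber directions. Sensory fibers run
rostrally in the dorsal columns (up to 6 mm), curve out through the dorsal
root entry zone and continue ~4 mm caudally in the dorsal root; motor fibers
start in the ventral horn, exit through the ventral white matter and run
~5 mm caudally in the ventral root. Trajectories get ±0.06 mm seeded jitter
and alternate left/right across the units of a pool. Motor pools (fractions
of 40 units per muscle): TA L3 0.2 / L4 0.7 / L5 0.1; GC L4 0.2 / L5 0.6 /
L6 0.2; VM L2 0.2 / L3 0.7 / L4 0.1; ST L4 0.2 / L5 0.8, rounded to integers
by largest remainder so each pool sums exactly to its size.

Electrode contacts are 1000 µm (z) × 300 µm (x) single-voxel-thick patches
on the epidural surface at the midpoint of L2–L6, midline, dorsal and
ventral, with an insulating backing layer; monopolar (5), bipolar (all 10
pairs, rostral contact active) and tripolar (all 10 triples, middle contact
active) configurations per side. Labels list the involved segments
(`L4`, `L2_5`, `L2_5_6`).

Tissue conductivities (S/m): gray 0.23; white and roots 0.6 longitudinal /
0.083 transverse; CSF 1.7; dura 0.6; fat 0.04; bone 0.02; saline 2.0. The
per-voxel tensor is σ⊥I + (σ∥−σ⊥)dd̂ᵀ with d the local fiber direction
(z in white matter, rootlet tangents in roots), which is symmetric positive
definite with eigenvalues {σ∥, σ⊥, σ⊥} by construction.

## Field solver

The quasi-static potential solves ∇·(σ∇V) = 0 with a 7-point finite-volume
scheme on the voxel grid; face conductances are harmonic means of the
adjacent voxels' normal projections n·σ·n — the standard treatment of
discontinuous coefficients, which keeps the matrix symmetric and interior
row sums exactly zero (discrete conservation). Contacts inject a prescribed
total current uniformly over their footprint voxels (unit stimulus 1 µA;
all amplitudes scale the unit field linearly, so each contact is solved once
and multipolar fields are superpositions). The outer bath boundary is
grounded (V = 0), which also realizes the monopolar distant return.
Insulation voxels carry zero conductivity and drop out of the system.
Solution by Jacobi-preconditioned conjugate gradients to a relative residual
of 1e-8 (1e-6 in the smoke preset), deterministic by construction.

Validation uses the exact Green's function of a grounded spherical bath,
V(r) = I/(4πσ)(1/r − 1/R): a grounded *finite* domain necessarily shifts the
point-source law 1/(4πσr) by the boundary term −1/(4πσR), so the test
compares against the closed form including that term (with the effective
radius of the discrete V=0 shell) and requires 5% agreement over mid-range
radii. Grid convergence is measured, not assumed: halving the voxel size
from 0.2 to 0.1 mm changes potentials sampled along fibers near a dorsal L4
contact by 4.9% RMS on the trimmed reference geometry.

Potentials along fibers are sampled trilinearly (exact for affine fields);
a compartment outside the grid is an error naming the fiber.

## Axon model

Fibers are 9 µm double-cable myelinated axons: nodes of Ranvier separated
by internodes of 2 MYSA + 2 FLUT + 6 STIN compartments, an explicit myelin
sheath and a periaxonal space. Geometry versus diameter (internodal length,
node/axon diameters, FLUT length, lamella count) comes from the published
double-cable diameter table, linearly interpolated — at 9 µm, between the
8.7 µm and 10.0 µm rows (internode ≈ 1035 µm, 112 lamellae). Passive
constants: axoplasmic and periaxonal resistivity 70 Ω·cm, membrane
capacitance 2 µF/cm², myelin 0.1 µF/cm² and 1 mS/cm² per membrane divided
by the 2N lamella membranes, periaxonal widths 2 nm (node/MYSA) and 4 nm
(FLUT/STIN). At nodes the myelin branch collapses to a short so the
periaxonal potential tracks the extracellular one.

Channels: nodal fast Na (m³h), persistent Na (p³), slow K (s), fast K (n⁴)
and leak; internodal leak plus a slow HCN conductance. Rate functions are
the standard 36–37 °C mammalian-node forms for m/h/p/s, a human-node-type
n gate and a slow Boltzmann HCN gate. Conductance densities and reversal
potentials live in editable YAML tables (`eesim/params/motor.yaml`,
`sensory.yaml`) with per-entry provenance comments. The sensory/motor
distinction — same-diameter sensory fibers are more excitable — is carried
by the sensory table's +2 mV hyperpolarizing shift of fast-Na activation;
the shift magnitude is a calibration chosen once to (a) keep the resting
state stable (settled rest −79 vs −81 mV) and (b) preserve the
sensory < motor threshold ordering (200 vs 300 µA on the reference straight
fiber over a point source), and is asserted by test, not assumed. Larger
shifts were rejected during design because they destabilize rest or cause
afterdischarge; both failure modes are what the rest-stability and
refractoriness tests guard.

Integration: backward Euler on the interleaved two-cable system (banded
solve, bandwidth 2) with gates advanced by exponential (Rush–Larsen) updates
at the previous membrane voltage; dt = 5 µs during the 4 ms after each pulse
onset and 50 µs between train pulses. Halving dt moves thresholds by at most
one 25 µA grid step. The extracellular drive is amplitude × unit-field ×
w(t) with w a symmetric biphasic rectangular waveform, 200 µs *per phase*
(cathodic leading at the active contact); the total-duration reading of the
pulse width is available as a config switch (`per_phase=False`) since both
conventions are in use. Runs start from the settled zero-drive steady
state (25 ms settle, cached per fiber class and compartment count).

A fiber is recruited when every node spikes (upward crossing of −20 mV)
within 10 ms of a pulse; for trains the default rule requires this for
every pulse of the train (one-to-one following), switchable to
first-pulse-only — the criterion under trains is genuinely underdetermined,
and accommodation by the slow-K conductance makes train thresholds sit
slightly above single-pulse thresholds here. Thresholds are the smallest
amplitude on the 25–1000 µA grid that recruits, found by bisection under a
monotonicity assumption whose lower neighbour is verified non-recruited by
the bisection invariant; monotonicity itself is spot-checked by test.

## Recruitment, selectivity, statistics

A motor unit's threshold is min(sensory fiber, motor fiber) — the
monosynaptic Ia→motoneuron relay is assumed reliably suprathreshold — with
class-specific rules available (`unit_rule="sensory"|"motor"`). Muscle
recruitment at an amplitude is the fraction of its units at or below it;
threshold/saturation are the smallest grid amplitudes reaching 10% / 90%
(40 distinct unit thresholds make these the 4th and 36th order statistics);
unreached levels are the sentinel +∞. The selectivity index at an amplitude
is target recruitment minus the mean of the other three muscles; the
reported SI is its maximum over the target's threshold→saturation range
(grid top when saturation is unreached), ties broken toward the lowest
amplitude. Per (side, mode, muscle), sweeps select Minimum Threshold,
Minimum Saturation and Maximum Selectivity Index over configurations with
lexicographic label tie-breaks. The frequency comparison re-evaluates the
deduplicated top-selectivity configurations under 5-pulse trains at 50 and
100 Hz.

Bootstrap: each replicate redraws m = 40 units per muscle with replacement
(a unit's two fibers travel together) and recomputes threshold, saturation
and SI_max; K = 10,000 replicates give the reported mean ± SD. Streams are
derived from one root seed and the (side, mode, configuration, muscle)
labels, so results are byte-reproducible. The t tests and one-way ANOVA
with Bonferroni correction operate on the replicate sets (dorsal winner
replicates against the ventral winner's point estimate, one-sided in the
metric's favourable direction). This inherits a known conceptual weakness:
bootstrap replicates are not independent observations, so these p-values
overstate evidence; `stats.percentile_ci` provides percentile intervals as
the calibrated alternative, and the reported stars (*, ***) should be read
as a reporting convention, not calibrated error rates.

## Presets and problem sizes

* `paper`: 0.1 mm voxels, 40 units/muscle, all 25 configurations/side,
  25 µA grid, K = 10,000 — the full study conditions (hours of CPU).
* `fast`: 0.2 mm voxels (bath margin 3 mm), 8 units/muscle, monopolar L4+L5
  per side, the full 25 µA grid, K = 200 — the desk-scale conditions used
  for the directional dorsal-vs-ventral checks (~4–5 min on one CPU). The
  25 µA amplitude resolution is kept because a coarser grid quantizes
  thresholds/saturations below the dorsal–ventral contrast itself.
* `tiny`: 0.2 mm voxels (margin 1.5 mm), 4 units/muscle, one monopolar
  configuration/side, 200 µA grid, K = 100 — smoke tests (~15 s).

## What the synthetic data does and does not show

The generator reproduces the *structure* of the modeled preparation —
segmental pool distributions, dorsal/ventral root courses, nested tissue
shells, contact geometry — but is left–right and dorso-ventrally symmetric
(real rat cords have thicker ventral white matter, which further raises
ventral thresholds), uses one fiber diameter (9 µm) per class, parametric
ellipses instead of histology contours, and no vertebra-level detail.
Passing tests therefore demonstrate internal consistency and the
physiology-driven directional effects (sensory > motor excitability
dominating the dorsal–ventral contrast), not quantitative prediction of
in-vivo thresholds. Known further limitations: no somas, dendrites,
synapses, Aβ/C fibers or network effects; strictly quasi-static (no
capacitive tissue behaviour); regular-grid voxelization of curved shells
(controlled by the measured convergence check).
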