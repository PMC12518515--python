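# eesim

Biophysical simulation of **epidural electrical stimulation (EES)** of the rat
lumbosacral spinal cord, comparing **dorsal (dEES)** and **ventral (vEES)**
electrode placements in how efficiently and how selectively they recruit four
hindlimb muscles: tibialis anterior (TA), gastrocnemius (GC), vastus medialis
(VM) and semitendinosus (ST).

The package is aimed at computational neuroscientists and neural-engineering
researchers who want a dependency-light, fully scriptable stand-in for the
usual CAD + FEM + NEURON toolchain: everything from the volume conductor to
the recruitment statistics is plain Python on numpy/scipy.

## What it computes

1. **Synthetic anatomy** (`eesim.anatomy`) — a parametric voxel model of
   segments L2–S1 (lengths 3.3/2.8/2.7/2.8/2.4/2.7 mm): gray-matter
   butterfly, white matter, dorsal/ventral rootlets, CSF, dura, epidural fat,
   vertebral bone and a grounded saline bath; 1000 × 300 µm epidural contacts
   on the dorsal and ventral midline of each segment (5 per side → 5
   monopolar, 10 bipolar, 10 tripolar configurations per side); and 40 motor
   units per muscle, each with one 9 µm Aα-sensory fiber in a dorsal root
   and one 9 µm α-motor fiber in a ventral root, distributed over segments
   by the muscle's motor-pool fractions.
2. **Extracellular fields** (`eesim.field`) — the quasi-static anisotropic
   Laplace problem ∇·(σ∇V) = 0 discretized by finite volumes on the voxel
   grid (white matter/roots: σ∥ = 0.6, σ⊥ = 0.083 S/m along the local fiber
   direction), solved by preconditioned CG for unit injected current;
   amplitudes scale the unit solution linearly.
3. **Axon models** (`eesim.cable`, `eesim.channels`) — double-cable
   myelinated fibers (NODE/MYSA/FLUT/STIN; each internode = 2 MYSA + 2 FLUT
   + 6 STIN) with nodal Na/Na_p/K_s/K_f/leak and internodal HCN channels in
   sensory- and motor-specific parameter tables, driven extracellularly by
   symmetric biphasic pulses (200 µs per phase) and integrated by backward
   Euler. A fiber is *recruited* when its action potential propagates from
   the first to the last node; thresholds are searched over the 25–1000 µA
   grid in 25 µA steps.
4. **Recruitment analysis** (`eesim.recruitment`, `eesim.stats`) — per-muscle
   recruitment curves R(amp); threshold/saturation = amplitudes reaching
   10% / 90% recruitment; the selectivity index of muscle *M* under
   configuration *E*

   SI_M^E = max over amp in DR of { R_M^E(amp) − (1/(N−1)) Σ_{n≠M} R_n^E(amp) },

   maximized over the muscle's dynamic range DR (threshold→saturation),
   bounded in [−1, 1]; per-mode Minimum Threshold / Minimum Saturation /
   Maximum Selectivity Index selections; bootstrap resampling of the 40
   motor units (m = 40 with replacement, K = 10,000 replicates) with
   one-sided t tests and one-way ANOVA + Bonferroni on the replicates.
5. **Pipeline + CLI** (`eesim.pipeline`, `eesim.cli`) — config-driven,
   cached, seeded orchestration with tidy CSV outputs, an HDF5 curve store,
   optional VTK export and figure generation.

## Worked example

```python
from eesim.config import ExperimentConfig
from eesim.pipeline import run_experiment

cfg = ExperimentConfig.fast(seed=1)   # 0.2 mm voxels, 8 units/muscle,
                                      # monopolar L4+L5 per side
res = run_experiment(cfg, out_dir="results/fast")
print(res.selections.pivot_table(index=["muscle", "selection"],
                                 columns="side", values="value"))
```

prints (µA for thresholds/saturations, dimensionless for SI):

```
muscle       selection     dorsal    ventral
    GC  min_threshold        75.0      150.0
    GC  min_saturation       75.0      200.0
    GC  max_selectivity     0.375      0.167
    ST  min_threshold        50.0      150.0
    ST  min_saturation       75.0      175.0
    TA  min_threshold        75.0      150.0
    TA  max_selectivity     0.083      0.333
    VM  min_threshold        75.0      125.0
    VM  max_selectivity     0.000      0.792
```

Read: dorsal stimulation recruits every muscle at roughly half the current
of ventral stimulation (minimum monopolar thresholds 50–75 µA vs
125–150 µA, saturations 75–125 µA vs 175–200 µA) because the dorsal contacts
sit over the highly excitable Aα-sensory fibers of the dorsal roots and
dorsal columns, while ventral contacts face the less excitable α-motor
fibers. Conversely, ventral stimulation is more *selective* for TA and VM
(SI 0.33 and 0.79 vs 0.08 and 0.00 dorsally): motor fibers are recruited
only close to the active contact, whereas dorsal stimulation co-activates
sensory fibers of many muscles running together in the dorsal columns. Both
directions mirror the experimental contrast between dorsal and ventral
epidural stimulation reported in the literature.

The same run from the shell:

```bash
eesim run-all --preset fast --seed 1 --out results/fast
```

## Layout

```
src/eesim/
  anatomy.py      volume conductor, electrode catalog, fiber populations
  field.py        finite-volume anisotropic Laplace solver + sampling
  channels.py     gating kinetics + YAML parameter tables (params/)
  cable.py        double-cable axon model, thresholds
  recruitment.py  curves, threshold/saturation, selectivity, sweeps
  stats.py        bootstrap, t tests, ANOVA + Bonferroni
  pipeline.py     cached orchestration, figures
  config.py       ExperimentConfig + presets (paper / fast / tiny)
  cli.py          `eesim` command
docs/methods.md   model description, parameter provenance, limitations
```
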