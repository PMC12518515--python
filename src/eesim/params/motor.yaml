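# Alpha-motor fiber channel table (double-cable myelinated axon).
#
# Provenance notes:
#   - NODE naf/nap/ks/leak densities and reversal potentials are the published
#     MRG mammalian-node values (McIntyre, Richardson & Grill 2002).
#   - NODE kf and the internodal kf/h/leak densities follow the motor-variant
#     extension of that model (Gaines et al. 2018); magnitudes here are
#     calibrated small densities with the documented channel placement (fast K
#     at the node, HCN and leak in the internodal membrane) since the source
#     prints no table we can ship verbatim.  Edit in place to explore.
fiber_class: motor
v_rest_mV: -80.0
na_activation_shift_mV: 0.0
reversal_potentials_mV:
  na: 50.0
  k: -90.0
  leak: -90.0
  h: -54.3
conductances_S_per_cm2:
  NODE:
    naf: 3.0
    nap: 0.01
    ks: 0.08
    kf: 0.02
    leak: 0.007
  MYSA:
    leak: 0.001
    h: 0.0002
  FLUT:
    leak: 0.0001
    kf: 0.002
    h: 0.0002
  STIN:
    leak: 0.0001
    h: 0.0002
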