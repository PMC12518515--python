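# Aalpha-sensory fiber channel table (double-cable myelinated axon).
#
# Differences from the motor table implement the sensory-variant physiology
# (sensory fibers of the same diameter are more excitable than motor fibers):
#   - na_activation_shift_mV: fast-Na activation (m gate) shifted toward
#     hyperpolarized voltages, the principal excitability difference of the
#     sensory parameterization (Gaines et al. 2018 direction); the magnitude
#     is calibrated to preserve sensory < motor thresholds, not copied from a
#     printed table.
# Everything else matches the motor table.
fiber_class: sensory
v_rest_mV: -80.0
na_activation_shift_mV: 2.0
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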