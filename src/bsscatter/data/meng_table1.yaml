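# Per-dataset parameterisation of the dehazing baseline, tuned per region
# (global / lung / spine) against ground truth in the original comparison.
SimPBU100:
  epsilon: 1.0e-8
  A_global: 1.5
  A_lung: 0.9
  A_spine: 2.5
  delta_global: 0.3
  delta_lung: 0.15
  delta_spine: 0.4
  C0: 1.0
  C1: 4.8
  lambda: 1.0
SimPat120:
  epsilon: 1.0e-8
  A_global: 1.9
  A_lung: 1.0
  A_spine: 2.8
  delta_global: 0.3
  delta_lung: 0.15
  delta_spine: 0.4
  C0: 1.0
  C1: 4.8
  lambda: 1.0
RePBU100:
  epsilon: 1.0e-8
  A_global: 1.5
  A_lung: 0.9
  A_spine: 2.5
  delta_global: 0.3
  delta_lung: 0.15
  delta_spine: 0.4
  C0: 1.0
  C1: 4.8
  lambda: 1.0
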