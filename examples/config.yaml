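# Example configuration for a scaled-down open-state study.
#
# The mechanical coefficients below are literature-typical orders of
# magnitude for torsional DNA models; they are NOT the coefficient set of
# any specific published study and should be replaced with authoritative
# values for quantitative work.

composition:
  seed: 1
  parts:                     # per-part length and A-T content
    - {length: 20, at_fraction: 49.8}
    - {length: 20, at_fraction: 57.1}
    - {length: 20, at_fraction: 72.2}

mechanics:
  bases:
    A: {inertia: 7.61e-44, radius: 5.8e-10, torsion: 6.0e-19, k12: 0.055}
    T: {inertia: 4.86e-44, radius: 4.8e-10, torsion: 6.0e-19, k12: 0.055}
    G: {inertia: 8.22e-44, radius: 5.7e-10, torsion: 6.0e-19, k12: 0.085}
    C: {inertia: 4.11e-44, radius: 4.7e-10, torsion: 6.0e-19, k12: 0.085}
  beta: 7.0e-34              # J s; damping time ~1e-10 s (calibration knob)

forcing:
  F0: 0.526e-22              # N m
  omega: 0.4e12              # 1/s

integration:
  dt: 1.0e-14                # s
  T: 3.0e-11                 # s

sampling:
  m: 500

bond:
  kD: 1.05
  energies: [1.0e-4, 1.0e-3, 1.0e-2]   # EcrH grid, units of 1e-22 N m

plots: false
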