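# Desk-scale scenario: the full design shrunk so that simulation + training
# run in minutes on one CPU, with selection strengthened (2Ns = 200 / 400)
# so the three classes remain learnable at the reduced scale: both selected
# classes approach the overdominant equilibrium (1/2) by the present, at
# different speeds, so the temporal trajectory carries the weak-vs-moderate
# signal while the present-day sweep-like cluster separates them from N.
#
# Population sizes/times are reduced ~20x relative to the full-scale design;
# the onset:sampling-age proportions (onset at 1.0, samples at 0.8 / 0.4 /
# 0.2 / 0.1 / 0 of it) and the 10/10/10/10/40 block sizes are unchanged.
# theta_locus = 4*N*mu*L = 20 at the bottlenecked size of 500.
simulation:
  locus_length: 50000.0
  mu: 1.0e-7
  rho: 1.0e-7
  demography:
    generation_time: 25.0
    epochs:
      - {start_time: 100, size: 1000} # ancestral
      - {start_time: 50, size: 500} # bottleneck to present
  selection_onset_time: 1000.0 # 40 generations before present
  focal_position: null
  sampling_scheme:
    - [800.0, 10] # 32 generations
    - [400.0, 10] # 16
    - [200.0, 10] #  8
    - [100.0, 10] #  4
    - [0.0, 40]
  rescale_factor: 1.0
  burn_in: {mode: coalescent, factor: 10.0}
  max_condition_attempts: 100
dataset:
  classes:
    - {name: "N", s: null}
    - {name: "D0.25", s: 0.20} # weak:     2Ns = 200
    - {name: "D0.5", s: 0.40} # moderate: 2Ns = 400
  n_per_class: 400
encoding:
  width: 64
network:
  mode: both
  n_filters: 16
  kernel: [3, 3]
  padding: [1, 1]
  n_residual_blocks: 2
  dropout: 0.25
  exchangeable_present: false
training:
  fractions: [0.75, 0.125, 0.125] # 300 / 50 / 50 per class
  batch_size: 32
  learning_rate: 0.001
  optimizer: adam
  max_epochs: 30
  patience: 8
  n_repeats: 3
seed: 0
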