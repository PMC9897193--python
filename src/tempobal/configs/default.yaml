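# Full-scale study design (documentation of the defaults; running it forward
# at human scale is expensive — see desk_scale.yaml for a runnable setup).
#
# 50 kbp loci under a European-like piecewise demography (a stand-in with
# round numbers, not a fitted published model), an overdominant de novo
# variant at the locus centre arising 10k years ago, three classes
# (neutral / s=0.25% / s=0.5%), 40 present-day haplotypes plus 10 ancient
# haplotypes at 8k, 4k, 2k and 1k years ago, a 64-filter 3x3/1x1 two-branch
# residual network and the 10-repeat training protocol.
simulation:
  locus_length: 50000.0
  mu: 1.25e-8
  rho: 1.25e-8
  demography:
    generation_time: 25.0
    epochs: # generations before present; oldest first; stand-in values
      - {start_time: 5000, size: 10000}
      - {start_time: 2000, size: 2000}
      - {start_time: 400, size: 5000}
      - {start_time: 200, size: 5000, growth_rate: 0.011512925464970229}
  selection_onset_time: 10000.0 # years before present
  focal_position: null # null -> locus centre
  sampling_scheme: # [age in years, haplotypes]
    - [8000.0, 10]
    - [4000.0, 10]
    - [2000.0, 10]
    - [1000.0, 10]
    - [0.0, 40]
  rescale_factor: 1.0
  burn_in: {mode: forward, factor: 10.0}
  max_condition_attempts: 100
dataset:
  classes:
    - {name: "N", s: null}
    - {name: "D0.25", s: 0.0025}
    - {name: "D0.5", s: 0.005}
  n_per_class: 2000
encoding:
  width: 128
network:
  mode: both
  n_filters: 64
  kernel: [3, 3]
  padding: [1, 1]
  n_residual_blocks: 2
  dropout: 0.25
  exchangeable_present: false
training:
  fractions: [0.8, 0.1, 0.1]
  batch_size: 32
  learning_rate: 0.001
  optimizer: adam
  max_epochs: 50
  patience: 10
  n_repeats: 10
seed: 0
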