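# Desk-scale end-to-end run: artidelta run-all --config examples/run.yaml --out results/ --seed 1
generator:
  n_participants: 6
  n_trials_per_condition: 10
  image_height_px: 57
  image_width_px: 128
exclusion:
  max_rt: 5.0
locks: [TL1, TL2, TL3]
permutation:
  n_permutations: 1000
  alpha_cluster: 0.05
  alpha_final: null   # defaults to .05 / number of locks
normalization: none
render: true
min_trials: 1
clip:
  TL1: [-3.0, 3.0]
  TL2: [-1.0, 5.0]
  TL3: [-4.0, 2.0]
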