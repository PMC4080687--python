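# Constant-total-dose experiment: eight upright positions at 1/8 of the
# photon budget each (total dose equal to one 400 mAs scan), median-combined.
# Compare the metrics.csv "all/median" row against a single full-dose run.
# Run: tiltmar -v pipeline --config dose_8x_split.yaml --out out/dose
phantom:
  kind: gammex
  spacing: 0.15
  grid: 256
positions:
  - [upright, 0]
  - [upright, 22.5]
  - [upright, -22.5]
  - [upright, 45]
  - [upright, -45]
  - [upright, 67.5]
  - [upright, -67.5]
  - [upright, 90]
dose:
  mas: 400
  mode: split     # each scan gets mas / n_positions
n_angles: 360
out_spacing: 0.1
seed: 11
combine:
  method: median
roi:
  center: [0.0, 0.0, 8.25]
  r_inner_mm: 8.0
  r_outer_mm: 16.0
  slab_mm: 7.0
  c: 11.0
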