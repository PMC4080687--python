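# Tissue-characterization disc with a 10 mm titanium rod, scanned in six
# positions (lying flat at two turns, standing upright at four turns about
# its own axis), median-combined, evaluated in an 8-16 mm ring around the rod.
# Run: tiltmar -v pipeline --config gammex_six_positions.yaml --out out/gammex
phantom:
  kind: gammex
  spacing: 0.15   # cm, in-plane pixel size of the scans
  grid: 256
positions:
  - [flat, 0]
  - [flat, 90]
  - [upright, 135]
  - [upright, 90]
  - [upright, 45]
  - [upright, 0]
dose:
  mas: 50
  mode: full      # every scan at the full tube current-time product
n_angles: 360
out_spacing: 0.1  # cm, common output mesh of the co-registration
seed: 11
combine:
  method: median
roi:
  center: [0.0, 0.0, 8.25]   # (z, y, x) cm: on the rod axis
  r_inner_mm: 8.0
  r_outer_mm: 16.0
  slab_mm: 7.0
  c: 11.0                    # Solid Water, HU
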