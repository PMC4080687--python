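# Dental phantom (six metal bodies in a 1.2 cm jaw band), scanned untilted
# and at two nods about the x axis; evaluated in a box inside the air-filled
# oral cavity (true value -1000 HU).  The metal sits at y >= 5.25 cm and the
# cavity at y = 3.5 cm, so x tilts move the restorations out of the slices
# through the cavity while the untilted scan keeps them in-slab.  Position
# entries are [axis, angle-in-degrees]; a plain number means a y tilt.
# Run: tiltmar -v pipeline --config dental_three_tilts.yaml --out out/dental
phantom:
  kind: dental
  spacing: 0.1
  grid: 256
  height: 12.0          # cm, extruded skull height
  metal_band: [-0.6, 0.6]  # cm, z range occupied by the metal restorations
positions: [["x", 0], ["x", -30], ["x", 30]]
dose:
  mas: 50
  mode: full
n_angles: 360
out_spacing: 0.1
seed: 11
combine:
  method: median
roi:
  center: [0.0, 3.5, 0.0]      # (z, y, x) cm, inside the oral cavity
  box_extents: [0.3, 1.1, 6.1] # cm
  c: -1000.0                   # air
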