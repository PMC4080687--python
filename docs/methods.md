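# Methods

This note documents the physics, algorithms and conventions implemented in
`tiltmar`, in the order data flows through the pipeline.

## Coordinate conventions

All world coordinates are `(z, y, x)` in cm, with the scanner rotation axis
along `z` and the rotation center at the world origin.  Volumes store values
as `(nz, ny, nx)` arrays; `origin` is the world position of voxel
`(0, 0, 0)`'s center.  A rigid pose maps object coordinates to laboratory
coordinates, `p_lab = R p_obj + t`; resampling onto a laboratory grid pulls
values through the inverse pose.

## Phantoms

Phantoms are 2D material-label grids over a material table (label 0 = air):

- **Tissue-characterization disc**: a 33 cm Solid Water disc (nominal
  11 HU) with a 10 mm titanium rod inserted 8.25 cm off-center.  Extruded to
  a 5 cm high cylinder for 3D scanning.
- **Dental phantom**: a jaw-sized bone/soft-tissue section with an air-filled
  oral cavity and six metal restorations (gold bridge, steel bridge, four
  gold crowns), extruded with the metal confined to a thin band of slices.

Material data are tabulated mass attenuation coefficients (cm²/g) over
40–120 keV for air, water, Solid Water, soft tissue, bone, titanium, steel
and gold.  Titanium at the 80 keV reference energy attenuates
0.405 cm²/g × 4.59 g/cm³ ≈ 1.86 cm⁻¹, so 3 cm of titanium transmits < 1% —
the root cause of photon starvation behind the rod.

## Acquisition model

For each projection angle the forward model computes per-material pathlengths
`L_m` with the Radon transform of the material indicator images, then the
polychromatic transmission over spectrum bins `b`:

```
T = Σ_b w_b · exp(−Σ_m μ_m(E_b) · L_m)
```

The default spectrum uses 3 bins at 60/80/100 keV with weights
0.50/0.30/0.20, following the bottom-heavy shape of a filtered 120 kVp tube
spectrum (fluence peaks near 60 keV after typical aluminum-equivalent
filtration).  Three bins are the minimum that produces beam hardening: the
effective attenuation per unit pathlength decreases with pathlength, which
is what bends metal line integrals away from the monochromatic truth and
creates streaks.

Detection applies, in order:

1. **Detector aperture**: transmission is convolved along the detector axis
   with a triangular kernel (0.25, 0.5, 0.25), modeling the finite detector
   pitch; this suppresses unphysical Gibbs overshoot at the sharp disc edge.
2. **Poisson dose noise**: expected counts are `N0 · T` with
   `N0 = mAs × photons_per_mas` per detector bin; counts are Poisson drawn
   from the scan's seeded generator.  The default 5000 counts per mAs places
   N0 in the 10⁵–10⁶ air-calibration range of clinical detectors at
   diagnostic current–time products.  Infinite mAs yields the noiseless
   expectation.
3. **Photon-starvation clamp**: counts are floored at 1 before the log
   transform, so rays through several cm of titanium saturate at `ln N0` —
   the mechanism behind the extreme streaks.
4. **Water precorrection**: scanners linearize the polychromatic log data
   against a water calibration; the simulator inverts the water
   beam-hardening curve so that water-only paths reconstruct correctly and
   only non-water materials (metal) leave residual hardening error.

Reconstruction is filtered back projection (ramp filter, `skimage.iradon`)
of the `ln(N0/I)` sinogram divided by the pixel pitch, followed by the HU
map `HU = 1000 (μ − μ_w)/μ_w` at the 80 keV reference (μ_w ≈ 0.1837 cm⁻¹).
360 projection angles over 180° satisfy the angular Nyquist condition for
256 detector bins.

## Tilted-series simulation

A scan of a 3D phantom at pose `R` slices the object along planes of
constant `z' = (R^T p)_z`: for each slice center inside the requested
coverage box the object section is extracted (nearest-neighbor lookup in
the rotated frame), projected, and reconstructed; stacked slices form the
scan volume, and the pose is recorded as the scan's rigid transform.  Six
standard positions are used for the disc: lying flat at two in-plane turns
and standing upright (rod axis in-plane) at four turns about the rod axis —
normals spanning multiple azimuths, so each scan's artifact halo lands on a
different part of the evaluation ring.  The dental experiment instead uses
an untilted scan plus two nods about the x axis: the restorations all sit in
the jaw band at y ≥ 5.25 cm while the evaluation box is in the cavity at
y = 3.5 cm, so an x tilt moves the metal out of the slices through the box
(a y tilt only mixes z and x and never clears it).  Split-dose mode divides
the mAs evenly across the scans.  Every scan draws noise from an independent stream
spawned from the experiment seed.

## Registration and combination

Scans are resampled onto a common output mesh of (0.1 cm)³ voxels by
pull-based trilinear interpolation through the known pose (sub-voxel
positions snap to the lattice within 1e-9 voxel to keep axis-aligned
transforms exact).  Coverage is conservative: an output voxel is covered
only if all eight interpolation corners are inside the source grid and
covered.  An optional normalized-cross-correlation grid search refines
sub-voxel translations when poses are only nominally known.

The combiner reduces the per-voxel sample set (covered scans only) by
arithmetic mean or median.  The mean's bias is, by linearity, exactly the
average of the single-scan biases — it reduces noise and error but not
bias.  The median rejects the artifact whenever fewer than half of the
scans are biased at a voxel, which the six-position geometry arranges for
almost the entire ring; it is the recommended method.

## Metrics

For a region of n voxels with values `x_i` and known truth `c`:

- bias = mean(x_i) − c
- error = mean |x_i − c|
- noise = sample standard deviation (ddof = 1)

The standard regions are a ring of 8–16 mm radius over a 7 mm slab around
the rod (Solid Water, c = 11 HU; ≈ 4200 voxels at 0.1 cm mesh) and a box
inside the dental phantom's air cavity (c = −1000 HU).  ROI voxels must all
be covered; metrics never silently shrink their support.

## Sinogram-domain MAR baselines

All four operate on a virtual sinogram (forward projection of the
HU-to-attenuation mapped slice) and the metal trace (rays intersecting the
thresholded metal mask, > 2000 HU), and re-insert the original metal voxels
after reconstruction:

- **LI**: per-projection linear interpolation across each traced run.
- **BI**: inverse-distance weighting of the nearest untraced neighbors
  along both the detector and the angle axis.
- **NMAR**: LI in-painting of the sinogram normalized by a tissue-class
  prior's sinogram (air/soft tissue/bone classification of the uncorrected
  slice), then de-normalization.
- **FSMAR**: NMAR low frequencies blended with the original's high
  frequencies near metal, weight = blurred metal mask.

Untraced bins pass through bit-exact; with an empty metal mask all four are
the identity on the sinogram.

## Dose experiment

Artifact reduction at constant total dose: one scan at 400 mAs versus eight
re-oriented scans at 50 mAs each, median-combined.  Poisson statistics give
each 1/8-dose scan √8 more noise; mean-combining would recover the
full-dose noise level exactly, and the median stays within a small factor
of it while additionally removing the orientation-dependent artifacts that
the single full-dose scan cannot escape.

## Simulator calibration

Free simulator constants were set from published physics, not fitted to
outcome thresholds: material tables from standard attenuation data; the
spectrum binning from the shape of filtered 120 kVp tube spectra; the
photon budget from clinical air-calibration count levels; scan positions,
dose levels, ring geometry and output mesh from the experimental protocol
the simulation reproduces.  The titanium rod diameter (10 mm) was chosen so
the simulated per-scan ring artifacts reach the amplitude reported for the
physical experiment, compensating for effects the simulator omits (scatter,
wider continuous spectra, cone-beam partial volume).
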