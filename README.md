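# tiltmar

Metal artifact reduction (MAR) for computed tomography by combining
co-registered scans of the same object taken in different orientations
("tilted" CTs), plus a simulation and evaluation toolkit around it.

Metal implants produce streak artifacts in CT reconstructions (beam
hardening, photon starvation).  The artifact pattern is tied to the slicing
geometry: a voxel that shares a slice plane with metal in one scan lies in a
metal-free slice when the object is re-oriented.  Combining several such
scans per voxel — by median, or by mean — therefore suppresses artifacts
that no single-scan method can remove, without any prior knowledge of the
object.  This package implements:

- **CT simulator** (`tiltmar.projector`, `tiltmar.phantoms`,
  `tiltmar.materials`): parallel-beam polychromatic Beer–Lambert forward
  projection of material-label phantoms, Poisson dose noise, a
  photon-starvation clamp, finite detector aperture, water-linearization
  precorrection and filtered back projection, producing realistic titanium
  streak artifacts.
- **Rigid co-registration** (`tiltmar.registration`,
  `tiltmar.transforms`): pull-based trilinear resampling of scan volumes
  onto a common output mesh through known rigid poses, with conservative
  coverage tracking and an optional NCC translation refinement.
- **Combiner** (`tiltmar.combine`): per-voxel mean / median over
  co-registered volumes, honoring per-voxel coverage counts.
- **Metrics** (`tiltmar.metrics`): bias, error and noise in Hounsfield
  units over ring or box ROIs with a known true value.
- **Sinogram-domain MAR baselines** (`tiltmar.mar`): linear interpolation
  (LI), bidirectional in-painting (BI), normalized MAR (NMAR) and
  frequency-split MAR (FSMAR), for comparison.
- **DICOM I/O** (`tiltmar.volume`) and a thin **CLI** (`tiltmar`).

## Quick start (library)

```python
from tiltmar import AcquisitionConfig, combine, evaluate, resample, ring_roi
from tiltmar.experiments import run_gammex_tilt_experiment

result = run_gammex_tilt_experiment(seed=0)   # ~2-3 min
print("single-scan average:", result.single_scan_avg_error, "HU error")
print("median of six:      ", result.median_report)
print("reductions:", result.reductions("median"))
```

Lower-level building blocks are shown in `examples/tilt_combination.py`
(simulate → register → combine → evaluate in ~40 lines) and
`examples/mar_baselines.py` (the four sinogram-domain baselines on one
slice).

## Quick start (CLI)

Experiments are declared in YAML (phantom, scan positions, dose, seed,
combination method, ROI); see `examples/configs/`.

```bash
# end-to-end: simulate -> register -> combine -> evaluate
tiltmar -v pipeline --config examples/configs/gammex_six_positions.yaml --out out/gammex

# or stage by stage
tiltmar simulate --config cfg.yaml --out out/scans
tiltmar register --series out/scans/scan_00 --transform out/scans/scan_00.transform.txt \
    ... --grid-shape 7 37 37 --grid-spacing 0.1 0.1 0.1 --grid-origin -0.3 -1.8 6.45 \
    --out out/reg
tiltmar combine out/reg/registered_* --method median --min-coverage 2 --out out/comb
tiltmar mar out/scans/scan_00 --algorithm nmar --out out/mar
tiltmar evaluate out/comb/combined --ring 0 0 8.25 8 16 7 --true-hu 11 --out metrics.csv
```

Volumes are written as DICOM series, metrics as CSV; every metrics row
embeds the voxel count n, the assumed true value c, the combination method
and the seed.  Runs are reproducible from the config file alone: all
randomness flows from its `seed`.

## Experiments

`tiltmar.experiments` packages the standard studies:

- `run_gammex_tilt_experiment`: a 33 cm tissue-characterization disc with a
  titanium rod, scanned in six positions (flat at two turns, upright at four
  turns about the rod axis) at 50 mAs, median/mean-combined, evaluated on an
  8–16 mm ring around the rod (Solid Water truth, 11 HU).
- `run_dose_experiment`: one scan at 400 mAs versus eight re-oriented scans
  at 50 mAs each (constant total dose), median-combined.
- `run_mar_comparison`: the four sinogram-domain baselines on a single
  uncorrected slice against the same ring metrics.
- `run_dental_incremental`: a dental phantom with six metal restorations;
  an untilted scan plus two nods about the x axis move the jaw metal out of
  the slices through the oral air cavity, evaluated in an air box as scans
  accumulate.

## Acceptance

`tests/test_acceptance.py` contains one test per acceptance criterion
(physics arithmetic, √n noise law, end-to-end tilt reduction, constant-dose
reduction, numerical oracles, MAR baseline direction, FBP calibration).
A standalone report is produced by:

```bash
python scripts/acceptance.py --seed 0 --out acceptance.json
```

## Development

```bash
pytest -o addopts= -p no:cacheprovider        # full suite
```

See `docs/methods.md` for the physics and algorithmic details and the
reasoning behind the simulator's calibration.
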