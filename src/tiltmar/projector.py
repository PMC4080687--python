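"""Parallel-beam polychromatic CT simulation and filtered back-projection.

The acquisition model per detector ray is Beer-Lambert over a discrete
spectrum::

    I = N0 * sum_b w_b * exp(-sum_m mu_{m,b} * L_m)

where ``L_m`` is the pathlength through material ``m`` (from the Radon
transform of its indicator image) and ``N0`` the unattenuated photon count
per ray, proportional to the tube current-time product (mAs).  If ``N0`` is
finite, detected counts are Poisson realizations, floored at a configurable
minimum (default 1 count) before the log transform -- the photon-starvation
clamp that produces the extreme streaks behind thick metal.  The recorded
sinogram is ``ln(N0 / I)``, a line integral in cm^-1 * cm.

Before reconstruction the recorded attenuation is linearized against the
water beam-hardening curve of the spectrum (standard scanner water
precorrection): the measured value is mapped to the water-equivalent
pathlength and re-expressed at the reference energy, so water-equivalent
material reads the same HU regardless of object cross-section and only
non-water-like materials (metal) produce residual beam-hardening streaks.
Reconstruction is ramp-filtered back-projection; the image is calibrated to
Hounsfield units through the water attenuation at the reference energy.

Two deliberate simplifications relative to a clinical scanner: the geometry
is parallel-beam (the combination method under study is geometry-agnostic),
and the background air is treated as non-attenuating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import iradon, radon

from tiltmar.materials import (
    MU_WATER_REFERENCE,
    Spectrum,
    default_materials,
    hounsfield_from_mu,
    linear_attenuation,
)
from tiltmar.phantoms import Phantom3D, PhantomImage
from tiltmar.transforms import RigidTransform, rotation_about_axis
from tiltmar.volume import Volume

__all__ = [
    "Sinogram",
    "AcquisitionConfig",
    "forward_project",
    "water_precorrection",
    "fbp_reconstruct",
    "simulate_tilted_series",
]


@dataclass
class Sinogram:
    """Line-integral data: projection angle x detector bin, parallel beam."""

    data: np.ndarray  # (n_angles, n_detectors), dimensionless line integrals
    angles: np.ndarray  # degrees, strictly increasing, spanning >= 180
    detector_spacing: float  # cm
    geometry: str = "parallel"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.angles.size:
            raise ValueError("data must be (n_angles, n_detectors)")
        d = np.diff(self.angles)
        if self.angles.size > 1 and (d <= 0).any():
            raise ValueError("angles must be strictly increasing")
        step = float(np.median(d)) if d.size else 180.0
        if self.angles[-1] - self.angles[0] + step < 180.0 * (1 - 1e-9):
            raise ValueError("projection angles must span at least 180 degrees")
        if self.detector_spacing <= 0:
            raise ValueError("detector spacing must be positive")


@dataclass
class AcquisitionConfig:
    """Scan settings: dose (mAs), angular sampling and noise seed.

    ``photon_budget`` = mAs x photons_per_mas is the unattenuated count N0
    per detector bin; infinite mAs means a noiseless acquisition.  The photon
    budget scales linearly with the current-time product, so "1/n dose" is
    simply mAs/n.  The default 5000 counts per mAs puts N0 in the
    10^5 - 10^6 range at clinical current-time products, the typical
    air-calibration count level of a diagnostic CT detector element.
    """

    tube_current_time_mas: float = 400.0
    n_angles: int = 192
    n_detectors: int | None = None  # None: one bin per image column
    noise_seed: int | None = 0
    photons_per_mas: float = 5000.0
    starvation_floor: float = 1.0
    slice_thickness: float | None = None  # cm; None: in-plane pixel size
    precorrect_water: bool = True  # scanner water beam-hardening precorrection
    # finite detector aperture: fluence is integrated over the detector pitch
    # (triangular response) before photon counting; None = ideal point detector
    aperture: tuple | None = (0.25, 0.5, 0.25)

    @property
    def photon_budget(self) -> float:
        n0 = self.tube_current_time_mas * self.photons_per_mas
        if not n0 > 0:
            raise ValueError("photon budget N0 must be positive")
        return n0

    def default_angles(self) -> np.ndarray:
        return np.linspace(0.0, 180.0, self.n_angles, endpoint=False)


def _pathlength_sinograms(p: PhantomImage, angles: np.ndarray) -> dict:
    """Radon transform of each non-air material's indicator, scaled to cm.

    Returns {material_index: (n_angles, n_det) pathlength array}.
    """
    out = {}
    for lab in np.unique(p.labels):
        if lab == 0:
            continue  # background air treated as non-attenuating
        ind = (p.labels == lab).astype(np.float64)
        sino = radon(ind, theta=angles, circle=True) * p.spacing
        out[int(lab)] = np.clip(sino.T, 0.0, None)
    return out


def _transmission(pathlengths: dict, p: PhantomImage, spectrum: Spectrum, shape):
    """Spectrum-weighted transmitted fraction per ray."""
    T = np.zeros(shape)
    for e, w in zip(spectrum.energies, spectrum.weights):
        optical = np.zeros(shape)
        for lab, L in pathlengths.items():
            optical += linear_attenuation(p.materials[lab], e) * L
        T += w * np.exp(-optical)
    return T


def _detect(T: np.ndarray, cfg: AcquisitionConfig, rng=None) -> np.ndarray:
    """Apply the dose model: detector aperture integration, Poisson counts,
    starvation clamp, log transform."""
    if cfg.aperture is not None:
        k = np.asarray(cfg.aperture, dtype=np.float64)
        T = ndimage.convolve1d(T, k / k.sum(), axis=1, mode="nearest")
    n0 = cfg.photon_budget
    if np.isfinite(n0):
        if rng is None:
            rng = np.random.default_rng(cfg.noise_seed)
        counts = rng.poisson(n0 * T).astype(np.float64)
        counts = np.maximum(counts, cfg.starvation_floor)
        data = np.log(n0 / counts)
    else:
        data = -np.log(np.clip(T, 1e-300, None))
    return np.clip(data, 0.0, None)


def water_precorrection(data: np.ndarray, spectrum: Spectrum) -> np.ndarray:
    """Linearize recorded attenuation against the spectrum's water curve.

    Standard scanner beam-hardening precorrection: each recorded value
    ``q = -ln(I/N0)`` is mapped to the water pathlength ``L`` with
    ``q_water(L) = q`` and re-expressed as ``mu_water(reference) * L``.  For a
    monochromatic beam at the reference energy this is the identity.  Values
    beyond the tabulated range (200 cm of water) are a hard error -- they
    cannot arise from the starvation-clamped detector model at sane doses.
    """
    water = default_materials()["water"]
    L = np.linspace(0.0, 200.0, 2001)
    T = np.zeros_like(L)
    for e, w in zip(spectrum.energies, spectrum.weights):
        T += w * np.exp(-linear_attenuation(water, e) * L)
    q = -np.log(T)
    if data.max() > q[-1]:
        raise ValueError(
            "recorded attenuation exceeds the water linearization table"
        )
    return MU_WATER_REFERENCE * np.interp(data, q, L)


def forward_project(
    p: PhantomImage,
    angles: np.ndarray,
    spectrum: Spectrum,
    cfg: AcquisitionConfig,
    rng=None,
) -> Sinogram:
    """Simulate one acquisition of a phantom slice.

    Noise is drawn from ``rng`` if given, otherwise from a generator seeded
    with ``cfg.noise_seed``; a noiseless sinogram is obtained with an
    infinite tube current-time product.
    """
    angles = np.asarray(angles, dtype=np.float64)
    pl = _pathlength_sinograms(p, angles)
    shape = (angles.size, p.labels.shape[0])
    T = _transmission(pl, p, spectrum, shape) if pl else np.ones(shape)
    data = _detect(T, cfg, rng=rng)
    if cfg.precorrect_water:
        data = water_precorrection(data, spectrum)
    return Sinogram(data, angles, detector_spacing=p.spacing)


def fbp_reconstruct(s: Sinogram, out_spacing: float | None = None, slice_thickness: float | None = None) -> Volume:
    """Filtered back-projection of one sinogram into a single-slice HU volume.

    The reconstructed attenuation map is calibrated to HU against water at
    the scanner reference energy; the region outside the reconstruction
    circle reads -1000 HU (air).
    """
    if s.angles.size < 16:
        warnings.warn(
            f"only {s.angles.size} projection angles: severe angular undersampling",
            stacklevel=2,
        )
    if out_spacing is not None and not np.isclose(out_spacing, s.detector_spacing):
        raise ValueError(
            "reconstruction is native-resolution: out_spacing must equal the "
            "detector spacing (resample the volume afterwards to change grids)"
        )
    mu = iradon(
        s.data.T / s.detector_spacing,
        theta=s.angles,
        filter_name="ramp",
        circle=True,
    )
    hu = hounsfield_from_mu(mu)
    dz = slice_thickness if slice_thickness is not None else s.detector_spacing
    return Volume.centered(
        hu[None, :, :], spacing=(dz, s.detector_spacing, s.detector_spacing)
    )


def _scan_slice_range(rotation, coverage_box, spacing, margin=2):
    """Grid-aligned scan-frame slice centers covering a laboratory-frame box.

    The box corners are pulled into the scan frame (inverse pose) and the
    range of their z' coordinates, padded by ``margin`` slices, is snapped to
    multiples of the slice spacing.
    """
    (z0, z1), (y0, y1), (x0, x1) = coverage_box
    corners = np.array(
        [[z, y, x] for z in (z0, z1) for y in (y0, y1) for x in (x0, x1)]
    ).T
    zp = (np.asarray(rotation).T @ corners)[0]
    k_lo = int(np.floor(zp.min() / spacing)) - margin
    k_hi = int(np.ceil(zp.max() / spacing)) + margin
    return np.arange(k_lo, k_hi + 1) * spacing


def simulate_tilted_series(
    p,
    tilt_angles,
    cfg: AcquisitionConfig,
    spectrum: Spectrum | None = None,
    n_slices: int = 1,
    projection_angles: np.ndarray | None = None,
    split_dose: bool = False,
    tilt_axis: str = "y",
    coverage_box=None,
    poses=None,
) -> list:
    """Acquire the phantom at several tilt angles.

    For a :class:`~tiltmar.phantoms.Phantom3D`, each tilt rotates the object
    about ``tilt_axis`` (default the in-slice-plane y axis, so the slice
    planes cut the object differently per tilt -- the source of the
    complementary information the combiner exploits); the scan reconstructs
    the slices needed to cover ``coverage_box``, a laboratory-frame
    ``((z0,z1),(y0,y1),(x0,x1))`` region of interest in cm.  Arbitrary object
    orientations (e.g. the phantom standing upright and turned about its own
    axis) can be given via ``poses``, a list of 3x3 rotation matrices mapping
    scan coordinates to laboratory coordinates; ``poses`` replaces
    ``tilt_angles`` and is only valid for 3D phantoms.

    For a 2D :class:`~tiltmar.phantoms.PhantomImage`, tilts are in-plane
    rotations and ``n_slices`` copies of the slice are acquired with
    independent noise (a z-extruded object).

    Every scan is returned with the exact rigid transform mapping it back
    into the laboratory frame; per-scan noise streams are distinct.  With
    ``split_dose=True`` each scan gets 1/n of the configured photon budget,
    keeping the total dose constant.

    Returns
    -------
    list of (Volume, RigidTransform)
    """
    if poses is not None:
        if not isinstance(p, Phantom3D):
            raise ValueError("poses are only supported for 3D phantoms")
        rotations = [np.asarray(R, dtype=np.float64) for R in poses]
        n_scans = len(rotations)
    else:
        tilt_angles = [float(t) for t in tilt_angles]
        if len(set(tilt_angles)) != len(tilt_angles):
            raise ValueError("tilt angles must be distinct")
        rotations = None
        n_scans = len(tilt_angles)
    spectrum = spectrum if spectrum is not None else Spectrum.polychromatic()
    angles = (
        np.asarray(projection_angles, dtype=np.float64)
        if projection_angles is not None
        else cfg.default_angles()
    )
    mas = cfg.tube_current_time_mas
    if split_dose:
        mas = mas / n_scans
    scan_cfg = AcquisitionConfig(
        tube_current_time_mas=mas,
        n_angles=cfg.n_angles,
        n_detectors=cfg.n_detectors,
        noise_seed=cfg.noise_seed,
        photons_per_mas=cfg.photons_per_mas,
        starvation_floor=cfg.starvation_floor,
        precorrect_water=cfg.precorrect_water,
        aperture=cfg.aperture,
    )

    seed_root = cfg.noise_seed if cfg.noise_seed is not None else 0
    scan_seeds = np.random.SeedSequence(seed_root).spawn(n_scans)

    if isinstance(p, Phantom3D):
        if coverage_box is None:
            raise ValueError("a 3D phantom needs a laboratory-frame coverage_box")
        if rotations is None:
            rotations = [
                rotation_about_axis(tilt_axis, theta) for theta in tilt_angles
            ]
        return _simulate_3d(
            p, rotations, scan_cfg, spectrum, angles, coverage_box, scan_seeds
        )

    dz = cfg.slice_thickness if cfg.slice_thickness is not None else p.spacing
    results = []
    for theta, sseq in zip(tilt_angles, scan_seeds):
        rotp = p.rotated(theta) if theta != 0.0 else p
        pl = _pathlength_sinograms(rotp, angles)
        shape = (angles.size, rotp.labels.shape[0])
        T = _transmission(pl, rotp, spectrum, shape) if pl else np.ones(shape)
        rng = np.random.default_rng(sseq)
        slices = []
        for _ in range(n_slices):
            data = _detect(T, scan_cfg, rng=rng)
            if scan_cfg.precorrect_water:
                data = water_precorrection(data, spectrum)
            sino = Sinogram(data, angles, detector_spacing=p.spacing)
            slices.append(fbp_reconstruct(sino).values[0])
        vol = Volume.centered(
            np.stack(slices, axis=0), spacing=(dz, p.spacing, p.spacing)
        )
        results.append((vol, RigidTransform.about_axis("z", -theta)))
    return results


def _simulate_3d(p, rotations, scan_cfg, spectrum, angles, coverage_box,
                 scan_seeds):
    sp = p.spacing
    ny, nx = p.labels.shape[1], p.labels.shape[2]
    results = []
    for R, sseq in zip(rotations, scan_seeds):
        t = RigidTransform(R)
        z_centers = _scan_slice_range(R, coverage_box, sp)
        rng = np.random.default_rng(sseq)
        slices = []
        for z_scan in z_centers:
            sect = p.section(R, z_scan)
            pl = _pathlength_sinograms(sect, angles)
            shape = (angles.size, ny)
            T = _transmission(pl, sect, spectrum, shape) if pl else np.ones(shape)
            data = _detect(T, scan_cfg, rng=rng)
            if scan_cfg.precorrect_water:
                data = water_precorrection(data, spectrum)
            sino = Sinogram(data, angles, detector_spacing=sp)
            slices.append(fbp_reconstruct(sino).values[0])
        origin = (
            float(z_centers[0]),
            -(ny - 1) / 2.0 * sp,
            -(nx - 1) / 2.0 * sp,
        )
        vol = Volume(
            np.stack(slices, axis=0), spacing=(sp, sp, sp), origin=origin
        )
        results.append((vol, t))
    return results
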