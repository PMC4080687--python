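"""Forward projection physics, FBP calibration, noise and artifact realism."""

import numpy as np
import pytest

from tiltmar.experiments import SOLID_WATER_HU
from tiltmar.materials import MU_WATER_REFERENCE, Spectrum, default_materials, linear_attenuation
from tiltmar.metrics import evaluate, ring_roi
from tiltmar.phantoms import extrude, make_gammex_phantom
from tiltmar.projector import (
    AcquisitionConfig,
    Sinogram,
    fbp_reconstruct,
    forward_project,
    simulate_tilted_series,
    water_precorrection,
)

NOISELESS = AcquisitionConfig(tube_current_time_mas=float("inf"), n_angles=180)
ANGLES_180 = np.linspace(0.0, 180.0, 180, endpoint=False)
ANGLES_360 = np.linspace(0.0, 180.0, 360, endpoint=False)


def _point_detector(cfg: AcquisitionConfig, **kw) -> AcquisitionConfig:
    """Ideal point detector (no aperture) for analytic chord-length checks."""
    return AcquisitionConfig(
        tube_current_time_mas=cfg.tube_current_time_mas,
        n_angles=cfg.n_angles, aperture=None, **kw,
    )


def test_central_ray_chord_length():
    # water disc of radius r: the central ray's line integral is mu * 2r
    p = make_gammex_phantom(
        insert_spec=[], disc_diameter=20.0, spacing=0.15, shape=(192, 192)
    )
    sino = forward_project(
        p, ANGLES_180, Spectrum.monochromatic(), _point_detector(NOISELESS)
    )
    mu = linear_attenuation(default_materials()["solid_water"], 80.0)
    central = sino.data[:, sino.data.shape[1] // 2]
    assert central.mean() == pytest.approx(mu * 20.0, rel=0.02)


def test_empty_phantom_zero_integrals():
    p = make_gammex_phantom(insert_spec=[], spacing=0.15, shape=(64, 64))
    p.labels[:] = 0
    sino = forward_project(p, ANGLES_180, Spectrum.polychromatic(), NOISELESS)
    assert np.all(sino.data == 0.0)


def test_beam_hardening_effective_mu_decreases():
    # two-bin spectrum through increasing titanium chords: effective mu
    # (line integral / pathlength) must fall -- the beam-hardening mechanism
    spec = Spectrum([60.0, 100.0], [0.5, 0.5])
    ti = default_materials()["titanium"]
    mus = np.array([linear_attenuation(ti, e) for e in spec.energies])
    L = np.array([0.5, 1.0, 2.0, 3.0])
    T = 0.5 * np.exp(-mus[0] * L) + 0.5 * np.exp(-mus[1] * L)
    eff_mu = -np.log(T) / L
    assert (np.diff(eff_mu) < 0).all()
    # and through the simulator: noiseless titanium discs of growing radius
    cfg = _point_detector(NOISELESS, precorrect_water=False)
    eff = []
    for d in (2.0, 6.0):
        p = make_gammex_phantom(
            insert_spec=[("titanium", (0.0, 0.0))], insert_diameter=d,
            disc_diameter=20.0, spacing=0.15, shape=(192, 192),
        )
        p.labels[p.labels == 1] = 0  # titanium only, no water
        sino = forward_project(p, ANGLES_180, spec, cfg)
        eff.append(sino.data[:, sino.data.shape[1] // 2].mean() / d)
    assert eff[1] < eff[0]


def test_all_zero_sinogram_reconstructs_air():
    sino = Sinogram(np.zeros((180, 64)), ANGLES_180, 0.1)
    vol = fbp_reconstruct(sino)
    assert np.allclose(vol.values, -1000.0, atol=1e-6)


def test_fbp_water_disc_calibration():
    # acceptance-style check at unit-test size: noiseless monochromatic disc
    p = make_gammex_phantom(insert_spec=[], spacing=0.15, shape=(256, 256))
    cfg = AcquisitionConfig(tube_current_time_mas=float("inf"), n_angles=360)
    vol = fbp_reconstruct(forward_project(p, ANGLES_360, Spectrum.monochromatic(), cfg))
    yy, xx = p.grid_coords()
    interior = (yy**2 + xx**2) < (0.8 * 16.5) ** 2
    assert abs(vol.values[0][interior].mean()) < 15.0


def test_water_precorrection_monochromatic_identity():
    data = np.linspace(0.0, 8.0, 50).reshape(5, 10)
    out = water_precorrection(data, Spectrum.monochromatic())
    assert out == pytest.approx(data, abs=1e-3)


def test_water_precorrection_flattens_polychromatic_disc():
    p = make_gammex_phantom(insert_spec=[], spacing=0.15, shape=(256, 256))
    cfg = AcquisitionConfig(tube_current_time_mas=float("inf"), n_angles=360)
    vol = fbp_reconstruct(forward_project(p, ANGLES_360, Spectrum.polychromatic(), cfg))
    yy, xx = p.grid_coords()
    interior = (yy**2 + xx**2) < (0.8 * 16.5) ** 2
    # water-equivalent disc reads ~Solid Water HU with no cupping
    assert vol.values[0][interior].mean() == pytest.approx(SOLID_WATER_HU, abs=15.0)
    assert vol.values[0][interior].std() < 25.0


def test_photon_budget_and_validation():
    cfg = AcquisitionConfig(tube_current_time_mas=400.0, photons_per_mas=500.0)
    assert cfg.photon_budget == 200000.0
    with pytest.raises(ValueError, match="positive"):
        AcquisitionConfig(tube_current_time_mas=0.0).photon_budget


def test_determinism_same_seed_bit_identical():
    p = make_gammex_phantom(insert_spec=[], disc_diameter=8.0, spacing=0.15,
                            shape=(64, 64))
    cfg = AcquisitionConfig(tube_current_time_mas=50.0, n_angles=60, noise_seed=42)
    angles = np.linspace(0, 180, 60, endpoint=False)
    a = forward_project(p, angles, Spectrum.polychromatic(), cfg)
    b = forward_project(p, angles, Spectrum.polychromatic(), cfg)
    assert np.array_equal(a.data, b.data)
    c = forward_project(
        p, angles, Spectrum.polychromatic(),
        AcquisitionConfig(tube_current_time_mas=50.0, n_angles=60, noise_seed=43),
    )
    assert not np.array_equal(a.data, c.data)


def test_noise_scales_as_inverse_sqrt_dose():
    # reconstructed noise in a uniform ROI ~ 1/sqrt(N0) within 10% over a decade
    p = make_gammex_phantom(insert_spec=[], disc_diameter=8.0, spacing=0.15,
                            shape=(64, 64))
    angles = np.linspace(0, 180, 96, endpoint=False)
    yy, xx = p.grid_coords()
    roi = (yy**2 + xx**2) < 3.0**2

    def avg_noise(mas):
        sds = []
        for seed in range(8):
            cfg = AcquisitionConfig(tube_current_time_mas=mas, n_angles=96,
                                    noise_seed=seed)
            vol = fbp_reconstruct(forward_project(p, angles, Spectrum.monochromatic(), cfg))
            sds.append(vol.values[0][roi].std(ddof=1))
        return np.mean(sds)

    ratio = avg_noise(40.0) / avg_noise(400.0)
    assert ratio == pytest.approx(np.sqrt(10.0), rel=0.10)


def test_artifact_realism_metal_streaks():
    # physics ON (polychromatic beam, dose noise, starvation clamp, finite
    # detector aperture) versus physics OFF (monochromatic, noiseless, ideal
    # point detector): in the upright pose the beam traverses the rod
    # lengthwise, and the full physics must produce a ring error >= 3x the
    # ideal acquisition, whose streaks vanish
    from tiltmar.experiments import _gammex_3d, _ring_coverage_box, position_rotation

    p3, center = _gammex_3d(spacing=0.15, grid=256)
    pose = position_rotation("upright", 90.0)
    box = _ring_coverage_box(center, 0.15)  # a single-slice slab

    def ring_error(mas, spectrum, aperture):
        cfg = AcquisitionConfig(tube_current_time_mas=mas, n_angles=180,
                                noise_seed=5, aperture=aperture)
        (vol, t), = simulate_tilted_series(
            p3, None, cfg, spectrum=spectrum, coverage_box=box, poses=[pose]
        )
        from tiltmar.registration import GridSpec, resample

        reg = resample(vol, t, GridSpec((3, 37, 37), (0.15, 0.1, 0.1),
                                        (center[0] - 0.15, center[1] - 1.8,
                                         center[2] - 1.8)))
        roi = ring_roi(center, 8.0, 16.0, 7.0, reg)
        return evaluate(reg, roi, SOLID_WATER_HU).error

    physics_on = ring_error(50.0, Spectrum.polychromatic(), (0.25, 0.5, 0.25))
    physics_off = ring_error(float("inf"), Spectrum.monochromatic(), None)
    assert physics_off < 15.0  # streaks vanish
    assert physics_on >= 3.0 * physics_off


def test_starvation_clamp_engages_behind_thick_metal():
    # a 3 cm titanium insert transmits < 1%; at low dose the counts behind it
    # hit the floor, so those sinogram bins saturate at the clamp value
    p = make_gammex_phantom(
        insert_spec=[("titanium", (0.0, 0.0))], insert_diameter=3.0,
        disc_diameter=20.0, spacing=0.15, shape=(160, 160),
    )
    cfg = AcquisitionConfig(tube_current_time_mas=2.0, n_angles=60, noise_seed=1,
                            precorrect_water=False)
    sino = forward_project(p, cfg.default_angles(), Spectrum.polychromatic(), cfg)
    clamp = np.log(cfg.photon_budget / cfg.starvation_floor)
    assert np.isclose(sino.data.max(), clamp)
    assert (np.isclose(sino.data, clamp)).sum() >= cfg.n_angles  # every view starves


def test_severe_undersampling_warns():
    sino_data = np.zeros((12, 16))
    sino = Sinogram(sino_data, np.linspace(0, 180, 12, endpoint=False), 0.1)
    with pytest.warns(UserWarning, match="undersampling"):
        fbp_reconstruct(sino)


def test_sinogram_validation():
    with pytest.raises(ValueError, match="at least 180"):
        Sinogram(np.zeros((10, 8)), np.linspace(0, 90, 10), 0.1)
    with pytest.raises(ValueError, match="strictly increasing"):
        Sinogram(np.zeros((3, 8)), np.array([0.0, 90.0, 90.0]), 0.1)


def test_split_dose_divides_photon_budget():
    # split over 8 scans: per-scan noise ~ sqrt(8) x the full-dose noise
    p2d = make_gammex_phantom(insert_spec=[], disc_diameter=8.0, spacing=0.15,
                              shape=(64, 64))
    p = extrude(p2d, 2.0)
    box = ((-0.2, 0.2), (-2.0, 2.0), (-2.0, 2.0))
    cfg = AcquisitionConfig(tube_current_time_mas=400.0, n_angles=96, noise_seed=9)
    poses = [np.eye(3)] * 1

    def center_noise(split, n):
        scans = simulate_tilted_series(
            p, None, cfg, coverage_box=box, poses=[np.eye(3)] * n, split_dose=split
        )
        vol = scans[0][0]
        k = vol.values.shape[0] // 2
        yy, xx = p2d.grid_coords()
        roi = (yy**2 + xx**2) < 3.0**2
        return vol.values[k][roi].std(ddof=1)

    ratio = center_noise(True, 8) / center_noise(False, 1)
    assert ratio == pytest.approx(np.sqrt(8.0), rel=0.25)


def test_single_tilt_matches_direct_acquisition():
    p = make_gammex_phantom(insert_spec=[], disc_diameter=8.0, spacing=0.15,
                            shape=(64, 64))
    cfg = AcquisitionConfig(tube_current_time_mas=float("inf"), n_angles=96)
    (vol, t), = simulate_tilted_series(p, [0.0], cfg, n_slices=1)
    sino = forward_project(
        p, cfg.default_angles(), Spectrum.polychromatic(), cfg
    )
    direct = fbp_reconstruct(sino)
    assert np.array_equal(vol.values[0], direct.values[0])
    assert np.allclose(t.rotation, np.eye(3))


def test_tilted_scans_have_distinct_artifacts():
    # artifact-only images of different poses decorrelate vs the clean images
    p2d = make_gammex_phantom(
        insert_spec=[("titanium", (0.0, 2.0))], insert_diameter=0.65,
        disc_diameter=8.0, spacing=0.15, shape=(64, 64),
    )
    p = extrude(p2d, 3.0)
    box = ((-0.2, 0.2), (-3.5, 3.5), (-3.5, 3.5))
    cfg = AcquisitionConfig(tube_current_time_mas=100.0, n_angles=96, noise_seed=3)
    from tiltmar.transforms import rotation_about_axis

    poses = [np.eye(3), rotation_about_axis("z", 90.0) @ rotation_about_axis("y", 90.0)]
    scans = simulate_tilted_series(p, None, cfg, coverage_box=box, poses=poses)
    from tiltmar.registration import GridSpec, resample

    target = GridSpec((3, 40, 40), (0.1, 0.1, 0.1), (-0.1, -2.0, -2.0))
    regs = [resample(v, t, target) for v, t in scans]
    # restrict to voxels that read as Solid Water in both scans (exclude the
    # metal itself and anything outside the object) and correlate the
    # deviations from the true value
    mask = regs[0].coverage & regs[1].coverage
    for reg in regs:
        mask &= (reg.values > -500.0) & (reg.values < 1500.0)
    arts = [reg.values - SOLID_WATER_HU for reg in regs]
    assert mask.sum() > 500
    r = np.corrcoef(arts[0][mask], arts[1][mask])[0, 1]
    assert r < 0.5  # complementary, not identical, artifact patterns
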