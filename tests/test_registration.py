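"""Trilinear resampling against oracles, coverage semantics, NCC refinement."""

import numpy as np
import pytest

from tiltmar.registration import GridSpec, refine_translation, resample, sample_points
from tiltmar.transforms import RigidTransform
from tiltmar.volume import Volume


def brute_force_resample(v: Volume, t: RigidTransform, target: GridSpec):
    """Independent 8-corner weighted-sum oracle (scalar loop)."""
    inv = t.inverse()
    pts = target.voxel_centers()
    src = inv.rotation @ pts + inv.translation[:, None]
    vals = np.zeros(pts.shape[1])
    cov = np.ones(pts.shape[1], dtype=bool)
    shape = v.values.shape
    for k in range(pts.shape[1]):
        idx = [(src[a, k] - v.origin[a]) / v.spacing[a] for a in range(3)]
        idx = [round(i) if abs(i - round(i)) < 1e-9 else i for i in idx]
        if any(i < 0 or i > n - 1 for i, n in zip(idx, shape)):
            cov[k] = False
            continue
        i0 = [min(int(np.floor(i)), n - 2) for i, n in zip(idx, shape)]
        f = [i - j for i, j in zip(idx, i0)]
        acc = 0.0
        for dz in (0, 1):
            for dy in (0, 1):
                for dx in (0, 1):
                    w = ((f[0] if dz else 1 - f[0])
                         * (f[1] if dy else 1 - f[1])
                         * (f[2] if dx else 1 - f[2]))
                    acc += w * v.values[i0[0] + dz, i0[1] + dy, i0[2] + dx]
        vals[k] = acc
    return vals, cov


def test_identity_resample_is_exact(rng):
    v = Volume(rng.normal(size=(5, 6, 7)), spacing=(0.1, 0.1, 0.1),
               origin=(-0.2, -0.25, -0.3))
    out = resample(v, RigidTransform.identity(), GridSpec.like(v))
    assert np.array_equal(out.values, v.values)
    assert out.coverage.all()


def test_90deg_rotation_is_exact_permutation(rng):
    vals = rng.normal(size=(4, 9, 9))
    v = Volume.centered(vals, spacing=(0.1, 0.1, 0.1))
    t = RigidTransform.about_axis("z", 90.0)
    out = resample(v, t, GridSpec.like(v))
    # +90 deg about z maps y -> x: the output is an exact voxel permutation
    expected = np.stack([np.rot90(vals[k], k=1) for k in range(vals.shape[0])])
    assert np.array_equal(out.values[out.coverage], expected[out.coverage])
    assert out.coverage.sum() == out.values.size  # square grid: all covered


def test_affine_field_resampled_exactly(rng):
    # trilinear interpolation is exact on affine functions a + bz + cy + dx
    a, b, c, d = 5.0, 2.0, -3.0, 1.5
    v = Volume.centered(np.zeros((8, 8, 8)), spacing=(0.11, 0.12, 0.13))
    z, y, x = np.meshgrid(*v.voxel_centers(), indexing="ij")
    v = Volume(a + b * z + c * y + d * x, spacing=v.spacing, origin=v.origin)
    t = RigidTransform.about_axis("y", 23.0, translation=(0.03, 0.01, -0.02))
    target = GridSpec((6, 6, 6), (0.09, 0.09, 0.09), (-0.2, -0.2, -0.2))
    out = resample(v, t, target)
    zz, yy, xx = np.meshgrid(
        *[target.origin[i] + np.arange(target.shape[i]) * target.spacing[i]
          for i in range(3)], indexing="ij",
    )
    inv = t.inverse()
    pts = inv.apply(np.stack([zz.ravel(), yy.ravel(), xx.ravel()]).T)
    expected = (a + b * pts[:, 0] + c * pts[:, 1] + d * pts[:, 2]).reshape(out.values.shape)
    assert out.values[out.coverage] == pytest.approx(expected[out.coverage], abs=1e-10)


def test_matches_brute_force_oracle_bit_exact(rng):
    for trial in range(3):
        v = Volume(
            rng.normal(size=(5, 6, 7)),
            spacing=(0.08, 0.1, 0.12),
            origin=(-0.15, -0.2, -0.3),
        )
        t = RigidTransform.about_axis(
            "zyx"[trial], 10.0 + 15.0 * trial,
            translation=rng.uniform(-0.05, 0.05, size=3),
        )
        target = GridSpec((5, 5, 5), (0.09, 0.09, 0.09), (-0.18, -0.18, -0.18))
        out = resample(v, t, target)
        vals, cov = brute_force_resample(v, t, target)
        assert np.array_equal(out.coverage.ravel(), cov)
        assert np.array_equal(out.values.ravel()[cov], vals[cov])


def test_round_trip_identity_on_affine(rng):
    v = Volume.centered(np.zeros((8, 8, 8)), spacing=(0.1, 0.1, 0.1))
    z, y, x = np.meshgrid(*v.voxel_centers(), indexing="ij")
    v = Volume(1.0 + z + 2 * y - x, spacing=v.spacing, origin=v.origin)
    t = RigidTransform.about_axis("x", 30.0)
    there = resample(v, t, GridSpec.like(v))
    back = resample(there, t.inverse(), GridSpec.like(v))
    m = back.coverage
    assert back.values[m] == pytest.approx(v.values[m], abs=1e-9)


def test_coverage_is_conservative():
    v = Volume(np.ones((4, 4, 4)), spacing=(0.1, 0.1, 0.1), origin=(0, 0, 0))
    # a target extending one voxel beyond the source on each side
    target = GridSpec((6, 6, 6), (0.1, 0.1, 0.1), (-0.1, -0.1, -0.1))
    out = resample(v, RigidTransform.identity(), target)
    assert out.coverage.sum() == 4**3
    assert not out.coverage[0].any() and not out.coverage[-1].any()
    # source coverage holes propagate to every interpolation corner user
    cov = np.ones((4, 4, 4), dtype=bool)
    cov[2, 2, 2] = False
    v2 = Volume(np.ones((4, 4, 4)), spacing=(0.1, 0.1, 0.1), origin=(0, 0, 0),
                coverage=cov)
    shifted = GridSpec((4, 4, 4), (0.1, 0.1, 0.1), (0.05, 0.05, 0.05))
    out2 = resample(v2, RigidTransform.identity(), shifted)
    assert not out2.coverage[1, 1, 1]  # cell adjacent to the hole
    assert not out2.coverage[2, 2, 2]


def test_sample_points_on_lattice(rng):
    v = Volume(rng.normal(size=(3, 4, 5)), spacing=(0.1, 0.1, 0.1),
               origin=(0.0, 0.0, 0.0))
    pts = np.array([[0.1], [0.2], [0.4]])
    vals, cov = sample_points(v, pts)
    assert cov[0]
    assert vals[0] == v.values[1, 2, 4]


def test_refine_translation_identity():
    rng = np.random.default_rng(5)
    base = rng.normal(size=(6, 12, 12)).cumsum(axis=1).cumsum(axis=2)
    v = Volume(base, spacing=(0.1, 0.1, 0.1))
    t = refine_translation(v, v)
    assert t.translation == pytest.approx(np.zeros(3), abs=1e-12)


def test_refine_translation_recovers_shift():
    rng = np.random.default_rng(6)
    # smooth volume: cumulative sums of noise, then a known 0.3-voxel shift
    base = rng.normal(size=(8, 16, 16)).cumsum(axis=1).cumsum(axis=2)
    moving = Volume(base, spacing=(0.1, 0.1, 0.1))
    shift = RigidTransform(np.eye(3), (0.0, 0.03, 0.0))  # 0.3 voxel along y
    fixed = resample(moving, shift, GridSpec.like(moving))
    t = refine_translation(moving, fixed)
    assert t.translation[1] == pytest.approx(0.03, abs=0.01)


def test_refine_translation_constant_overlap_errors():
    v = Volume(np.zeros((4, 8, 8)), spacing=(0.1, 0.1, 0.1))
    with pytest.raises(ValueError, match="constant overlap|correlation"):
        refine_translation(v, v)
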