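"""Rigid co-registration: pull-based trilinear resampling onto a common grid
and sub-voxel translation refinement.

Resampling is pull-based: for every *target* voxel center the inverse
transform gives a source coordinate, which is interpolated trilinearly from
the 8 surrounding source voxels (weights are the fractional parts of the
source index).  A target voxel is covered only if all 8 source corners are
inside the source grid and themselves covered -- conservative by design, so
out-of-field air never bleeds into downstream mean/median combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tiltmar.transforms import RigidTransform
from tiltmar.volume import Volume

__all__ = ["GridSpec", "resample", "sample_points", "refine_translation"]


@dataclass
class GridSpec:
    """Target grid: shape, per-axis spacing (cm) and origin of voxel (0,0,0)."""

    shape: tuple
    spacing: tuple
    origin: tuple

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("target spacing must be positive")

    @classmethod
    def like(cls, v: Volume) -> "GridSpec":
        return cls(v.values.shape, v.spacing, v.origin)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (3, nz*ny*nx)."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        return np.stack([zz.ravel(), yy.ravel(), xx.ravel()])


def _trilinear(v: Volume, idx: np.ndarray):
    """Trilinear interpolation at fractional index coordinates.

    idx: (3, N) fractional voxel indices into ``v``.  Returns (values,
    covered) where covered is False unless all 8 corners are in-grid and
    covered in the source.
    """
    nz, ny, nx = v.values.shape
    # snap indices a hair away from the lattice onto it, so lattice-preserving
    # transforms (identity, axis-aligned 90 deg rotations) are exact
    rounded = np.round(idx)
    idx = np.where(np.abs(idx - rounded) < 1e-9, rounded, idx)

    inside = np.ones(idx.shape[1], dtype=bool)
    for a, n in enumerate((nz, ny, nx)):
        inside &= (idx[a] >= 0) & (idx[a] <= n - 1)
    # enclosing cell, clamped so a sample on the upper boundary face uses the
    # last interior cell (frac 1); out-of-grid samples are uncovered anyway
    i0c = np.empty((3, idx.shape[1]), dtype=np.int64)
    for a, n in enumerate((nz, ny, nx)):
        i0c[a] = np.clip(np.floor(idx[a]), 0, n - 2).astype(np.int64)
    frac = idx - i0c

    fz, fy, fx = frac
    gz, gy, gx = 1.0 - fz, 1.0 - fy, 1.0 - fx
    vals = np.zeros(idx.shape[1])
    covered = inside.copy()
    src_cov = v.coverage
    for dz, wz in ((0, gz), (1, fz)):
        for dy, wy in ((0, gy), (1, fy)):
            for dx, wx in ((0, gx), (1, fx)):
                corner = v.values[i0c[0] + dz, i0c[1] + dy, i0c[2] + dx]
                vals += wz * wy * wx * corner
                if src_cov is not None:
                    covered &= src_cov[i0c[0] + dz, i0c[1] + dy, i0c[2] + dx]
    vals[~covered] = 0.0
    return vals, covered


def sample_points(v: Volume, world_points: np.ndarray):
    """Trilinear sample of ``v`` at world coordinates, shape (3, N).

    Returns (values, covered).
    """
    pts = np.asarray(world_points, dtype=np.float64)
    idx = np.empty_like(pts)
    for a in range(3):
        idx[a] = (pts[a] - v.origin[a]) / v.spacing[a]
    return _trilinear(v, idx)


def resample(v: Volume, t: RigidTransform, target: GridSpec) -> Volume:
    """Resample ``v`` through rigid transform ``t`` onto the target grid.

    ``t`` maps source (scan) coordinates to target (laboratory) coordinates;
    each target voxel center is pulled back through ``t``:sup:`-1` and
    sampled trilinearly from ``v``.
    """
    t.validate()
    inv = t.inverse()
    pts = target.voxel_centers()
    src_world = inv.rotation @ pts + inv.translation[:, None]
    vals, covered = sample_points(v, src_world)
    return Volume(
        vals.reshape(target.shape),
        spacing=target.spacing,
        origin=target.origin,
        coverage=covered.reshape(target.shape),
    )


def refine_translation(
    moving: Volume,
    fixed: Volume,
    radius: float = 0.5,
    step: float = 0.1,
    max_samples: int = 20000,
) -> RigidTransform:
    """Sub-voxel translation alignment of ``moving`` onto ``fixed``'s grid.

    Searches translations on a per-axis grid of ``step`` voxels within
    ``+/-radius`` voxels (defaults: 0.1 within +/-0.5) and returns the pure
    translation maximizing normalized cross-correlation over jointly covered
    voxels; the rotation is left untouched (tilt angles are taken as known).

    Raises
    ------
    ValueError
        If the volumes overlap on fewer than 10% of the fixed voxels or the
        overlap region is constant (correlation undefined).
    """
    fcov = fixed.full_coverage()
    idx = np.argwhere(fcov)
    if idx.shape[0] < 0.1 * fixed.values.size:
        raise ValueError("volumes overlap on fewer than 10% of voxels")
    if idx.shape[0] > max_samples:  # evaluate NCC on a deterministic subsample
        sel = np.linspace(0, idx.shape[0] - 1, max_samples).astype(np.int64)
        idx = idx[sel]
    pts = np.stack(
        [fixed.origin[a] + idx[:, a] * fixed.spacing[a] for a in range(3)]
    )
    ref = fixed.values[idx[:, 0], idx[:, 1], idx[:, 2]]

    offsets = np.arange(-radius, radius + step / 2, step)
    best = (-np.inf, np.zeros(3))
    for oz in offsets:
        for oy in offsets:
            for ox in offsets:
                shift = np.array(
                    [
                        oz * moving.spacing[0],
                        oy * moving.spacing[1],
                        ox * moving.spacing[2],
                    ]
                )
                vals, cov = sample_points(moving, pts - shift[:, None])
                if cov.sum() < max(10, 0.1 * pts.shape[1]):
                    continue
                a, b = vals[cov], ref[cov]
                sa, sb = a.std(), b.std()
                if sa == 0 or sb == 0:
                    raise ValueError(
                        "constant overlap region: correlation undefined"
                    )
                ncc = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
                if ncc > best[0]:
                    best = (ncc, shift)
    if not np.isfinite(best[0]):
        raise ValueError("no translation with sufficient overlap found")
    return RigidTransform(np.eye(3), best[1])
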