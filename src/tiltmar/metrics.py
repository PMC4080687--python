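"""Quantitative evaluation in Hounsfield units: bias, error and noise over ROIs.

For a region of n voxels with grey values x_i whose true value is a known
constant c:

- bias  = mean(x_i) - c          (overall shift of the grey level),
- error = mean(|x_i - c|)        (average total per-voxel deviation),
- noise = sqrt( 1/(n-1) * sum (x_i - mean)^2 )   (sample standard deviation).

Bias and error need the true value; noise is meaningful for regions that are
truly constant.  ROI membership is by voxel-center test: a ring (annulus in
the slice plane, over a slab of slices) around a metal insert, or an
axis-aligned box, e.g. inside an air cavity where c = -1000 HU by definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tiltmar.volume import Volume

__all__ = ["Roi", "RoiReport", "evaluate", "ring_roi", "box_roi"]


@dataclass
class Roi:
    """A voxel index set within a volume, with a human-readable descriptor."""

    indices: tuple  # (iz, iy, ix) integer arrays
    descriptor: str

    def __post_init__(self):
        if len(self.indices) != 3 or self.indices[0].size == 0:
            raise ValueError("ROI must contain at least one voxel")

    @property
    def n(self) -> int:
        return int(self.indices[0].size)


@dataclass
class RoiReport:
    """Bias / error / noise in HU over one ROI, with voxel count and assumed truth."""

    bias: float
    error: float
    noise: float
    n: int
    c: float

    def __str__(self):
        return (
            f"n={self.n} c={self.c:g} HU: bias={self.bias:.1f} "
            f"error={self.error:.1f} noise={self.noise:.1f} HU"
        )


def evaluate(v: Volume, roi: Roi, c: float) -> RoiReport:
    """Compute bias, error and noise of ``v`` over ``roi`` against truth ``c``.

    Every ROI voxel must be covered (metrics over artifact regions must not
    silently shrink) and n >= 2 is required for the noise estimate.
    """
    cov = v.full_coverage()
    if not cov[roi.indices].all():
        missing = int((~cov[roi.indices]).sum())
        raise ValueError(f"{missing} ROI voxels are uncovered in the volume")
    x = v.values[roi.indices]
    if x.size < 2:
        raise ValueError("noise requires at least 2 ROI voxels")
    mean = float(x.mean())
    return RoiReport(
        bias=mean - c,
        error=float(np.abs(x - c).mean()),
        noise=float(x.std(ddof=1)),
        n=x.size,
        c=float(c),
    )


def ring_roi(
    center,
    r_inner_mm: float = 8.0,
    r_outer_mm: float = 16.0,
    slab_mm: float = 7.0,
    v: Volume = None,
) -> Roi:
    """Ring (annulus x slice slab) around a point, radii in mm.

    Voxel centers with ``r_inner <= in-plane distance < r_outer`` from
    ``center`` (world (z, y, x), cm) and ``|z - center_z| < slab/2`` are
    members.  Defaults are the standard ring around a metal insert: radii
    8 and 16 mm over a 7 mm slab.
    """
    if not (r_outer_mm > r_inner_mm >= 0):
        raise ValueError("need r_outer > r_inner >= 0")
    cz, cy, cx = (float(c) for c in center)
    z, y, x = v.voxel_centers()
    in_slab = np.abs(z - cz) < slab_mm / 20.0  # mm -> cm, half-width
    dy = (y - cy)[None, :, None]
    dx = (x - cx)[None, None, :]
    r = np.sqrt(dy**2 + dx**2) * 10.0  # cm -> mm
    member = in_slab[:, None, None] & (r >= r_inner_mm) & (r < r_outer_mm)
    idx = np.nonzero(member)
    if idx[0].size == 0:
        raise ValueError("ring lies entirely outside the volume grid")
    return Roi(
        idx,
        f"ring center=({cz:g},{cy:g},{cx:g})cm r=[{r_inner_mm:g},{r_outer_mm:g})mm "
        f"slab={slab_mm:g}mm",
    )


def box_roi(center, extents, v: Volume) -> Roi:
    """Axis-aligned box of voxel centers; center and extents in cm (z, y, x)."""
    extents = tuple(float(e) for e in extents)
    if any(e <= 0 for e in extents):
        raise ValueError("box extents must be positive")
    cz, cy, cx = (float(c) for c in center)
    z, y, x = v.voxel_centers()
    inz = np.abs(z - cz) < extents[0] / 2.0
    iny = np.abs(y - cy) < extents[1] / 2.0
    inx = np.abs(x - cx) < extents[2] / 2.0
    member = inz[:, None, None] & iny[None, :, None] & inx[None, None, :]
    idx = np.nonzero(member)
    if idx[0].size == 0:
        raise ValueError("box lies entirely outside the volume grid")
    return Roi(
        idx,
        f"box center=({cz:g},{cy:g},{cx:g})cm extents=({extents[0]:g},"
        f"{extents[1]:g},{extents[2]:g})cm",
    )
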