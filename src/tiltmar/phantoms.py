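"""Digital phantoms: a tissue-characterization disc with a titanium insert, and
a dental phantom with multiple metal restorations.

Phantoms are 2D material-label grids (one transverse slice); the acquisition
layer stacks reconstructed slices into 3D volumes.  Positions are world
coordinates (y, x) in cm relative to the grid center, matching the volume
convention that the rotation center is the world origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from tiltmar.materials import Material, default_materials, hounsfield_from_mu, linear_attenuation, REFERENCE_ENERGY_KEV

__all__ = [
    "PhantomImage",
    "Phantom3D",
    "extrude",
    "make_gammex_phantom",
    "make_dental_phantom",
]


@dataclass
class PhantomImage:
    """Material-label grid plus material table.

    labels[i, j] indexes into ``materials``; label 0 is always air
    (background).  ``spacing`` is the isotropic in-plane pixel size in cm.
    """

    labels: np.ndarray
    materials: list
    spacing: float = 0.1

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D grid")
        if self.labels.max() >= len(self.materials) or self.labels.min() < 0:
            raise ValueError("every label must index a defined material")
        if self.materials[0].name != "air":
            raise ValueError("background material (label 0) must be air")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self):
        return self.labels.shape

    def grid_coords(self):
        """World (y, x) coordinate arrays of pixel centers, cm, centered grid."""
        ny, nx = self.labels.shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing
        return np.meshgrid(y, x, indexing="ij")

    def ideal_hu(self, energy_kev: float = REFERENCE_ENERGY_KEV) -> np.ndarray:
        """Noise-free HU rendering at a given energy (the ground-truth image)."""
        hu = np.empty(len(self.materials))
        for i, m in enumerate(self.materials):
            hu[i] = hounsfield_from_mu(linear_attenuation(m, energy_kev))
        hu[0] = -1000.0  # air by definition
        return hu[self.labels]

    def metal_labels(self) -> list:
        """Indices of materials rendering above 2000 HU at reference energy."""
        return [
            i
            for i, m in enumerate(self.materials)
            if i > 0 and m.reference_hu > 2000.0
        ]

    def rotated(self, angle_deg: float) -> "PhantomImage":
        """Phantom rotated in-plane about the grid center (nearest-neighbor)."""
        lab = ndimage.rotate(
            self.labels, angle_deg, reshape=False, order=0, mode="constant", cval=0
        )
        return PhantomImage(lab, self.materials, self.spacing)


@dataclass
class Phantom3D:
    """A 3D material-label volume for simulating tilted acquisitions.

    Objects have finite extent along z (e.g. a 5 cm high disc, or metal
    restorations confined to the jaw slices), which is what makes tilted
    scans complementary: a slice plane that cuts through metal in one scan
    orientation misses it in another.  The grid is isotropic with y/x
    centered on the rotation axis; ``z_origin`` is the world z of slice 0's
    center (cm).  Label 0 is air, including everything outside the grid.
    """

    labels: np.ndarray  # (nz, ny, nx) material indices
    materials: list
    spacing: float
    z_origin: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if self.labels.max() >= len(self.materials) or self.labels.min() < 0:
            raise ValueError("every label must index a defined material")
        if self.materials[0].name != "air":
            raise ValueError("background material (label 0) must be air")

    def section(self, rotation: np.ndarray, z_scan: float) -> PhantomImage:
        """Oblique cross-section: the scan slice at height ``z_scan`` of the
        phantom posed by ``rotation`` (scan frame -> laboratory frame).

        The slice plane z' = z_scan is sampled on the in-plane (y, x') grid;
        each point is mapped to the laboratory frame by ``rotation`` and the
        nearest label is looked up (air outside the grid).
        """
        nz, ny, nx = self.labels.shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing
        yy, xx = np.meshgrid(y, x, indexing="ij")
        pts = np.stack(
            [np.full(yy.size, float(z_scan)), yy.ravel(), xx.ravel()]
        )
        lab_pts = np.asarray(rotation, dtype=np.float64) @ pts

        iz = np.round((lab_pts[0] - self.z_origin) / self.spacing).astype(np.int64)
        iy = np.round((lab_pts[1] - y[0]) / self.spacing).astype(np.int64)
        ix = np.round((lab_pts[2] - x[0]) / self.spacing).astype(np.int64)
        inside = (
            (iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
        )
        out = np.zeros(yy.size, dtype=self.labels.dtype)
        out[inside] = self.labels[iz[inside], iy[inside], ix[inside]]
        return PhantomImage(out.reshape(ny, nx), self.materials, self.spacing)


def extrude(p: PhantomImage, height: float, label_z_ranges: dict | None = None) -> Phantom3D:
    """Extrude a 2D phantom along z into a :class:`Phantom3D`.

    Every label spans ``|z| < height/2`` unless ``label_z_ranges`` gives it a
    narrower ``(z_lo, z_hi)`` interval (cm); where a restricted label is
    absent the underlying 2D neighborhood majority is not reconstructed --
    the voxel falls back to the *unrestricted* phantom with that label
    replaced by the surrounding soft material, which callers encode by
    passing a ``fallback_label`` per range: ``{label: (z_lo, z_hi, fallback)}``.
    """
    nz = int(round(height / p.spacing))
    nz = max(nz, 1)
    z0 = -(nz - 1) / 2.0 * p.spacing
    labels = np.repeat(p.labels[None, :, :], nz, axis=0).copy()
    if label_z_ranges:
        z = z0 + np.arange(nz) * p.spacing
        for lab, spec in label_z_ranges.items():
            z_lo, z_hi, fallback = spec
            outside = (z < z_lo) | (z > z_hi)
            mask2d = p.labels == lab
            for k in np.nonzero(outside)[0]:
                labels[k][mask2d] = fallback
    return Phantom3D(labels, p.materials, p.spacing, z0)


def _disc_mask(yy, xx, center, radius):
    cy, cx = center
    return (yy - cy) ** 2 + (xx - cx) ** 2 < radius**2


def make_gammex_phantom(
    insert_spec=None,
    disc_diameter: float = 33.0,
    insert_diameter: float = 3.0,
    spacing: float = 0.1,
    shape=None,
) -> PhantomImage:
    """Tissue-characterization disc ('Solid Water') with cylindrical inserts.

    Parameters
    ----------
    insert_spec : list of (material_name, (y, x)) or None
        Insert material names and center positions in cm relative to the disc
        center.  None gives the default configuration: a single titanium
        insert.  Pass ``[]`` for a homogeneous Solid Water disc.
    disc_diameter, insert_diameter : float
        Diameters in cm (33 cm disc, 3 cm inserts by default).
    spacing : float
        Pixel size in cm (default 0.1).
    shape : (ny, nx) or None
        Grid shape; by default sized so the disc fits the inscribed circle
        of the field of view with a small margin.

    Raises
    ------
    ValueError
        If an insert extends beyond the disc or two inserts overlap.
    """
    if insert_spec is None:
        insert_spec = [("titanium", (0.0, disc_diameter / 4.0))]
    if shape is None:
        n = int(math.ceil(disc_diameter * 1.12 / spacing))
        n += n % 2
        shape = (n, n)

    mats = default_materials()
    materials = [mats["air"], mats["solid_water"]]
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = PhantomImage(labels, materials, spacing).grid_coords()

    disc_r = disc_diameter / 2.0
    ins_r = insert_diameter / 2.0
    labels[_disc_mask(yy, xx, (0.0, 0.0), disc_r)] = 1

    centers = []
    for name, pos in insert_spec:
        cy, cx = float(pos[0]), float(pos[1])
        if math.hypot(cy, cx) + ins_r > disc_r:
            raise ValueError(
                f"insert '{name}' at ({cy}, {cx}) cm extends beyond the "
                f"{disc_diameter} cm disc"
            )
        for (oy, ox) in centers:
            if math.hypot(cy - oy, cx - ox) < insert_diameter:
                raise ValueError(f"insert '{name}' at ({cy}, {cx}) cm overlaps another insert")
        centers.append((cy, cx))
        if name not in mats:
            raise ValueError(f"unknown material '{name}'")
        materials.append(mats[name])
        labels[_disc_mask(yy, xx, (cy, cx), ins_r)] = len(materials) - 1

    return PhantomImage(labels, materials, spacing)


def make_dental_phantom(spacing: float = 0.1, shape=(256, 256)) -> PhantomImage:
    """Skull-like dental phantom: bone shell, soft-tissue interior, an air-filled
    oral cavity, and six disjoint metal bodies (a gold bridge, a steel bridge
    and four gold crowns) arranged along the jaw.

    The cavity is large enough to hold a 6.1 x 1.1 cm in-plane evaluation box.
    """
    mats = default_materials()
    materials = [mats["air"], mats["soft_tissue"], mats["bone"], mats["gold"], mats["steel"]]
    SOFT, BONE, GOLD, STEEL = 1, 2, 3, 4

    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = PhantomImage(labels, materials, spacing).grid_coords()

    def ellipse(center, semi):
        cy, cx = center
        ay, ax = semi
        return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 < 1.0

    labels[ellipse((0.0, 0.0), (8.5, 6.5))] = BONE  # cranium / mandible shell
    labels[ellipse((0.0, 0.0), (7.5, 5.5))] = SOFT
    labels[ellipse((3.5, 0.0), (1.2, 3.6))] = 0  # oral cavity (air)

    def rect(y0, y1, x0, x1, lab):
        labels[(yy >= y0) & (yy < y1) & (xx >= x0) & (xx < x1)] = lab

    rect(5.3, 5.8, -2.8, -0.8, GOLD)   # full gold bridge
    rect(5.3, 5.8, 0.8, 2.8, STEEL)    # full steel bridge
    for cy, cx in [(5.55, -3.7), (5.55, 3.7), (6.6, -1.6), (6.6, 1.6)]:
        labels[_disc_mask(yy, xx, (cy, cx), 0.3)] = GOLD  # crowns

    return PhantomImage(labels, materials, spacing)
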