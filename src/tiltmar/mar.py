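"""Sinogram-domain metal artifact reduction baselines: LI, BI, NMAR, FSMAR.

All four operate on a *virtual sinogram* -- the forward projection (Radon
transform) of the already-reconstructed slice, used when raw scanner data is
unavailable.  Metal is segmented in image space by a HU threshold (default
2000 HU), its forward projection defines the *metal trace* -- the sinogram
bins whose rays intersect metal -- and the trace is in-painted:

- LI:    per projection angle, 1D linear interpolation across each traced run
         between the nearest untraced detector bins;
- BI:    bidirectional inverse-distance weighting of the nearest untraced
         neighbors along both the detector axis and the angle axis;
- NMAR:  LI in-painting applied to the sinogram normalized by the virtual
         sinogram of a tissue-class prior image, then de-normalized;
- FSMAR: frequency split -- the corrected image's low frequencies blended
         with the original's high frequencies near metal, with a blurred
         metal map as the blending weight.

After in-painting, the corrected sinogram is reconstructed by FBP and the
metal voxels of the original image are re-inserted inside the metal mask.
In-painting never touches untraced bins.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import radon

from tiltmar.materials import mu_from_hounsfield
from tiltmar.projector import Sinogram, fbp_reconstruct
from tiltmar.volume import Volume

__all__ = [
    "virtual_sinogram",
    "segment_metal",
    "metal_trace",
    "li_mar",
    "bi_mar",
    "nmar",
    "build_nmar_prior",
    "fs_mar",
    "run_mar",
]

METAL_THRESHOLD_HU = 2000.0

_TRACE_TOL = 1e-9


def _as_slice(image) -> tuple:
    """Accept a 2D array or a single-slice Volume; return (2D HU array, spacing)."""
    if isinstance(image, Volume):
        if image.values.shape[0] != 1:
            raise ValueError("expected a single-slice volume")
        return image.values[0], image.spacing[1]
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2D slice")
    return arr, 0.1


def _inscribed_circle(shape) -> np.ndarray:
    n = shape[0]
    if shape[0] != shape[1]:
        raise ValueError("virtual sinogram requires a square slice")
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= (n / 2.0 - 1) ** 2


def virtual_sinogram(image, angles=None, spacing: float | None = None) -> Sinogram:
    """Forward-project a reconstructed slice (HU mapped back to attenuation).

    The region outside the inscribed reconstruction circle is zeroed (it is
    air up to reconstruction noise and must be empty for the parallel-beam
    Radon transform).
    """
    img, sp = _as_slice(image)
    if spacing is not None:
        sp = spacing
    if angles is None:
        angles = np.linspace(0.0, 180.0, 180, endpoint=False)
    angles = np.asarray(angles, dtype=np.float64)
    mu = mu_from_hounsfield(img)
    mu[~_inscribed_circle(img.shape)] = 0.0
    data = np.clip(radon(mu, theta=angles, circle=True).T * sp, 0.0, None)
    return Sinogram(data, angles, detector_spacing=sp)


def segment_metal(image, threshold: float = METAL_THRESHOLD_HU) -> np.ndarray:
    """Binary metal map: strict HU-threshold exceedance."""
    img, _ = _as_slice(image)
    return img > threshold


def metal_trace(mask: np.ndarray, angles, spacing: float = 0.1) -> np.ndarray:
    """Sinogram-domain trace: rays whose forward-projected metal map is nonzero."""
    angles = np.asarray(angles, dtype=np.float64)
    proj = radon(mask.astype(np.float64), theta=angles, circle=True).T * spacing
    return proj > _TRACE_TOL


def _check_trace(s: Sinogram, trace: np.ndarray):
    trace = np.asarray(trace, dtype=bool)
    if trace.shape != s.data.shape:
        raise ValueError("trace shape must match sinogram shape")
    return trace


def li_mar(s: Sinogram, trace: np.ndarray) -> Sinogram:
    """Linear-interpolation MAR: per angle, bridge each traced run linearly.

    Untraced bins are returned bit-exact; a fully traced projection row is a
    hard error (nothing to interpolate from).
    """
    trace = _check_trace(s, trace)
    data = s.data.copy()
    cols = np.arange(s.data.shape[1])
    for a in range(s.data.shape[0]):
        t = trace[a]
        if not t.any():
            continue
        if t.all():
            raise ValueError(
                f"projection at {s.angles[a]:g} deg is fully metal-traced"
            )
        data[a, t] = np.interp(cols[t], cols[~t], data[a, ~t])
    return Sinogram(data, s.angles, s.detector_spacing, s.geometry)


def _nearest_untraced_along_axis(trace: np.ndarray):
    """Index of nearest untraced bin at-or-before / at-or-after, along axis 1."""
    n = trace.shape[1]
    idx = np.arange(n)[None, :]
    before = np.where(~trace, idx, -1)
    before = np.maximum.accumulate(before, axis=1)
    after = np.where(~trace, idx, n)
    after = np.minimum.accumulate(after[:, ::-1], axis=1)[:, ::-1]
    return before, after


def bi_mar(s: Sinogram, trace: np.ndarray) -> Sinogram:
    """Bidirectional MAR: inverse-distance weighting of the nearest untraced
    neighbors along both the detector axis and the angle axis."""
    trace = _check_trace(s, trace)
    data = s.data.copy()
    n_a, n_d = data.shape

    d_before, d_after = _nearest_untraced_along_axis(trace)
    a_before_t, a_after_t = _nearest_untraced_along_axis(trace.T)
    a_before, a_after = a_before_t.T, a_after_t.T

    ta, td = np.nonzero(trace)
    num = np.zeros(ta.size)
    den = np.zeros(ta.size)

    def _add(nb_idx, along_detector: bool):
        if along_detector:
            valid = (nb_idx >= 0) & (nb_idx < n_d)
            dist = np.abs(td - nb_idx)
            vals = data[ta, np.clip(nb_idx, 0, n_d - 1)]
        else:
            valid = (nb_idx >= 0) & (nb_idx < n_a)
            dist = np.abs(ta - nb_idx)
            vals = data[np.clip(nb_idx, 0, n_a - 1), td]
        w = np.where(valid, 1.0 / np.maximum(dist, 1), 0.0)
        return w * np.where(valid, vals, 0.0), w

    for nb, along_det in (
        (d_before[ta, td], True),
        (d_after[ta, td], True),
        (a_before[ta, td], False),
        (a_after[ta, td], False),
    ):
        contrib, w = _add(nb, along_det)
        num += contrib
        den += w

    if (den == 0).any():
        bad = int(np.argmax(den == 0))
        raise ValueError(
            f"traced bin (angle {s.angles[ta[bad]]:g} deg, detector {td[bad]}) "
            "has no untraced neighbor in either direction"
        )
    data[ta, td] = num / den
    return Sinogram(data, s.angles, s.detector_spacing, s.geometry)


def build_nmar_prior(
    image,
    metal_mask: np.ndarray | None = None,
    air_threshold: float = -500.0,
    bone_threshold: float = 500.0,
    metal_threshold: float = METAL_THRESHOLD_HU,
) -> np.ndarray:
    """Tissue-class prior for NMAR from the uncorrected slice.

    Air (< air_threshold) maps to -1000 HU, soft tissue to the median soft
    value, bone (>= bone_threshold) keeps its grey value, and metal voxels
    are replaced by the soft-tissue value.
    """
    img, _ = _as_slice(image)
    if metal_mask is None:
        metal_mask = segment_metal(img, metal_threshold)
    prior = img.copy()
    air = img < air_threshold
    soft = (~air) & (img < bone_threshold) & ~metal_mask
    soft_value = float(np.median(img[soft])) if soft.any() else 0.0
    prior[air] = -1000.0
    prior[soft] = soft_value
    prior[metal_mask] = soft_value
    return prior


def nmar(
    s: Sinogram,
    trace: np.ndarray,
    prior=None,
    prior_sinogram: Sinogram | None = None,
    floor: float = 1e-6,
) -> Sinogram:
    """Normalized MAR: in-paint in the prior-normalized sinogram domain.

    The sinogram is divided bin-wise by the prior's virtual sinogram (floored
    at ``floor`` to stay strictly positive), the trace is in-painted by
    :func:`li_mar` in the normalized domain, and the result is de-normalized.
    Untraced bins are returned bit-exact.
    """
    trace = _check_trace(s, trace)
    if prior_sinogram is None:
        if prior is None:
            raise ValueError("nmar needs a prior image or a prior sinogram")
        prior_sinogram = virtual_sinogram(prior, s.angles, s.detector_spacing)
    ps = np.asarray(prior_sinogram.data, dtype=np.float64)
    if ps.shape != s.data.shape:
        raise ValueError("prior sinogram shape must match the input sinogram")
    if ps.max() <= 0:
        raise ValueError("prior sinogram is identically zero after flooring")
    ps = np.maximum(ps, floor)

    norm = Sinogram(s.data / ps, s.angles, s.detector_spacing, s.geometry)
    filled = li_mar(norm, trace)
    data = s.data.copy()
    data[trace] = (filled.data * ps)[trace]
    return Sinogram(data, s.angles, s.detector_spacing, s.geometry)


def fs_mar(
    original,
    mar_image,
    mask: np.ndarray,
    sigma_low: float = 3.0,
    sigma_weight: float = 30.0,
):
    """Frequency-split blend: MAR low frequencies + original high frequencies.

    ``low(x)`` is a Gaussian blur of radius (sigma) ``sigma_low`` pixels;
    the blending weight ``w`` is the metal map blurred with ``sigma_weight``
    pixels, rescaled to [0, 1].  Output::

        w * (low(mar) + high(original)) + (1 - w) * mar
    """
    orig, _ = _as_slice(original)
    mar_img, _ = _as_slice(mar_image)
    if orig.shape != mar_img.shape or orig.shape != mask.shape:
        raise ValueError("original, MAR image and mask must share one grid")

    def low(x):
        return ndimage.gaussian_filter(x, sigma_low)

    w = ndimage.gaussian_filter(mask.astype(np.float64), sigma_weight)
    if w.max() > 0:
        w = w / w.max()
    high_orig = orig - low(orig)
    return w * (low(mar_img) + high_orig) + (1.0 - w) * mar_img


def run_mar(
    image,
    algorithm: str,
    angles=None,
    threshold: float = METAL_THRESHOLD_HU,
    spacing: float | None = None,
):
    """Full MAR pipeline on one reconstructed slice.

    segment metal -> virtual sinogram -> metal trace -> in-paint (LI | BI |
    NMAR | FSMAR base) -> FBP -> re-insert the original metal voxels; FSMAR
    additionally post-blends high frequencies of the original near metal.

    Returns the corrected slice as a 2D HU array.
    """
    algorithm = algorithm.lower()
    if algorithm not in ("li", "bi", "nmar", "fsmar"):
        raise ValueError(f"unknown MAR algorithm {algorithm!r}")
    img, sp = _as_slice(image)
    if spacing is not None:
        sp = spacing
    if angles is None:
        angles = np.linspace(0.0, 180.0, 180, endpoint=False)

    mask = segment_metal(img, threshold)
    sino = virtual_sinogram(img, angles, sp)
    trace = metal_trace(mask, angles, sp)

    if algorithm == "li":
        corrected = li_mar(sino, trace)
    elif algorithm == "bi":
        corrected = bi_mar(sino, trace)
    else:  # nmar and fsmar both in-paint in the normalized domain
        prior = build_nmar_prior(img, metal_mask=mask)
        corrected = nmar(sino, trace, prior=prior)

    recon = fbp_reconstruct(corrected).values[0]
    recon[mask] = img[mask]  # metal re-insertion
    if algorithm == "fsmar":
        recon = fs_mar(img, recon, mask)
    return recon
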