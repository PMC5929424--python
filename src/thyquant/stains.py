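"""Optical-density colour deconvolution for H-DAB brightfield images.

Brightfield absorbance obeys Beer-Lambert: a pixel observed at intensity
``I`` against a white reference ``I0 = 255`` has optical density
``OD = -log10(I / I0)`` per channel, and the OD vector is (to first order)
a nonnegative linear combination of per-stain absorbance vectors.  Unmixing
is therefore a 3x3 linear solve in OD space, after which the DAB channel is
re-expressed on the conventional 0-255 dark-to-light intensity scale used
for threshold gating.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.filters import median as _median_filter
from skimage.morphology import disk

__all__ = [
    "BrightfieldImage",
    "StainChannelSet",
    "default_hdab_matrix",
    "normalize_stain_matrix",
    "median_denoise",
    "rgb_to_od",
    "od_to_intensity8",
    "deconvolve",
]

#: White reference intensity for the OD transform (8-bit full scale).
WHITE_REFERENCE = 255.0

# Hematoxylin / DAB absorbance vectors (Ruifrok & Johnston).  The residual
# row is completed per-channel as sqrt(1 - h^2 - d^2) so all components stay
# nonnegative, then renormalised.
_HEMA = (0.650, 0.704, 0.286)
_DAB = (0.269, 0.568, 0.778)


@dataclasses.dataclass(frozen=True)
class BrightfieldImage:
    """A calibrated 8-bit RGB photomicrograph.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    mpp : float
        Microns per pixel; every physical area downstream derives from it.
    """

    pixels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("brightfield image must be H x W x 3")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclasses.dataclass(frozen=True)
class StainChannelSet:
    """Per-pixel stain contributions recovered by deconvolution.

    ``dab_intensity8`` maps DAB optical density back onto the 0-255
    dark-to-light scale (255 = unstained) on which the positivity gate is
    expressed.
    """

    hema_od: np.ndarray
    dab_od: np.ndarray
    residual_od: np.ndarray
    dab_intensity8: np.ndarray


def normalize_stain_matrix(matrix: np.ndarray) -> np.ndarray:
    """Validate a 3x3 stain matrix and renormalise each row to unit norm.

    Rows are (hematoxylin, DAB, residual) absorbance vectors.  Raises
    ``ValueError`` for wrong shape, negative components, zero rows or
    linearly dependent rows.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
    if np.any(m < 0):
        raise ValueError("stain matrix components must be nonnegative")
    norms = np.linalg.norm(m, axis=1)
    if np.any(norms == 0):
        raise ValueError("stain matrix rows must be nonzero")
    m = m / norms[:, None]
    if abs(np.linalg.det(m)) < 1e-8:
        bad = _dependent_rows(m)
        raise ValueError(f"stain matrix rows are linearly dependent: {bad}")
    return m


def _dependent_rows(m: np.ndarray) -> str:
    names = ("hematoxylin", "DAB", "residual")
    for i in range(3):
        for j in range(i + 1, 3):
            if np.linalg.matrix_rank(m[[i, j]]) < 2:
                return f"{names[i]} vs {names[j]}"
    return "all three rows"


def default_hdab_matrix() -> np.ndarray:
    """Standard H-DAB absorbance matrix with a complemented residual row."""
    h = np.array(_HEMA)
    d = np.array(_DAB)
    res = np.sqrt(np.clip(1.0 - h**2 - d**2, 0.0, None))
    return normalize_stain_matrix(np.stack([h, d, res]))


def median_denoise(img: BrightfieldImage, radius_px: int = 2) -> BrightfieldImage:
    """Median-filter each channel over a disc neighbourhood.

    Performs the background/impulse-noise suppression step; edge-preserving,
    so stain boundaries survive.  Dimensions and calibration are preserved.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    h, w = img.shape
    if 2 * radius_px + 1 > min(h, w):
        raise ValueError(
            f"median radius {radius_px} px too large for a {h}x{w} image"
        )
    footprint = disk(radius_px)
    out = np.empty_like(img.pixels)
    for c in range(3):
        out[..., c] = _median_filter(img.pixels[..., c], footprint=footprint)
    return BrightfieldImage(pixels=out, mpp=img.mpp)


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Beer-Lambert transform to optical density, white reference 255.

    Accepts uint8 or float intensities in [0, 255]; intensities below 1 are
    clamped to 1 so the result is finite.  OD(255) = 0 exactly.
    """
    i = np.maximum(np.asarray(pixels, dtype=float), 1.0)
    return -np.log10(i / WHITE_REFERENCE)


def od_to_intensity8(od: np.ndarray) -> np.ndarray:
    """Map optical density back to the 0-255 dark-to-light scale."""
    return np.clip(WHITE_REFERENCE * 10.0 ** (-np.asarray(od, dtype=float)), 0.0, 255.0)


def deconvolve(od_maps: np.ndarray, matrix: np.ndarray) -> StainChannelSet:
    """Unmix per-channel OD into hematoxylin / DAB / residual densities.

    Parameters
    ----------
    od_maps : (H, W, 3) float array of per-channel optical densities.
    matrix : 3x3 stain matrix, rows = stain absorbance vectors (renormalised
        here; singular matrices are rejected naming the offending rows).

    Negative unmixed concentrations (noise artefacts) are clipped to zero.
    """
    m = normalize_stain_matrix(matrix)
    od = np.asarray(od_maps, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("od_maps must be H x W x 3")
    # od_pixel = conc @ m  =>  conc = od_pixel @ inv(m)
    conc = od.reshape(-1, 3) @ np.linalg.inv(m)
    conc = np.clip(conc, 0.0, None).reshape(od.shape)
    hema = conc[..., 0]
    dab = conc[..., 1]
    residual = conc[..., 2]
    return StainChannelSet(
        hema_od=hema,
        dab_od=dab,
        residual_od=residual,
        dab_intensity8=od_to_intensity8(dab),
    )
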