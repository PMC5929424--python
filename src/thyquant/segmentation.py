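"""Histomorphological tissue segmentation for thyroid follicular tissue.

The pipeline partitions every pixel into background, colloid, parenchyma
(follicular epithelium), stroma or nucleus, then derives the quantitation
region as the epithelial rim hugging each colloid lumen — the interface
between parafollicular stroma and colloid — with nuclei excluded so only
cytoplasmic/membranous staining is measured.

Thresholds are global (a single set per slide batch), stored in config;
they deliberately trade adaptivity for robustness to background staining
variation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing as _closing
from skimage.morphology import dilation as _dilation
from skimage.morphology import disk
from skimage.segmentation import watershed

from .stains import BrightfieldImage, StainChannelSet

__all__ = [
    "BACKGROUND",
    "COLLOID",
    "PARENCHYMA",
    "STROMA",
    "NUCLEUS",
    "LYMPHOCYTE",
    "LABEL_NAMES",
    "TissueLabelMap",
    "ConfigError",
    "default_thresholds",
    "classify_pixels",
    "refine_labels",
    "follicular_interface",
    "exclude_nuclei",
    "detect_nuclei",
]

logger = logging.getLogger(__name__)

# Integer label codes, also used by the serialized single-channel PNG.
BACKGROUND = 0
COLLOID = 1
PARENCHYMA = 2
STROMA = 3
NUCLEUS = 4
#: Generator-side only: lymphocyte nuclei in stroma.  The classifier has no
#: lymphocyte class — hematoxylin-dark lymphocytes come out as NUCLEUS,
#: which is exactly the confounder lymphocytic thyroiditis poses.
LYMPHOCYTE = 5

LABEL_NAMES = {
    BACKGROUND: "background",
    COLLOID: "colloid",
    PARENCHYMA: "parenchyma",
    STROMA: "stroma",
    NUCLEUS: "nucleus",
    LYMPHOCYTE: "lymphocyte",
}

#: Refinement precedence, lowest to highest: the highest-precedence class
#: wins wherever per-class morphological closings overlap.
REFINE_PRECEDENCE = (BACKGROUND, STROMA, PARENCHYMA, COLLOID, NUCLEUS)


class ConfigError(ValueError):
    """Raised when required configuration keys are missing or invalid."""


@dataclasses.dataclass(frozen=True)
class TissueLabelMap:
    """Per-pixel tissue partition with inherited calibration."""

    labels: np.ndarray  # (H, W) uint8 of label codes
    mpp: float

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def class_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))


REQUIRED_THRESHOLD_KEYS = (
    "nucleus_hema_od",
    "bright_mean_rgb",
    "stroma_residual_min",
    "stroma_residual_margin",
)


def default_thresholds() -> dict[str, float]:
    """Global segmentation thresholds.

    nucleus_hema_od
        Hematoxylin OD at or above which a pixel is nuclear chromatin.
    bright_mean_rgb
        Mean-RGB brightness at or above which a pixel is unstained lumen
        or glass (colloid vs background is then decided by enclosure).
    stroma_residual_min / stroma_residual_margin
        Non-bright, non-nuclear tissue is stroma when its residual-channel
        OD clears ``stroma_residual_min`` and exceeds hematoxylin+DAB OD by
        ``stroma_residual_margin``; otherwise it is epithelial parenchyma.
    """
    return {
        "nucleus_hema_od": 0.35,
        "bright_mean_rgb": 232.0,
        "stroma_residual_min": 0.08,
        "stroma_residual_margin": 0.0,
    }


def classify_pixels(
    channels: StainChannelSet,
    denoised_img: BrightfieldImage,
    thresholds: dict[str, float] | None = None,
) -> TissueLabelMap:
    """Threshold-classify every pixel into the five tissue classes.

    Bright regions are split by connectivity: components touching the image
    border are glass BACKGROUND, enclosed bright components are COLLOID
    (both are unstained; only topology separates them).  Hematoxylin-dark
    pixels become NUCLEUS; the remaining tissue splits into STROMA vs
    PARENCHYMA by the residual-stain rule (see ``default_thresholds``).
    """
    thr = dict(default_thresholds()) if thresholds is None else dict(thresholds)
    missing = [k for k in REQUIRED_THRESHOLD_KEYS if k not in thr]
    if missing:
        raise ConfigError(f"missing segmentation threshold keys: {missing}")

    brightness = denoised_img.pixels.astype(float).mean(axis=2)
    bright = brightness >= thr["bright_mean_rgb"]

    labels = np.full(brightness.shape, STROMA, dtype=np.uint8)

    comp = cc_label(bright, connectivity=1)
    if comp.max() > 0:
        border = np.zeros_like(bright)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        border_ids = np.unique(comp[border & bright])
        border_ids = border_ids[border_ids > 0]
        touches_border = np.isin(comp, border_ids)
        labels[bright & touches_border] = BACKGROUND
        labels[bright & ~touches_border] = COLLOID

    nucleus = (channels.hema_od >= thr["nucleus_hema_od"]) & ~bright
    labels[nucleus] = NUCLEUS

    tissue = ~bright & ~nucleus
    stroma = (
        tissue
        & (channels.residual_od >= thr["stroma_residual_min"])
        & (
            channels.residual_od
            > channels.hema_od + channels.dab_od + thr["stroma_residual_margin"]
        )
    )
    labels[tissue & ~stroma] = PARENCHYMA
    labels[stroma] = STROMA
    return TissueLabelMap(labels=labels, mpp=denoised_img.mpp)


def refine_labels(
    labels: TissueLabelMap,
    min_area_um2: float = 30.0,
    closing_radius_um: float = 0.0,
) -> TissueLabelMap:
    """Morphological/contextual clean-up of the raw classification.

    Connected components smaller than ``min_area_um2`` are reassigned to the
    majority label of their immediate surround, then a per-class binary
    closing is applied in fixed precedence order (nucleus highest) so that
    the result remains a partition.  ``min_area_um2=0`` with
    ``closing_radius_um=0`` is the identity.
    """
    if min_area_um2 < 0 or closing_radius_um < 0:
        raise ValueError("refinement parameters must be >= 0")
    out = labels.labels.copy()
    min_px = min_area_um2 / labels.mpp**2

    if min_px > 1:
        for code in (COLLOID, NUCLEUS, PARENCHYMA, STROMA, BACKGROUND):
            comp = cc_label(out == code, connectivity=1)
            for region in regionprops(comp):
                if region.area >= min_px:
                    continue
                rr0, cc0, rr1, cc1 = region.bbox
                rr0, cc0 = max(rr0 - 1, 0), max(cc0 - 1, 0)
                rr1, cc1 = min(rr1 + 1, out.shape[0]), min(cc1 + 1, out.shape[1])
                patch = comp[rr0:rr1, cc0:cc1] == region.label
                ring = _dilation(patch, disk(1)) & ~patch
                surround = out[rr0:rr1, cc0:cc1][ring]
                surround = surround[surround != code]
                if surround.size:
                    vals, counts = np.unique(surround, return_counts=True)
                    out[rr0:rr1, cc0:cc1][patch] = vals[np.argmax(counts)]

    radius_px = int(round(closing_radius_um / labels.mpp))
    if radius_px >= 1:
        footprint = disk(radius_px)
        snapshot = out.copy()
        for code in REFINE_PRECEDENCE:
            closed = _closing(snapshot == code, footprint)
            out[closed] = code
    return TissueLabelMap(labels=out, mpp=labels.mpp)


def follicular_interface(labels: TissueLabelMap, band_width_um: float = 8.0) -> np.ndarray:
    """Epithelial rim around each colloid lumen — the follicular cells.

    The colloid mask is dilated by ``band_width_um`` and intersected with
    non-colloid, non-stromal tissue (parenchyma plus the nuclei embedded in
    it), yielding the band of follicular-cell cytoplasm and nuclei hugging
    the lumen.  Empty (with a warning) when the slide has no colloid.
    """
    if band_width_um < 0:
        raise ValueError("band_width_um must be >= 0")
    colloid = labels.mask(COLLOID)
    if not colloid.any():
        logger.warning("no colloid labels present; follicular interface is empty")
        return np.zeros_like(colloid)
    band_px = int(round(band_width_um / labels.mpp))
    if band_px < 1:
        return np.zeros_like(colloid)
    dilated = _dilation(colloid, disk(band_px))
    cellular = labels.mask(PARENCHYMA) | labels.mask(NUCLEUS)
    return dilated & cellular


def exclude_nuclei(
    band_mask: np.ndarray,
    labels: TissueLabelMap,
    nucleus_dilation_um: float = 1.0,
) -> np.ndarray:
    """Remove (dilated) nuclei from the interface band.

    The result is the cytoplasmic/membranous quantitation mask; by
    construction it never intersects NUCLEUS pixels.
    """
    if nucleus_dilation_um < 0:
        raise ValueError("nucleus_dilation_um must be >= 0")
    nuc = labels.mask(NUCLEUS)
    dil_px = int(round(nucleus_dilation_um / labels.mpp))
    if dil_px >= 1:
        nuc = _dilation(nuc, disk(dil_px))
    return band_mask & ~nuc


def detect_nuclei(
    labels: TissueLabelMap, nucleus_radius_um: float = 4.0
) -> tuple[list[tuple[float, float]], int]:
    """Locate individual nuclei by component analysis with watershed splits.

    Oversized components are split on the distance transform (seeded
    watershed), so touching nuclei are counted separately.  The split
    threshold is 1.5x the nominal nucleus area: rim nuclei are clipped by
    the epithelial band, so an abutting pair typically measures below twice
    the nominal area, and single nuclei are protected by the peak guard
    (one distance peak leaves the component whole).  Returns
    ``(centroids, count)`` with centroids as (x, y) pixel coordinates
    (0-based, pixel-centre).
    """
    nuc = labels.mask(NUCLEUS)
    if not nuc.any():
        return [], 0
    r_px = max(nucleus_radius_um / labels.mpp, 1.0)
    typical_area = np.pi * r_px**2
    comp = cc_label(nuc, connectivity=1)
    centroids: list[tuple[float, float]] = []
    for region in regionprops(comp):
        if region.area <= 1.5 * typical_area:
            cy, cx = region.centroid
            centroids.append((cx, cy))
            continue
        rr0, cc0, rr1, cc1 = region.bbox
        patch = comp[rr0:rr1, cc0:cc1] == region.label
        dist = ndi.distance_transform_edt(patch)
        peaks = peak_local_max(
            dist, min_distance=max(int(round(r_px)), 1), labels=patch
        )
        if len(peaks) < 2:
            cy, cx = region.centroid
            centroids.append((cx, cy))
            continue
        markers = np.zeros(patch.shape, dtype=int)
        for i, (pr, pc) in enumerate(peaks, start=1):
            markers[pr, pc] = i
        ws = watershed(-dist, markers, mask=patch)
        for sub in regionprops(ws):
            cy, cx = sub.centroid
            centroids.append((cx + cc0, cy + rr0))
    centroids.sort(key=lambda p: (p[1], p[0]))
    return centroids, len(centroids)
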