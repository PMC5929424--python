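"""DAB stain quantitation over the follicular-cell mask.

Two parameters are extracted, mirroring routine IHC digital readouts:

* **percent positivity** — 100 x (pixels whose DAB intensity falls below,
  i.e. darker than, the threshold gate) / (all quantified pixels);
* **mean intensity** — the average DAB intensity over *all* quantified
  pixels on the 0-255 dark-to-light scale (lower = more stain).

Both weight every pixel equally.  An alternative mean over positive pixels
only is available via ``mean_over_positives``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .sampling import SamplingPlan, subroi_mask
from .segmentation import TissueLabelMap, detect_nuclei

__all__ = ["QuantResult", "quantify_mask", "quantify_subrois", "render_quant_overlay"]

logger = logging.getLogger(__name__)

DEFAULT_POSITIVITY_THRESHOLD = 180.0

OVERLAY_POSITIVE = (255, 255, 0)  # yellow
OVERLAY_NEGATIVE = (173, 216, 230)  # light blue


@dataclasses.dataclass(frozen=True)
class QuantResult:
    """Stain readout for one subROI (or the pooled aggregate).

    ``percent_positivity`` and ``mean_intensity`` are ``None`` when the
    quantified region is empty (``n_pixels == 0``); a warning is logged so
    empty regions never pass silently.
    """

    subroi_id: str
    n_pixels: int
    n_positive: int
    percent_positivity: float | None
    mean_intensity: float | None
    quantified_area_um2: float
    n_cells: int = 0


def quantify_mask(
    dab_intensity8: np.ndarray,
    mask: np.ndarray,
    positivity_threshold: float = DEFAULT_POSITIVITY_THRESHOLD,
    mpp: float = 1.0,
    subroi_id: str = "aggregate",
    n_cells: int = 0,
    mean_over_positives: bool = False,
) -> QuantResult:
    """Threshold-gate DAB intensity within ``mask`` and summarise.

    A pixel is positive iff its intensity is strictly below the gate
    (darker brown than the threshold).  ``mean_over_positives`` switches the
    intensity average to the positive subset only.
    """
    if not 0 < positivity_threshold < 255:
        raise ValueError("positivity_threshold must lie in (0, 255)")
    if mask.shape != dab_intensity8.shape:
        raise ValueError("mask and intensity map shapes differ")
    vals = np.asarray(dab_intensity8, dtype=float)[mask]
    n = int(vals.size)
    if n == 0:
        logger.warning("empty quantitation mask for subROI %r", subroi_id)
        return QuantResult(
            subroi_id=subroi_id,
            n_pixels=0,
            n_positive=0,
            percent_positivity=None,
            mean_intensity=None,
            quantified_area_um2=0.0,
            n_cells=n_cells,
        )
    positive = vals < positivity_threshold
    n_pos = int(positive.sum())
    if mean_over_positives:
        mean_int = float(vals[positive].mean()) if n_pos else None
    else:
        mean_int = float(vals.mean())
    return QuantResult(
        subroi_id=subroi_id,
        n_pixels=n,
        n_positive=n_pos,
        percent_positivity=100.0 * n_pos / n,
        mean_intensity=mean_int,
        quantified_area_um2=n * mpp**2,
        n_cells=n_cells,
    )


def quantify_subrois(
    labels: TissueLabelMap,
    mask: np.ndarray,
    plan: SamplingPlan,
    dab_intensity8: np.ndarray,
    positivity_threshold: float = DEFAULT_POSITIVITY_THRESHOLD,
    nucleus_radius_um: float = 4.0,
) -> tuple[list[QuantResult], QuantResult]:
    """Quantify each subROI and the pixel-weighted aggregate.

    The aggregate is computed on the union of the subROI regions, which for
    disjoint subROIs equals pooled counting (total positives over total
    pixels).  Cell counts attribute each detected nucleus to the subROI
    containing its centroid, restricted to nuclei adjacent to the
    quantitation band.
    """
    if not plan.subrois:
        raise ValueError("sampling plan contains no subROIs")
    centroids, _ = detect_nuclei(labels, nucleus_radius_um=nucleus_radius_um)
    results: list[QuantResult] = []
    union = np.zeros_like(mask)
    for i, sub in enumerate(plan.subrois):
        smask = subroi_mask(sub, mask.shape)
        if not (smask & plan.roi_mask).any():
            raise ValueError(f"subROI {i} ({sub}) lies entirely outside the ROI")
        region = mask & smask
        union |= region
        n_cells = sum(
            1
            for (cx, cy) in centroids
            if sub.contains(cx, cy)
            and _near_mask(mask, cx, cy, radius=nucleus_radius_um / labels.mpp + 2)
        )
        results.append(
            quantify_mask(
                dab_intensity8,
                region,
                positivity_threshold,
                mpp=labels.mpp,
                subroi_id=f"subroi_{i}",
                n_cells=n_cells,
            )
        )
    aggregate = quantify_mask(
        dab_intensity8,
        union,
        positivity_threshold,
        mpp=labels.mpp,
        subroi_id="aggregate",
        n_cells=sum(r.n_cells for r in results),
    )
    return results, aggregate


def _near_mask(mask: np.ndarray, cx: float, cy: float, radius: float) -> bool:
    """True when any mask pixel lies within ``radius`` of (cx, cy)."""
    h, w = mask.shape
    x0, x1 = max(int(cx - radius), 0), min(int(cx + radius) + 2, w)
    y0, y1 = max(int(cy - radius), 0), min(int(cy + radius) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return False
    return bool(mask[y0:y1, x0:x1].any())


def render_quant_overlay(
    image_pixels: np.ndarray,
    mask: np.ndarray,
    dab_intensity8: np.ndarray,
    positivity_threshold: float = DEFAULT_POSITIVITY_THRESHOLD,
) -> np.ndarray:
    """Pseudocolour the gated mask: positive yellow, negative light blue.

    Pixels outside the mask keep their original appearance.  Purely
    presentational and bit-stable for fixed inputs.
    """
    out = np.asarray(image_pixels).copy()
    positive = mask & (dab_intensity8 < positivity_threshold)
    negative = mask & ~positive
    out[positive] = OVERLAY_POSITIVE
    out[negative] = OVERLAY_NEGATIVE
    return out
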