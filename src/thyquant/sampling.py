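"""Tumor sampling: subROI selection within an operator-delineated ROI.

Four strategies are provided.  Manual subROIs echo a pathologist's circles;
SURS (systematic uniform random sampling) keeps a fixed area fraction of a
randomly offset tile grid; the two hotspot methods place a fixed budget of
circles at maxima of a density heatmap — nuclear density alone, or nuclear
density jointly elevated with DAB positivity.

The default budget matches the study design: five circular subROIs of
2 x 10^5 um^2 each (10^6 um^2 total, > 1000 cells).  Circles never overlap;
"well-distributed" is enforced as a minimum centre separation (default two
radii) rather than any fixed template.
"""

from __future__ import annotations

import dataclasses
import enum
import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.morphology import erosion as _erosion

__all__ = [
    "SamplingMethod",
    "Circle",
    "Tile",
    "SamplingPlan",
    "Heatmap",
    "CapacityError",
    "DEFAULT_N_SUBROIS",
    "DEFAULT_SUBROI_AREA_UM2",
    "DEFAULT_SURS_FRACTION",
    "DEFAULT_TILE_UM",
    "DEFAULT_BANDWIDTH_UM",
    "subroi_radius_px",
    "subroi_mask",
    "surs_plan",
    "nuclear_density_heatmap",
    "dab_positivity_heatmap",
    "combine_heatmaps",
    "select_hotspots",
    "load_manual_subrois",
]

logger = logging.getLogger(__name__)

DEFAULT_N_SUBROIS = 5
DEFAULT_SUBROI_AREA_UM2 = 2.0e5
DEFAULT_SURS_FRACTION = 0.03
DEFAULT_TILE_UM = 100.0
DEFAULT_BANDWIDTH_UM = 50.0


class CapacityError(ValueError):
    """The ROI cannot accommodate the requested sampling geometry."""


class SamplingMethod(str, enum.Enum):
    MANUAL = "manual"
    SURS = "surs"
    HOTSPOT_NUCLEUS = "hotspot_nucleus"
    HOTSPOT_NUCLEUS_DAB = "hotspot_nucleus_dab"


@dataclasses.dataclass(frozen=True)
class Circle:
    """Circular subROI in pixel coordinates (0-based, pixel-centre)."""

    cx: float
    cy: float
    r: float

    def contains(self, x: float, y: float) -> bool:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.r**2

    def overlaps(self, other: "Circle") -> bool:
        return np.hypot(self.cx - other.cx, self.cy - other.cy) < self.r + other.r


@dataclasses.dataclass(frozen=True)
class Tile:
    """Axis-aligned square/rectangular subROI (x, y = top-left, px)."""

    x: int
    y: int
    w: int
    h: int

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px < self.x + self.w and self.y <= py < self.y + self.h


@dataclasses.dataclass(frozen=True)
class SamplingPlan:
    method: SamplingMethod
    roi_mask: np.ndarray
    subrois: tuple
    mpp: float
    fraction: float | None = None
    subroi_area_um2: float | None = None
    min_separation_um: float | None = None
    seed: int | None = None


@dataclasses.dataclass(frozen=True)
class Heatmap:
    """Nonnegative density field; integral preserves total event mass."""

    values: np.ndarray
    bandwidth_um: float


def subroi_radius_px(subroi_area_um2: float, mpp: float) -> float:
    """Circle radius (px) realising a target physical area."""
    return float(np.sqrt(subroi_area_um2 / np.pi) / mpp)


def subroi_mask(sub, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a Circle or Tile into a boolean mask."""
    h, w = shape
    if isinstance(sub, Circle):
        x0 = max(int(sub.cx - sub.r) - 1, 0)
        x1 = min(int(sub.cx + sub.r) + 2, w)
        y0 = max(int(sub.cy - sub.r) - 1, 0)
        y1 = min(int(sub.cy + sub.r) + 2, h)
        out = np.zeros(shape, dtype=bool)
        if x0 >= x1 or y0 >= y1:
            return out
        yy, xx = np.mgrid[y0:y1, x0:x1]
        out[y0:y1, x0:x1] = (xx - sub.cx) ** 2 + (yy - sub.cy) ** 2 <= sub.r**2
        return out
    if isinstance(sub, Tile):
        out = np.zeros(shape, dtype=bool)
        out[max(sub.y, 0) : sub.y + sub.h, max(sub.x, 0) : sub.x + sub.w] = True
        return out
    raise TypeError(f"unsupported subROI type {type(sub)!r}")


def surs_plan(
    roi_mask: np.ndarray,
    fraction: float = DEFAULT_SURS_FRACTION,
    tile_um: float = DEFAULT_TILE_UM,
    mpp: float = 1.0,
    seed: int = 0,
) -> SamplingPlan:
    """Systematic uniform random sampling of the ROI.

    A square tile grid with a seeded uniform-random offset is laid over the
    ROI; tiles intersecting the ROI are enumerated in raster order and
    every k-th tile is kept (k = round(1/fraction)), starting at a seeded
    random phase.  The selected area tracks ``fraction`` of the ROI to
    within about one tile.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if tile_um <= 0:
        raise ValueError("tile_um must be positive")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    tile_px = max(int(round(tile_um / mpp)), 1)
    rows = np.any(roi_mask, axis=1).nonzero()[0]
    cols = np.any(roi_mask, axis=0).nonzero()[0]
    if rows.size < tile_px and cols.size < tile_px:
        raise CapacityError(
            f"ROI bounding box {rows.size}x{cols.size} px is smaller than one "
            f"{tile_px} px tile"
        )
    h, w = roi_mask.shape
    rng = np.random.default_rng(seed)
    ox = int(rng.integers(0, tile_px))
    oy = int(rng.integers(0, tile_px))
    k = max(int(round(1.0 / fraction)), 1)
    phase = int(rng.integers(0, k))

    candidates: list[Tile] = []
    y = oy - tile_px
    while y < h:
        x = ox - tile_px
        while x < w:
            ys, xs = max(y, 0), max(x, 0)
            ye, xe = min(y + tile_px, h), min(x + tile_px, w)
            if ye > ys and xe > xs and roi_mask[ys:ye, xs:xe].any():
                candidates.append(Tile(x=x, y=y, w=tile_px, h=tile_px))
            x += tile_px
        y += tile_px
    selected = tuple(candidates[phase::k])
    return SamplingPlan(
        method=SamplingMethod.SURS,
        roi_mask=roi_mask,
        subrois=selected,
        mpp=mpp,
        fraction=fraction,
        seed=seed,
    )


def _kde(events: np.ndarray, bandwidth_um: float, mpp: float) -> np.ndarray:
    sigma_px = bandwidth_um / mpp
    # reflective boundary conserves total mass, so the map integrates to
    # the event count
    return ndi.gaussian_filter(events, sigma_px, mode="reflect")


def nuclear_density_heatmap(
    nucleus_centroids: list[tuple[float, float]],
    shape: tuple[int, int],
    bandwidth_um: float = DEFAULT_BANDWIDTH_UM,
    mpp: float = 1.0,
) -> Heatmap:
    """Gaussian kernel density of nucleus centroids (events / pixel)."""
    if bandwidth_um <= 0:
        raise ValueError("bandwidth_um must be positive")
    events = np.zeros(shape, dtype=float)
    if not nucleus_centroids:
        logger.warning("no nucleus centroids; heatmap is identically zero")
        return Heatmap(values=events, bandwidth_um=bandwidth_um)
    h, w = shape
    for cx, cy in nucleus_centroids:
        ix = min(max(int(round(cx)), 0), w - 1)
        iy = min(max(int(round(cy)), 0), h - 1)
        events[iy, ix] += 1.0
    return Heatmap(values=_kde(events, bandwidth_um, mpp), bandwidth_um=bandwidth_um)


def dab_positivity_heatmap(
    dab_intensity8: np.ndarray,
    quant_mask: np.ndarray,
    positivity_threshold: float,
    bandwidth_um: float = DEFAULT_BANDWIDTH_UM,
    mpp: float = 1.0,
) -> Heatmap:
    """Smoothed indicator of DAB-positive pixels within the quantitation mask."""
    if bandwidth_um <= 0:
        raise ValueError("bandwidth_um must be positive")
    indicator = (quant_mask & (dab_intensity8 < positivity_threshold)).astype(float)
    return Heatmap(values=_kde(indicator, bandwidth_um, mpp), bandwidth_um=bandwidth_um)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi > lo:
        return (values - lo) / (hi - lo)
    return np.ones_like(values) if hi > 0 else np.zeros_like(values)


def combine_heatmaps(nucleus_hm: Heatmap, dab_hm: Heatmap) -> Heatmap:
    """Joint hotspot field: product of min-max normalised maps.

    The product demands *joint* elevation — a region dense in nuclei but
    DAB-negative (or vice versa) scores zero.
    """
    if nucleus_hm.values.shape != dab_hm.values.shape:
        raise ValueError(
            f"heatmap shapes differ: {nucleus_hm.values.shape} vs {dab_hm.values.shape}"
        )
    combined = _minmax(nucleus_hm.values) * _minmax(dab_hm.values)
    return Heatmap(values=combined, bandwidth_um=nucleus_hm.bandwidth_um)


def select_hotspots(
    heatmap: Heatmap,
    roi_mask: np.ndarray,
    n: int = DEFAULT_N_SUBROIS,
    radius_px: float | None = None,
    min_sep_um: float | None = None,
    mpp: float = 1.0,
    subroi_area_um2: float = DEFAULT_SUBROI_AREA_UM2,
    method: SamplingMethod = SamplingMethod.HOTSPOT_NUCLEUS,
) -> SamplingPlan:
    """Greedy placement of ``n`` non-overlapping circles at heatmap maxima.

    Each iteration takes the global argmax over centres whose full circle
    lies inside the ROI (ties broken in raster order: smallest row, then
    column), then suppresses a neighbourhood of at least two radii (or
    ``min_sep_um`` if larger).  Raises :class:`CapacityError`, stating the
    achievable count, when the ROI cannot host ``n`` circles.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius_px is None:
        radius_px = subroi_radius_px(subroi_area_um2, mpp)
    # centres whose full circle fits inside the ROI, via distance transform
    # (equivalent to erosion by a disc but O(N) at any radius); the frame
    # border counts as outside the ROI
    padded = np.pad(roi_mask, 1, constant_values=False)
    valid = ndi.distance_transform_edt(padded)[1:-1, 1:-1] > radius_px
    if not valid.any():
        raise CapacityError(
            f"ROI cannot contain even one circle of radius {radius_px:.0f} px "
            "(achievable count: 0)"
        )
    sep_px = 2.0 * radius_px
    if min_sep_um is not None:
        sep_px = max(sep_px, min_sep_um / mpp)
    work = np.where(valid, heatmap.values, -np.inf)
    h, w = work.shape
    yy, xx = np.mgrid[0:h, 0:w]
    circles: list[Circle] = []
    for _ in range(n):
        flat = int(np.argmax(work))  # raster-first on ties
        cy, cx = divmod(flat, w)
        if not np.isfinite(work[cy, cx]):
            raise CapacityError(
                f"ROI fits only {len(circles)} of {n} non-overlapping circles "
                f"of radius {radius_px:.0f} px"
            )
        circles.append(Circle(cx=float(cx), cy=float(cy), r=float(radius_px)))
        work[(xx - cx) ** 2 + (yy - cy) ** 2 < sep_px**2] = -np.inf
    return SamplingPlan(
        method=method,
        roi_mask=roi_mask,
        subrois=tuple(circles),
        mpp=mpp,
        subroi_area_um2=subroi_area_um2,
        min_separation_um=sep_px * mpp,
    )


def load_manual_subrois(
    spec: list[dict],
    roi_mask: np.ndarray,
    mpp: float = 1.0,
) -> SamplingPlan:
    """Validate pathologist-specified circles into a MANUAL plan.

    Each entry gives ``center`` (x, y) and ``radius`` with ``units`` of
    ``"um"`` (default; converted through mpp) or ``"px"``.  Circles must
    have their centre inside the ROI and be pairwise non-overlapping; the
    offending entry is named otherwise.
    """
    if not spec:
        raise ValueError("manual subROI spec is empty")
    circles: list[Circle] = []
    for i, entry in enumerate(spec):
        try:
            cx, cy = entry["center"]
            radius = float(entry["radius"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"manual subROI {i}: malformed entry ({exc})") from exc
        units = entry.get("units", "um")
        if units == "um":
            cx, cy, radius = cx / mpp, cy / mpp, radius / mpp
        elif units != "px":
            raise ValueError(f"manual subROI {i}: unknown units {units!r}")
        circ = Circle(cx=float(cx), cy=float(cy), r=radius)
        iy, ix = int(round(circ.cy)), int(round(circ.cx))
        h, w = roi_mask.shape
        if not (0 <= iy < h and 0 <= ix < w and roi_mask[iy, ix]):
            raise ValueError(f"manual subROI {i} centre ({cx:.0f}, {cy:.0f}) px is outside the ROI")
        for j, prev in enumerate(circles):
            if circ.overlaps(prev):
                raise ValueError(f"manual subROI {i} overlaps subROI {j}")
        circles.append(circ)
    return SamplingPlan(
        method=SamplingMethod.MANUAL,
        roi_mask=roi_mask,
        subrois=tuple(circles),
        mpp=mpp,
    )
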