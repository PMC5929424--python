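"""Ground-truthed synthetic thyroid histology.

Renders brightfield H-DAB photomicrographs of follicular thyroid tissue —
colloid lumens ringed by a one-cell epithelial rim with hematoxylin-dark
nuclei, embedded in stroma, optionally with lymphocytic infiltrate — via a
Beer-Lambert forward model.  Because the image is synthesised from known
per-pixel stain optical densities and a known label partition, every
downstream stage (deconvolution, segmentation, interface derivation, DAB
quantitation, sampling) has an exact oracle.

The default frame is 1392 x 1040 RGB at 1.0 micron/pixel; all geometric
parameters are physical (microns) and converted through ``mpp``.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
from scipy import ndimage as ndi

from . import segmentation as seg
from .stains import BrightfieldImage, default_hdab_matrix, normalize_stain_matrix

__all__ = [
    "SynthParams",
    "GroupSpec",
    "GroundTruth",
    "CohortCase",
    "CapacityError",
    "render_hdab",
    "generate_tissue",
    "generate_cohort",
    "preset_params",
    "PRESET_NAMES",
]


class CapacityError(ValueError):
    """Requested geometry cannot be placed in the frame."""


@dataclasses.dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic slide.

    Staining is controlled by optical densities: DAB-positive epithelium
    carries ``dab_od_positive`` on the DAB vector, negative epithelium a
    faint ``dab_od_negative``, nuclei ``hema_od_nucleus`` on hematoxylin.
    ``dab_positive_fraction`` is the target fraction of non-nuclear
    epithelial area rendered positive (realised via a spatially smooth
    random field thresholded at the matching quantile, so the realised
    fraction tracks the target almost exactly).
    """

    image_width_px: int = 1392
    image_height_px: int = 1040
    mpp: float = 1.0
    n_follicles: int = 12
    follicle_radius_um: tuple[float, float] = (50.0, 110.0)
    epithelium_thickness_um: float = 10.0
    nucleus_radius_um: float = 4.0
    nuclei_per_100um_rim: float = 8.0
    dab_positive_fraction: float = 0.3
    dab_od_positive: float = 0.6
    dab_od_negative: float = 0.05
    hema_od_nucleus: float = 0.8
    lymphocyte_density: float = 0.0  # count per mm^2 of stroma-bearing frame
    noise_sd: float = 2.0  # additive RGB noise, 8-bit units
    seed: int = 0
    # appearance details beyond the headline staining parameters
    cyto_hema_od: float = 0.15
    stroma_od: float = 0.20
    colloid_od: float = 0.03
    boundary_irregularity: float = 0.025
    positive_field_sigma_um: float = 10.0

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")
        if self.n_follicles < 0:
            raise ValueError("n_follicles must be >= 0")
        rmin, rmax = self.follicle_radius_um
        if not (0 < rmin <= rmax):
            raise ValueError("follicle radius range must be positive with min <= max")
        if not self.epithelium_thickness_um > 0:
            raise ValueError("epithelium thickness must be positive")
        if not self.nucleus_radius_um > 0:
            raise ValueError("nucleus radius must be positive")
        if self.nuclei_per_100um_rim < 0:
            raise ValueError("nuclear rim density must be >= 0")
        if not 0.0 <= self.dab_positive_fraction <= 1.0:
            raise ValueError("dab_positive_fraction must be in [0, 1]")
        if not self.dab_od_positive > self.dab_od_negative >= 0:
            raise ValueError("require dab_od_positive > dab_od_negative >= 0")
        if not self.hema_od_nucleus > 0:
            raise ValueError("hema_od_nucleus must be > 0")
        if self.lymphocyte_density < 0 or self.noise_sd < 0:
            raise ValueError("densities and noise must be >= 0")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth enabling exact oracles downstream."""

    label_mask: np.ndarray  # (H, W) codes incl. LYMPHOCYTE
    positive_mask: np.ndarray  # true DAB+ pixels, subset of epithelium\nuclei
    follicle_centers: list[tuple[float, float, float]]  # (x, y, r_px)
    nucleus_centroids: list[tuple[float, float]]  # (x, y) px
    true_positive_fraction: float
    hema_od: np.ndarray
    dab_od: np.ndarray
    residual_od: np.ndarray

    @property
    def epithelium_mask(self) -> np.ndarray:
        return self.label_mask == seg.PARENCHYMA


@dataclasses.dataclass(frozen=True)
class GroupSpec:
    """Per-group parameter distribution for cohort simulation."""

    base: SynthParams
    fraction_mean: float
    fraction_sd: float = 0.05
    od_positive_mean: float | None = None
    od_positive_sd: float = 0.0


@dataclasses.dataclass(frozen=True)
class CohortCase:
    case_id: str
    group: str
    image: BrightfieldImage
    ground_truth: GroundTruth
    params: SynthParams


def render_hdab(
    hema_od_map: np.ndarray,
    dab_od_map: np.ndarray,
    stain_matrix: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    residual_od_map: np.ndarray | None = None,
    mpp: float = 1.0,
    quantize: bool = True,
) -> BrightfieldImage:
    """Beer-Lambert forward renderer.

    ``RGB = 255 * 10**-(c_h * S_h + c_d * S_d + c_r * S_r) + noise``,
    clipped to [0, 255].  With ``noise_sd=0`` and ``quantize=False`` the
    forward model is exact, so deconvolution recovers the OD maps to
    numerical precision; ``quantize=True`` rounds to 8-bit (adding up to
    half a grey level of quantisation error).
    """
    hema = np.asarray(hema_od_map, dtype=float)
    dab = np.asarray(dab_od_map, dtype=float)
    if hema.shape != dab.shape or hema.ndim != 2:
        raise ValueError("OD maps must be 2-D and share a shape")
    res = (
        np.zeros_like(hema)
        if residual_od_map is None
        else np.asarray(residual_od_map, dtype=float)
    )
    if res.shape != hema.shape:
        raise ValueError("residual OD map shape mismatch")
    for name, m in (("hematoxylin", hema), ("DAB", dab), ("residual", res)):
        if np.any(m < 0):
            raise ValueError(f"negative optical density in {name} map")
    matrix = (
        default_hdab_matrix()
        if stain_matrix is None
        else normalize_stain_matrix(stain_matrix)
    )
    od = (
        hema[..., None] * matrix[0]
        + dab[..., None] * matrix[1]
        + res[..., None] * matrix[2]
    )
    rgb = 255.0 * 10.0 ** (-od)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 255.0)
    pixels = np.round(rgb).astype(np.uint8) if quantize else rgb
    return BrightfieldImage(pixels=pixels, mpp=mpp)


def _radial_perturbation(rng: np.random.Generator, amplitude: float):
    """Low-frequency radial boundary perturbation r(theta) = r0*(1+p(theta))."""
    ks = np.arange(2, 6)
    a = rng.normal(0.0, amplitude, size=ks.size)
    b = rng.normal(0.0, amplitude, size=ks.size)

    def pert(theta: np.ndarray) -> np.ndarray:
        t = theta[..., None] * ks
        return (np.cos(t) * a + np.sin(t) * b).sum(axis=-1)

    return pert


def _place_follicles(
    params: SynthParams, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping follicle centres; (x, y, r_px)."""
    h, w = params.image_height_px, params.image_width_px
    rmin_px = params.follicle_radius_um[0] / params.mpp
    rmax_px = params.follicle_radius_um[1] / params.mpp
    margin = 1.0 + 2.0 * params.boundary_irregularity * 4  # perturbation headroom
    placed: list[tuple[float, float, float]] = []
    max_attempts = max(2000, 400 * params.n_follicles)
    attempts = 0
    while len(placed) < params.n_follicles:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not place {params.n_follicles} follicles of radius "
                f"{params.follicle_radius_um} um in a {w}x{h} px frame "
                f"(placed {len(placed)} after {attempts} attempts)"
            )
        attempts += 1
        r = rng.uniform(rmin_px, rmax_px)
        rr = r * margin
        if 2 * rr + 4 > min(h, w):
            raise CapacityError(
                f"follicle radius {r * params.mpp:.0f} um does not fit in a "
                f"{w}x{h} px frame at {params.mpp} um/px"
            )
        cx = rng.uniform(rr + 2, w - rr - 2)
        cy = rng.uniform(rr + 2, h - rr - 2)
        if all(
            np.hypot(cx - px, cy - py) > margin * (r + pr) + 3 for px, py, pr in placed
        ):
            placed.append((cx, cy, r))
    return placed


def generate_tissue(params: SynthParams) -> tuple[BrightfieldImage, GroundTruth]:
    """Render one slide and its ground truth.

    Deterministic under ``params.seed`` (same params -> bit-identical image
    and masks).  Raises :class:`CapacityError` when the requested follicle
    count cannot be placed.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height_px, params.image_width_px
    labels = np.full((h, w), seg.STROMA, dtype=np.uint8)
    t_px = params.epithelium_thickness_um / params.mpp

    follicles = _place_follicles(params, rng)
    yy, xx = np.mgrid[0:h, 0:w]
    nucleus_centroids: list[tuple[float, float]] = []

    for cx, cy, r in follicles:
        pert = _radial_perturbation(rng, params.boundary_irregularity)
        pad = int(np.ceil(r * 1.5 + 2))
        x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad + 1, w)
        y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad + 1, h)
        dx = xx[y0:y1, x0:x1] - cx
        dy = yy[y0:y1, x0:x1] - cy
        dist = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        boundary = r * (1.0 + pert(theta))
        inner = boundary - t_px
        patch = labels[y0:y1, x0:x1]
        patch[(dist < boundary) & (dist >= inner)] = seg.PARENCHYMA
        patch[dist < inner] = seg.COLLOID

        # nuclei seated mid-rim, spaced by arclength along the lumen
        perimeter_um = 2 * np.pi * r * params.mpp
        n_nuc = int(round(perimeter_um / 100.0 * params.nuclei_per_100um_rim))
        if n_nuc == 0:
            continue
        base = rng.uniform(0, 2 * np.pi)
        angles = base + np.linspace(0, 2 * np.pi, n_nuc, endpoint=False)
        angles = angles + rng.normal(0, 0.1 / n_nuc * 2 * np.pi, size=n_nuc)
        nr_px = params.nucleus_radius_um / params.mpp
        accepted: list[tuple[float, float]] = []
        for ang in angles:
            rad = r * (1.0 + pert(np.array(ang))) - t_px / 2.0
            nx, ny = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            # epithelium is a monolayer: neighbouring nuclei keep at least
            # a sliver of cytoplasm between them
            if any(np.hypot(nx - px, ny - py) < 2 * nr_px + 2 for px, py in accepted):
                continue
            accepted.append((nx, ny))
            gx0, gx1 = max(int(nx - nr_px) - 1, 0), min(int(nx + nr_px) + 2, w)
            gy0, gy1 = max(int(ny - nr_px) - 1, 0), min(int(ny + nr_px) + 2, h)
            if gx0 >= gx1 or gy0 >= gy1:
                continue
            nd = np.hypot(xx[gy0:gy1, gx0:gx1] - nx, yy[gy0:gy1, gx0:gx1] - ny)
            spot = (nd <= nr_px) & (labels[gy0:gy1, gx0:gx1] == seg.PARENCHYMA)
            if spot.any():
                labels[gy0:gy1, gx0:gx1][spot] = seg.NUCLEUS
                nucleus_centroids.append((float(nx), float(ny)))

    # lymphocytic infiltrate: small hematoxylin-only discs in stroma
    area_mm2 = h * w * params.mpp**2 / 1e6
    n_lym = int(round(params.lymphocyte_density * area_mm2))
    if n_lym > 0:
        stroma_idx = np.flatnonzero(labels == seg.STROMA)
        if stroma_idx.size:
            picks = rng.choice(stroma_idx, size=min(n_lym, stroma_idx.size), replace=False)
            lr_px = max(params.nucleus_radius_um * 0.8 / params.mpp, 1.0)
            for flat in picks:
                ly, lx = divmod(int(flat), w)
                gx0, gx1 = max(int(lx - lr_px) - 1, 0), min(int(lx + lr_px) + 2, w)
                gy0, gy1 = max(int(ly - lr_px) - 1, 0), min(int(ly + lr_px) + 2, h)
                nd = np.hypot(xx[gy0:gy1, gx0:gx1] - lx, yy[gy0:gy1, gx0:gx1] - ly)
                spot = (nd <= lr_px) & (labels[gy0:gy1, gx0:gx1] == seg.STROMA)
                labels[gy0:gy1, gx0:gx1][spot] = seg.LYMPHOCYTE

    # DAB positivity: smooth random field thresholded at the target quantile
    epithelium = labels == seg.PARENCHYMA
    positive = np.zeros((h, w), dtype=bool)
    n_epi = int(epithelium.sum())
    if n_epi > 0 and params.dab_positive_fraction > 0:
        if params.dab_positive_fraction >= 1.0:
            positive = epithelium.copy()
        else:
            sigma_px = params.positive_field_sigma_um / params.mpp
            field = ndi.gaussian_filter(rng.standard_normal((h, w)), sigma_px)
            cut = np.quantile(field[epithelium], 1.0 - params.dab_positive_fraction)
            positive = epithelium & (field > cut)
    true_fraction = float(positive.sum() / n_epi) if n_epi else 0.0

    hema_od = np.zeros((h, w))
    hema_od[epithelium] = params.cyto_hema_od
    hema_od[(labels == seg.NUCLEUS) | (labels == seg.LYMPHOCYTE)] = params.hema_od_nucleus
    dab_od = np.zeros((h, w))
    dab_od[epithelium] = params.dab_od_negative
    dab_od[positive] = params.dab_od_positive
    residual_od = np.zeros((h, w))
    residual_od[labels == seg.STROMA] = params.stroma_od
    residual_od[labels == seg.COLLOID] = params.colloid_od

    image = render_hdab(
        hema_od,
        dab_od,
        noise_sd=params.noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
        residual_od_map=residual_od,
        mpp=params.mpp,
    )
    truth = GroundTruth(
        label_mask=labels,
        positive_mask=positive,
        follicle_centers=follicles,
        nucleus_centroids=nucleus_centroids,
        true_positive_fraction=true_fraction,
        hema_od=hema_od,
        dab_od=dab_od,
        residual_od=residual_od,
    )
    return image, truth


def generate_cohort(
    group_specs: Mapping[str, GroupSpec],
    n_per_group: int,
    seed: int = 0,
) -> list[CohortCase]:
    """Simulate a multi-group cohort with per-group staining distributions.

    Each case draws its DAB-positive fraction (and optionally positive OD)
    from the group's normal distribution, clipped to the valid range, and
    renders an independent slide.  Reproducible under ``seed``.
    """
    if not group_specs:
        raise ValueError("group_specs must be nonempty")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    cases: list[CohortCase] = []
    for group, spec in group_specs.items():
        for i in range(n_per_group):
            frac = float(
                np.clip(rng.normal(spec.fraction_mean, spec.fraction_sd), 0.0, 1.0)
            )
            od_mean = (
                spec.base.dab_od_positive
                if spec.od_positive_mean is None
                else spec.od_positive_mean
            )
            od_pos = float(
                np.clip(
                    rng.normal(od_mean, spec.od_positive_sd),
                    spec.base.dab_od_negative + 0.02,
                    3.0,
                )
            )
            params = dataclasses.replace(
                spec.base,
                dab_positive_fraction=frac,
                dab_od_positive=od_pos,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            image, truth = generate_tissue(params)
            cases.append(
                CohortCase(
                    case_id=f"{group}_{i:03d}",
                    group=group,
                    image=image,
                    ground_truth=truth,
                    params=params,
                )
            )
    return cases


PRESET_NAMES = ("adenomatous", "microfollicular", "papillary")


def preset_params(
    name: str,
    width_px: int = 640,
    height_px: int = 480,
    seed: int = 0,
    **overrides,
) -> SynthParams:
    """Histomorphology presets spanning the diagnostic spectrum.

    ``adenomatous``: few large distended follicles; ``microfollicular``:
    many small crowded follicles; ``papillary``: mid-sized follicles with
    markedly irregular lumen boundaries.  Follicle counts scale with frame
    area so presets work at any desk-scale size.
    """
    area = width_px * height_px
    if name == "adenomatous":
        kw = dict(
            n_follicles=max(2, round(area / 120_000)),
            follicle_radius_um=(70.0, 110.0),
        )
    elif name == "microfollicular":
        kw = dict(
            n_follicles=max(6, round(area / 18_000)),
            follicle_radius_um=(18.0, 32.0),
        )
    elif name == "papillary":
        kw = dict(
            n_follicles=max(3, round(area / 55_000)),
            follicle_radius_um=(40.0, 70.0),
            boundary_irregularity=0.05,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    kw.update(overrides)
    return SynthParams(
        image_width_px=width_px, image_height_px=height_px, seed=seed, **kw
    )
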