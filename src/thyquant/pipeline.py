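"""End-to-end case analysis: denoise -> deconvolve -> segment -> refine ->
interface -> nucleus exclusion -> subROI sampling -> DAB quantitation.

This is the library-level orchestration behind the ``analyze`` command;
every stage is an independently testable function from the sibling
modules, and per-stage wall times and pixel counts are logged.
"""

from __future__ import annotations

import dataclasses
import logging
import time

import numpy as np

from . import sampling as smp
from .config import RunConfig
from .quantitation import QuantResult, quantify_subrois
from .segmentation import (
    TissueLabelMap,
    classify_pixels,
    detect_nuclei,
    exclude_nuclei,
    follicular_interface,
)
from .segmentation import refine_labels as _refine
from .stains import BrightfieldImage, StainChannelSet, deconvolve, median_denoise, rgb_to_od

__all__ = ["CaseAnalysis", "analyze_case", "build_sampling_plan"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class CaseAnalysis:
    channels: StainChannelSet
    labels: TissueLabelMap
    quant_mask: np.ndarray
    plan: smp.SamplingPlan
    subroi_results: list[QuantResult]
    aggregate: QuantResult
    timings_s: dict[str, float]


def build_sampling_plan(
    config: RunConfig,
    roi_mask: np.ndarray,
    labels: TissueLabelMap | None = None,
    quant_mask: np.ndarray | None = None,
    channels: StainChannelSet | None = None,
) -> smp.SamplingPlan:
    """Construct the subROI plan for the configured sampling method."""
    mpp = config.require_mpp()
    method = smp.SamplingMethod(config.sampling_method)
    if method is smp.SamplingMethod.MANUAL:
        if not config.manual_subrois:
            raise ValueError("sampling_method=manual requires manual_subrois in config")
        return smp.load_manual_subrois(config.manual_subrois, roi_mask, mpp=mpp)
    if method is smp.SamplingMethod.SURS:
        return smp.surs_plan(
            roi_mask,
            fraction=config.surs_fraction,
            tile_um=config.tile_um,
            mpp=mpp,
            seed=config.seed,
        )
    if labels is None or quant_mask is None:
        raise ValueError(f"{method.value} sampling needs segmentation outputs")
    centroids, _ = detect_nuclei(labels, nucleus_radius_um=config.nucleus_radius_um)
    nucleus_hm = smp.nuclear_density_heatmap(
        centroids, labels.labels.shape, bandwidth_um=config.bandwidth_um, mpp=mpp
    )
    heatmap = nucleus_hm
    if method is smp.SamplingMethod.HOTSPOT_NUCLEUS_DAB:
        if channels is None:
            raise ValueError("hotspot_nucleus_dab sampling needs stain channels")
        dab_hm = smp.dab_positivity_heatmap(
            channels.dab_intensity8,
            quant_mask,
            config.positivity_threshold,
            bandwidth_um=config.bandwidth_um,
            mpp=mpp,
        )
        heatmap = smp.combine_heatmaps(nucleus_hm, dab_hm)
    return smp.select_hotspots(
        heatmap,
        roi_mask,
        n=config.n_subrois,
        min_sep_um=config.min_separation_um,
        mpp=mpp,
        subroi_area_um2=config.subroi_area_um2,
        method=method,
    )


def analyze_case(
    image: BrightfieldImage,
    roi_mask: np.ndarray | None,
    config: RunConfig,
) -> CaseAnalysis:
    """Run the full quantitation pipeline on one calibrated image.

    ``roi_mask=None`` analyses the whole frame.  Raises on an empty ROI and
    propagates stage errors so a batch run exits nonzero on any failure.
    """
    config.require_mpp()
    if image.mpp != config.mpp:
        raise ValueError(
            f"image calibration ({image.mpp} um/px) disagrees with config ({config.mpp})"
        )
    if roi_mask is None:
        roi_mask = np.ones(image.shape, dtype=bool)
    if roi_mask.shape != image.shape:
        raise ValueError("ROI mask shape does not match the image")
    if not roi_mask.any():
        raise ValueError("ROI is empty")

    timings: dict[str, float] = {}

    def _stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = time.perf_counter() - t0
            logger.info("stage %-12s %.3f s", name, timings[name])

        return done

    end = _stage("denoise")
    denoised = median_denoise(image, radius_px=config.median_radius_px)
    end()

    end = _stage("deconvolve")
    matrix = np.asarray(config.stain_matrix) if config.stain_matrix else None
    from .stains import default_hdab_matrix

    channels = deconvolve(
        rgb_to_od(denoised.pixels),
        matrix if matrix is not None else default_hdab_matrix(),
    )
    end()

    end = _stage("classify")
    labels = classify_pixels(channels, denoised, config.thresholds)
    end()

    end = _stage("refine")
    labels = _refine(
        labels,
        min_area_um2=config.min_area_um2,
        closing_radius_um=config.closing_radius_um,
    )
    logger.info("class pixel counts: %s", labels.class_counts())
    end()

    end = _stage("interface")
    band = follicular_interface(labels, band_width_um=config.band_width_um)
    end()

    end = _stage("exclude")
    quant_mask = exclude_nuclei(band, labels, nucleus_dilation_um=config.nucleus_dilation_um)
    end()

    end = _stage("sample")
    plan = build_sampling_plan(
        config, roi_mask, labels=labels, quant_mask=quant_mask, channels=channels
    )
    end()

    end = _stage("quantify")
    subroi_results, aggregate = quantify_subrois(
        labels,
        quant_mask,
        plan,
        channels.dab_intensity8,
        positivity_threshold=config.positivity_threshold,
        nucleus_radius_um=config.nucleus_radius_um,
    )
    end()

    return CaseAnalysis(
        channels=channels,
        labels=labels,
        quant_mask=quant_mask,
        plan=plan,
        subroi_results=subroi_results,
        aggregate=aggregate,
        timings_s=timings,
    )
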