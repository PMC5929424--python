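"""File formats: images, label maps, ground truth sidecars, geometry, CSV.

Label maps serialise as single-channel PNG with the documented integer
codes (background 0, colloid 1, parenchyma 2, stroma 3, nucleus 4,
lymphocyte 5).  Sampling geometry serialises as GeoJSON-style feature
collections with micron units plus an ``mpp`` header, and round-trips
losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.draw import polygon as draw_polygon

from . import segmentation as seg
from .sampling import Circle, SamplingMethod, SamplingPlan, Tile
from .stains import BrightfieldImage
from .synthetic import GroundTruth, SynthParams

__all__ = [
    "save_image",
    "load_image",
    "save_label_png",
    "load_label_png",
    "label_overlay",
    "save_ground_truth",
    "plan_to_geojson",
    "plan_from_geojson",
    "roi_mask_from_geojson",
    "results_to_frame",
]

# Pseudocolour palette for label overlays (colloid blue, parenchyma pink,
# stroma red, nucleus green).
LABEL_PALETTE = {
    seg.BACKGROUND: (255, 255, 255),
    seg.COLLOID: (70, 110, 230),
    seg.PARENCHYMA: (240, 170, 200),
    seg.STROMA: (210, 60, 60),
    seg.NUCLEUS: (60, 180, 75),
    seg.LYMPHOCYTE: (20, 110, 50),
}


def save_image(path: str | Path, img: BrightfieldImage) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels)
    else:
        iio.imwrite(path, img.pixels)


def load_image(path: str | Path, mpp: float) -> BrightfieldImage:
    """Read an 8-bit RGB image; calibration must be supplied explicitly."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = iio.imread(path)
    pixels = np.asarray(pixels)
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[..., :3]
    return BrightfieldImage(pixels=pixels.astype(np.uint8), mpp=mpp)


def save_label_png(path: str | Path, labels: np.ndarray) -> None:
    iio.imwrite(Path(path), labels.astype(np.uint8))


def load_label_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.uint8)


def label_overlay(labels: np.ndarray) -> np.ndarray:
    """Pseudocolour RGB rendering of a label map."""
    out = np.zeros((*labels.shape, 3), dtype=np.uint8)
    for code, colour in LABEL_PALETTE.items():
        out[labels == code] = colour
    return out


def save_ground_truth(
    out_dir: str | Path, case_id: str, truth: GroundTruth, params: SynthParams
) -> None:
    """Write the generator sidecar: label/positive masks plus parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_label_png(out / f"{case_id}_labels.png", truth.label_mask)
    save_label_png(out / f"{case_id}_positive.png", truth.positive_mask.astype(np.uint8))
    meta = dataclasses.asdict(params)
    meta["follicle_radius_um"] = list(meta["follicle_radius_um"])
    meta["true_positive_fraction"] = truth.true_positive_fraction
    meta["n_nuclei"] = len(truth.nucleus_centroids)
    with open(out / f"{case_id}_params.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def plan_to_geojson(plan: SamplingPlan) -> dict:
    """Serialise a sampling plan as a micron-unit feature collection."""
    features = []
    for sub in plan.subrois:
        if isinstance(sub, Circle):
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [sub.cx * plan.mpp, sub.cy * plan.mpp],
                    },
                    "properties": {"shape": "circle", "radius_um": sub.r * plan.mpp},
                }
            )
        elif isinstance(sub, Tile):
            x0, y0 = sub.x * plan.mpp, sub.y * plan.mpp
            x1, y1 = (sub.x + sub.w) * plan.mpp, (sub.y + sub.h) * plan.mpp
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]],
                    },
                    "properties": {"shape": "tile"},
                }
            )
    return {
        "type": "FeatureCollection",
        "mpp": plan.mpp,
        "method": plan.method.value,
        "fraction": plan.fraction,
        "subroi_area_um2": plan.subroi_area_um2,
        "min_separation_um": plan.min_separation_um,
        "seed": plan.seed,
        "features": features,
    }


def plan_from_geojson(data: dict, roi_mask: np.ndarray) -> SamplingPlan:
    mpp = float(data["mpp"])
    subrois = []
    for feat in data["features"]:
        geom = feat["geometry"]
        props = feat.get("properties", {})
        if props.get("shape") == "circle" or geom["type"] == "Point":
            cx, cy = geom["coordinates"]
            subrois.append(
                Circle(cx=cx / mpp, cy=cy / mpp, r=float(props["radius_um"]) / mpp)
            )
        else:
            ring = geom["coordinates"][0]
            xs = [p[0] / mpp for p in ring]
            ys = [p[1] / mpp for p in ring]
            x0, y0 = min(xs), min(ys)
            subrois.append(
                Tile(
                    x=int(round(x0)),
                    y=int(round(y0)),
                    w=int(round(max(xs) - x0)),
                    h=int(round(max(ys) - y0)),
                )
            )
    return SamplingPlan(
        method=SamplingMethod(data["method"]),
        roi_mask=roi_mask,
        subrois=tuple(subrois),
        mpp=mpp,
        fraction=data.get("fraction"),
        subroi_area_um2=data.get("subroi_area_um2"),
        min_separation_um=data.get("min_separation_um"),
        seed=data.get("seed"),
    )


def roi_mask_from_geojson(data: dict, shape: tuple[int, int], mpp: float) -> np.ndarray:
    """Rasterise a polygon feature collection into a boolean ROI mask."""
    mask = np.zeros(shape, dtype=bool)
    features = data["features"] if data.get("type") == "FeatureCollection" else [data]
    for feat in features:
        geom = feat.get("geometry", feat)
        if geom["type"] != "Polygon":
            raise ValueError(f"ROI features must be polygons, got {geom['type']}")
        ring = geom["coordinates"][0]
        rows = [p[1] / mpp for p in ring]
        cols = [p[0] / mpp for p in ring]
        rr, cc = draw_polygon(rows, cols, shape=shape)
        mask[rr, cc] = True
    return mask


def results_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Tidy per-subROI results table with a stable column order."""
    columns = [
        "case_id",
        "group",
        "method",
        "subroi_id",
        "percent_positivity",
        "mean_intensity",
        "area_um2",
        "n_pixels",
        "n_cells",
    ]
    frame = pd.DataFrame(rows)
    for col in columns:
        if col not in frame.columns:
            frame[col] = None
    return frame[columns]


def write_json(path: str | Path, data: dict) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
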