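"""Run configuration: every tunable of the analysis pipeline in one place.

A :class:`RunConfig` is fully serialisable; ``analyze``/``simulate`` echo
the effective configuration verbatim into the output directory so any run
can be reproduced from its artefacts alone.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .sampling import (
    DEFAULT_BANDWIDTH_UM,
    DEFAULT_N_SUBROIS,
    DEFAULT_SUBROI_AREA_UM2,
    DEFAULT_SURS_FRACTION,
    DEFAULT_TILE_UM,
)
from .segmentation import default_thresholds

__all__ = ["RunConfig"]


@dataclasses.dataclass
class RunConfig:
    """Pipeline parameters with study defaults.

    ``mpp`` has no default on purpose: physical calibration must be stated
    explicitly (there is never a silent pixel-unit fallback).
    """

    mpp: float | None = None
    stain_matrix: list[list[float]] | None = None  # None -> standard H-DAB
    median_radius_px: int = 2
    thresholds: dict[str, float] = dataclasses.field(default_factory=default_thresholds)
    min_area_um2: float = 30.0
    closing_radius_um: float = 0.0
    band_width_um: float = 8.0
    nucleus_dilation_um: float = 1.0
    nucleus_radius_um: float = 4.0
    positivity_threshold: float = 180.0
    sampling_method: str = "hotspot_nucleus"
    n_subrois: int = DEFAULT_N_SUBROIS
    subroi_area_um2: float = DEFAULT_SUBROI_AREA_UM2
    min_separation_um: float | None = None  # None -> two radii
    surs_fraction: float = DEFAULT_SURS_FRACTION
    tile_um: float = DEFAULT_TILE_UM
    bandwidth_um: float = DEFAULT_BANDWIDTH_UM
    manual_subrois: list[dict] | None = None
    seed: int = 0
    log_level: str = "INFO"

    def require_mpp(self) -> float:
        if self.mpp is None or not self.mpp > 0:
            raise ValueError(
                "missing image calibration: set a positive mpp (microns per pixel)"
            )
        return float(self.mpp)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
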