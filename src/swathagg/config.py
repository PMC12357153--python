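"""Run configuration: the knobs of a full oversampling/disparity run.

A RunConfig collects the method choice and every numeric constant of the
pipeline (QA threshold 0.75, kernel exponents n=2/m=4, 10x10 polygon
raster, 0.01 deg grid with explicit registration, truncation factor,
weight floor), round-trips losslessly through JSON, and hashes to a short
digest recorded in run manifests so outputs are traceable to their exact
configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from .oversampler import OversamplingConfig

VALID_METHODS = ("pgo", "awo", "awo-grid")


@dataclass(frozen=True)
class RunConfig:
    method: str = "pgo"
    qa_threshold: float = 0.75
    n: float = 2.0
    m: float = 4.0
    raster_resolution: int = 10
    grid_resolution: float = 0.01
    grid_lon0: float | None = None  # grid registration origin; None = input bbox
    grid_lat0: float | None = None
    window_start: str | None = None  # ISO dates; None = span of the input
    window_end: str | None = None
    window_label: str = "full"
    truncation_factor: float = 3.0
    weight_floor: float = 1e-6
    fwhm_scale: float = 1.0
    top_fraction: float = 0.05
    min_coverage: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; valid choices: {', '.join(VALID_METHODS)}"
            )
        if not (0.0 <= self.qa_threshold <= 1.0):
            raise ValueError("qa_threshold must be in [0, 1]")
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.raster_resolution < 2:
            raise ValueError("raster_resolution must be >= 2")

    def oversampling(self) -> OversamplingConfig:
        return OversamplingConfig(
            n=self.n,
            m=self.m,
            raster_resolution=self.raster_resolution,
            truncation_factor=self.truncation_factor,
            weight_floor=self.weight_floor,
            fwhm_scale=self.fwhm_scale,
        )

    def window_dates(self) -> tuple[_dt.date, _dt.date] | None:
        if self.window_start is None or self.window_end is None:
            return None
        return (_dt.date.fromisoformat(self.window_start), _dt.date.fromisoformat(self.window_end))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
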