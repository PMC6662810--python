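"""Pipeline configuration with documented defaults and TOML loading."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Every knob of the extraction/selection/evaluation pipeline.

    Defaults encode the standard operating point: 64 gray levels, GLCM
    pixel distance 3 (the distance at which the co-occurrence parameters
    stabilize on low-power images), correlation / long-run-emphasis as the
    direction-weighting sentinels, area-weighted shape aggregation, a
    data-driven L1 weight, and a C=1 linear SVM.
    """

    levels: int = 64                       # quantization gray levels
    glcm_distance: int = 3                 # co-occurrence pixel distance
    stability_distances: tuple = (1, 2, 3, 4, 5)
    sentinel_glcm: str = "correlation"
    sentinel_glrlm: str = "long_run_emphasis"
    shape_aggregation: str = "area_weighted"   # | unweighted | largest
    min_component_area: int = 20           # pixels
    lam1: float | None = None              # None -> grid rule
    solver_tol: float = 1e-6
    solver_max_iter: int = 10_000
    threshold_scale: str = "prox"          # | absolute (literal lam1)
    svm_C: float = 1.0
    selection_scope: str = "full"          # | nested
    seed: int = 0

    @property
    def sentinels(self) -> dict[str, str]:
        return {"glcm": self.sentinel_glcm, "glrlm": self.sentinel_glrlm}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional TOML file plus keyword overrides.

    Unknown keys are rejected so typos fail loudly.
    """
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            values.update(tomllib.load(fh))
    values.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stability_distances" in values:
        values["stability_distances"] = tuple(values["stability_distances"])
    return PipelineConfig(**values)
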