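"""Pipeline configuration: every tunable of every stage, validated on load.

Defaults are the pipeline's standard protocol values: 1.5 km thinning
over 100 replicates, 70% slope / 15 m top-elevation cliff criteria, 5 m
transect spacing, Pearson |r| < 0.75 screening, the 13 feature-class combos x
21 regularization multipliers tuning grid, 10-fold cross-validation, 5000
background cells, 1000 optimizer iterations, the 10-percentile training
presence threshold, a 2 km dispersal buffer cropped at 7 km from shore, and a
60% suitability cut for high-suitability cell counts.  No constant is
hard-coded elsewhere; stages read these fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

#: the 13 admissible feature-class combinations for model tuning
FEATURE_COMBOS = ("L", "Q", "H", "LP", "LQ", "LH", "PQ", "PH", "QH",
                  "LPQ", "LPH", "LQH", "PQH")

#: published Maxent default per-class regularization interpolation tables
#: (sample sizes -> beta); clamped linear interpolation over presence count
BETA_TABLES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "L": ((10, 30, 100), (1.0, 0.2, 0.05)),
    "Q": ((0, 10, 17, 30, 100), (1.3, 0.8, 0.5, 0.25, 0.05)),
    "P": ((0, 10, 17, 30, 100), (2.6, 1.6, 0.9, 0.55, 0.05)),
    "H": ((0,), (0.5,)),
}


class PipelineConfig(BaseModel):
    """All tunables of the pipeline; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # occurrence cleaning / thinning
    max_uncertainty_m: float = Field(1000.0, gt=0)
    thin_distance_m: float = Field(1500.0, gt=0)
    thin_reps: int = Field(100, ge=1)

    # cliff delineation
    transect_spacing_m: float = Field(5.0, gt=0)
    transect_length_m: float = Field(300.0, gt=0)
    transect_step_m: float = Field(2.0, gt=0)
    cliff_slope_min_pct: float = Field(70.0, gt=0)
    cliff_top_min_elev_m: float = Field(15.0, gt=0)
    cliff_seg_slope_pct: float = Field(30.0, gt=0)
    cliff_toe_min_elev_m: float = Field(1.0, ge=0)
    tangent_smooth_window: int = Field(3, ge=1)
    # optional manual curation stand-in: ids to force-include / exclude
    cliff_include_ids: tuple[int, ...] = ()
    cliff_exclude_ids: tuple[int, ...] = ()

    # predictor screening
    pearson_r_max: float = Field(0.75, gt=0, le=1)

    # model tuning and fitting
    feature_combos: tuple[str, ...] = FEATURE_COMBOS
    rm_start: float = Field(1.0, gt=0)
    rm_stop: float = Field(5.0, gt=0)
    rm_step: float = Field(0.2, gt=0)
    n_background: int = Field(5000, ge=1)
    max_iterations: int = Field(1000, ge=1)
    convergence_tol: float = Field(1e-7, gt=0)
    n_hinge_knots: int = Field(50, ge=1)
    k_folds: int = Field(10, ge=2)
    penalty_sd_floor: float = Field(0.05, ge=0)

    # thresholding / range change
    threshold_percentile: float = Field(10.0, ge=0, le=100)
    suitability_count_cut: float = Field(0.60, gt=0, lt=1)
    dispersal_buffer_m: float = Field(2000.0, ge=0)
    max_shore_distance_m: float = Field(7000.0, gt=0)

    # seeds
    seed: int = Field(0, ge=0)

    @field_validator("feature_combos")
    @classmethod
    def _combos_known(cls, v: Sequence[str]) -> tuple[str, ...]:
        bad = [c for c in v if c not in FEATURE_COMBOS]
        if bad:
            raise ValueError(f"unknown feature-class combos: {bad}")
        return tuple(v)

    def rm_values(self) -> list[float]:
        """The regularization-multiplier lattice (default 1.0, 1.2, ..., 5.0)."""
        n = int(round((self.rm_stop - self.rm_start) / self.rm_step)) + 1
        return [round(self.rm_start + i * self.rm_step, 10) for i in range(n)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)
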