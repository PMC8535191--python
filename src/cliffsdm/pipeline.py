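"""End-to-end orchestration: simulate → cliffs → clean/thin → screen → tune →
fit → project → change accounting → land use.

Every stage reads its tunables from :class:`~cliffsdm.config.PipelineConfig`
and every stochastic step derives its seed deterministically from the config
seed, so a rerun with the same config is numerically identical.  Any stage
failure aborts with the stage name and cause.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cliffs as _cliffs
from . import maxent, selection, synthetic
from .config import PipelineConfig
from .grids import Grid, ScenarioStack, write_grid
from .metrics import ten_percentile_threshold
from .occurrences import OccurrenceSet, clean_records, thin, write_occurrences_csv
from .range_change import (BinaryMap, binarize, build_dispersal_polygon,
                           change_account, count_above, landuse_crosstab)

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "load_predictors"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_predictors(paths: dict[str, str | Path]) -> dict[str, Grid]:
    """Read named predictor rasters; a missing file aborts naming the variable."""
    from .grids import read_grid
    grids = {}
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"predictor raster {name!r} not found at {path}")
        grids[name] = read_grid(path, name=name)
    return grids


@dataclass
class PipelineResult:
    config: PipelineConfig
    world: synthetic.SyntheticWorld
    cliff_points: list
    dist_cliffs: Grid
    shore_distance: Grid
    occurrences: OccurrenceSet
    present_stack: ScenarioStack
    selected: selection.TuneResult
    evaluation: selection.EvalResult
    threshold: float
    suitability_present: Grid
    binary_present: BinaryMap
    change_table: pd.DataFrame
    landuse_table: pd.DataFrame
    high_suitability_counts: pd.DataFrame
    run_log: dict = field(default_factory=dict)


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False
    return _Ctx()


def run_pipeline(
    config: PipelineConfig,
    world_spec: synthetic.SyntheticWorldSpec | None = None,
    true_model: synthetic.TrueModel | None = None,
    scenario_deltas: list[synthetic.ScenarioDelta] | None = None,
    m_presences: int = 150,
    dirty: synthetic.DirtySpec | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole synthetic pipeline and (optionally) write its artifacts.

    ``scenario_deltas`` defaults to the full 5 GCM x 2 period x 2 RCP set
    (20 projections); pass a subset for quick runs.
    """
    if world_spec is None:
        world_spec = synthetic.SyntheticWorldSpec(seed=config.seed)
    if true_model is None:
        true_model = synthetic.TrueModel()
    if scenario_deltas is None:
        scenario_deltas = synthetic.default_scenario_deltas()
    run_log: dict = {"config": config.model_dump(mode="json"),
                     "seed": config.seed, "stages": {}}

    with _stage("simulate"):
        world = synthetic.gen_world(world_spec)
        run_log["stages"]["simulate"] = {
            "coarse_cells": int(np.prod(world_spec.coarse_shape)),
            "seed": world_spec.seed}

    with _stage("cliffs"):
        points = _cliffs.delineate_cliffs(
            world.dtm, world.coastline,
            spacing_m=config.transect_spacing_m,
            length_m=config.transect_length_m,
            step_m=config.transect_step_m,
            slope_min_pct=config.cliff_slope_min_pct,
            top_min_elev_m=config.cliff_top_min_elev_m,
            seg_slope_pct=config.cliff_seg_slope_pct,
            toe_min_elev_m=config.cliff_toe_min_elev_m,
            smooth_window=config.tangent_smooth_window,
            include_ids=config.cliff_include_ids,
            exclude_ids=config.cliff_exclude_ids,
        )
        tops = [p for p in points if p.role == "Top"]
        if not tops:
            raise ValueError("no cliff Top points detected")
        template = next(iter(world.climate.values()))
        dist_cliffs = _cliffs.distance_raster(template, points, name="dist_cliffs")
        shore = _cliffs.shore_distance_raster(template, world.coastline)
        run_log["stages"]["cliffs"] = {"n_top_points": len(tops)}

    with _stage("stack"):
        stack = world.present_stack(dist_cliffs)

    with _stage("presences"):
        occ = synthetic.sample_presences(
            true_model, stack, m_presences, seed=config.seed + 1,
            max_uncertainty_m=config.max_uncertainty_m, dirty=dirty)
        occ = clean_records(occ, world.range_polygon(), config.max_uncertainty_m)
        occ = thin(occ, config.thin_distance_m, config.thin_reps,
                   seed=config.seed + 2)
        run_log["stages"]["presences"] = dict(occ.log)

    with _stage("screen"):
        ranking = [synthetic.STATIC_VARIABLE] + [v for v in stack.variables
                                                 if v != synthetic.STATIC_VARIABLE]
        kept, corr = selection.pearson_screen(stack, ranking, config.pearson_r_max)
        stack = ScenarioStack(grids={v: stack.grids[v] for v in kept},
                              label=stack.label)
        run_log["stages"]["screen"] = {"kept": kept}

    with _stage("background"):
        _, _, bg_raw = maxent.sample_background(stack, config.n_background,
                                                seed=config.seed + 3)
        pres_raw = maxent.presence_values(stack, occ.coords())
        mask = stack.valid_mask()
        rows, cols = np.nonzero(mask)
        region_raw = stack.values_at_cells(rows, cols)
        run_log["stages"]["background"] = {
            "n_background": config.n_background, "n_region_cells": int(mask.sum()),
            "coverage_pct": round(100.0 * config.n_background / int(mask.sum()), 1),
            "seed": config.seed + 3}

    fit_kwargs = dict(max_iter=config.max_iterations, tol=config.convergence_tol,
                      n_hinge_knots=config.n_hinge_knots,
                      penalty_sd_floor=config.penalty_sd_floor)

    with _stage("tune"):
        candidates = selection.candidate_grid(config.feature_combos,
                                              config.rm_values())
        results = selection.tune(pres_raw, bg_raw, region_raw, stack.variables,
                                 candidates, **fit_kwargs)
        best = selection.select_best(results)
        run_log["stages"]["tune"] = {
            "n_candidates": len(candidates),
            "selected_combo": best.spec.combo, "selected_rm": best.spec.rm,
            "aicc": best.aicc, "K": best.k_nonzero}

    with _stage("evaluate"):
        evaluation = selection.kfold_evaluate(
            pres_raw, bg_raw, stack.variables, best.spec,
            k=min(config.k_folds, len(pres_raw)), seed=config.seed + 4,
            threshold_percentile=config.threshold_percentile, **fit_kwargs)
        run_log["stages"]["evaluate"] = {
            "mean_auc": evaluation.mean_auc, "mean_tss": evaluation.mean_tss,
            "seed": config.seed + 4}

    with _stage("project"):
        model = best.model
        tau = ten_percentile_threshold(model.cloglog(pres_raw),
                                       config.threshold_percentile)
        suit_present = maxent.predict(model, stack, "cloglog")
        bin_present = binarize(suit_present, tau, scenario="present")
        futures: dict[str, tuple[ScenarioStack, Grid, BinaryMap]] = {}
        for delta in scenario_deltas:
            fstack = synthetic.apply_delta(stack, delta)
            fsuit = maxent.predict(model, fstack, "cloglog")
            futures[fstack.scenario_id()] = (fstack, fsuit, binarize(
                fsuit, tau, scenario=fstack.scenario_id()))
        run_log["stages"]["project"] = {"threshold": tau,
                                        "n_projections": len(futures)}

    with _stage("change"):
        polygon = build_dispersal_polygon(
            occ.coords(), shore, config.dispersal_buffer_m,
            config.max_shore_distance_m)
        rows_out = []
        counts = [{"scenario": "present",
                   "cells_above_cut": count_above(suit_present,
                                                  config.suitability_count_cut)}]
        for sid, (fstack, fsuit, fbin) in futures.items():
            for constraint in (None, polygon):
                summary, _ = change_account(bin_present, fbin, constraint)
                rows_out.append(summary.as_row())
            counts.append({"scenario": sid,
                           "cells_above_cut": count_above(
                               fsuit, config.suitability_count_cut)})
        change_table = pd.DataFrame(rows_out)
        high_counts = pd.DataFrame(counts)
        run_log["stages"]["change"] = {
            "polygon_cells": int(polygon.cell_mask.sum())}

    with _stage("landuse"):
        lu_rows = [{"scenario": "present",
                    **landuse_crosstab(bin_present, world.landuse).to_dict()}]
        for i, (sid, (_, _, fbin)) in enumerate(futures.items()):
            lu_future = synthetic.evolve_landuse(world.landuse,
                                                 seed=config.seed + 10 + i)
            lu_rows.append({"scenario": sid,
                            **landuse_crosstab(fbin, lu_future).to_dict()})
        landuse_table = pd.DataFrame(lu_rows)

    result = PipelineResult(
        config=config, world=world, cliff_points=points, dist_cliffs=dist_cliffs,
        shore_distance=shore, occurrences=occ, present_stack=stack,
        selected=best, evaluation=evaluation, threshold=tau,
        suitability_present=suit_present, binary_present=bin_present,
        change_table=change_table, landuse_table=landuse_table,
        high_suitability_counts=high_counts, run_log=run_log)

    if out_dir is not None:
        with _stage("write"):
            _write_outputs(result, futures, polygon, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, futures, polygon, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_grid(result.suitability_present, out / "suitability_present.asc")
    write_grid(result.binary_present.grid, out / "binary_present.asc")
    write_grid(result.dist_cliffs, out / "dist_cliffs.asc")
    for sid, (_, fsuit, fbin) in futures.items():
        write_grid(fsuit, out / f"suitability_{sid}.asc")
        write_grid(fbin.grid, out / f"binary_{sid}.asc")
    result.change_table.to_csv(out / "change_summary.csv", index=False)
    result.landuse_table.to_csv(out / "landuse_percentages.csv", index=False)
    result.high_suitability_counts.to_csv(out / "high_suitability_counts.csv",
                                          index=False)
    write_occurrences_csv(result.occurrences, out / "occurrences.csv")
    _cliffs.cliff_points_to_geojson(result.cliff_points, out / "cliff_points.geojson")
    polygon.to_geojson(out / "dispersal_polygon.geojson")
    if result.selected.model is not None:
        result.selected.model.to_json(out / "model.json")
    (out / "run_log.json").write_text(json.dumps(result.run_log, indent=2,
                                                 default=float))
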