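"""End-to-end pipeline: geometry -> flow -> WSS -> shear sites -> chip
operating points.

Each stage writes its artifacts (VTK fields, CSV tables, JSON sites)
into the output directory, and the run finishes with a JSON manifest
holding the config hash, per-stage timings, output paths and collected
warnings.  The whole chain is deterministic: identical configurations
produce bitwise-identical numerical outputs (manifest timings aside).
On a stage failure the error propagates, annotated with the stage name,
after a partial manifest marking the remaining stages as skipped has
been written.
"""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np

from . import geometry as geo
from . import vtkio
from .chip import map_sites
from .config import PipelineConfig, config_hash, dump_config
from .errors import AneuchipError
from .solver import PenalizedFlowSolver
from .wss import compute_wss, find_extreme_sites, time_average_wss

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("aneuchip")

STAGES = ("geometry", "solve", "wss", "sites", "chip_map")


class PipelineError(AneuchipError):
    """Stage failure wrapper carrying the stage name and the partial
    manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"pipeline failed in stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause
        self.manifest = manifest


def _build_geometry(cfg: PipelineConfig) -> geo.VoxelMask:
    g = cfg.geometry
    if g.kind == "stl":
        mask = geo.voxelize_stl(g.stl_path, g.spacing, flow_axis=0)
    elif g.kind == "straight_vessel":
        mask = geo.make_straight_vessel(
            g.params(), g.spacing,
            domain_height=g.domain_height, wall_offset=g.wall_offset,
        )
    elif g.kind == "sidewall_aneurysm":
        mask = geo.make_sidewall_aneurysm(
            g.params(), g.spacing,
            domain_height=g.domain_height, wall_offset=g.wall_offset,
        )
    else:
        raise AneuchipError(f"unknown geometry kind {g.kind!r}")
    if g.refine_factor > 1:
        mask = geo.refine_mask(mask, g.refine_factor)
    if g.smoothing_radius > 0:
        mask = geo.smooth_mask(mask, g.smoothing_radius)
    mask.validate()
    return mask


def run_pipeline(cfg: PipelineConfig, out_dir: str | None = None) -> dict:
    """Execute all stages and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    cfg.validate_cross()
    out = out_dir or cfg.output.directory
    os.makedirs(out, exist_ok=True)
    log.setLevel(getattr(logging, cfg.output.log_level.upper(), logging.INFO))

    manifest: dict = {
        "config_hash": config_hash(cfg),
        "stages": {s: {"status": "pending"} for s in STAGES},
        "outputs": {},
        "warnings": [],
    }
    with open(os.path.join(out, "config_resolved.yaml"), "w") as fh:
        fh.write(dump_config(cfg))

    def fail(stage: str, err: Exception):
        manifest["stages"][stage] = {"status": "failed", "error": str(err)}
        for later in STAGES[STAGES.index(stage) + 1:]:
            manifest["stages"][later] = {"status": "skipped"}
        _write_manifest(out, manifest)
        raise PipelineError(stage, err, manifest) from err

    # -- geometry ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        mask = _build_geometry(cfg)
    except Exception as err:
        fail("geometry", err)
    manifest["stages"]["geometry"] = {
        "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
        "shape": list(mask.shape), "fluid_fraction": mask.fluid_fraction,
    }
    geo.save_mask(mask, os.path.join(out, "mask"))
    if "vtk" in cfg.output.formats:
        vtkio.write_rectilinear(
            os.path.join(out, "mask.vtk"), mask.spacing, mask.origin,
            {"solid_indicator": mask.indicator.astype(float)},
        )
        manifest["outputs"]["mask_vtk"] = "mask.vtk"
    manifest["outputs"]["mask"] = "mask.npz"
    log.info("geometry: %s cells, fluid fraction %.3f", mask.shape, mask.fluid_fraction)

    # -- flow solve ----------------------------------------------------
    t0 = time.perf_counter()
    pulsatile = cfg.physics.waveform_amplitude > 0
    try:
        solver = PenalizedFlowSolver(mask, cfg.solver_config())
        if pulsatile:
            sol = solver.solve_pulsatile(cfg.solver.n_periods, cfg.solver.n_phases)
        else:
            sol = solver.solve_steady()
    except Exception as err:
        fail("solve", err)
    manifest["stages"]["solve"] = {
        "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
        "steps": sol.n_steps, "time": sol.time,
        "final_residual": sol.residual_history[-1] if sol.residual_history else None,
        "max_divergence": sol.max_fluid_divergence(),
    }
    np.savetxt(
        os.path.join(out, "residual_history.csv"),
        np.column_stack([np.arange(1, len(sol.residual_history) + 1), sol.residual_history]),
        delimiter=",", header="step,residual", comments="",
    )
    manifest["outputs"]["residuals"] = "residual_history.csv"
    if "vtk" in cfg.output.formats:
        vtkio.write_rectilinear(
            os.path.join(out, "flow.vtk"), mask.spacing, mask.origin,
            {
                "velocity": sol.cell_velocity(),
                "pressure": sol.p,
                "solid_indicator": mask.indicator.astype(float),
            },
        )
        manifest["outputs"]["flow_vtk"] = "flow.vtk"
    log.info("solve: %d steps to t=%.3f (residual %.3g)",
             sol.n_steps, sol.time, manifest["stages"]["solve"]["final_residual"] or 0.0)

    # -- WSS -----------------------------------------------------------
    t0 = time.perf_counter()
    scaling = cfg.physics.scaling()
    try:
        if pulsatile:
            snaps = []
            for t_snap, u, v, p in sol.history[:-1]:
                snap_sol = type(sol)(
                    u=u, v=v, p=p, time=t_snap, h=sol.h, mask=mask,
                    length_scale=sol.length_scale, reynolds=sol.reynolds,
                )
                snaps.append(compute_wss(snap_sol, scaling=scaling))
            averaged, peak = time_average_wss(snaps)
            wss_field = peak if cfg.wss.temporal_statistic == "peak" else averaged
        else:
            wss_field = compute_wss(sol, scaling=scaling)
    except Exception as err:
        fail("wss", err)
    manifest["stages"]["wss"] = {
        "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
        "n_wall_faces": len(wss_field),
        "tau_pa_median": float(np.median(wss_field.tau_pa)),
        "tau_pa_max": float(wss_field.tau_pa.max()),
    }
    if "csv" in cfg.output.formats:
        wss_field.to_dataframe().to_csv(os.path.join(out, "wss.csv"), index=False)
        manifest["outputs"]["wss"] = "wss.csv"

    # -- sites ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        sites = find_extreme_sites(
            wss_field, cfg.wss.low_percentile, cfg.wss.high_percentile,
            cfg.wss.min_region_faces,
        )
    except Exception as err:
        fail("sites", err)
    manifest["stages"]["sites"] = {
        "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
        "n_low": len(sites.low_sites), "n_high": len(sites.high_sites),
    }
    with open(os.path.join(out, "sites.json"), "w") as fh:
        json.dump(sites.to_dict(), fh, indent=1)
    manifest["outputs"]["sites"] = "sites.json"
    log.info("sites: %d low, %d high", len(sites.low_sites), len(sites.high_sites))

    # -- chip map ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        pairs = map_sites(sites, cfg.chip.spec())
    except Exception as err:
        fail("chip_map", err)
    points = [op.to_dict() for _, op in pairs]
    for op in points:
        manifest["warnings"].extend(op["warnings"])
    manifest["stages"]["chip_map"] = {
        "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
        "n_operating_points": len(points),
    }
    with open(os.path.join(out, "operating_points.json"), "w") as fh:
        json.dump(points, fh, indent=1)
    manifest["outputs"]["operating_points"] = "operating_points.json"
    if "csv" in cfg.output.formats:
        import pandas as pd

        pd.DataFrame(points).to_csv(os.path.join(out, "operating_points.csv"), index=False)
        manifest["outputs"]["operating_points_csv"] = "operating_points.csv"

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: str, manifest: dict) -> None:
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
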