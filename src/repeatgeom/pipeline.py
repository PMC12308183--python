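"""Per-region orchestration and batch processing.

For every consecutive unit pair the pipeline runs: sliding-window selection
-> centroids -> PCA plane -> initial circle -> widest-crown refinement ->
curvature -> local frames -> canonicalization -> superposition -> Tait-Bryan
decomposition -> descriptor row.  Degenerate geometry in any stage flags the
row (null angles, reason recorded) and processing continues; a region fails
only when every pair fails.

Near-linear windows (centroid principal-value ratio below
``RunConfig.linear_ratio``, or fitted radius above ``RunConfig.radius_cap``)
take a straight-line fallback: curvature 0, infinite radius, pitch axis
taken from the third principal direction, row flagged ``linear``.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, structure_io
from .decomposition import (TaitBryan, decompose_tait_bryan, pair_descriptor,
                            superpose_units, canonicalize_unit)
from .errors import RegionResolutionError, RepeatGeomError
from .geometry import (LINEAR_RATIO, RADIUS_CAP, WINDOW, FittedCircle,
                       frame_from_axes)
from .structure_io import (GeometryTable, PAIR_COLUMNS, RegionSpec, Structure,
                           write_geometry_csv)

logger = logging.getLogger(__name__)

#: Angle columns summarized per region.
ANGLE_COLUMNS = ["curvature", "twist", "pitch"]


@dataclass(frozen=True)
class RunConfig:
    """Knobs of the measurement pipeline.

    ``window`` sliding-window length in units (>= 3); ``backend`` the
    superposition backend (``"internal"`` Kabsch or ``"tmalign"``);
    ``radius_cap`` (Å) and ``linear_ratio`` the near-linear thresholds;
    ``clockwise_positive`` the twist sign convention (clockwise looking
    along the travel direction is positive); ``pitch_disp_ratio`` the
    minimum vertical-displacement fraction of the chord before the pitch
    sign is reconciled with the actual up/down movement; ``refine_center``
    fits the initial circle to all projected Calpha rather than centroids
    only; ``wrap`` adds the closing pair (last unit, first unit) for ring
    topologies; ``workers`` the batch parallelism.
    """

    window: int = WINDOW
    backend: str = "internal"
    radius_cap: float = RADIUS_CAP
    linear_ratio: float = LINEAR_RATIO
    clockwise_positive: bool = True
    pitch_disp_ratio: float = 0.05
    refine_center: bool = False
    wrap: bool = False
    workers: int = 1
    seed: int = 0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("window must be >= 3 units")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


DEFAULT_CONFIG = RunConfig()


def _null_row(region: RegionSpec, i: int, j: int, flag: str) -> dict:
    ui, uj = region.units[i], region.units[j]
    row = {c: np.nan for c in PAIR_COLUMNS}
    row.update(region_id=region.region_id, pair_index=i, chain=ui.chain,
               unit_i_start=ui.start, unit_i_end=ui.end,
               unit_j_start=uj.start, unit_j_end=uj.end, flags=flag)
    return row


def _fit_window_circle(centroids_w: np.ndarray, ca_w: np.ndarray,
                       window: range, config: RunConfig
                       ) -> tuple[FittedCircle | None, geometry.Plane, list[str]]:
    """Plane + circle of one window; ``None`` circle means linear fallback."""
    flags: list[str] = []
    plane = geometry.fit_plane(centroids_w)
    s1, s2, _ = plane.singular_values
    if s2 < config.linear_ratio * s1:
        return None, plane, ["linear"]
    circle_pts = ca_w if config.refine_center else centroids_w
    try:
        center2d, radius = geometry.fit_initial_circle(plane.project(circle_pts))
    except RepeatGeomError:
        return None, plane, ["linear"]
    if radius > config.radius_cap:
        return None, plane, ["linear"]
    circle = geometry.widest_crown_refine(
        plane.project(ca_w), center2d, radius, plane=plane,
        window_units=window)
    if circle.flag != "crown":
        flags.append(circle.flag)
    return circle, plane, flags


@dataclass
class PairGeometry:
    """Geometric context of one unit pair: circle, frames, oriented normal."""

    frame_i: geometry.LocalFrame
    frame_j: geometry.LocalFrame
    curvature: float
    radius: float
    crown_inner: float
    crown_outer: float
    normal: np.ndarray
    flags: list[str]


def _pair_geometry(region: RegionSpec, i: int, j: int, coords: list,
                   centroids: list, config: RunConfig,
                   prev_normal: np.ndarray | None) -> PairGeometry:
    """Window circle and local frames for the pair (unit i -> unit j)."""
    n = region.n_units
    window = geometry.select_window(min(i, n - 2), n, config.window)
    w_idx = [k for k in window if coords[k] is not None]
    if j not in w_idx:
        w_idx.append(j)
    if len(w_idx) < 3:
        raise RepeatGeomError("window has fewer than 3 resolved units")

    centroids_w = np.array([centroids[k] for k in w_idx])
    ca_w = np.vstack([coords[k] for k in w_idx])
    ci, cj = centroids[i], centroids[j]
    travel_ij = cj - ci
    travel_j = (centroids[j + 1] - cj
                if j + 1 < n and coords[j + 1] is not None
                else travel_ij)

    circle, plane, flags = _fit_window_circle(centroids_w, ca_w, window,
                                              config)
    if circle is None:
        # Straight-line fallback: pitch axis from the third principal
        # direction (the plane normal), curvature defined as zero.
        plane = geometry.orient_plane(plane, prev_normal=prev_normal,
                                      travel0=travel_ij, y0=plane.normal)
        normal = plane.normal
        return PairGeometry(
            frame_from_axes(normal, travel_ij, ci),
            frame_from_axes(normal, travel_j, cj),
            0.0, np.inf, np.nan, np.nan, normal, flags)

    y_i = ci - circle.center3d
    plane = geometry.orient_plane(plane, prev_normal=prev_normal,
                                  travel0=travel_ij, y0=y_i)
    return PairGeometry(
        geometry.build_local_frame(circle, ci, cj),
        frame_from_axes(cj - circle.center3d, travel_j, cj),
        geometry.curvature_angle(circle.center3d, ci, cj),
        circle.radius, circle.crown_inner, circle.crown_outer,
        plane.normal, flags)


def _pair_row(region: RegionSpec, i: int, j: int, coords: list,
              centroids: list, config: RunConfig,
              prev_normal: np.ndarray | None
              ) -> tuple[dict, np.ndarray | None]:
    """One descriptor row for the pair (unit i -> unit j).

    Returns the row plus the continuity-oriented window normal (or the
    previous normal if the pair failed).
    """
    if coords[i] is None or coords[j] is None:
        return _null_row(region, i, j, "unresolved_unit"), prev_normal

    ci, cj = centroids[i], centroids[j]
    travel_ij = cj - ci
    try:
        geo = _pair_geometry(region, i, j, coords, centroids, config,
                             prev_normal)
        flags = geo.flags
        normal = geo.normal
        curvature, radius = geo.curvature, geo.radius
        crown_inner, crown_outer = geo.crown_inner, geo.crown_outer

        sup = superpose_units(canonicalize_unit(coords[j], geo.frame_j),
                              canonicalize_unit(coords[i], geo.frame_i),
                              backend=config.backend)
        # Rotation of unit j relative to unit i in the canonical frame.
        step = sup.rotation.T
        raw = decompose_tait_bryan(step)
        if raw.gimbal:
            flags.append("gimbal_lock")

        twist = -raw.roll if config.clockwise_positive else raw.roll
        pitch = raw.pitch
        disp = float(np.dot(travel_ij, normal))
        chord = float(np.linalg.norm(travel_ij))
        if (abs(disp) > config.pitch_disp_ratio * chord
                and pitch * disp < 0):
            pitch = -pitch
            flags.append("pitch_sign_reconciled")

        desc = pair_descriptor(curvature,
                               TaitBryan(raw.yaw, pitch, twist, raw.gimbal),
                               sup.rmsd, sup.aligned_length)
    except RepeatGeomError as exc:
        logger.warning("region %s pair %d: %s", region.region_id, i, exc)
        return _null_row(region, i, j, f"degenerate:{exc}"), prev_normal

    ui, uj = region.units[i], region.units[j]
    row = dict(region_id=region.region_id, pair_index=i, chain=ui.chain,
               unit_i_start=ui.start, unit_i_end=ui.end,
               unit_j_start=uj.start, unit_j_end=uj.end,
               curvature=desc.curvature, twist=desc.twist, pitch=desc.pitch,
               twist_handedness=desc.twist_handedness,
               pitch_handedness=desc.pitch_handedness,
               rmsd=desc.rmsd, aligned_length=desc.aligned_length,
               radius=radius, crown_inner=crown_inner,
               crown_outer=crown_outer, yaw_residual=desc.yaw_residual,
               flags=";".join(flags))
    return row, normal


def _resolve_units(structure: Structure, region: RegionSpec
                   ) -> tuple[list, list]:
    """Per-unit coordinates and centroids; unresolvable units become None."""
    coords: list[np.ndarray | None] = []
    for unit in region.units:
        try:
            coords.append(structure_io._unit_coords(structure, unit,
                                                    region.insertions))
        except RegionResolutionError as exc:
            logger.warning("region %s: %s", region.region_id, exc)
            coords.append(None)
    centroids = [geometry.unit_centroid(c) if c is not None else None
                 for c in coords]
    return coords, centroids


def region_frames(structure: Structure, region: RegionSpec,
                  config: RunConfig = DEFAULT_CONFIG
                  ) -> list[geometry.LocalFrame]:
    """Left-unit local frame of every computable consecutive pair.

    Used by the axes-visualization export; pairs whose geometry is
    degenerate are skipped.
    """
    region.validate()
    coords, centroids = _resolve_units(structure, region)
    frames = []
    prev_normal = None
    for i in range(region.n_units - 1):
        if coords[i] is None or coords[i + 1] is None:
            continue
        try:
            geo = _pair_geometry(region, i, i + 1, coords, centroids,
                                 config, prev_normal)
        except RepeatGeomError:
            continue
        frames.append(geo.frame_i)
        prev_normal = geo.normal
    return frames


def compute_region_geometry(structure: Structure, region: RegionSpec,
                            config: RunConfig = DEFAULT_CONFIG
                            ) -> GeometryTable:
    """Full descriptor table for one repeat region.

    One row per consecutive unit pair (indexed by the left unit), plus the
    closing pair when ``config.wrap`` is set.  The summary holds the
    arithmetic mean and sample standard deviation of curvature, twist and
    pitch over the computable pairs.
    """
    region.validate()
    n = region.n_units
    coords, centroids = _resolve_units(structure, region)

    pairs = [(i, i + 1) for i in range(n - 1)]
    if config.wrap:
        pairs.append((n - 1, 0))

    rows = []
    prev_normal: np.ndarray | None = None
    for i, j in pairs:
        row, prev_normal = _pair_row(region, i, j, coords, centroids,
                                     config, prev_normal)
        rows.append(row)

    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    summary = pd.DataFrame({
        col: [df[col].mean(), df[col].std(ddof=1)]
        for col in ANGLE_COLUMNS
    }, index=["mean", "std"])
    return GeometryTable(region.region_id, df, summary)


def table_status(table: GeometryTable) -> int:
    """Exit-code style status: 0 all rows computed, 1 partial, 2 none."""
    ok = table.pairs["curvature"].notna()
    if ok.all():
        return 0
    return 1 if ok.any() else 2


# ---------------------------------------------------------------------------
# batch mode


@dataclass
class BatchResult:
    """Per-job status plus the combined per-region summary table."""

    status: pd.DataFrame
    summary: pd.DataFrame
    tables: list[GeometryTable]


def _run_job(args: tuple[str, str, RunConfig]
             ) -> tuple[str, list[GeometryTable] | None, str]:
    """Worker: one (structure, regions) job; never raises."""
    structure_path, region_path, config = args
    try:
        structure = structure_io.parse_structure(structure_path)
        regions = structure_io.parse_region_spec(region_path)
        tables = [compute_region_geometry(structure, r, config)
                  for r in regions]
        return structure_path, tables, ""
    except (RepeatGeomError, OSError) as exc:
        return structure_path, None, str(exc)


def run_batch(jobs: list[tuple[str, str]], config: RunConfig = DEFAULT_CONFIG,
              out_dir: str | Path | None = None) -> BatchResult:
    """Process many (structure path, region-spec path) jobs.

    Jobs are independent; with ``config.workers > 1`` they run in parallel
    processes, but results are collected and written in input order, so the
    output is byte-identical to a serial run.  Per-region CSVs and a
    combined summary CSV are written under ``out_dir`` when given.  Job
    failures are isolated and reported in the status table.
    """
    if not jobs:
        raise ValueError("empty job list")
    arglist = [(str(s), str(r), config) for s, r in jobs]
    if config.workers == 1:
        results = [_run_job(a) for a in arglist]
    else:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(_run_job, arglist))

    status_rows, summary_rows, all_tables = [], [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for (spath, tables, err) in results:
        stem = Path(spath).stem
        if tables is None:
            status_rows.append({"structure": spath, "status": "error",
                                "n_regions": 0, "message": err})
            continue
        status_rows.append({"structure": spath, "status": "ok",
                            "n_regions": len(tables), "message": ""})
        for table in tables:
            all_tables.append(table)
            if out is not None:
                write_geometry_csv(table, out / f"{stem}_{table.region_id}.csv")
            srow = {"structure": spath, "region_id": table.region_id,
                    "n_pairs": len(table.pairs)}
            for col in ANGLE_COLUMNS:
                srow[f"{col}_mean"] = table.summary.loc["mean", col]
                srow[f"{col}_std"] = table.summary.loc["std", col]
            summary_rows.append(srow)

    status = pd.DataFrame(status_rows)
    summary = pd.DataFrame(summary_rows)
    if out is not None:
        status.to_csv(out / "batch_status.csv", index=False,
                      float_format="%.10g")
        summary.to_csv(out / "batch_summary.csv", index=False,
                       float_format="%.10g")
    if (status["status"] == "ok").sum() == 0:
        raise RepeatGeomError("no job succeeded in batch mode")
    return BatchResult(status, summary, all_tables)
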