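"""End-to-end case workflow: scan -> QC -> reconstruct -> measure -> design -> fit-check.

A *case* is one patient wound treated over time. Each invocation of
:func:`run_workflow` appends one adapter version to the case bundle; the
remodeling loop (wound geometry evolves under therapy, device is re-made
from the latest measurements) is simply a second invocation with the new
scan on the same bundle.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

from . import adapter_design, scan_io, wound_model
from .adapter_design import AdapterSpec, build_adapter, fit_check, ledge_report
from .scan_io import PointCloud, SurfaceMesh

__all__ = ["RunConfig", "CaseBundle", "WorkflowError", "run_workflow", "render_report"]


class WorkflowError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Validated workflow configuration (defaults are the clinical ones)."""

    qc_threshold: int = scan_io.DEFAULT_QC_THRESHOLD
    grid_pitch: float = 1.0  # mm
    height: float | None = None  # mm; None = from wound depth, clamped to 10-20
    bottom_offset: float = 5.0
    top_offset: float | None = None  # mm; None = auto from rim clearance
    middle_fraction: float | None = None  # None = height-dependent rule
    hole_clearance: float = 0.0
    eccentricity: tuple[float, float] = (0.0, 0.0)
    swap_axes: bool = False
    contour_samples: int = 256
    seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.qc_threshold < 0:
            raise ValueError("qc_threshold must be >= 0")
        if self.grid_pitch <= 0:
            raise ValueError("grid_pitch must be positive")
        if self.height is not None and self.height <= 0:
            raise ValueError("height must be positive")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "eccentricity" in data:
            data["eccentricity"] = tuple(data["eccentricity"])
        if "out_dir" in data and data["out_dir"] is not None:
            data["out_dir"] = Path(data["out_dir"])
        return cls(**data)


@dataclass
class CaseBundle:
    """Ordered artifacts of one case; adapter versions form a linear history."""

    case_id: str
    artifacts: dict = field(default_factory=dict)
    versions: list[dict] = field(default_factory=list)

    def latest(self) -> dict:
        if not self.versions:
            raise WorkflowError("report", "bundle has no adapter versions")
        return self.versions[-1]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "case_id": self.case_id,
            "artifacts": {k: str(v) for k, v in self.artifacts.items()},
            "versions": [
                {k: v for k, v in ver.items() if k not in ("timestamp",)}
                for ver in self.versions
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _auto_height(depth_cm: float) -> float:
    """Device height from wound depth: 10-20 mm, tracking the depth."""
    return float(np.clip(depth_cm * 10.0, 10.0, 20.0))


def _auto_top_offset(contour: wound_model.FistulaContour, frame, wound_lasso, margin: float = 5.0) -> float:
    """Brim offset from rim clearance: min(20 mm, clearance - margin), >= bottom."""
    rim_local = frame.to_local(np.asarray(wound_lasso))[:, :2]
    from shapely.geometry import LinearRing

    ring = LinearRing(rim_local)
    clearance = min(ring.distance(Polygon(contour.points).exterior), float("inf"))
    return float(np.clip(min(20.0, clearance - margin), 5.0, 20.0))


def run_workflow(
    config: RunConfig,
    cloud: PointCloud | None = None,
    second_cloud: PointCloud | None = None,
    mesh: SurfaceMesh | None = None,
    wound_lasso: np.ndarray | None = None,
    fistula_lasso: np.ndarray | None = None,
    bundle: CaseBundle | None = None,
    case_id: str = "case",
) -> CaseBundle:
    """Run one pass of the clinical workflow, appending an adapter version.

    Either a point cloud (QC'd and reconstructed at ``config.grid_pitch``)
    or an already-reconstructed mesh must be given, plus the wound-rim and
    fistula lassos. When QC rejects the first cloud the second is merged
    in if supplied; if the merged cloud still fails, the bundle records a
    re-scan instruction and no adapter is designed.
    """
    bundle = bundle or CaseBundle(case_id=case_id)
    t0 = time.monotonic()

    if mesh is None:
        if cloud is None:
            raise WorkflowError("input", "need a point cloud or a mesh")
        report = scan_io.qc_point_cloud(cloud, config.qc_threshold)
        bundle.artifacts[f"qc_v{len(bundle.versions) + 1}"] = dataclasses.asdict(report)
        if not report.accepted and second_cloud is not None:
            cloud = scan_io.merge_clouds(cloud, second_cloud)
            report = scan_io.qc_point_cloud(cloud, config.qc_threshold)
            bundle.artifacts[f"qc_merged_v{len(bundle.versions) + 1}"] = dataclasses.asdict(report)
        if not report.accepted:
            bundle.artifacts["rescan_required"] = (
                f"cloud has {report.n_points} < {report.threshold} points; re-scan the wound"
            )
            return bundle
        try:
            mesh = scan_io.reconstruct_surface(cloud, config.grid_pitch)
        except scan_io.ReconstructionError as exc:
            raise WorkflowError("reconstruct", str(exc)) from exc

    if wound_lasso is None or fistula_lasso is None:
        raise WorkflowError("measure", "wound and fistula lassos are required")

    try:
        region = wound_model.select_fistula_region(mesh, fistula_lasso)
        measurements = wound_model.measure_wound(
            mesh, wound_lasso, [region], swap_axes=config.swap_axes
        )
        frame = wound_model.fit_design_frame(region)
        contour = wound_model.extract_contour(region, frame, config.contour_samples)
    except (wound_model.SelectionError, wound_model.GeometryError) as exc:
        raise WorkflowError("measure", str(exc)) from exc

    height = config.height if config.height is not None else _auto_height(measurements.depth_cm)
    top_offset = (
        config.top_offset
        if config.top_offset is not None
        else _auto_top_offset(contour, frame, wound_lasso)
    )
    spec = AdapterSpec(
        height=height,
        bottom_offset=config.bottom_offset,
        top_offset=top_offset,
        middle_fraction=config.middle_fraction,
        eccentricity=config.eccentricity,
        hole_clearance=config.hole_clearance,
    )
    try:
        adapter = build_adapter(contour, spec, provenance=f"{bundle.case_id} v{len(bundle.versions) + 1}")
    except adapter_design.DesignInfeasible as exc:
        raise WorkflowError("design", str(exc)) from exc

    ledges = ledge_report(adapter)
    fit = fit_check(adapter, mesh, frame, fistula_region=region, rest_on_surface=True, seed=config.seed)

    version = {
        "version": len(bundle.versions) + 1,
        "measurements": measurements.as_dict(),
        "spec": dataclasses.asdict(spec),
        "report": ledges.as_dict(),
        "fit": dataclasses.asdict(fit),
        "hole_area_mm2": adapter.hole.area,
        "volume_mm3": adapter.mesh.volume(),
        "watertight": adapter.mesh.is_watertight(),
        "timestamp": time.monotonic() - t0,  # stage timing, metadata only
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stl = out / f"{bundle.case_id}_v{version['version']}.stl"
        scan_io.write_stl(adapter.mesh, stl)
        bundle.artifacts[f"adapter_v{version['version']}"] = stl
    bundle.versions.append(version)
    return bundle


def render_report(bundle: CaseBundle) -> str:
    """Per-version table mirroring the clinical device-characteristics layout."""
    if not bundle.versions:
        raise WorkflowError("report", "bundle has no adapter versions")
    cols = ["Version", "Height", "Width", "Length", "Top ledge", "Bottom ledge"]
    rows = [cols]
    for ver in bundle.versions:
        r = ver["report"]
        rows.append(
            [
                str(ver["version"]),
                f"{r['height_cm']:g}",
                f"{r['width_cm']:g}",
                f"{r['length_cm']:g}",
                r["top_ledge"],
                r["bottom_ledge"],
            ]
        )
    widths = [max(len(row[i]) for row in rows) for i in range(len(cols))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip() for row in rows]
    lines.insert(1, "-" * len(lines[0]))
    return "\n".join(lines)
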