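"""Point-cloud and mesh I/O, scan quality control, and 2.5-D surface reconstruction.

The scanning workflow this module supports starts from a structured-light
capture of an open abdominal wound: the scanner exports a point cloud
(sub-millimetre resolution), the cloud is gated on a minimum point count
(re-scan if too sparse), and the accepted cloud is meshed into an open
surface patch that downstream modules measure and design against.

All geometry is in millimetres. Clinical reports convert to centimetres at
the reporting boundary only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "CaptureStage",
    "MeshKind",
    "PointCloud",
    "SurfaceMesh",
    "QCReport",
    "MeshStats",
    "ParseError",
    "ReconstructionError",
    "DEFAULT_QC_THRESHOLD",
    "read_point_cloud",
    "write_point_cloud",
    "qc_point_cloud",
    "merge_clouds",
    "reconstruct_surface",
    "mesh_stats",
    "read_mesh",
    "write_stl",
]

#: Clouds with fewer points than this require a re-scan of the wound.
DEFAULT_QC_THRESHOLD = 400_000


class CaptureStage(str, enum.Enum):
    first_scan = "first_scan"
    second_scan = "second_scan"
    merged = "merged"


class MeshKind(str, enum.Enum):
    open_patch = "open_patch"
    closed_solid = "closed_solid"


class ParseError(ValueError):
    """A point-cloud file contained a malformed record."""


class ReconstructionError(RuntimeError):
    """The cloud is too sparse for the requested reconstruction pitch."""


@dataclass
class PointCloud:
    """Raw scanner points, positions in mm."""

    points: np.ndarray  # (n, 3) float64
    source_id: str = ""
    capture_stage: CaptureStage = CaptureStage.first_scan

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("point cloud contains non-finite coordinates")
        self.points = pts

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def __len__(self) -> int:
        return self.n_points


@dataclass
class SurfaceMesh:
    """Oriented triangle mesh: an open wound patch or a closed solid."""

    vertices: np.ndarray  # (v, 3) float64
    faces: np.ndarray  # (f, 3) int
    kind: MeshKind = MeshKind.open_patch

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return int(len(self.vertices))

    @property
    def n_faces(self) -> int:
        return int(len(self.faces))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def volume(self) -> float:
        """Signed enclosed volume (mm^3); meaningful for closed solids."""
        return float(self.to_trimesh().volume)


@dataclass(frozen=True)
class QCReport:
    n_points: int
    threshold: int
    decision: str  # "accept" | "rescan"

    @property
    def accepted(self) -> bool:
        return self.decision == "accept"


@dataclass(frozen=True)
class MeshStats:
    n_vertices: int
    n_triangles: int
    n_edges: int
    n_boundary_edges: int
    euler_characteristic: int


# ---------------------------------------------------------------------------
# I/O


def _parse_xyz(path: Path) -> np.ndarray:
    """Whitespace-separated ``x y z`` per line; ``#`` starts a comment line."""
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return np.array(rows, dtype=np.float64).reshape(-1, 3)


def read_point_cloud(
    path: str | Path,
    fmt: str = "auto",
    source_id: str | None = None,
    capture_stage: CaptureStage = CaptureStage.first_scan,
) -> PointCloud:
    """Read a scanner point-cloud export (PLY or XYZ ASCII).

    ``fmt`` is one of ``"ply"``, ``"xyz"`` or ``"auto"`` (decide by suffix,
    defaulting to XYZ).
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    if fmt == "auto":
        fmt = "ply" if path.suffix.lower() == ".ply" else "xyz"
    if fmt == "ply":
        try:
            loaded = trimesh.load(str(path), file_type="ply", process=False)
        except Exception as exc:  # malformed ply
            raise ParseError(f"{path}: invalid PLY: {exc}") from exc
        pts = np.asarray(loaded.vertices, dtype=np.float64)
    elif fmt == "xyz":
        pts = _parse_xyz(path)
    else:
        raise ValueError(f"unknown point-cloud format {fmt!r}")
    return PointCloud(pts, source_id=source_id or path.name, capture_stage=capture_stage)


def write_point_cloud(cloud: PointCloud, path: str | Path) -> Path:
    """Write the cloud in the XYZ dialect read by :func:`read_point_cloud`."""
    path = Path(path)
    header = f"# {cloud.n_points} points, mm, source={cloud.source_id}"
    np.savetxt(path, cloud.points, fmt="%.6f", header=header, comments="")
    return path


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Load a triangle mesh (STL/PLY) and classify it as patch or solid."""
    tm = trimesh.load(str(path), process=False)
    if not isinstance(tm, trimesh.Trimesh):
        raise OSError(f"{path}: not a triangle mesh")
    tm.merge_vertices()  # STL stores a triangle soup; restore shared topology
    kind = MeshKind.closed_solid if tm.is_watertight else MeshKind.open_patch
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), kind=kind)


def write_stl(mesh: SurfaceMesh, path: str | Path, dialect: str = "binary") -> Path:
    """Export to STL (``binary`` or ``ascii``); refuses to write an empty mesh."""
    if mesh.n_faces == 0:
        raise ValueError("refusing to write an empty mesh to STL")
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    path = Path(path)
    tm = mesh.to_trimesh()
    if dialect == "ascii":
        path.write_text(trimesh.exchange.stl.export_stl_ascii(tm))
    else:
        path.write_bytes(trimesh.exchange.stl.export_stl(tm))
    return path


# ---------------------------------------------------------------------------
# QC and merging


def qc_point_cloud(cloud: PointCloud, threshold: int = DEFAULT_QC_THRESHOLD) -> QCReport:
    """Gate a cloud on minimum point count: below threshold means re-scan."""
    decision = "rescan" if cloud.n_points < threshold else "accept"
    return QCReport(n_points=cloud.n_points, threshold=int(threshold), decision=decision)


def merge_clouds(a: PointCloud, b: PointCloud) -> PointCloud:
    """Concatenate two pre-aligned captures (no registration is performed)."""
    pts = np.vstack([a.points, b.points])
    return PointCloud(
        pts,
        source_id=f"{a.source_id}+{b.source_id}",
        capture_stage=CaptureStage.merged,
    )


# ---------------------------------------------------------------------------
# Reconstruction


def _best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane of a cloud: (centroid, right-handed 3x3 basis).

    Basis rows are (x, y, n); n is oriented so the residual distribution is
    not skewed toward +n (the wound crater dips toward the body side), with
    world +z as the tie-break for flat patches.
    """
    centroid = points.mean(axis=0)
    cov = np.cov((points - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    normal = evecs[:, 0]  # smallest-variance direction
    resid = (points - centroid) @ normal
    skew = float(np.mean(resid**3))
    if abs(skew) > 1e-9 * (float(np.mean(resid**2)) ** 1.5 + 1e-30):
        if skew > 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal
    x_axis = evecs[:, 2]
    y_axis = np.cross(normal, x_axis)
    basis = np.vstack([x_axis, y_axis, normal])
    return centroid, basis


def reconstruct_surface(cloud: PointCloud, grid_pitch: float) -> SurfaceMesh:
    """Reconstruct an open surface patch from a height-field-like cloud.

    The cloud is projected onto its best-fit plane, binned on a regular grid
    of the given pitch (mm), one vertex per occupied cell at the mean of the
    cell's points, and adjacent occupied cells are triangulated. Triangles
    are wound so normals point away from the body side (toward the scanner).

    Raises :class:`ReconstructionError` when fewer than half the cells of
    the bounding rectangle contain points, which signals that the pitch is
    finer than the sampling density.
    """
    if grid_pitch <= 0:
        raise ValueError("grid_pitch must be positive")
    if cloud.n_points < 3:
        raise ReconstructionError("cloud has fewer than 3 points")

    centroid, basis = _best_fit_plane(cloud.points)
    local = (cloud.points - centroid) @ basis.T  # rows: x, y, n-residual

    ij = np.floor(local[:, :2] / grid_pitch).astype(np.int64)
    ij -= ij.min(axis=0)
    ni, nj = ij.max(axis=0) + 1
    flat = ij[:, 0] * nj + ij[:, 1]
    order = np.argsort(flat, kind="stable")
    flat_sorted = flat[order]
    cell_ids, starts = np.unique(flat_sorted, return_index=True)
    occupancy = len(cell_ids) / float(ni * nj)
    if occupancy < 0.5:
        raise ReconstructionError(
            f"only {occupancy:.0%} of grid cells contain points at pitch "
            f"{grid_pitch} mm; try a larger pitch"
        )

    # per-cell mean of the points that fell in the cell
    sums = np.add.reduceat(local[order], starts, axis=0)
    counts = np.diff(np.append(starts, len(flat)))
    cell_means = sums / counts[:, None]

    grid_index = np.full((ni, nj), -1, dtype=np.int64)
    grid_index[cell_ids // nj, cell_ids % nj] = np.arange(len(cell_ids))

    # two triangles per fully occupied quad, CCW in plane coords (+n normals)
    a = grid_index[:-1, :-1]
    b = grid_index[1:, :-1]
    c = grid_index[1:, 1:]
    d = grid_index[:-1, 1:]
    full = (a >= 0) & (b >= 0) & (c >= 0) & (d >= 0)
    t1 = np.stack([a[full], b[full], c[full]], axis=1)
    t2 = np.stack([a[full], c[full], d[full]], axis=1)
    faces = np.vstack([t1, t2])
    if len(faces) == 0:
        raise ReconstructionError("no complete grid quads; try a larger pitch")

    # drop cells that ended up in no triangle (isolated specks near steep walls)
    used = np.unique(faces)
    remap = np.full(len(cell_ids), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    faces = remap[faces]
    cell_means = cell_means[used]

    vertices = centroid + cell_means @ basis
    return SurfaceMesh(vertices, faces, kind=MeshKind.open_patch)


# ---------------------------------------------------------------------------
# Statistics


def mesh_stats(mesh: SurfaceMesh) -> MeshStats:
    """Exact vertex/triangle/edge counts and Euler characteristic V - E + F."""
    edges = np.sort(
        np.vstack(
            [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
        ),
        axis=1,
    )
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    n_e = len(unique)
    n_boundary = int((counts == 1).sum())
    chi = mesh.n_vertices - n_e + mesh.n_faces
    return MeshStats(
        n_vertices=mesh.n_vertices,
        n_triangles=mesh.n_faces,
        n_edges=n_e,
        n_boundary_edges=n_boundary,
        euler_characteristic=int(chi),
    )
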