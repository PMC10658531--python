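"""Fistula selection, design-frame fitting, contour extraction, and wound morphometry.

The clinical workflow needs two kinds of geometry taken off the wound mesh:

* the outline of the exposed intestinal surface (the fistula), which becomes
  the through-hole of the personalized adapter, and
* caliper-style wound dimensions (length, width, depth, orifice heights)
  that size the adapter and populate the per-patient outcome records.

Selections are supplied as lassos: closed 3D polylines drawn on or near the
mesh surface (plain-text ``x y z`` rows; hand-editable). All geometry is in
mm; :class:`WoundMeasurements` reports in cm to match clinical convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Polygon

from ._geometry import ensure_ccw, resample_closed, signed_area, smooth_closed
from .scan_io import SurfaceMesh

__all__ = [
    "SelectionError",
    "GeometryError",
    "FistulaRegion",
    "DesignFrame",
    "FistulaContour",
    "WoundMeasurements",
    "read_lasso",
    "select_fistula_region",
    "fit_design_frame",
    "extract_contour",
    "extrude_fistula",
    "measure_wound",
]


class SelectionError(ValueError):
    """A lasso selected nothing, or was not a usable closed curve."""


class GeometryError(ValueError):
    """Derived geometry is degenerate or self-intersecting."""


def read_lasso(path: str | Path) -> np.ndarray:
    """Read a lasso polyline: whitespace-separated x y z per line, '#' comments."""
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            rows.append([float(v) for v in s.split()[:3]])
    pts = np.asarray(rows, dtype=np.float64)
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise SelectionError(f"{path}: lasso needs at least 3 points")
    return pts


@dataclass(frozen=True)
class DesignFrame:
    """Right-handed orthonormal frame; z points outward from the wound bed."""

    origin: np.ndarray  # (3,)
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def to_local(self, points: np.ndarray) -> np.ndarray:
        basis = np.vstack([self.x_axis, self.y_axis, self.z_axis])
        return (np.atleast_2d(points) - self.origin) @ basis.T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        basis = np.vstack([self.x_axis, self.y_axis, self.z_axis])
        return np.atleast_2d(points) @ basis + self.origin


@dataclass
class FistulaRegion:
    """A connected set of mesh faces covering the exposed intestinal surface."""

    mesh: SurfaceMesh
    face_indices: np.ndarray  # (k,)
    boundary: np.ndarray  # ordered vertex-index loop

    @property
    def boundary_points(self) -> np.ndarray:
        return self.mesh.vertices[self.boundary]

    def area(self) -> float:
        tri = self.mesh.vertices[self.mesh.faces[self.face_indices]]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())


@dataclass
class FistulaContour:
    """Closed planar CCW polygon in a design frame's xy-plane (mm)."""

    points: np.ndarray  # (n, 2)
    frame: DesignFrame | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        poly = Polygon(pts)
        if not poly.is_valid:
            raise GeometryError("contour is self-intersecting; re-select the region")
        if poly.area <= 0:
            raise GeometryError("contour has zero area")
        self.points = ensure_ccw(pts)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    @property
    def perimeter(self) -> float:
        return float(self.polygon.length)

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])


@dataclass(frozen=True)
class WoundMeasurements:
    """Caliper-style wound dimensions in cm (rounded at reporting, not here)."""

    length_cm: float
    width_cm: float
    depth_cm: float
    fistula_orifice_heights_cm: tuple[float, ...]

    @property
    def n_orifices(self) -> int:
        return len(self.fistula_orifice_heights_cm)

    def as_dict(self) -> dict:
        return {
            "length_cm": round(self.length_cm, 1),
            "width_cm": round(self.width_cm, 1),
            "depth_cm": round(self.depth_cm, 1),
            "fistula_orifice_heights_cm": [round(v, 1) for v in self.fistula_orifice_heights_cm],
            "n_orifices": self.n_orifices,
        }


# ---------------------------------------------------------------------------
# plane fitting shared by lassos and boundary loops


def _fit_plane(points: np.ndarray, orient_hint: np.ndarray | None = None):
    """Least-squares plane: (centroid, unit normal, in-plane principal axes)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * (svals[0] + 1e-30):
        raise GeometryError("points are collinear; cannot fit a plane")
    normal = vt[2]
    if orient_hint is not None and np.dot(normal, orient_hint) < 0:
        normal = -normal
    x_axis = vt[0]
    y_axis = np.cross(normal, x_axis)
    return centroid, normal, x_axis, y_axis


def _project_to_plane(points: np.ndarray, centroid, x_axis, y_axis) -> np.ndarray:
    centered = np.atleast_2d(points) - centroid
    return np.stack([centered @ x_axis, centered @ y_axis], axis=1)


# ---------------------------------------------------------------------------
# region selection


def _boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex loops of the boundary edges of a face subset."""
    edges = np.sort(
        np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    border = uniq[counts == 1]
    if len(border) == 0:
        return []
    nxt: dict[int, list[int]] = {}
    for a, b in border:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    unused = {tuple(e) for e in border.tolist()}
    loops = []
    while unused:
        a, b = next(iter(unused))
        unused.discard((a, b))
        loop = [a, b]
        while True:
            cur, prev = loop[-1], loop[-2]
            cands = [v for v in nxt[cur] if v != prev and tuple(sorted((cur, v))) in unused]
            if not cands:
                break
            v = cands[0]
            unused.discard(tuple(sorted((cur, v))))
            if v == loop[0]:
                break
            loop.append(v)
        loops.append(np.array(loop, dtype=np.int64))
    loops.sort(key=len, reverse=True)
    return loops


def select_fistula_region(mesh: SurfaceMesh, lasso: np.ndarray) -> FistulaRegion:
    """Select the faces whose centroids fall inside a closed 3D lasso.

    The lasso and face centroids are projected onto the lasso's best-fit
    plane; the inside test is 2D (no geodesics). If the selection splits
    into several edge-connected components the largest is kept and a
    warning is emitted.
    """
    lasso = np.asarray(lasso, dtype=np.float64)
    centroid, normal, xa, ya = _fit_plane(lasso)
    loop2 = _project_to_plane(lasso, centroid, xa, ya)
    poly = Polygon(loop2)
    if not poly.is_valid or poly.area <= 0:
        raise SelectionError("lasso does not project to a simple closed curve")

    fc = mesh.vertices[mesh.faces].mean(axis=1)
    fc2 = _project_to_plane(fc, centroid, xa, ya)
    inside = shapely.contains_xy(poly, fc2[:, 0], fc2[:, 1])
    sel = np.nonzero(inside)[0]
    if len(sel) == 0:
        raise SelectionError("lasso selects no faces on the mesh")

    # keep the largest edge-connected component of the selected faces
    sub = mesh.faces[sel]
    edges = np.sort(np.vstack([sub[:, [0, 1]], sub[:, [1, 2]], sub[:, [2, 0]]]), axis=1)
    owner = np.tile(np.arange(len(sel)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges_sorted, owner_sorted = edges[order], owner[order]
    same = np.all(edges_sorted[1:] == edges_sorted[:-1], axis=1)
    pairs_a, pairs_b = owner_sorted[:-1][same], owner_sorted[1:][same]
    adj = coo_matrix(
        (np.ones(len(pairs_a)), (pairs_a, pairs_b)), shape=(len(sel), len(sel))
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        keep = labels == sizes.argmax()
        warnings.warn(
            f"selection has {n_comp} components; keeping the largest "
            f"({sizes.max()} of {len(sel)} faces)",
            stacklevel=2,
        )
        sel = sel[keep]

    loops = _boundary_loops(mesh.faces[sel])
    if not loops:
        raise SelectionError("selected region has no boundary loop")
    return FistulaRegion(mesh=mesh, face_indices=sel, boundary=loops[0])


def fit_design_frame(region: FistulaRegion) -> DesignFrame:
    """Design frame of a fistula region: least-squares plane of its boundary.

    The z-axis is the plane normal oriented to agree with the mean face
    normal of the region (outward from the wound bed); the origin is the
    boundary centroid; x/y are the boundary's in-plane principal directions.
    """
    pts = region.boundary_points
    if len(pts) < 3:
        raise GeometryError("boundary has fewer than 3 vertices")
    tri = region.mesh.vertices[region.mesh.faces[region.face_indices]]
    face_n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]).sum(axis=0)
    centroid, normal, xa, ya = _fit_plane(pts, orient_hint=face_n)
    ya = np.cross(normal, xa)
    return DesignFrame(origin=centroid, x_axis=xa, y_axis=ya, z_axis=normal)


def extract_contour(
    region: FistulaRegion, frame: DesignFrame, n_samples: int = 256, smooth_window: int = 5
) -> FistulaContour:
    """Project the region boundary into the frame xy-plane and resample it.

    Output has ``n_samples`` points at uniform arc length, counter-clockwise.
    A short cyclic moving average (``smooth_window`` samples) removes the
    mesh-grid zigzag that face-boundary loops carry; at 5 of 256 samples it
    perturbs a smooth contour's area by about 0.1%.
    """
    loop2 = frame.to_local(region.boundary_points)[:, :2]
    if not Polygon(loop2).is_valid:
        raise GeometryError("projected boundary self-intersects; re-select the region")
    loop2 = smooth_closed(resample_closed(ensure_ccw(loop2), n_samples), smooth_window)
    return FistulaContour(loop2, frame=frame)


def extrude_fistula(contour: FistulaContour, z_min: float, z_max: float) -> SurfaceMesh:
    """Extrude the fistula contour into a watertight prism over [z_min, z_max].

    This is the solid subtracted from the lofted adapter body to open the
    through-hole; it is also useful on its own for visual checks.
    """
    from ._geometry import ear_clip, strip_between_loops
    from .scan_io import MeshKind

    if z_max <= z_min:
        raise GeometryError("extrusion needs z_max > z_min")
    loop = contour.points
    n = len(loop)
    bottom = np.column_stack([loop, np.full(n, float(z_min))])
    top = np.column_stack([loop, np.full(n, float(z_max))])
    vertices = np.vstack([bottom, top])
    wall = strip_between_loops(n, 0, n)
    cap_tris = ear_clip(loop)
    bottom_cap = cap_tris[:, ::-1]  # normal -z
    top_cap = cap_tris + n  # normal +z
    faces = np.vstack([wall, bottom_cap, top_cap])
    return SurfaceMesh(vertices, faces, kind=MeshKind.closed_solid)


# ---------------------------------------------------------------------------
# morphometry


def measure_wound(
    mesh: SurfaceMesh,
    wound_lasso: np.ndarray,
    fistula_regions: list[FistulaRegion] | None = None,
    depth_percentile: float = 5.0,
    swap_axes: bool = False,
) -> WoundMeasurements:
    """Caliper-style wound measurements, reported in cm.

    length/width
        extents of the wound rim lasso along its two in-plane principal
        axes (length is the larger unless ``swap_axes``).
    depth
        distance from the rim's best-fit plane down to the wound bed,
        taken as the ``depth_percentile``-th percentile of the signed
        surface heights inside the rim (robust to mesh noise).
    orifice heights
        per fistula region, the stoma rim plane level minus the wound-bed
        level, along the rim-plane normal.
    """
    lasso = np.asarray(wound_lasso, dtype=np.float64)
    if len(lasso) < 3:
        raise SelectionError("wound lasso needs at least 3 points")
    centroid, normal, xa, ya = _fit_plane(lasso)
    # outward = away from the wound bed: most mesh vertices sit at/below rim level
    heights_all = (mesh.vertices - centroid) @ normal
    if np.mean(heights_all) > 0:
        normal, ya = -normal, -ya
    loop2 = _project_to_plane(lasso, centroid, xa, ya)
    poly = Polygon(loop2)
    if not poly.is_valid or poly.area <= 0:
        raise SelectionError("wound lasso does not close into a simple curve")

    # principal axes of the rim loop (resampled so vertex density can't bias them)
    dense = resample_closed(loop2, 512)
    dense -= dense.mean(axis=0)
    _, _, vt = np.linalg.svd(dense, full_matrices=False)
    proj = dense @ vt.T
    ext = proj.max(axis=0) - proj.min(axis=0)
    length_mm, width_mm = float(max(ext)), float(min(ext))
    if swap_axes:
        length_mm, width_mm = width_mm, length_mm

    verts2 = _project_to_plane(mesh.vertices, centroid, xa, ya)
    inside = shapely.contains_xy(poly, verts2[:, 0], verts2[:, 1])
    heights = (mesh.vertices - centroid) @ normal
    if inside.any():
        bed_level = float(np.percentile(heights[inside], depth_percentile))
    else:
        bed_level = 0.0
    depth_mm = max(0.0, -bed_level)

    # stoma rim plane: the top plateau of the raised stoma, taken as a high
    # quantile of the region's vertex heights (the selection boundary itself
    # lies on the wound bed, so it cannot serve as the rim level)
    orifices = []
    for region in fistula_regions or []:
        vids = np.unique(region.mesh.faces[region.face_indices])
        region_h = (region.mesh.vertices[vids] - centroid) @ normal
        rim_level = float(np.percentile(region_h, 100.0 - depth_percentile))
        orifices.append(max(0.0, (rim_level - bed_level) / 10.0))

    return WoundMeasurements(
        length_cm=length_mm / 10.0,
        width_cm=width_mm / 10.0,
        depth_cm=depth_mm / 10.0,
        fistula_orifice_heights_cm=tuple(orifices),
    )
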