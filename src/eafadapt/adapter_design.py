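"""Parametric design of the personalized fistula adapter ring.

The adapter is a hollow, ring-like solid that lets the exteriorized
intestinal surface pass through its central hole while its flanged outer
wall interfaces with the NPWT sponge and sealing film. It is built from
the fistula contour in four steps:

1. three planar sketches — outward offsets of the fistula contour — at
   z = 0 (bottom, small offset so the sponge reaches close to the hole),
   z = f*h (middle, keeps the body narrow for the conical morphology the
   vacuum dressing needs), and z = h (top brim, large offset, optionally
   shifted off-axis when the fistula sits near the adipose wall);
2. a loft (ruled skin plus caps) through the three sketches;
3. subtraction of the fistula prism, opening the through-hole. Because
   the hole is a straight extrusion strictly inside every cross-section,
   the ring is assembled analytically (outer wall + inner wall + annular
   caps) instead of via general mesh CSG — watertight by construction;
4. a ledge/dimension report in cm, matching clinical table precision.

All dimensions in mm unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from ._geometry import align_loop_start, ear_clip, ensure_ccw, resample_closed, strip_between_loops
from .scan_io import MeshKind, SurfaceMesh
from .wound_model import DesignFrame, FistulaContour, FistulaRegion, GeometryError

__all__ = [
    "DesignInfeasible",
    "AdapterSpec",
    "PlaneSketch",
    "AdapterSolid",
    "LedgeReport",
    "FitReport",
    "offset_contour",
    "resolve_middle_fraction",
    "build_sketches",
    "loft_solid",
    "subtract_hole",
    "build_adapter",
    "ledge_report",
    "fit_check",
    "format_range_cm",
]

#: Points per contour ring after resampling.
N_RING = 256


class DesignInfeasible(ValueError):
    """The requested parameters cannot produce a valid ring (e.g. the hole
    would breach a wall); carries the violating margin in mm when known."""

    def __init__(self, message: str, margin: float | None = None):
        super().__init__(message)
        self.margin = margin


@dataclass(frozen=True)
class AdapterSpec:
    """Design parameters of the adapter.

    height
        device height h in mm; the clinical range is 10-20 mm depending on
        the depth of the wound (adipose-tissue height and stoma height).
    bottom_offset / top_offset
        outward offsets of the bottom and top sketches from the fistula
        contour: 5 mm at the bottom (larger granulation area in contact
        with the sponge) and up to 20 mm at the top (brim that carries the
        polyurethane sealing film).
    middle_fraction
        height fraction of the middle sketch, in [0.15, 0.25], or None for
        the height-dependent rule (lower devices place it higher).
    middle_offset
        outward offset of the middle sketch; defaults to bottom_offset,
        keeping the body narrow below the brim.
    eccentricity
        xy shift of the top sketch, used when the fistula lies close to
        the adipose wall and the brim must be steered away from it.
    hole_clearance
        extra outward offset of the through-hole beyond the fistula
        contour (0 = hole matches the intestinal surface exactly).
    """

    height: float = 15.0
    bottom_offset: float = 5.0
    top_offset: float = 15.0
    middle_fraction: float | None = None
    middle_offset: float | None = None
    eccentricity: tuple[float, float] = (0.0, 0.0)
    hole_clearance: float = 0.0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.bottom_offset <= 0 or self.top_offset <= 0:
            raise ValueError("offsets must be positive")
        if self.top_offset > 20.0 + 1e-9:
            raise ValueError("top_offset exceeds the 20 mm brim limit")
        if self.middle_fraction is not None and not 0 < self.middle_fraction < 1:
            raise ValueError("middle_fraction must lie in (0, 1)")
        if self.hole_clearance < 0 or self.hole_clearance > 1.0 + 1e-9:
            raise ValueError("hole_clearance must lie in [0, 1] mm")

    @property
    def resolved_middle_offset(self) -> float:
        return self.bottom_offset if self.middle_offset is None else self.middle_offset

    def resolved_middle_fraction(self) -> float:
        if self.middle_fraction is not None:
            return self.middle_fraction
        return resolve_middle_fraction(self.height)


@dataclass
class PlaneSketch:
    """Closed CCW contour at height z."""

    z: float
    contour: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.contour, dtype=np.float64).reshape(-1, 2)
        if not Polygon(pts).is_valid:
            raise GeometryError("sketch contour is not a simple polygon")
        self.contour = ensure_ccw(pts)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.contour)


@dataclass
class AdapterSolid:
    """The watertight through-hole ring plus the inputs that produced it."""

    mesh: SurfaceMesh
    spec: AdapterSpec
    hole: FistulaContour
    sketches: tuple[PlaneSketch, PlaneSketch, PlaneSketch]
    provenance: str = ""

    def volume(self) -> float:
        return self.mesh.volume()


@dataclass(frozen=True)
class LedgeReport:
    """Ledge widths and bounding dimensions in cm (0.1 cm precision)."""

    top_ledge_cm: tuple[float, float]
    bottom_ledge_cm: tuple[float, float]
    height_cm: float
    width_cm: float
    length_cm: float

    def as_dict(self) -> dict:
        return {
            "height_cm": self.height_cm,
            "width_cm": self.width_cm,
            "length_cm": self.length_cm,
            "top_ledge": format_range_cm(*self.top_ledge_cm),
            "bottom_ledge": format_range_cm(*self.bottom_ledge_cm),
        }


@dataclass(frozen=True)
class FitReport:
    max_penetration_mm: float
    min_clearance_to_rim_mm: float
    hole_contains_fistula: bool


def format_range_cm(lo: float, hi: float) -> str:
    """Render a ledge range as ``a–b`` cm, collapsing equal endpoints to ``a``."""

    def fmt(v: float) -> str:
        s = f"{v:.1f}"
        return s.rstrip("0").rstrip(".") if "." in s else s

    return fmt(lo) if fmt(lo) == fmt(hi) else f"{fmt(lo)}–{fmt(hi)}"


# ---------------------------------------------------------------------------
# sketch construction


def offset_contour(contour: FistulaContour, d: float, n_samples: int = N_RING) -> FistulaContour:
    """Outward offset of the contour by ``d`` mm with round joins.

    ``d = 0`` returns the contour unchanged (resampled). If cleanup after
    self-intersection removal leaves several components, the largest is kept.
    """
    if d < 0:
        raise ValueError("offset distance must be >= 0")
    if d == 0:
        return FistulaContour(resample_closed(contour.points, n_samples), frame=contour.frame)
    buffered = contour.polygon.buffer(d, quad_segs=32, join_style="round")
    if buffered.geom_type == "MultiPolygon":
        buffered = max(buffered.geoms, key=lambda g: g.area)
    ring = np.asarray(buffered.exterior.coords)[:-1]
    return FistulaContour(resample_closed(ensure_ccw(ring), n_samples), frame=contour.frame)


def resolve_middle_fraction(h: float) -> float:
    """Height fraction of the middle sketch: the lower the device, the higher
    the fraction — 0.25 at h <= 10 mm, 0.15 at h >= 20 mm, linear between."""
    if h <= 0:
        raise ValueError("height must be positive")
    if h <= 10.0:
        return 0.25
    if h >= 20.0:
        return 0.15
    return 0.25 - 0.10 * (h - 10.0) / 10.0


def _containment_margin(outer: Polygon, hole: Polygon) -> float:
    """Positive clearance (mm) if hole is strictly inside outer, else negative
    by the worst protrusion."""
    if shapely.contains_properly(outer, hole):
        return float(hole.exterior.distance(outer.exterior))
    protruding = hole.difference(outer)
    if protruding.is_empty:
        return 0.0
    return -float(protruding.hausdorff_distance(outer))


def build_sketches(
    contour: FistulaContour, spec: AdapterSpec
) -> tuple[tuple[PlaneSketch, PlaneSketch, PlaneSketch], FistulaContour]:
    """The three design sketches plus the hole contour.

    Bottom sketch at z=0 (offset ``bottom_offset``), middle at z=f*h
    (offset ``middle_offset``), top at z=h (offset ``top_offset``,
    translated by the eccentricity). Every sketch must strictly contain
    the hole contour (fistula contour offset by the clearance), otherwise
    :class:`DesignInfeasible` is raised with the violating margin.
    """
    h = spec.height
    f = spec.resolved_middle_fraction()
    hole = offset_contour(contour, spec.hole_clearance) if spec.hole_clearance > 0 else (
        FistulaContour(resample_closed(contour.points, N_RING), frame=contour.frame)
    )
    bottom = PlaneSketch(0.0, offset_contour(contour, spec.bottom_offset).points)
    middle = PlaneSketch(f * h, offset_contour(contour, spec.resolved_middle_offset).points)
    top_pts = offset_contour(contour, spec.top_offset).points + np.asarray(spec.eccentricity)
    top = PlaneSketch(h, top_pts)

    hole_poly = hole.polygon
    for name, sk in (("bottom", bottom), ("middle", middle), ("top", top)):
        margin = _containment_margin(sk.polygon, hole_poly)
        if margin <= 1e-9:
            raise DesignInfeasible(
                f"{name} sketch does not strictly contain the hole contour "
                f"(margin {margin:.3f} mm)",
                margin=margin,
            )
    return (bottom, middle, top), hole


# ---------------------------------------------------------------------------
# solid construction


def loft_solid(sketches: tuple[PlaneSketch, PlaneSketch, PlaneSketch]) -> SurfaceMesh:
    """Loft a watertight genus-0 solid through three stacked sketches.

    Contours are resampled to ``N_RING`` points at uniform arc length;
    ring correspondence is by arc length with the cyclic start index of
    each upper ring chosen to minimize twist against the ring below
    (lowest shift wins ties). The surface is ruled between consecutive
    rings and closed by planar caps.
    """
    zs = [sk.z for sk in sketches]
    if not (zs[0] < zs[1] < zs[2]):
        raise GeometryError("sketch planes must be strictly increasing in z")
    rings2 = [resample_closed(ensure_ccw(sk.contour), N_RING) for sk in sketches]
    rings2[1] = align_loop_start(rings2[0], rings2[1])
    rings2[2] = align_loop_start(rings2[1], rings2[2])
    n = N_RING
    vertices = np.vstack(
        [np.column_stack([r, np.full(n, z)]) for r, z in zip(rings2, zs)]
    )
    faces = [strip_between_loops(n, 0, n), strip_between_loops(n, n, 2 * n)]
    bottom_cap = ear_clip(rings2[0])[:, ::-1]  # -z normal
    top_cap = ear_clip(rings2[2]) + 2 * n  # +z normal
    faces.extend([bottom_cap, top_cap])
    mesh = SurfaceMesh(vertices, np.vstack(faces), kind=MeshKind.closed_solid)
    if mesh.volume() < 0:
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1], kind=MeshKind.closed_solid)
    return mesh


def subtract_hole(loft: SurfaceMesh, hole_contour: FistulaContour, h: float) -> SurfaceMesh:
    """Open the through-hole: ring solid = outer loft wall + inner prism wall
    + annular caps.

    ``loft`` must come from :func:`loft_solid` (its first 3 * N_RING
    vertices are the three rings). The hole contour must lie strictly
    inside every cross-section — guaranteed when the sketches came from
    :func:`build_sketches`.
    """
    n = N_RING
    if loft.n_vertices != 3 * n:
        raise GeometryError("loft mesh was not produced by loft_solid")
    rings = [loft.vertices[i * n : (i + 1) * n] for i in range(3)]
    hole2 = align_loop_start(rings[0][:, :2], resample_closed(ensure_ccw(hole_contour.points), n))

    hole_poly = Polygon(hole2)
    for ring in rings:
        if not shapely.contains_properly(Polygon(ring[:, :2]), hole_poly):
            raise DesignInfeasible("hole contour breaches a loft cross-section")

    z0, zh = float(rings[0][0, 2]), float(rings[2][0, 2])
    if abs(zh - z0 - h) > 1e-6:
        raise GeometryError(f"loft height {zh - z0:.3f} does not match h={h}")

    hole_bottom = np.column_stack([hole2, np.full(n, z0)])
    hole_top = np.column_stack([hole2, np.full(n, zh)])
    vertices = np.vstack(rings + [hole_bottom, hole_top])
    faces = np.vstack(
        [
            strip_between_loops(n, 0, n),  # outer wall, bottom->middle
            strip_between_loops(n, n, 2 * n),  # outer wall, middle->top
            strip_between_loops(n, 3 * n, 4 * n, flip=True),  # inner wall (into hole)
            strip_between_loops(n, 0, 3 * n, flip=True),  # bottom annulus, -z
            strip_between_loops(n, 2 * n, 4 * n),  # top annulus, +z
        ]
    )
    mesh = SurfaceMesh(vertices, faces, kind=MeshKind.closed_solid)
    if mesh.volume() < 0:
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1], kind=MeshKind.closed_solid)
    return mesh


def build_adapter(
    contour: FistulaContour, spec: AdapterSpec, provenance: str = ""
) -> AdapterSolid:
    """Full chain: sketches -> loft -> hole subtraction -> AdapterSolid."""
    sketches, hole = build_sketches(contour, spec)
    loft = loft_solid(sketches)
    ring = subtract_hole(loft, hole, spec.height)
    return AdapterSolid(mesh=ring, spec=spec, hole=hole, sketches=sketches, provenance=provenance)


# ---------------------------------------------------------------------------
# reporting and fit checking


def _round_half_up_cm(v_mm: float) -> float:
    """mm -> cm at 0.1 cm precision, ties away from zero (clinical rounding)."""
    return float(np.floor(v_mm / 10.0 * 10.0 + 0.5) / 10.0)


def _ledge_range(hole_pts: np.ndarray, outer_pts: np.ndarray) -> tuple[float, float]:
    """Min/max radial wall width (mm) from hole contour to outer contour."""
    outer = shapely.LinearRing(outer_pts)
    d = np.array([Point(p).distance(outer) for p in hole_pts])
    return float(d.min()), float(d.max())


def ledge_report(adapter: AdapterSolid) -> LedgeReport:
    """Ledge (protrusion) widths at top and bottom planes, plus bounding
    dimensions, in cm at Table precision (0.1 cm, half-up)."""
    hole_pts = adapter.hole.points
    bottom, _, top = adapter.sketches
    b_lo, b_hi = _ledge_range(hole_pts, bottom.contour)
    t_lo, t_hi = _ledge_range(hole_pts, top.contour)
    v = adapter.mesh.vertices
    ext = v.max(axis=0) - v.min(axis=0)
    width_mm, length_mm = sorted(ext[:2])
    return LedgeReport(
        top_ledge_cm=(_round_half_up_cm(t_lo), _round_half_up_cm(t_hi)),
        bottom_ledge_cm=(_round_half_up_cm(b_lo), _round_half_up_cm(b_hi)),
        height_cm=_round_half_up_cm(ext[2]),
        width_cm=_round_half_up_cm(width_mm),
        length_cm=_round_half_up_cm(length_mm),
    )


def fit_check(
    adapter: AdapterSolid,
    wound: SurfaceMesh,
    frame: DesignFrame,
    fistula_region: FistulaRegion | None = None,
    pose_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
    rest_on_surface: bool = False,
    containment_tol: float = 0.5,
    n_samples: int = 2000,
    seed: int = 0,
) -> FitReport:
    """Pose the adapter in the wound's design frame and check the assembly.

    The adapter sits with its bottom plane (z=0) at the frame origin, hole
    axis along frame z, optionally displaced by ``pose_offset`` (frame
    coordinates, mm). Penetration is how far bottom-face sample points dip
    below the wound surface (surface height looked up by nearest vertex in
    the frame xy-plane); ``hole_contains_fistula`` asks whether every
    boundary point of the fistula region projects inside the hole contour
    (to within ``containment_tol`` mm — the hole may equal the fistula
    outline exactly, putting boundary points on the ring itself).

    With ``rest_on_surface`` the adapter is additionally lifted along
    frame z until its bottom face just touches the wound surface, the
    pose a clinician gives it; penetration is then zero by construction
    and the report verifies the assembly is achievable.
    """
    rng = np.random.default_rng(seed)
    offset = np.asarray(pose_offset, dtype=np.float64)

    # sample the bottom annulus between hole and bottom sketch contours
    hole_pts = adapter.hole.points
    outer_pts = adapter.sketches[0].contour
    t = rng.random((n_samples, 1))
    idx = rng.integers(0, len(hole_pts), n_samples)
    samples2 = hole_pts[idx] * (1 - t) + outer_pts[idx % len(outer_pts)] * t
    samples_local = np.column_stack([samples2, np.zeros(n_samples)]) + offset

    wound_local = frame.to_local(wound.vertices)
    tree = cKDTree(wound_local[:, :2])
    _, nearest = tree.query(samples_local[:, :2])
    wound_z = wound_local[nearest, 2]
    if rest_on_surface:
        lift = float(np.max(wound_z - samples_local[:, 2]))
        offset = offset + np.array([0.0, 0.0, lift])
        samples_local[:, 2] += lift
    penetration = np.maximum(0.0, wound_z - samples_local[:, 2])
    max_pen = float(penetration.max()) if n_samples else 0.0

    hole_poly = Polygon(hole_pts + offset[:2]).buffer(containment_tol)
    contains = True
    clearance = float("nan")
    if fistula_region is not None:
        # the raw boundary loop zigzags at mesh-grid scale; test the same
        # smoothed outline the contour-extraction step measures
        fb = frame.to_local(fistula_region.boundary_points)[:, :2]
        from ._geometry import smooth_closed

        fb = smooth_closed(resample_closed(fb, len(hole_pts)))
        inside = shapely.contains_xy(hole_poly, fb[:, 0], fb[:, 1])
        contains = bool(inside.all())
        ring = shapely.LinearRing(hole_pts + offset[:2])
        dists = np.array([Point(p).distance(ring) for p in fb])
        clearance = float(dists.min()) if contains else -float(dists[~inside].max())
    return FitReport(
        max_penetration_mm=max_pen,
        min_clearance_to_rim_mm=clearance,
        hole_contains_fistula=contains,
    )
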