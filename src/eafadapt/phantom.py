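"""Synthetic abdominal-wound scans with analytic ground truth.

A phantom emulates what a structured-light scanner sees over an open
abdominal wound: a roughly planar skin patch, a crater-shaped wound
depression with soft (adipose) walls, and one or more raised fistula
stomas — the exteriorized intestinal endings — standing up from the wound
bed. The surface is an analytic height field

    z(x, y) = -depth * crater(x, y) + sum_k height_k * stoma_k(x, y)

with the skin plane at z = 0. The crater profile has a flat bed and a
C^1 cosine taper up to the elliptical wound rim, so "wound depth" has a
single unambiguous truth value; each stoma is a plateau-topped bump so
"orifice height" (stoma top above the wound bed) is likewise unambiguous.

Scanner noise is Gaussian along the local surface normal with a default
sigma of 0.2 mm, the middle of the 0.1-0.3 mm resolution band of white
light scanners; the default target of 500,000 points matches the order of
magnitude of clinical wound meshes and sits above the 400,000-point QC
gate. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scan_io import CaptureStage, PointCloud

__all__ = ["StomaSpec", "PhantomSpec", "PhantomTruth", "generate_phantom", "truth_contour"]

#: Fraction of the crater (and stoma) radius that is flat bed / plateau.
FLAT_FRACTION = 0.6


@dataclass(frozen=True)
class StomaSpec:
    """One raised fistula stoma: 2D center (mm), base radius (mm), height above bed (mm)."""

    center: tuple[float, float]
    base_radius: float
    height: float


@dataclass(frozen=True)
class PhantomSpec:
    patch_size: tuple[float, float] = (160.0, 120.0)  # mm
    wound_semi_axes: tuple[float, float] = (60.0, 40.0)  # mm
    wound_depth: float = 20.0  # mm
    stomas: tuple[StomaSpec, ...] = (StomaSpec((0.0, 0.0), 12.0, 15.0),)
    noise_sigma: float = 0.2  # mm, scanner band 0.1-0.3
    dropout: float = 0.0
    n_points: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wound_depth <= 0:
            raise ValueError("wound_depth must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        a, b = self.wound_semi_axes
        for s in self.stomas:
            cx, cy = s.center
            # stoma (including its base) must sit inside the wound ellipse
            rho = np.hypot(cx / a, cy / b)
            margin = s.base_radius / min(a, b)
            if rho + margin > 1.0:
                raise ValueError(f"stoma at {s.center} extends outside the wound ellipse")


def _taper(rho: np.ndarray) -> np.ndarray:
    """1 on the flat core, cosine falloff to 0 at rho=1, 0 outside; C^1 everywhere."""
    t = np.clip((rho - FLAT_FRACTION) / (1.0 - FLAT_FRACTION), 0.0, 1.0)
    out = 0.5 * (1.0 + np.cos(np.pi * t))
    return np.where(rho >= 1.0, 0.0, out)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth the analysis pipeline is asked to recover."""

    spec: PhantomSpec
    length_cm: float  # 2a / 10
    width_cm: float  # 2b / 10
    depth_cm: float
    stoma_heights_cm: tuple[float, ...]

    def surface(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Noise-free height field z(x, y) in mm."""
        a, b = self.spec.wound_semi_axes
        rho = np.hypot(np.asarray(x) / a, np.asarray(y) / b)
        z = -self.spec.wound_depth * _taper(rho)
        for s in self.spec.stomas:
            r = np.hypot(np.asarray(x) - s.center[0], np.asarray(y) - s.center[1])
            z = z + s.height * _taper(r / s.base_radius)
        return z

    def normal(self, x: np.ndarray, y: np.ndarray, h: float = 1e-4) -> np.ndarray:
        """Unit outward (+z side) surface normal, central differences."""
        gx = (self.surface(x + h, y) - self.surface(x - h, y)) / (2 * h)
        gy = (self.surface(x, y + h) - self.surface(x, y - h)) / (2 * h)
        n = np.stack([-gx, -gy, np.ones_like(gx)], axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)

    def wound_rim_loop(self, n: int = 256) -> np.ndarray:
        """The elliptical wound rim at skin level, as a 3D loop (lasso input)."""
        a, b = self.spec.wound_semi_axes
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.stack([a * np.cos(th), b * np.sin(th), np.zeros(n)], axis=1)

    def stoma_lasso(self, index: int, n: int = 128, margin: float = 1.15) -> np.ndarray:
        """A loop around stoma ``index`` (slightly outside its base), on the surface."""
        s = self.spec.stomas[index]
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x = s.center[0] + margin * s.base_radius * np.cos(th)
        y = s.center[1] + margin * s.base_radius * np.sin(th)
        return np.stack([x, y, self.surface(x, y)], axis=1)

    def stoma_plateau_radius(self, index: int) -> float:
        return FLAT_FRACTION * self.spec.stomas[index].base_radius


def generate_phantom(spec: PhantomSpec) -> tuple[PointCloud, PhantomTruth]:
    """Sample a scanner-like point cloud of the phantom surface.

    Points are uniform over the patch; noise is drawn along the true surface
    normal; dropout removes a random fraction. Deterministic given the seed.
    """
    truth = PhantomTruth(
        spec=spec,
        length_cm=2 * spec.wound_semi_axes[0] / 10.0,
        width_cm=2 * spec.wound_semi_axes[1] / 10.0,
        depth_cm=spec.wound_depth / 10.0,
        stoma_heights_cm=tuple(s.height / 10.0 for s in spec.stomas),
    )
    rng = np.random.default_rng(spec.seed)
    w, h = spec.patch_size
    n = spec.n_points
    x = rng.uniform(-w / 2, w / 2, n)
    y = rng.uniform(-h / 2, h / 2, n)
    z = truth.surface(x, y)
    pts = np.stack([x, y, z], axis=1)
    if spec.noise_sigma > 0:
        normals = truth.normal(x, y)
        pts = pts + normals * rng.normal(0.0, spec.noise_sigma, n)[:, None]
    if spec.dropout > 0:
        keep = rng.random(n) >= spec.dropout
        pts = pts[keep]
    cloud = PointCloud(pts, source_id=f"phantom-seed{spec.seed}", capture_stage=CaptureStage.first_scan)
    return cloud, truth


def truth_contour(truth: PhantomTruth, stoma_index: int, n: int = 256) -> np.ndarray:
    """Analytic base contour of a stoma as an (n, 2) CCW loop in the skin plane."""
    stomas = truth.spec.stomas
    if not 0 <= stoma_index < len(stomas):
        raise IndexError(f"stoma index {stoma_index} out of range (have {len(stomas)})")
    s = stomas[stoma_index]
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack(
        [s.center[0] + s.base_radius * np.cos(th), s.center[1] + s.base_radius * np.sin(th)],
        axis=1,
    )
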