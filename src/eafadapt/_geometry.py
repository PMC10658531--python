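"""Low-level polygon/loop helpers shared by the measurement and design modules.

Everything here operates on closed loops stored as (n, 2) or (n, 3) arrays
WITHOUT a repeated end point. Planar polygon caps are triangulated by ear
clipping (robust for the simple polygons this package produces); side walls
and annular caps between two equal-length loops are strip-triangulated.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "signed_area",
    "ensure_ccw",
    "resample_closed",
    "smooth_closed",
    "ear_clip",
    "strip_between_loops",
    "align_loop_start",
]


def signed_area(loop: np.ndarray) -> float:
    """Shoelace signed area of a closed 2D loop (positive = counter-clockwise)."""
    x, y = loop[:, 0], loop[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(loop: np.ndarray) -> np.ndarray:
    return loop[::-1].copy() if signed_area(loop) < 0 else loop


def resample_closed(loop: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` points at uniform arc length.

    The first output point coincides with the first input point, so cyclic
    alignment done before resampling survives it.
    """
    closed = np.vstack([loop, loop[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate loop with zero perimeter")
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, closed.shape[1]))
    for d in range(closed.shape[1]):
        out[:, d] = np.interp(targets, s, closed[:, d])
    return out


def smooth_closed(loop: np.ndarray, window: int = 5) -> np.ndarray:
    """Cyclic moving average over a closed loop; removes grid-scale zigzag."""
    if window <= 1:
        return loop
    kernel = np.ones(window) / window
    padded = np.vstack([loop[-(window // 2):], loop, loop[: window // 2]])
    return np.column_stack(
        [np.convolve(padded[:, d], kernel, mode="valid") for d in range(loop.shape[1])]
    )


def _point_in_triangle(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized strict-interior test for points ``p`` against triangle abc (CCW)."""
    def cross(o, d, q):
        return (d[0] - o[0]) * (q[:, 1] - o[1]) - (d[1] - o[1]) * (q[:, 0] - o[0])

    eps = -1e-12
    return (cross(a, b, p) > eps) & (cross(b, c, p) > eps) & (cross(c, a, p) > eps)


def ear_clip(loop: np.ndarray) -> np.ndarray:
    """Triangulate a simple CCW 2D polygon by ear clipping.

    Returns (m, 3) indices into ``loop``. O(n^2), fine for the few-hundred
    point contours used throughout.
    """
    loop = np.asarray(loop, dtype=np.float64)
    n = len(loop)
    if n < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if signed_area(loop) < 0:
        raise ValueError("ear_clip expects a counter-clockwise polygon")
    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 2 * n * n:
            raise RuntimeError("ear clipping failed to converge; polygon may be non-simple")
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = loop[i0], loop[i1], loop[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-14:  # reflex or collinear: not an ear
                continue
            others = np.array([j for j in idx if j not in (i0, i1, i2)])
            if len(others) and _point_in_triangle(loop[others], a, b, c).any():
                continue
            tris.append((i0, i1, i2))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            # numerical fallback: clip the most convex corner regardless
            best = max(
                range(m),
                key=lambda k: np.cross(
                    loop[idx[k]] - loop[idx[(k - 1) % m]],
                    loop[idx[(k + 1) % m]] - loop[idx[k]],
                ),
            )
            tris.append((idx[(best - 1) % m], idx[best], idx[(best + 1) % m]))
            idx.pop(best)
    tris.append((idx[0], idx[1], idx[2]))
    return np.array(tris, dtype=np.int64)


def strip_between_loops(n: int, offset_a: int, offset_b: int, flip: bool = False) -> np.ndarray:
    """Triangle strip between two aligned n-point loops.

    Loop A occupies vertex ids ``offset_a..offset_a+n-1``, loop B likewise.
    With both loops CCW viewed from +z and B above A, the default winding
    gives outward-pointing normals on a side wall; ``flip`` reverses it
    (used for inner walls and for caps wound the other way).
    """
    i = np.arange(n)
    j = (i + 1) % n
    a0, a1 = offset_a + i, offset_a + j
    b0, b1 = offset_b + i, offset_b + j
    t1 = np.stack([a0, a1, b1], axis=1)
    t2 = np.stack([a0, b1, b0], axis=1)
    faces = np.vstack([t1, t2])
    if flip:
        faces = faces[:, ::-1]
    return faces


def align_loop_start(reference: np.ndarray, loop: np.ndarray) -> np.ndarray:
    """Cyclically shift ``loop`` to minimize twist against ``reference``.

    Both loops must have the same length and orientation. The shift chosen
    minimizes the total squared distance between corresponding points
    (ties broken by the lowest shift index).
    """
    n = len(loop)
    if len(reference) != n:
        raise ValueError("loops must have equal point counts")
    ref2 = reference[:, :2]
    pts2 = loop[:, :2]
    # cost(s) = sum |pts[(i+s) % n] - ref[i]|^2; evaluate all shifts via FFT-free direct scan
    best_shift, best_cost = 0, np.inf
    for s in range(n):
        rolled = np.roll(pts2, -s, axis=0)
        cost = float(np.sum((rolled - ref2) ** 2))
        if cost < best_cost - 1e-12:
            best_cost, best_shift = cost, s
    return np.roll(loop, -best_shift, axis=0)
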