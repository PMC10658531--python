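"""Shared fixtures: canonical contours, a reusable phantom case, and the
independent voxelization volume oracle."""

from __future__ import annotations

import numpy as np
import pytest

from eafadapt import phantom, scan_io, wound_model


def circle_contour(r: float, n: int = 256, center=(0.0, 0.0)) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)], axis=1)


def random_smooth_contour(rng: np.random.Generator, r0: float = 10.0) -> np.ndarray:
    """Star-shaped smooth contour r(theta) = r0 (1 + small Fourier wobble)."""
    th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    r = np.full_like(th, 1.0)
    for k in range(2, 6):
        r += rng.uniform(-0.06, 0.06) * np.cos(k * th + rng.uniform(0, 2 * np.pi))
    r = r0 * r
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


def planar_polygon_region(loop2: np.ndarray, z: float = 0.0) -> wound_model.FistulaRegion:
    """A FistulaRegion covering an ear-clipped planar polygon at height z."""
    from eafadapt._geometry import ear_clip, ensure_ccw

    loop2 = ensure_ccw(np.asarray(loop2, dtype=np.float64))
    vertices = np.column_stack([loop2, np.full(len(loop2), z)])
    faces = ear_clip(loop2)
    mesh = scan_io.SurfaceMesh(vertices, faces)
    return wound_model.FistulaRegion(
        mesh=mesh,
        face_indices=np.arange(len(faces)),
        boundary=np.arange(len(loop2)),
    )


@pytest.fixture(scope="session")
def default_phantom():
    """One patient-like phantom: (cloud, truth), 500k points, sigma=0.2 mm."""
    return phantom.generate_phantom(phantom.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def phantom_mesh(default_phantom):
    cloud, _ = default_phantom
    return scan_io.reconstruct_surface(cloud, grid_pitch=1.0)


@pytest.fixture(scope="session")
def phantom_region(default_phantom, phantom_mesh):
    _, truth = default_phantom
    return wound_model.select_fistula_region(phantom_mesh, truth.stoma_lasso(0))


def voxel_volume(mesh: scan_io.SurfaceMesh, pitch: float = 0.25) -> float:
    """Voxel-column volume oracle, independent of the analytic construction.

    Rasterizes the xy-plane at the given pitch, casts a vertical line
    through every column center, collects its intersections with the mesh
    triangles, pairs them by parity, and accumulates the exact inside
    length per column (z is integrated exactly: the solids under test have
    flat caps grid-aligned in z, where counting voxel centers would bias
    systematically instead of averaging out). The grid is offset by an
    irrational fraction of the pitch so columns never hit triangle edges
    exactly.
    """
    v, f = mesh.vertices, mesh.faces
    lo, hi = v.min(axis=0), v.max(axis=0)
    off = pitch * (np.sqrt(2.0) - 1.0)  # irrational phase
    xs = np.arange(lo[0] - pitch, hi[0] + pitch, pitch) + off
    ys = np.arange(lo[1] - pitch, hi[1] + pitch, pitch) + off
    cols: list[np.ndarray] = []
    hits: list[np.ndarray] = []
    tri = v[f]
    for t in tri:
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = t
        i0 = np.searchsorted(xs, min(x0, x1, x2))
        i1 = np.searchsorted(xs, max(x0, x1, x2), side="right")
        j0 = np.searchsorted(ys, min(y0, y1, y2))
        j1 = np.searchsorted(ys, max(y0, y1, y2), side="right")
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        d = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        if abs(d) < 1e-12:
            continue
        w0 = ((y1 - y2) * (gx - x2) + (x2 - x1) * (gy - y2)) / d
        w1 = ((y2 - y0) * (gx - x2) + (x0 - x2) * (gy - y2)) / d
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        z = w0 * z0 + w1 * z1 + w2 * z2
        ii, jj = np.nonzero(inside)
        cols.append((i0 + ii) * len(ys) + (j0 + jj))
        hits.append(z[inside])
    col = np.concatenate(cols)
    z = np.concatenate(hits)
    order = np.lexsort((z, col))
    col, z = col[order], z[order]
    length = 0.0
    starts = np.flatnonzero(np.diff(col, prepend=col[0] - 1))
    bounds = np.append(starts, len(col))
    for a, b in zip(bounds[:-1], bounds[1:]):
        zz = z[a:b]
        if len(zz) % 2:  # grazing hit; drop the column
            continue
        length += float(np.sum(zz[1::2] - zz[0::2]))
    return length * pitch**2


@pytest.fixture(scope="session")
def voxel_volume_oracle():
    return voxel_volume
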