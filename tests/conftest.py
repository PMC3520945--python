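"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from tinrugosity.mesh import TriangleMesh


@pytest.fixture
def unit_square_mesh() -> TriangleMesh:
    """Flat unit square in the z=0 plane, two triangles."""
    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [0.0, 1.0, 0.0]]
    )
    triangles = np.array([[0, 1, 2], [0, 2, 3]])
    return TriangleMesh(vertices=vertices, triangles=triangles)


def grid_mesh(k: int = 5, spacing: float = 1.0, z_fn=None) -> TriangleMesh:
    """Regular k x k grid mesh with structured two-triangles-per-cell faces."""
    xs = np.arange(k) * spacing
    ee, nn = np.meshgrid(xs, xs, indexing="ij")
    e, n = ee.ravel(), nn.ravel()
    z = z_fn(e, n) if z_fn is not None else np.zeros_like(e)
    tris = []
    for i in range(k - 1):
        for j in range(k - 1):
            a = i * k + j
            b = (i + 1) * k + j
            tris.append([a, b, a + 1])
            tris.append([a + 1, b, b + 1])
    return TriangleMesh(
        vertices=np.column_stack([e, n, z]), triangles=np.array(tris)
    )


@pytest.fixture
def grid5() -> TriangleMesh:
    return grid_mesh(5, spacing=0.5)


def rotation_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation from QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def heron_area(a, b, c) -> float:
    """Independent triangle-area oracle: Heron's formula on side lengths."""
    la = np.linalg.norm(np.asarray(b) - np.asarray(a))
    lb = np.linalg.norm(np.asarray(c) - np.asarray(b))
    lc = np.linalg.norm(np.asarray(a) - np.asarray(c))
    s = 0.5 * (la + lb + lc)
    return float(np.sqrt(max(s * (s - la) * (s - lb) * (s - lc), 0.0)))


def rasterised_projected_area(mesh, triangle_indices, plane_normal,
                              n_cells: int = 1500) -> float:
    """Brute-force projected-area oracle: rasterise and count covered cells.

    Projects the member triangles into the plane's own 2D frame, lays a
    fine raster over their bounding box and counts cells whose centre is
    covered by at least one triangle (a union, so valid only when no two
    triangles overlap in projection).
    """
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    # orthonormal in-plane frame
    seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, seed)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    corners = mesh.vertices[mesh.triangles[triangle_indices]]
    p2 = np.stack([corners @ u, corners @ v], axis=-1)  # (m, 3, 2)
    lo = p2.reshape(-1, 2).min(axis=0)
    hi = p2.reshape(-1, 2).max(axis=0)
    cell = float(np.max(hi - lo)) / n_cells
    nx = int(np.ceil((hi[0] - lo[0]) / cell)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / cell)) + 1
    covered = np.zeros((nx, ny), dtype=bool)
    xs = lo[0] + (np.arange(nx) + 0.5) * cell
    ys = lo[1] + (np.arange(ny) + 0.5) * cell
    for tri in p2:
        i0 = max(int((tri[:, 0].min() - lo[0]) / cell) - 1, 0)
        i1 = min(int((tri[:, 0].max() - lo[0]) / cell) + 2, nx)
        j0 = max(int((tri[:, 1].min() - lo[1]) / cell) - 1, 0)
        j1 = min(int((tri[:, 1].max() - lo[1]) / cell) + 2, ny)
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        covered[i0:i1, j0:j1] |= _in_triangle(pts, tri).reshape(gx.shape)
    return float(covered.sum()) * cell * cell


def _in_triangle(pts: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric point-in-triangle test (inclusive of edges)."""
    a, b, c = tri
    v0, v1 = b - a, c - a
    v2 = pts - a
    den = v0[0] * v1[1] - v1[0] * v0[1]
    if abs(den) < 1e-300:
        return np.zeros(len(pts), dtype=bool)
    wa = (v2[:, 0] * v1[1] - v1[0] * v2[:, 1]) / den
    wb = (v0[0] * v2[:, 1] - v2[:, 0] * v0[1]) / den
    return (wa >= -1e-12) & (wb >= -1e-12) & (wa + wb <= 1 + 1e-12)
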