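"""Exact geometric queries on triangle meshes.

Self-contained kernels used throughout the package: exact closest-point
queries (KD-tree pruned but provably exact), vectorized Moller-Trumbore
ray casting, generalized-winding-number containment, and small rotation
helpers. All coordinates are in mm.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "closest_point_on_triangles",
    "MeshQuery",
    "ray_mesh_intersections",
    "winding_number",
    "points_inside",
    "rotation_about_axis",
    "random_rotation",
    "orthonormal_basis",
]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray):
    """Closest point on each triangle to each query point (paired, vectorized).

    Parameters
    ----------
    points : (n, 3) float array
    triangles : (n, 3, 3) float array, triangle vertices paired with ``points``

    Returns
    -------
    closest : (n, 3) array of closest points
    dist : (n,) array of Euclidean distances
    """
    # Ericson, "Real-Time Collision Detection", 5.1.5, vectorized.
    p = np.asarray(points, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    mask = (d1 <= 0) & (d2 <= 0)
    out[mask] = a[mask]
    done |= mask
    mask = (~done) & (d3 >= 0) & (d4 <= d3)
    out[mask] = b[mask]
    done |= mask
    mask = (~done) & (d6 >= 0) & (d5 <= d6)
    out[mask] = c[mask]
    done |= mask

    # edge AB
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    mask = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out[mask] = a[mask] + v_ab[mask, None] * ab[mask]
    done |= mask

    # edge AC
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = d2 / (d2 - d6)
    mask = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out[mask] = a[mask] + w_ac[mask, None] * ac[mask]
    done |= mask

    # edge BC
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    mask = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out[mask] = b[mask] + w_bc[mask, None] * (c[mask] - b[mask])
    done |= mask

    # interior
    mask = ~done
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = vb / denom
        w = vc / denom
    # degenerate triangles (zero area): fall back to vertex a
    bad = mask & ~np.isfinite(v + w)
    out[bad] = a[bad]
    good = mask & ~bad
    out[good] = a[good] + v[good, None] * ab[good] + w[good, None] * ac[good]

    dist = np.linalg.norm(p - out, axis=1)
    return out, dist


class MeshQuery:
    """Exact nearest-point queries against a fixed triangle soup.

    A KD-tree on triangle centroids prunes candidates; the pruning radius
    accounts for the maximum centroid-to-vertex distance, so the returned
    point is the true global minimizer over all triangles. Equidistant ties
    resolve to the lowest triangle index.
    """

    def __init__(self, triangles: np.ndarray):
        self.triangles = np.asarray(triangles, dtype=float)
        if self.triangles.ndim != 3 or self.triangles.shape[1:] != (3, 3):
            raise ValueError("triangles must have shape (m, 3, 3)")
        self.centroids = self.triangles.mean(axis=1)
        self._radii = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self._rmax = float(self._radii.max()) if len(self._radii) else 0.0
        self._tree = cKDTree(self.centroids)

    def closest(self, points: np.ndarray):
        """Return (closest_points, distances, triangle_indices) for queries.

        Exact: d(p, T) >= d(p, centroid_T) - r_T, so scanning every triangle
        whose centroid lies within (upper bound + r_max) cannot miss the
        global minimizer.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        m = len(self.triangles)
        k = min(8, m)
        _, knn = self._tree.query(pts, k=k)
        knn = np.atleast_2d(knn.reshape(n, k))
        # exact distance to the k nearest-centroid triangles -> upper bound
        flat_tri = knn.ravel()
        _, d_knn = closest_point_on_triangles(
            np.repeat(pts, k, axis=0), self.triangles[flat_tri]
        )
        upper = d_knn.reshape(n, k).min(axis=1)

        lists = self._tree.query_ball_point(pts, upper + self._rmax + 1e-9)
        counts = np.fromiter((len(l) for l in lists), dtype=int, count=n)
        flat_idx = np.concatenate([np.sort(l) for l in lists]) if counts.sum() else np.empty(0, int)
        flat_pt = np.repeat(np.arange(n), counts)
        cp, d = closest_point_on_triangles(pts[flat_pt], self.triangles[flat_idx])

        # first minimum per query in ascending (distance, triangle index) order
        order = np.lexsort((flat_idx, d, flat_pt))
        starts = np.searchsorted(flat_pt[order], np.arange(n))
        pick = order[starts]
        return cp[pick], d[pick], flat_idx[pick]


def ray_mesh_intersections(origin, direction, triangles, t_min=1e-9):
    """All ray-triangle intersection parameters t (ascending, t > t_min).

    Moller-Trumbore over every triangle; suitable for the mesh sizes used
    here and exact up to floating point.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(d[None, :], e2)
    det = np.einsum("ij,ij->i", e1, h)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = 1.0 / det
        s = o[None, :] - v0
        u = np.einsum("ij,ij->i", s, h) * inv_det
        q = np.cross(s, e1)
        v = np.einsum("j,ij->i", d, q) * inv_det
        t = np.einsum("ij,ij->i", e2, q) * inv_det
    hit = (
        (np.abs(det) > 1e-14)
        & (u >= -1e-12)
        & (v >= -1e-12)
        & (u + v <= 1 + 1e-12)
        & (t > t_min)
    )
    return np.sort(t[hit])


def winding_number(points, triangles, chunk=2_000_000):
    """Generalized winding number of each point w.r.t. a triangle soup.

    Uses the Van Oosterom-Strackee solid-angle formula; ~1 inside a
    watertight mesh, ~0 outside, robust to glancing rays.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = np.asarray(triangles, dtype=float)
    n, m = len(pts), len(tri)
    w = np.zeros(n)
    rows = max(1, int(chunk // max(m, 1)))
    for lo in range(0, n, rows):
        p = pts[lo : lo + rows]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        numer = np.einsum("nmj,nmj->nm", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("nmj,nmj->nm", a, b) * lc
            + np.einsum("nmj,nmj->nm", b, c) * la
            + np.einsum("nmj,nmj->nm", c, a) * lb
        )
        omega = 2.0 * np.arctan2(numer, denom)
        w[lo : lo + rows] = omega.sum(axis=1) / (4.0 * np.pi)
    return w


def points_inside(points, triangles, threshold=0.5):
    """Boolean inside test via the generalized winding number."""
    return np.abs(winding_number(points, triangles)) > threshold


def rotation_about_axis(axis, angle_rad):
    """Rotation matrix about a unit axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def orthonormal_basis(normal, reference=None):
    """Deterministic orthonormal (e1, e2) spanning the plane orthogonal to ``normal``.

    e1 is the unit projection of ``reference`` (default: world superior +z;
    falls back to +y when degenerate) onto the plane; e2 = normal x e1.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    candidates = [reference] if reference is not None else []
    candidates += [np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])]
    for ref in candidates:
        if ref is None:
            continue
        e1 = np.asarray(ref, dtype=float) - np.dot(ref, n) * n
        norm = np.linalg.norm(e1)
        if norm > 1e-8:
            e1 = e1 / norm
            return e1, np.cross(n, e1)
    raise ValueError("could not build a tangent basis for the given normal")
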