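"""Smooth cortical envelope (SCE) construction and surface queries.

The SCE approximates the inner dural sheet: a watertight, smooth surface
enclosing the pial surface, on which subdural grids and strips rest. It is
built by morphological closing of the voxelized pial solid with a spherical
element (default radius 30 mm), isosurface extraction, and low-pass mesh
smoothing (100 iterations, alpha = 0.5). Synthetic pial-like surfaces
(sphere / ellipsoid / bumpy) are provided so nothing needs downloading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage, sparse
from skimage import measure

from ._geometry import MeshQuery, points_inside, ray_mesh_intersections

__all__ = [
    "SurfaceMesh",
    "SeedPoint",
    "load_surface",
    "save_surface",
    "generate_synthetic_pial",
    "build_sce",
    "smooth_lowpass",
    "local_curvature",
    "classify_and_select_seeds",
]

CURVATURE_CLASSES = ("Low", "Medium", "High")


@dataclass
class SurfaceMesh:
    """Triangulated surface in mm world coordinates (RAS convention).

    Wraps a :class:`trimesh.Trimesh` and caches the exact nearest-point
    query structure and per-vertex curvature.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_curvature: np.ndarray | None = None
    _tm: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)
    _query: MeshQuery | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise ValueError("empty mesh")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    @property
    def tm(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._tm

    @property
    def vertex_normals(self) -> np.ndarray:
        n = np.asarray(self.tm.vertex_normals, dtype=float)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    @property
    def is_watertight(self) -> bool:
        return bool(self.tm.is_watertight)

    def query(self) -> MeshQuery:
        if self._query is None:
            self._query = MeshQuery(self.triangles)
        return self._query

    def closest_point(self, points):
        """Exact closest point(s) on the surface.

        Returns ``(surface_points, distances, triangle_indices)``; accepts a
        single point or an (n, 3) array.
        """
        single = np.asarray(points).ndim == 1
        cp, d, tri = self.query().closest(np.atleast_2d(points))
        if single:
            return cp[0], float(d[0]), int(tri[0])
        return cp, d, tri

    def contains(self, points) -> np.ndarray:
        """Inside test (generalized winding number); mesh must be closed."""
        return points_inside(np.atleast_2d(points), self.triangles)

    def signed_distance(self, points) -> np.ndarray:
        """Distance to the surface, negative inside."""
        pts = np.atleast_2d(points)
        _, d, _ = self.closest_point(pts)
        inside = self.contains(pts)
        return np.where(inside, -d, d)

    def ray_intersections(self, origin, direction):
        """Ascending intersection parameters t of origin + t*direction."""
        return ray_mesh_intersections(origin, direction, self.triangles)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_curvature is None else self.vertex_curvature.copy(),
        )


@dataclass
class SeedPoint:
    """Reference point on the SCE where an array is centred or enters."""

    position: np.ndarray
    curvature_class: str
    hemisphere: str = "synthetic"
    vertex_index: int | None = None
    curvature: float | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.curvature_class not in CURVATURE_CLASSES:
            raise ValueError(f"unknown curvature class {self.curvature_class!r}")


# ---------------------------------------------------------------------------
# I/O


def load_surface(path) -> SurfaceMesh:
    """Read a surface mesh (FreeSurfer binary, PLY, STL, or OFF), mm coords."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".ply", ".stl", ".off", ".obj"}:
        tm = trimesh.load(str(path), force="mesh", process=False)
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    # FreeSurfer binary geometry (lh.pial etc. -- no/unknown extension)
    import nibabel.freesurfer as nbfs

    coords, faces = nbfs.read_geometry(str(path))
    return SurfaceMesh(np.asarray(coords, dtype=float), np.asarray(faces))


def save_surface(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".ply", ".stl", ".off", ".obj"}:
        mesh.tm.export(str(path))
        return
    import nibabel.freesurfer as nbfs

    nbfs.write_geometry(str(path), mesh.vertices, mesh.faces)


# ---------------------------------------------------------------------------
# Synthetic pial-like surfaces


def generate_synthetic_pial(
    kind: str,
    radius_mm: float = 70.0,
    semiaxes_mm=None,
    bump_amplitude_mm: float = 5.0,
    bump_frequency: float = 4.0,
    subdivisions: int = 4,
    rng_seed: int = 0,
) -> SurfaceMesh:
    """Watertight synthetic test surface: ``sphere``, ``ellipsoid`` or ``bumpy``.

    ``bumpy`` perturbs a sphere radially with a deterministic band-limited
    field (sum of oriented cosine lobes) of the requested amplitude and
    angular frequency; identical seeds give bit-identical meshes.
    """
    if kind not in {"sphere", "ellipsoid", "bumpy"}:
        raise ValueError(f"unknown kind {kind!r}")
    if kind == "ellipsoid":
        semiaxes = np.asarray(
            semiaxes_mm if semiaxes_mm is not None else (80.0, 65.0, 60.0), dtype=float
        )
        if np.any(semiaxes <= 0):
            raise ValueError("semiaxes must be positive")
        base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        verts = np.asarray(base.vertices) * semiaxes
        return SurfaceMesh(verts, np.asarray(base.faces))

    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    unit = np.asarray(base.vertices)
    if kind == "sphere":
        return SurfaceMesh(unit * radius_mm, np.asarray(base.faces))

    if bump_amplitude_mm < 0:
        raise ValueError("bump amplitude must be non-negative")
    rng = np.random.default_rng(rng_seed)
    n_lobes = 6
    dirs = rng.normal(size=(n_lobes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.uniform(0.5, 1.0, size=n_lobes)
    phases = rng.uniform(0, 2 * np.pi, size=n_lobes)
    f = np.zeros(len(unit))
    for d, a, ph in zip(dirs, amps, phases):
        f += a * np.cos(bump_frequency * (unit @ d) * np.pi + ph)
    f /= np.abs(f).max()
    r = radius_mm + bump_amplitude_mm * f
    return SurfaceMesh(unit * r[:, None], np.asarray(base.faces))


# ---------------------------------------------------------------------------
# Smoothing


def _adjacency(n_vertices: int, faces: np.ndarray) -> sparse.csr_matrix:
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2],
                        faces[:, 1], faces[:, 2], faces[:, 0]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0],
                        faces[:, 0], faces[:, 1], faces[:, 2]])
    A = sparse.coo_matrix(
        (np.ones(len(i)), (i, j)), shape=(n_vertices, n_vertices)
    ).tocsr()
    A.data[:] = 1.0  # collapse duplicate entries
    A.sum_duplicates()
    A.data[:] = 1.0
    return A


def smooth_lowpass(
    mesh: SurfaceMesh, iterations: int = 100, alpha: float = 0.5
) -> SurfaceMesh:
    """Low-pass (Taubin lambda|mu) mesh smoothing.

    Each iteration applies a forward umbrella step of weight ``alpha``
    followed by a backward step of weight ``-1.02 * alpha``; this removes
    high-frequency protuberances with negligible shrinkage of closed
    surfaces, unlike a plain Laplacian filter.
    """
    V = mesh.vertices.copy()
    A = _adjacency(len(V), mesh.faces)
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    inv_deg = (1.0 / deg)[:, None]
    mu = -1.02 * alpha
    for _ in range(iterations):
        V = V + alpha * (A @ V * inv_deg - V)
        V = V + mu * (A @ V * inv_deg - V)
    return SurfaceMesh(V, mesh.faces.copy())


# ---------------------------------------------------------------------------
# SCE construction


def build_sce(
    pial: SurfaceMesh,
    closing_radius_mm: float = 30.0,
    smooth_iterations: int = 100,
    smooth_alpha: float = 0.5,
    voxel_pitch_mm: float = 1.0,
) -> SurfaceMesh:
    """Build the smooth cortical envelope enclosing a pial-like mesh.

    Pipeline: voxelize the pial surface at ``voxel_pitch_mm`` and fill it to
    a solid; morphologically close with a spherical element of
    ``closing_radius_mm`` (distance-transform implementation), bridging
    concavities narrower than twice the radius; pad by one voxel so the
    extracted isosurface strictly contains the input; run marching cubes and
    low-pass smoothing. The result is watertight and contains every pial
    vertex.
    """
    if closing_radius_mm <= 0:
        raise ValueError("closing radius must be positive")
    if len(pial.vertices) < 4:
        raise ValueError("pial mesh needs at least 4 vertices")

    pitch = float(voxel_pitch_mm)
    lo = pial.vertices.min(axis=0)
    hi = pial.vertices.max(axis=0)
    pad = closing_radius_mm + 4 * pitch
    origin = lo - pad
    shape = np.ceil((hi - lo + 2 * pad) / pitch).astype(int) + 1

    # occupancy of the *solid*: containment test of voxel centres
    grids = [origin[k] + pitch * np.arange(shape[k]) for k in range(3)]
    # surface voxelization first (cheap, conservative), then fill
    occ = np.zeros(shape, dtype=bool)
    surface_pts = _densify_surface(pial, pitch / 2.0)
    ijk = np.round((surface_pts - origin) / pitch).astype(int)
    ijk = np.clip(ijk, 0, np.array(shape) - 1)
    occ[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    occ = ndimage.binary_fill_holes(occ)
    if occ is None or not occ.any():
        raise ValueError("voxelization produced an empty solid")

    r_vox = closing_radius_mm / pitch
    # closing = erosion(dilation(occ)); both via Euclidean distance transforms
    dist_to_occ = ndimage.distance_transform_edt(~occ)
    dilated = dist_to_occ <= r_vox
    dist_to_bg = ndimage.distance_transform_edt(dilated)
    closed = dist_to_bg > r_vox
    closed |= occ  # closing is extensive; keep exact on the discrete grid
    # one-voxel safety dilation so the 0.5-isosurface strictly encloses the pial
    closed = ndimage.binary_dilation(closed, ndimage.generate_binary_structure(3, 1))

    verts, faces, _, _ = measure.marching_cubes(
        closed.astype(np.float32), level=0.5, spacing=(pitch, pitch, pitch)
    )
    verts = verts + origin
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if not tm.is_watertight:
        trimesh.repair.fill_holes(tm)
    sce = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    sce = smooth_lowpass(sce, iterations=smooth_iterations, alpha=smooth_alpha)
    if not sce.is_watertight:
        raise RuntimeError("SCE extraction produced a non-watertight mesh")
    return sce


def _densify_surface(mesh: SurfaceMesh, max_edge: float) -> np.ndarray:
    """Sample points on the mesh so every triangle is covered at ``max_edge``."""
    tm = mesh.tm
    v, f = trimesh.remesh.subdivide_to_size(
        np.asarray(tm.vertices), np.asarray(tm.faces), max_edge=max_edge
    )
    return np.asarray(v)


# ---------------------------------------------------------------------------
# Curvature


def local_curvature(
    mesh: SurfaceMesh, smoothing_level: int = 20, store: bool = True
) -> np.ndarray:
    """Discrete mean-curvature magnitude per vertex (1/mm).

    Cotangent Laplace-Beltrami estimate on a pre-smoothed copy of the mesh
    (``smoothing_level`` low-pass iterations): H = |K| / 2 with
    K_i = (1/2A_i) * sum_j (cot a_ij + cot b_ij)(x_i - x_j), using the
    mixed Voronoi vertex areas A_i (exact on irregular-valence vertices,
    unlike the barycentric third-of-triangle weight). Degenerate triangles
    are excluded with a warning. Invariant under rigid motion.
    """
    work = smooth_lowpass(mesh, iterations=smoothing_level) if smoothing_level else mesh
    V, F = work.vertices, work.faces
    n = len(V)

    tri = V[F]
    rows, cols, vals = [], [], []
    area = np.zeros(n)
    e = [tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2]]
    double_area = np.linalg.norm(np.cross(e[0], -e[2]), axis=1)
    degenerate = double_area < 1e-12
    if degenerate.any():
        warnings.warn(
            f"excluding {int(degenerate.sum())} degenerate triangles from curvature"
        )
    ok = ~degenerate
    Fo = F[ok]
    trio = tri[ok]
    da = double_area[ok]
    cots = []
    for corner in range(3):
        i = Fo[:, (corner + 1) % 3]
        j = Fo[:, (corner + 2) % 3]
        u = trio[:, (corner + 1) % 3] - trio[:, corner]
        v = trio[:, (corner + 2) % 3] - trio[:, corner]
        cot = np.einsum("ij,ij->i", u, v) / da
        cots.append(cot)
        rows += [i, j]
        cols += [j, i]
        vals += [cot, cot]
    # mixed Voronoi areas (Meyer et al.): circumcentric for non-obtuse
    # triangles, half/quarter split when an angle is obtuse
    cots = np.stack(cots, axis=1)  # cot of angle at corner k
    obtuse_any = (cots < 0).any(axis=1)
    edge_sq = np.stack(
        [
            ((trio[:, 2] - trio[:, 1]) ** 2).sum(1),  # opposite corner 0
            ((trio[:, 0] - trio[:, 2]) ** 2).sum(1),
            ((trio[:, 1] - trio[:, 0]) ** 2).sum(1),
        ],
        axis=1,
    )
    tri_area = da / 2.0
    for corner in range(3):
        voronoi = (
            edge_sq[:, (corner + 1) % 3] * cots[:, (corner + 1) % 3]
            + edge_sq[:, (corner + 2) % 3] * cots[:, (corner + 2) % 3]
        ) / 8.0
        obtuse_here = cots[:, corner] < 0
        contrib = np.where(
            obtuse_any,
            np.where(obtuse_here, tri_area / 2.0, tri_area / 4.0),
            voronoi,
        )
        np.add.at(area, Fo[:, corner], contrib)

    W = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    L = sparse.diags(np.asarray(W.sum(axis=1)).ravel()) - W
    K = L @ V
    area[area == 0] = np.inf
    H = np.linalg.norm(K, axis=1) / (4.0 * area)
    if store:
        mesh.vertex_curvature = H
    return H


# ---------------------------------------------------------------------------
# Seed selection


def classify_curvature(curvature: np.ndarray) -> np.ndarray:
    """Tercile labels Low/Medium/High from per-vertex curvature."""
    lo, hi = np.percentile(curvature, [100.0 / 3.0, 200.0 / 3.0])
    labels = np.full(len(curvature), "Medium", dtype=object)
    labels[curvature <= lo] = "Low"
    labels[curvature > hi] = "High"
    return labels


def classify_and_select_seeds(
    mesh: SurfaceMesh,
    n_seeds: int = 57,
    rng_seed: int = 0,
    min_spacing_mm: float = 15.0,
    hemisphere: str = "synthetic",
) -> list[SeedPoint]:
    """Stratified, reproducible seed points on the SCE.

    Vertices are labelled Low/Medium/High by curvature terciles; seeds are
    drawn round-robin across the classes with a minimum pairwise Euclidean
    spacing. Raises with the achievable count if ``n_seeds`` cannot be met.
    """
    if mesh.vertex_curvature is None:
        local_curvature(mesh)
    curv = mesh.vertex_curvature
    labels = classify_curvature(curv)
    rng = np.random.default_rng(rng_seed)

    pools = []
    for cls in CURVATURE_CLASSES:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        pools.append(list(idx))

    chosen: list[int] = []
    positions: list[np.ndarray] = []
    stalled = 0
    k = 0
    while len(chosen) < n_seeds and stalled < 3:
        pool = pools[k % 3]
        k += 1
        if not pool:
            stalled += 1
            continue
        while pool:
            cand = pool.pop()
            p = mesh.vertices[cand]
            if not positions or np.min(
                np.linalg.norm(np.asarray(positions) - p, axis=1)
            ) >= min_spacing_mm:
                chosen.append(cand)
                positions.append(p)
                stalled = 0
                break
        else:
            stalled += 1
    if len(chosen) < n_seeds:
        raise ValueError(
            f"only {len(chosen)} seeds satisfy spacing {min_spacing_mm} mm; "
            f"requested {n_seeds}"
        )
    return [
        SeedPoint(
            position=mesh.vertices[i],
            curvature_class=str(labels[i]),
            hemisphere=hemisphere,
            vertex_index=int(i),
            curvature=float(curv[i]),
        )
        for i in chosen
    ]
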