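"""Undeformed grid/strip/depth array geometry and tangential placement.

A flat array is a planar lattice of contacts with spring-like neighbor
edges in three classes: *first* (adjacent along rows/columns, rest length
IED), *diagonal* (rest length IED*sqrt(2), shear control), and *second*
(two steps along a row/column, rest length 2*IED, bending control).
Strips are modelled as 3-row lattices to keep their fit well-posed; only
the middle row is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import orthonormal_basis, rotation_about_axis
from .surface import SeedPoint, SurfaceMesh

__all__ = [
    "FlatArrayModel",
    "ArrayCatalogEntry",
    "ARRAY_CATALOG",
    "make_flat_grid",
    "make_strip_model",
    "place_tangential",
]

EDGE_CLASSES = ("first", "diagonal", "second")


@dataclass
class FlatArrayModel:
    """Planar lattice model of a grid or strip before surface fitting."""

    n_rows: int
    n_cols: int
    ied_mm: float
    initial_coords: np.ndarray  # (N, 3), z = 0, centred at the origin
    edges: np.ndarray  # (E, 2) int
    edge_class: np.ndarray  # (E,) str in EDGE_CLASSES
    rest_lengths: np.ndarray  # (E,) mm
    array_kind: str = "grid"
    reported_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.reported_mask is None:
            self.reported_mask = np.ones(len(self.initial_coords), dtype=bool)

    @property
    def n_electrodes(self) -> int:
        return len(self.initial_coords)

    def edge_lengths(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(coords, dtype=float)
        return np.linalg.norm(c[self.edges[:, 0]] - c[self.edges[:, 1]], axis=1)

    def lattice_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col


@dataclass(frozen=True)
class ArrayCatalogEntry:
    label: str
    kind: str  # grid | strip | depth
    n_rows: int  # depth: 1
    n_cols: int  # depth: contact count
    ied_mm: float


def _catalog() -> dict[str, ArrayCatalogEntry]:
    entries = []
    for r, c in [(2, 4), (4, 4), (4, 8), (8, 8), (8, 16), (16, 16)]:
        for ied in (3.0, 5.0, 10.0):
            entries.append(
                ArrayCatalogEntry(f"G_{r}x{c}_{ied:g}mm", "grid", r, c, ied)
            )
    for c in (4, 6, 8):
        for ied in (3.0, 5.0, 10.0):
            entries.append(ArrayCatalogEntry(f"S_1x{c}_{ied:g}mm", "strip", 1, c, ied))
    for c in (4, 8, 10, 12, 15, 18):
        for ied in (3.0, 5.0, 10.0):
            entries.append(ArrayCatalogEntry(f"D_{c}c_{ied:g}mm", "depth", 1, c, ied))
    return {e.label: e for e in entries}


ARRAY_CATALOG: dict[str, ArrayCatalogEntry] = _catalog()


def make_flat_grid(n_rows: int, n_cols: int, ied_mm: float) -> FlatArrayModel:
    """Planar R x C lattice centred at the origin with its neighbor graph.

    Closed-form edge counts for an R x C grid: first = R(C-1) + C(R-1),
    diagonal = 2(R-1)(C-1), second = R max(C-2, 0) + C max(R-2, 0).
    """
    if n_rows < 1 or n_cols < 2:
        raise ValueError("grid needs n_rows >= 1 and n_cols >= 2")
    if ied_mm <= 0:
        raise ValueError("IED must be positive")

    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    xy = np.stack([cc.ravel(), rr.ravel()], axis=1).astype(float)
    xy -= xy.mean(axis=0)
    coords = np.column_stack([xy * ied_mm, np.zeros(n_rows * n_cols)])

    def idx(r, c):
        return r * n_cols + c

    edges, classes, rests = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            i = idx(r, c)
            if c + 1 < n_cols:
                edges.append((i, idx(r, c + 1))); classes.append("first"); rests.append(ied_mm)
            if r + 1 < n_rows:
                edges.append((i, idx(r + 1, c))); classes.append("first"); rests.append(ied_mm)
            if r + 1 < n_rows and c + 1 < n_cols:
                edges.append((i, idx(r + 1, c + 1))); classes.append("diagonal")
                rests.append(ied_mm * np.sqrt(2.0))
                edges.append((idx(r, c + 1), idx(r + 1, c))); classes.append("diagonal")
                rests.append(ied_mm * np.sqrt(2.0))
            if c + 2 < n_cols:
                edges.append((i, idx(r, c + 2))); classes.append("second"); rests.append(2 * ied_mm)
            if r + 2 < n_rows:
                edges.append((i, idx(r + 2, c))); classes.append("second"); rests.append(2 * ied_mm)

    return FlatArrayModel(
        n_rows=n_rows,
        n_cols=n_cols,
        ied_mm=float(ied_mm),
        initial_coords=coords,
        edges=np.asarray(edges, dtype=int),
        edge_class=np.asarray(classes, dtype=object),
        rest_lengths=np.asarray(rests, dtype=float),
        array_kind="grid",
    )


def make_strip_model(n_contacts: int, ied_mm: float) -> FlatArrayModel:
    """Strip as a 3 x n lattice; the middle row carries the reported contacts.

    The two lateral rows stabilise the fit against unrealistic undulating
    deformations and are discarded after fitting.
    """
    if n_contacts < 2:
        raise ValueError("strip needs at least 2 contacts")
    model = make_flat_grid(3, n_contacts, ied_mm)
    model.array_kind = "strip"
    mask = np.zeros(model.n_electrodes, dtype=bool)
    mask[model.n_cols : 2 * model.n_cols] = True  # lattice row index 1
    model.reported_mask = mask
    return model


def place_tangential(
    model: FlatArrayModel,
    mesh: SurfaceMesh,
    seed: SeedPoint,
    rotation_deg: float = 0.0,
) -> np.ndarray:
    """Rigidly map the flat lattice onto the tangent plane at a seed point.

    The lattice is centred at the seed, laid in the plane orthogonal to the
    outward surface normal there, and rotated by ``rotation_deg`` about the
    normal. The zero-rotation reference direction is the projection of the
    world superior (+z) axis onto the tangent plane. Pairwise distances are
    preserved exactly (rigid placement).
    """
    if seed.vertex_index is not None:
        normal = mesh.vertex_normals[seed.vertex_index]
    else:
        _, _, tri_idx = mesh.closest_point(seed.position)
        normal = np.asarray(mesh.tm.face_normals[tri_idx], dtype=float)
    nrm = np.linalg.norm(normal)
    if not np.isfinite(nrm) or nrm < 1e-12:
        raise ValueError("degenerate surface normal at seed point")
    normal = normal / nrm

    e1, e2 = orthonormal_basis(normal)
    R = rotation_about_axis(normal, np.deg2rad(rotation_deg))
    e1r, e2r = R @ e1, R @ e2
    uv = model.initial_coords[:, :2]
    return seed.position[None, :] + uv[:, 0:1] * e1r[None, :] + uv[:, 1:2] * e2r[None, :]
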