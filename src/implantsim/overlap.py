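"""Overlapping grid/strip scenarios on top of a fitted background array.

Real implantations sometimes stack arrays; overlapping artifacts are a
stress case for localization algorithms. The procedure: fit a quadratic
height-field surface to the background electrodes in their principal-
component frame; place the overlay flat in the (PC1, PC2) plane at a random
orientation far outside the background footprint; translate it along a
random direction until the requested number of overlay electrodes falls
inside the background's 2D convex hull; lift the overlay onto the fitted
surface and interpolate its normals from nearby background electrodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay

from .arrays import FlatArrayModel
from .gridfit import FittedArray

__all__ = [
    "QuadraticSurface",
    "OverlapScenario",
    "fit_background_surface",
    "simulate_overlap",
    "interpolate_overlay_normals",
]


@dataclass
class QuadraticSurface:
    """Height field z = f(u, v) over the background's PC1-PC2 plane."""

    origin: np.ndarray  # 3D centroid of the background
    axes: np.ndarray  # (3, 3) rows = PC1, PC2, PC3 unit vectors
    coeffs: np.ndarray  # (6,) for [1, u, v, u^2, u*v, v^2]
    residual_rms: float = np.nan

    def height(self, uv: np.ndarray) -> np.ndarray:
        u, v = uv[:, 0], uv[:, 1]
        A = np.column_stack([np.ones_like(u), u, v, u**2, u * v, v**2])
        return A @ self.coeffs

    def lift(self, uv: np.ndarray) -> np.ndarray:
        """Map (u, v) plane coordinates to 3D points on the surface."""
        w = self.height(uv)
        return (
            self.origin[None, :]
            + uv[:, 0:1] * self.axes[0][None, :]
            + uv[:, 1:2] * self.axes[1][None, :]
            + w[:, None] * self.axes[2][None, :]
        )

    def normal(self, uv: np.ndarray) -> np.ndarray:
        """Unit surface normal (PC3-ward) at plane coordinates."""
        u, v = uv[:, 0], uv[:, 1]
        c = self.coeffs
        dw_du = c[1] + 2 * c[3] * u + c[4] * v
        dw_dv = c[2] + c[4] * u + 2 * c[5] * v
        n = (
            -dw_du[:, None] * self.axes[0][None, :]
            - dw_dv[:, None] * self.axes[1][None, :]
            + self.axes[2][None, :]
        )
        return n / np.linalg.norm(n, axis=1, keepdims=True)


@dataclass
class OverlapScenario:
    background: FittedArray
    overlay_coords: np.ndarray
    overlay_normals: np.ndarray
    overlay_model: FlatArrayModel
    requested_overlap_fraction: float
    achieved_overlap_count: int
    overlay_rotation_deg: float
    translation_direction: np.ndarray
    surface: QuadraticSurface = field(repr=False, default=None)  # type: ignore[assignment]


def _pca_frame(coords: np.ndarray):
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt.copy()
    # deterministic sign: largest-magnitude entry of each axis positive
    for k in range(3):
        j = np.argmax(np.abs(axes[k]))
        if axes[k, j] < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return centroid, axes, s


def fit_background_surface(background: FittedArray) -> QuadraticSurface:
    """Fit the quadratic height field to the background electrode cloud."""
    coords = background.reported_coords
    if len(coords) < 6:
        raise ValueError("need at least 6 electrodes to fit a quadratic surface")
    centroid, axes, s = _pca_frame(coords)
    local = (coords - centroid) @ axes.T
    u, v, w = local[:, 0], local[:, 1], local[:, 2]
    A = np.column_stack([np.ones_like(u), u, v, u**2, u * v, v**2])
    if np.linalg.matrix_rank(A) < 6:
        raise ValueError("rank-deficient quadratic fit (degenerate electrode layout)")
    coeffs, *_ = np.linalg.lstsq(A, w, rcond=None)
    resid = w - A @ coeffs
    return QuadraticSurface(
        origin=centroid,
        axes=axes,
        coeffs=coeffs,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def count_overlapping(overlay_uv: np.ndarray, background_uv: np.ndarray) -> int:
    """Overlay electrodes inside the background's 2D convex hull."""
    hull = Delaunay(background_uv[ConvexHull(background_uv).vertices])
    return int(np.sum(hull.find_simplex(overlay_uv) >= 0))


def simulate_overlap(
    background: FittedArray,
    overlay_model: FlatArrayModel,
    overlap_fraction: float,
    rng_seed: int | np.random.Generator = 0,
    max_direction_retries: int = 20,
) -> OverlapScenario:
    """Place an overlay array achieving round(fraction * N) overlapping electrodes.

    The overlay is rotated uniformly at random in the PC plane and slid
    along a random direction toward the background centroid; the exact
    translation is found by bisection (overlap count is monotone along the
    approach). If the drawn direction cannot realize the requested count,
    a new direction is drawn, up to ``max_direction_retries``.
    """
    if not 0 <= overlap_fraction <= 0.5:
        raise ValueError("overlap fraction must be in [0, 0.5]")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    surface = fit_background_surface(background)
    bg_uv = (background.reported_coords - surface.origin) @ surface.axes.T
    bg_uv = bg_uv[:, :2]

    n_overlay = int(overlay_model.reported_mask.sum())
    target = int(round(overlap_fraction * n_overlay))
    flat_uv = overlay_model.initial_coords[:, :2]
    span = np.linalg.norm(bg_uv, axis=1).max() + np.abs(flat_uv).max() + 1.0

    for _ in range(max_direction_retries):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        uv0 = flat_uv @ rot.T
        phi = rng.uniform(0.0, 2.0 * np.pi)
        direction = np.array([np.cos(phi), np.sin(phi)])

        def count_at(t):
            return count_overlapping(uv0 + (span - t) * direction[None, :], bg_uv)

        # t is the approach distance: t=0 far outside, t=span at the centroid
        if count_at(0.0) > target:
            continue
        lo, hi = 0.0, span
        if count_at(hi) < target:
            continue
        # bisection on the monotone step function
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if count_at(mid) >= target:
                hi = mid
            else:
                lo = mid
        t_star = hi
        achieved = count_at(t_star)
        if achieved != target:
            continue
        # bisection converges onto the crossing where the marginal electrode
        # sits exactly on the hull boundary; nudge strictly inside so the
        # count is robust to round-off
        nudge = t_star + 1e-6 * span
        if count_at(nudge) == target:
            t_star = nudge
        uv = uv0 + (span - t_star) * direction[None, :]
        coords3d = surface.lift(uv)
        normals = interpolate_overlay_normals(background, coords3d, surface=surface)
        return OverlapScenario(
            background=background,
            overlay_coords=coords3d,
            overlay_normals=normals,
            overlay_model=overlay_model,
            requested_overlap_fraction=overlap_fraction,
            achieved_overlap_count=achieved,
            overlay_rotation_deg=float(np.degrees(theta)),
            translation_direction=direction,
            surface=surface,
        )
    raise RuntimeError(
        f"could not achieve overlap count {target} in {max_direction_retries} "
        "direction draws"
    )


def interpolate_overlay_normals(
    background: FittedArray,
    overlay_coords: np.ndarray,
    k: int = 4,
    surface: QuadraticSurface | None = None,
) -> np.ndarray:
    """Inverse-distance-weighted average of the nearest background normals.

    Exact coincidence with a background electrode returns that electrode's
    normal; overlay points farther than 3 IED from every background
    electrode fall back to the fitted-surface normal with a warning.
    """
    bg_coords = background.reported_coords
    bg_normals = background.reported_normals
    ied = background.model.ied_mm
    pts = np.atleast_2d(overlay_coords)
    out = np.empty_like(pts)
    n_fallback = 0
    for idx, p in enumerate(pts):
        d = np.linalg.norm(bg_coords - p, axis=1)
        order = np.argsort(d)[:k]
        if d[order[0]] < 1e-9:
            n = bg_normals[order[0]]
        elif d[order[0]] > 3.0 * ied:
            if surface is None:
                surface = fit_background_surface(background)
            n_fallback += 1
            uv = ((p - surface.origin) @ surface.axes.T)[None, :2]
            n = surface.normal(uv)[0]
        else:
            w = 1.0 / d[order]
            n = (w[:, None] * bg_normals[order]).sum(axis=0)
        out[idx] = n / np.linalg.norm(n)
    if n_fallback:
        warnings.warn(
            f"{n_fallback} overlay points farther than 3 IED from every "
            "background electrode; used fitted-surface normals there"
        )
    return out
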