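"""Fit flat grid/strip models to the envelope by constrained energy minimization.

The fitted coordinates minimize E = Et + K * Ed subject to every electrode
lying within a tolerance ``epsilon`` of the surface, where

* Et = sum_i ||x_i - x_i^0||^2 is the translation energy from the initial
  tangential placement, and
* Ed = sum_(i,j in edges) (d_ij - d_ij^0)^2 is the spring deformation energy
  over first/diagonal/second neighbor edges.

K weighs rigidity against displacement; defaults K = 1000, epsilon = 0.1 mm
(16 x 16 grids use K = 100, epsilon = 0.5 mm). The surface constraint is
handled by quasi-Newton descent on the energy plus an escalating quadratic
penalty on the surface-distance excess max(0, ||x_i - s_i|| - epsilon),
with the closest surface point s_i recomputed at every evaluation, followed
by exact projection of any residual out-of-tolerance electrode. The whole
procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .arrays import EDGE_CLASSES, FlatArrayModel
from .surface import SurfaceMesh

__all__ = [
    "FitConfig",
    "FittedArray",
    "translation_energy",
    "deformation_energy",
    "fit_to_surface",
    "electrode_normals",
    "deformation_report",
    "qc_filter",
    "strip_middle_row",
]


@dataclass
class FitConfig:
    K: float = 1000.0
    epsilon_mm: float = 0.1
    max_iterations: int = 2000
    convergence_tol: float = 1e-6

    def __post_init__(self):
        if self.K <= 0 or self.epsilon_mm <= 0:
            raise ValueError("K and epsilon must be positive")

    @classmethod
    def for_model(cls, model: FlatArrayModel) -> "FitConfig":
        """Paper defaults: K=1000, eps=0.1 mm; 16x16 grids use K=100, eps=0.5."""
        if model.n_rows * model.n_cols >= 256:
            return cls(K=100.0, epsilon_mm=0.5)
        return cls()


@dataclass
class FittedArray:
    """Electrode coordinates on the envelope with per-electrode normals."""

    coords: np.ndarray
    normals: np.ndarray | None
    surface_distances: np.ndarray
    model: FlatArrayModel
    objective: float = np.nan
    provenance: dict = field(default_factory=dict)

    @property
    def reported_coords(self) -> np.ndarray:
        return self.coords[self.model.reported_mask]

    @property
    def reported_normals(self) -> np.ndarray:
        return self.normals[self.model.reported_mask]


class FitConvergenceError(RuntimeError):
    def __init__(self, msg, coords=None, trace=None):
        super().__init__(msg)
        self.coords = coords
        self.trace = trace


# ---------------------------------------------------------------------------
# Energies


def translation_energy(coords: np.ndarray, initial: np.ndarray) -> float:
    """Sum of squared displacements from the initial placement."""
    c = np.asarray(coords, dtype=float)
    c0 = np.asarray(initial, dtype=float)
    if c.shape != c0.shape:
        raise ValueError("coords and initial must have the same shape")
    return float(((c - c0) ** 2).sum())


def deformation_energy(coords: np.ndarray, model: FlatArrayModel) -> float:
    """Sum over neighbor edges of (d_ij - d_ij^0)^2; zero for rigid motions."""
    d = model.edge_lengths(coords)
    return float(((d - model.rest_lengths) ** 2).sum())


def _energy_and_grad(coords, initial, model, K):
    diff0 = coords - initial
    et = (diff0**2).sum()
    grad = 2.0 * diff0

    i, j = model.edges[:, 0], model.edges[:, 1]
    dv = coords[i] - coords[j]
    d = np.linalg.norm(dv, axis=1)
    safe = np.where(d > 1e-12, d, 1.0)
    resid = d - model.rest_lengths
    ed = (resid**2).sum()
    g_edge = (2.0 * resid / safe)[:, None] * dv
    np.add.at(grad, i, K * g_edge)
    np.add.at(grad, j, -K * g_edge)
    return et + K * ed, grad


def fit_to_surface(
    initial: np.ndarray,
    model: FlatArrayModel,
    mesh: SurfaceMesh,
    config: FitConfig | None = None,
) -> FittedArray:
    """Minimize E = Et + K*Ed with all electrodes within epsilon of the surface.

    Runs L-BFGS on E plus a quadratic penalty mu * sum max(0, d_i - eps)^2
    on the exact mesh distance d_i, escalating mu until the iterate is
    feasible, then projects any electrode still marginally out of tolerance
    onto its closest surface point. Raises :class:`FitConvergenceError`
    (carrying the last iterate and the objective trace) if no feasible
    solution is reached.
    """
    if config is None:
        config = FitConfig.for_model(model)
    x0 = np.asarray(initial, dtype=float)
    if x0.shape != (model.n_electrodes, 3):
        raise ValueError("initial coords shape mismatch with model")
    query = mesh.query()
    eps = config.epsilon_mm

    def penalized(x, mu):
        coords = x.reshape(-1, 3)
        e, grad = _energy_and_grad(coords, x0, model, config.K)
        cp, dist, _ = query.closest(coords)
        viol = np.maximum(dist - eps, 0.0)
        active = viol > 0
        if active.any():
            u = np.zeros_like(coords)
            u[active] = (coords[active] - cp[active]) / dist[active, None]
            grad = grad + mu * 2.0 * viol[:, None] * u
            e = e + mu * float((viol**2).sum())
        return e, grad.ravel()

    # start from the naive per-electrode projection (always feasible)
    cp, dist, _ = query.closest(x0)
    coords = cp.copy()
    trace = []
    feasible = False
    mu = 100.0 * config.K
    for _ in range(6):
        res = minimize(
            penalized,
            coords.ravel(),
            args=(mu,),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": config.max_iterations,
                "maxfun": 2 * config.max_iterations,
                "ftol": config.convergence_tol * 1e-8,
                "gtol": 1e-10,
                "maxcor": 50,
            },
        )
        coords = res.x.reshape(-1, 3)
        trace.append(float(res.fun))
        cp, dist, _ = query.closest(coords)
        if dist.max() <= eps * (1 + 1e-3):
            feasible = True
            break
        mu *= 10.0

    # snap marginal stragglers exactly onto the surface
    cp, dist, _ = query.closest(coords)
    off = dist > eps
    coords[off] = cp[off]
    dist[off] = 0.0
    obj, _ = _energy_and_grad(coords, x0, model, config.K)
    trace.append(float(obj))
    if not feasible or np.any(dist > eps + 1e-9):
        raise FitConvergenceError(
            "surface fit did not reach a feasible solution "
            f"(max distance {dist.max():.4g} mm, eps {eps})",
            coords=coords,
            trace=trace,
        )

    fitted = FittedArray(
        coords=coords,
        normals=None,
        surface_distances=dist,
        model=model,
        objective=float(trace[-1]),
        provenance={"K": config.K, "epsilon_mm": config.epsilon_mm},
    )
    fitted.normals = electrode_normals(fitted, model, mesh=mesh)
    return fitted


# ---------------------------------------------------------------------------
# Normals


def _lattice_neighborhood(model: FlatArrayModel, index: int) -> np.ndarray:
    r, c = divmod(index, model.n_cols)
    ids = [
        model.lattice_index(rr, cc)
        for rr in range(max(r - 1, 0), min(r + 2, model.n_rows))
        for cc in range(max(c - 1, 0), min(c + 2, model.n_cols))
    ]
    return np.asarray(ids, dtype=int)


def electrode_normals(
    fitted: FittedArray, model: FlatArrayModel, mesh: SurfaceMesh | None = None
) -> np.ndarray:
    """Per-electrode normal as the smallest principal component of the
    electrode and its 8-connected lattice neighbors, oriented outward.

    Outward disambiguation uses the envelope's face normal at the closest
    surface point when a mesh is given (falling back to the mean offset from
    the array centroid). Collinear neighborhoods fall back to the mesh
    normal with a warning.
    """
    import warnings

    coords = fitted.coords
    ref_normals = None
    if mesh is not None:
        _, _, tri = mesh.closest_point(coords)
        ref_normals = np.asarray(mesh.tm.face_normals, dtype=float)[tri]

    centroid = coords.mean(axis=0)
    normals = np.empty_like(coords)
    for i in range(len(coords)):
        pts = coords[_lattice_neighborhood(model, i)]
        centered = pts - pts.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if len(s) < 3 or s[1] < 1e-9:  # collinear neighborhood
            if ref_normals is None:
                raise ValueError("collinear neighborhood and no mesh normal available")
            warnings.warn(f"collinear neighborhood at electrode {i}; using mesh normal")
            n = ref_normals[i]
        else:
            n = vt[2]
        ref = ref_normals[i] if ref_normals is not None else coords[i] - centroid
        if np.dot(n, ref) < 0:
            n = -n
        normals[i] = n / np.linalg.norm(n)
    return normals


# ---------------------------------------------------------------------------
# Deformation QC


def deformation_report(fitted: FittedArray, model: FlatArrayModel | None = None):
    """Per-edge deformation fractions |d - d0| / IED and per-class medians.

    Returns ``(edge_table, medians)`` with the table as a DataFrame
    (columns: i, j, edge_class, rest_mm, length_mm, fraction).
    """
    model = model or fitted.model
    d = model.edge_lengths(fitted.coords)
    frac = np.abs(d - model.rest_lengths) / model.ied_mm
    table = pd.DataFrame(
        {
            "i": model.edges[:, 0],
            "j": model.edges[:, 1],
            "edge_class": model.edge_class,
            "rest_mm": model.rest_lengths,
            "length_mm": d,
            "fraction": frac,
        }
    )
    medians = {
        cls: float(np.median(frac[model.edge_class == cls]))
        for cls in EDGE_CLASSES
        if np.any(model.edge_class == cls)
    }
    return table, medians


def qc_filter(
    fitted: FittedArray,
    threshold_fraction: float = 0.05,
    model: FlatArrayModel | None = None,
):
    """Accept/reject a fit on the 5%-of-IED neighbor-deformation rule.

    Returns ``(accepted, offending_edges)``: reject iff any edge deformation
    fraction exceeds the threshold; offenders are listed.
    """
    table, _ = deformation_report(fitted, model)
    offending = table[table["fraction"] > threshold_fraction]
    return offending.empty, offending


def strip_middle_row(fitted: FittedArray, model: FlatArrayModel | None = None) -> FittedArray:
    """Keep only the middle-row contacts of a fitted strip."""
    model = model or fitted.model
    if model.array_kind != "strip":
        raise ValueError("strip_middle_row requires a strip model")
    mask = model.reported_mask
    sub = FittedArray(
        coords=fitted.coords[mask],
        normals=None if fitted.normals is None else fitted.normals[mask],
        surface_distances=fitted.surface_distances[mask],
        model=model,
        objective=fitted.objective,
        provenance=dict(fitted.provenance, strip_reported=True),
    )
    return sub
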