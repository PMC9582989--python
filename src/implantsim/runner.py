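"""Factorial scenario campaigns: array x seed x rotation x noise level.

A campaign enumerates placements over a surface's seed points, fits each
array, applies the 5%-IED quality-control rule, simulates artifacts at the
requested noise levels, and (optionally) benchmarks localization plug-ins
against the known ground truth. All randomness flows from one master seed
through independently derived named streams (placement / lattice / noise /
clustering), so campaigns are exactly reproducible and adding a stage never
perturbs another stage's draws.

Array eligibility follows the curvature gating used for realistic
implantations: large grids go on Low-curvature seeds, medium on Medium,
small grids and strips anywhere. The gating table lives in the config and
can be overridden.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import ARRAY_CATALOG, make_flat_grid, make_strip_model, place_tangential
from .ctsim import merge_artifacts, simulate_scenario_artifacts
from .depth import bend_depth_array, make_trajectory, place_depth_array
from .gridfit import FitConfig, FitConvergenceError, fit_to_surface, qc_filter, strip_middle_row
from .localize import (
    localize_kmeans,
    localize_kmedoids,
    match_and_errors,
    threshold_for_level,
    threshold_voxels,
)
from .surface import SurfaceMesh, classify_and_select_seeds

__all__ = [
    "CampaignConfig",
    "GridScenario",
    "named_rng",
    "run_grid_campaign",
    "run_depth_campaign",
    "evaluate_campaign",
    "BUILTIN_LOCALIZERS",
]

# grid size class -> admissible seed curvature classes
DEFAULT_CURVATURE_GATING = {
    "large": ("Low",),
    "medium": ("Low", "Medium"),
    "small": ("Low", "Medium", "High"),
}


def named_rng(master_seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible stream derived from a master seed and a
    stage name (CRC32 of the name keys the stream)."""
    return np.random.default_rng([int(master_seed), zlib.crc32(name.encode())])


def _size_class(entry) -> str:
    n = entry.n_rows * entry.n_cols
    if entry.kind == "strip":
        return "small"
    if n >= 128:
        return "large"
    if n >= 32:
        return "medium"
    return "small"


@dataclass
class CampaignConfig:
    array_labels: list
    n_seeds: int = 5
    rotations_deg: tuple = tuple(range(0, 360, 30))
    noise_levels: tuple = ()
    master_seed: int = 0
    qc_threshold: float = 0.05
    min_seed_spacing_mm: float = 15.0
    curvature_gating: dict = field(default_factory=lambda: dict(DEFAULT_CURVATURE_GATING))
    curved_depth_fraction: float = 0.01


@dataclass
class GridScenario:
    scenario_id: str
    label: str
    seed_index: int
    rotation_deg: float
    fitted: object  # FittedArray (reported contacts for strips)
    accepted: bool
    reject_reason: str = ""


def run_grid_campaign(config: CampaignConfig, mesh: SurfaceMesh):
    """Place, fit and QC every eligible (seed x array x rotation) scenario.

    Returns ``(scenarios, summary)``: the scenario list (rejected ones kept
    with their reason) and a one-row-per-scenario DataFrame.
    """
    seeds = classify_and_select_seeds(
        mesh,
        n_seeds=config.n_seeds,
        rng_seed=int(named_rng(config.master_seed, "seeds").integers(2**31)),
        min_spacing_mm=config.min_seed_spacing_mm,
    )
    scenarios: list[GridScenario] = []
    rows = []
    for label in config.array_labels:
        entry = ARRAY_CATALOG[label]
        if entry.kind == "depth":
            raise ValueError(f"{label} is a depth array; use run_depth_campaign")
        allowed = config.curvature_gating[_size_class(entry)]
        if entry.kind == "strip":
            model = make_strip_model(entry.n_cols, entry.ied_mm)
        else:
            model = make_flat_grid(entry.n_rows, entry.n_cols, entry.ied_mm)
        fit_config = FitConfig.for_model(model)
        for s_idx, seed in enumerate(seeds):
            if seed.curvature_class not in allowed:
                continue
            for rot in config.rotations_deg:
                sid = f"{label}_s{s_idx}_r{int(rot)}"
                accepted, reason, fitted = True, "", None
                try:
                    init = place_tangential(model, mesh, seed, rot)
                    fitted = fit_to_surface(init, model, mesh, fit_config)
                    ok, offending = qc_filter(fitted, config.qc_threshold)
                    if not ok:
                        accepted = False
                        reason = (
                            f"deformation>{config.qc_threshold:.0%} on "
                            f"{len(offending)} edges"
                        )
                    elif entry.kind == "strip":
                        fitted = strip_middle_row(fitted)
                except FitConvergenceError as exc:
                    accepted, reason = False, f"no convergence: {exc}"
                scenarios.append(
                    GridScenario(sid, label, s_idx, float(rot), fitted, accepted, reason)
                )
                rows.append(
                    {
                        "scenario_id": sid,
                        "label": label,
                        "seed_index": s_idx,
                        "rotation_deg": rot,
                        "curvature_class": seed.curvature_class,
                        "accepted": accepted,
                        "reject_reason": reason,
                    }
                )
    summary = pd.DataFrame(rows)
    return scenarios, summary


def run_depth_campaign(config: CampaignConfig, mesh: SurfaceMesh):
    """Depth scenarios: entry seeds x catalog entries x straight/curved."""
    seeds = classify_and_select_seeds(
        mesh,
        n_seeds=config.n_seeds,
        rng_seed=int(named_rng(config.master_seed, "seeds").integers(2**31)),
        min_spacing_mm=config.min_seed_spacing_mm,
    )
    placement_rng = named_rng(config.master_seed, "placement")
    arrays, rows = [], []
    for label in config.array_labels:
        entry = ARRAY_CATALOG[label]
        if entry.kind != "depth":
            raise ValueError(f"{label} is not a depth array")
        for s_idx, seed in enumerate(seeds):
            traj = make_trajectory(mesh, seed)
            for curved in (False, True):
                sid = f"{label}_s{s_idx}_{'curved' if curved else 'straight'}"
                arr = place_depth_array(
                    traj, entry.n_cols, entry.ied_mm, rng_seed=placement_rng
                )
                if curved:
                    arr = bend_depth_array(
                        arr, config.curved_depth_fraction, rng_seed=placement_rng
                    )
                arr.provenance["scenario_id"] = sid
                arrays.append(arr)
                rows.append(
                    {
                        "scenario_id": sid,
                        "label": label,
                        "seed_index": s_idx,
                        "curved": curved,
                        "n_contacts": arr.n_contacts,
                    }
                )
    return arrays, pd.DataFrame(rows)


def _localizer_kmeans(coords, intensities, k, rng_seed):
    return localize_kmeans(coords, intensities, k, rng_seed)


def _localizer_kmedoids(coords, intensities, k, rng_seed):
    return localize_kmedoids(coords, intensities, k, rng_seed)


BUILTIN_LOCALIZERS = {
    "kmeans": _localizer_kmeans,
    "kmedoids": _localizer_kmedoids,
}


def evaluate_campaign(
    scenarios: list[GridScenario],
    noise_levels,
    localizers: dict | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Benchmark localization plug-ins on accepted scenarios.

    For each accepted scenario and noise level: simulate artifacts on a
    fresh shared lattice, merge and threshold the voxels (schedule 0.6 at
    level 1 down to 0.25 at level 12), run every localizer with the true
    contact count, and score errors against ground truth. Plug-in failures
    are isolated per scenario. Returns a long-format table with one row per
    (scenario, noise level, method).
    """
    localizers = localizers if localizers is not None else BUILTIN_LOCALIZERS
    lattice_rng = named_rng(master_seed, "lattice")
    cluster_rng = named_rng(master_seed, "clustering")
    rows = []
    for scen in scenarios:
        if not scen.accepted or scen.fitted is None:
            continue
        fitted = scen.fitted
        truth = fitted.reported_coords
        ied = fitted.model.ied_mm
        k = len(truth)
        for level in noise_levels:
            arts = simulate_scenario_artifacts([fitted], level, lattice_seed=lattice_rng)
            table = merge_artifacts(arts)
            thr = threshold_for_level(level)
            try:
                coords, inten = threshold_voxels(
                    table[["x", "y", "z"]].to_numpy(),
                    table["intensity"].to_numpy(),
                    thr,
                )
            except ValueError as exc:
                rows.append(
                    {
                        "scenario_id": scen.scenario_id,
                        "noise_level": level,
                        "ied_mm": ied,
                        "method": "-",
                        "error": str(exc),
                    }
                )
                continue
            seed_i = int(cluster_rng.integers(2**31))  # shared across methods
            for name, fn in localizers.items():
                try:
                    found = fn(coords, inten, k, seed_i)
                    res = match_and_errors(found, truth, ied, method=name)
                    rows.append(
                        {
                            "scenario_id": scen.scenario_id,
                            "noise_level": level,
                            "ied_mm": ied,
                            "method": name,
                            "median_error_fraction": res.median_error_fraction,
                            "max_error_fraction": res.max_error_fraction,
                            "errors_mm": res.per_electrode_error_mm,
                        }
                    )
                except Exception as exc:  # plug-in crash isolated
                    rows.append(
                        {
                            "scenario_id": scen.scenario_id,
                            "noise_level": level,
                            "ied_mm": ied,
                            "method": name,
                            "error": str(exc),
                        }
                    )
    return pd.DataFrame(rows)
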