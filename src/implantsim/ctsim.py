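"""Synthetic thresholded-CT voxel artifacts with calibrated noise.

Each metallic contact produces a cluster of bright voxels in a CT volume.
After thresholding these clusters are approximately ellipsoidal with
intensity decaying from the centre, modelled here as

    intensity(x, y, z) = 1 - r,   r = sqrt((x/a)^2 + (y/b)^2 + (z/c)^2)

in an electrode-local frame whose z-axis is the contact normal (grids /
strips) or trajectory direction (depths). Voxels are sampled on a shared
0.5 mm lattice with a random origin and orientation per scenario (the
patient's head pose in the scanner), within a 10 mm cube per electrode.

Noise is a sum of spatially correlated (smoothed Gaussian field, rescaled
to its target pointwise variance) and uncorrelated Gaussian components with
variance ratio 20:1; twelve total-variance levels run geometrically from
0.2 to 2.2. Voxels with negative noisy intensity are pruned last, so noise
can both carve the core cluster and scatter detached voxels around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._geometry import orthonormal_basis, random_rotation

__all__ = [
    "EllipsoidSpec",
    "VoxelLattice",
    "NoiseSpec",
    "VoxelArtifact",
    "SEMIAXES_CATALOG",
    "semiaxes_for",
    "clean_artifact",
    "noise_level_variances",
    "add_noise",
    "sample_noise_field",
    "simulate_scenario_artifacts",
    "merge_artifacts",
]

CORR_TO_UNCORR_RATIO = 20.0
N_NOISE_LEVELS = 12
NOISE_VARIANCE_LO = 0.2
NOISE_VARIANCE_HI = 2.2


@dataclass(frozen=True)
class EllipsoidSpec:
    """Semi-axes (mm) of the artifact ellipsoid in the electrode frame."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("semi-axes must be positive")

    def scaled_radius(self, local: np.ndarray) -> np.ndarray:
        return np.sqrt(
            (local[:, 0] / self.a) ** 2
            + (local[:, 1] / self.b) ** 2
            + (local[:, 2] / self.c) ** 2
        )


# semi-axes by (electrode type, IED); strips share grid values
SEMIAXES_CATALOG: dict[tuple[str, float], EllipsoidSpec] = {
    ("grid", 10.0): EllipsoidSpec(2.2, 2.2, 1.5),
    ("grid", 5.0): EllipsoidSpec(2.2, 2.2, 1.5),
    ("grid", 3.0): EllipsoidSpec(1.1, 1.1, 1.0),
    ("depth", 10.0): EllipsoidSpec(1.25, 1.25, 1.75),
    ("depth", 5.0): EllipsoidSpec(1.25, 1.25, 1.75),
    ("depth", 3.0): EllipsoidSpec(1.1, 1.1, 1.5),
}


def semiaxes_for(electrode_type: str, ied_mm: float) -> EllipsoidSpec:
    """Catalog lookup of artifact semi-axes; strips use grid values and
    off-catalog IEDs map to the nearest catalog IED with a warning."""
    kind = "grid" if electrode_type in {"grid", "strip"} else "depth"
    if electrode_type not in {"grid", "strip", "depth"}:
        raise ValueError(f"unknown electrode type {electrode_type!r}")
    ieds = np.array([3.0, 5.0, 10.0])
    if ied_mm not in ieds:
        nearest = float(ieds[np.argmin(np.abs(ieds - ied_mm))])
        warnings.warn(
            f"IED {ied_mm} mm not in catalog; using nearest catalog IED {nearest} mm"
        )
        ied_mm = nearest
    return SEMIAXES_CATALOG[(kind, float(ied_mm))]


@dataclass
class VoxelLattice:
    """Shared sampling lattice: world = origin + orientation @ (spacing * ijk)."""

    origin: np.ndarray
    orientation: np.ndarray  # orthonormal 3x3
    spacing_mm: float = 0.5
    extent_mm: float = 10.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if not np.allclose(
            self.orientation @ self.orientation.T, np.eye(3), atol=1e-9
        ):
            raise ValueError("orientation must be orthonormal")

    @classmethod
    def random(cls, rng: np.random.Generator, spacing_mm=0.5, extent_mm=10.0):
        R = random_rotation(rng)
        origin = rng.uniform(0.0, spacing_mm, size=3)
        return cls(origin=origin, orientation=R, spacing_mm=spacing_mm,
                   extent_mm=extent_mm)

    def cube_around(self, center: np.ndarray):
        """Integer lattice indices and world coordinates of the cube of
        side ``extent_mm`` centred (on-lattice) at ``center``."""
        c_lat = self.orientation.T @ (np.asarray(center, dtype=float) - self.origin)
        c_lat /= self.spacing_mm
        half = self.extent_mm / 2.0 / self.spacing_mm
        axes = [
            np.arange(int(np.ceil(c - half)), int(np.floor(c + half)) + 1)
            for c in c_lat
        ]
        I, J, K = np.meshgrid(*axes, indexing="ij")
        ijk = np.column_stack([I.ravel(), J.ravel(), K.ravel()])
        world = (self.spacing_mm * ijk) @ self.orientation.T + self.origin
        shape = tuple(len(a) for a in axes)
        return ijk, world, shape


@dataclass(frozen=True)
class NoiseSpec:
    """Total noise variance split into correlated and uncorrelated parts."""

    level_index: int
    sigma2_total: float
    sigma2_corr: float
    sigma2_uncorr: float
    corr_to_uncorr_ratio: float = CORR_TO_UNCORR_RATIO
    rng_seed: int = 0

    @classmethod
    def for_level(
        cls,
        level_index: int,
        rng_seed: int = 0,
        n_levels: int = N_NOISE_LEVELS,
        lo: float = NOISE_VARIANCE_LO,
        hi: float = NOISE_VARIANCE_HI,
        ratio: float = CORR_TO_UNCORR_RATIO,
    ) -> "NoiseSpec":
        if not 1 <= level_index <= n_levels:
            raise ValueError(f"level index must be in 1..{n_levels}")
        total = noise_level_variances(n_levels, lo, hi)[level_index - 1]
        uncorr = total / (ratio + 1.0)
        corr = total - uncorr  # sum exact by construction
        return cls(
            level_index=level_index,
            sigma2_total=total,
            sigma2_corr=corr,
            sigma2_uncorr=uncorr,
            corr_to_uncorr_ratio=ratio,
            rng_seed=rng_seed,
        )


def noise_level_variances(
    n_levels: int = N_NOISE_LEVELS,
    lo: float = NOISE_VARIANCE_LO,
    hi: float = NOISE_VARIANCE_HI,
) -> np.ndarray:
    """Geometric ladder of total noise variances from lo to hi inclusive."""
    if n_levels < 2 or not 0 < lo < hi:
        raise ValueError("need n_levels >= 2 and 0 < lo < hi")
    return lo * (hi / lo) ** (np.arange(n_levels) / (n_levels - 1))


@dataclass
class VoxelArtifact:
    """One electrode's cluster of lattice voxels with intensities.

    ``voxel_coords`` / ``intensities`` hold the emitted support: the open
    ellipsoid (r < 1) for a clean artifact, the non-negative noisy voxels
    after noise. The full sampling cube is retained privately so noise can
    be applied over it (noise precedes the final pruning and may lift
    voxels outside the clean support above zero).
    """

    electrode_id: str
    center: np.ndarray
    axis: np.ndarray  # local z direction (unit)
    spec: EllipsoidSpec
    lattice: VoxelLattice
    voxel_ijk: np.ndarray
    voxel_coords: np.ndarray
    intensities: np.ndarray
    noise: NoiseSpec | None = None
    _cube_ijk: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _cube_coords: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _cube_clean: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _cube_shape: tuple = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_coords)


def clean_artifact(
    center: np.ndarray,
    axis: np.ndarray,
    spec: EllipsoidSpec,
    lattice: VoxelLattice,
    electrode_id: str = "e0",
) -> VoxelArtifact:
    """Noise-free artifact: lattice voxels in the electrode's cube with
    intensity 1 - r, support restricted to the open ellipsoid r < 1."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    center = np.asarray(center, dtype=float)
    ijk, world, shape = lattice.cube_around(center)
    e1, e2 = orthonormal_basis(axis)
    frame = np.stack([e1, e2, axis])  # rows: local x, y, z
    local = (world - center) @ frame.T
    r = spec.scaled_radius(local)
    clean = 1.0 - r
    support = r < 1.0
    return VoxelArtifact(
        electrode_id=electrode_id,
        center=center,
        axis=axis,
        spec=spec,
        lattice=lattice,
        voxel_ijk=ijk[support],
        voxel_coords=world[support],
        intensities=clean[support],
        noise=None,
        _cube_ijk=ijk,
        _cube_coords=world,
        _cube_clean=clean,
        _cube_shape=shape,
    )


def sample_noise_field(
    shape: tuple,
    noise: NoiseSpec,
    rng: np.random.Generator,
    kernel_fwhm_mm: float = 1.0,
    spacing_mm: float = 0.5,
) -> np.ndarray:
    """Correlated + uncorrelated Gaussian noise field on a voxel grid.

    The correlated component convolves white noise with an isotropic
    Gaussian kernel (FWHM in mm; periodic boundaries preserve
    stationarity) and is rescaled to pointwise variance sigma2_corr; the
    uncorrelated component is i.i.d. N(0, sigma2_uncorr).
    """
    sigma_vox = kernel_fwhm_mm / spacing_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    white = rng.normal(size=shape)
    corr = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = corr.std()
    if sd > 0 and noise.sigma2_corr > 0:
        corr *= np.sqrt(noise.sigma2_corr) / sd
    else:
        corr[:] = 0.0
    uncorr = rng.normal(scale=np.sqrt(noise.sigma2_uncorr), size=shape) \
        if noise.sigma2_uncorr > 0 else np.zeros(shape)
    return corr + uncorr


def add_noise(
    artifact: VoxelArtifact,
    noise: NoiseSpec,
    kernel_fwhm_mm: float = 1.0,
    rng: np.random.Generator | None = None,
) -> VoxelArtifact:
    """Add calibrated noise over the artifact's sampling cube, then prune.

    Noise is applied to every cube voxel's clean intensity (Eq.-style
    1 - r, negative outside the ellipsoid); voxels with noisy intensity
    below zero are removed last, so high noise can both erode the cluster
    and produce detached voxels around it. Reproducible given the seed.
    """
    if artifact._cube_clean is None or len(artifact._cube_clean) == 0:
        return artifact
    if noise.sigma2_total == 0:
        return replace(artifact, noise=noise)
    rng = rng if rng is not None else np.random.default_rng(noise.rng_seed)
    field_ = sample_noise_field(
        artifact._cube_shape, noise, rng, kernel_fwhm_mm, artifact.lattice.spacing_mm
    )
    noisy = artifact._cube_clean + field_.ravel()
    keep = noisy >= 0.0
    return VoxelArtifact(
        electrode_id=artifact.electrode_id,
        center=artifact.center,
        axis=artifact.axis,
        spec=artifact.spec,
        lattice=artifact.lattice,
        voxel_ijk=artifact._cube_ijk[keep],
        voxel_coords=artifact._cube_coords[keep],
        intensities=noisy[keep],
        noise=noise,
        _cube_ijk=artifact._cube_ijk,
        _cube_coords=artifact._cube_coords,
        _cube_clean=artifact._cube_clean,
        _cube_shape=artifact._cube_shape,
    )


def simulate_scenario_artifacts(
    arrays: list,
    noise_level: int | None,
    lattice_seed: int | np.random.Generator = 0,
    spacing_mm: float = 0.5,
    extent_mm: float = 10.0,
    kernel_fwhm_mm: float = 1.0,
) -> list[VoxelArtifact]:
    """Artifacts for every electrode of a scenario on one shared lattice.

    ``arrays`` mixes grid/strip fits (surface normals as local z-axis) and
    depth arrays (trajectory direction as local z-axis); the semi-axis
    catalog is keyed by electrode type and IED. ``noise_level`` of None or
    0 yields clean artifacts; levels 1..12 add the corresponding calibrated
    noise, one independent draw per electrode from the scenario stream.
    """
    from .depth import DepthArray
    from .gridfit import FittedArray

    rng = (
        lattice_seed
        if isinstance(lattice_seed, np.random.Generator)
        else np.random.default_rng(lattice_seed)
    )
    lattice = VoxelLattice.random(rng, spacing_mm=spacing_mm, extent_mm=extent_mm)
    noise = (
        NoiseSpec.for_level(noise_level) if noise_level else None
    )

    artifacts: list[VoxelArtifact] = []
    for a_idx, arr in enumerate(arrays):
        if isinstance(arr, FittedArray):
            coords = arr.reported_coords
            axes = arr.reported_normals
            spec = semiaxes_for(arr.model.array_kind, arr.model.ied_mm)
        elif isinstance(arr, DepthArray):
            coords = arr.contact_coords
            axes = np.tile(arr.main_axis, (len(coords), 1))
            spec = semiaxes_for("depth", arr.ied_mm)
        elif isinstance(arr, dict):  # overlay-style: explicit coords+normals
            coords = np.asarray(arr["coords"])
            axes = np.asarray(arr["normals"])
            spec = semiaxes_for(arr.get("kind", "grid"), arr["ied_mm"])
        else:
            raise TypeError(f"unsupported array object {type(arr)!r}")
        for e_idx in range(len(coords)):
            art = clean_artifact(
                coords[e_idx],
                axes[e_idx],
                spec,
                lattice,
                electrode_id=f"a{a_idx}_e{e_idx}",
            )
            if noise is not None:
                art = add_noise(art, noise, kernel_fwhm_mm, rng=rng)
            artifacts.append(art)
    return artifacts


def merge_artifacts(artifacts: list[VoxelArtifact]):
    """Merged sparse voxel table; duplicate lattice sites keep the maximum
    intensity (adjacent metal artifacts merge and brighten in real CT)."""
    import pandas as pd

    frames = [
        pd.DataFrame(
            {
                "electrode_id": a.electrode_id,
                "i": a.voxel_ijk[:, 0],
                "j": a.voxel_ijk[:, 1],
                "k": a.voxel_ijk[:, 2],
                "x": a.voxel_coords[:, 0],
                "y": a.voxel_coords[:, 1],
                "z": a.voxel_coords[:, 2],
                "intensity": a.intensities,
            }
        )
        for a in artifacts
        if a.n_voxels
    ]
    if not frames:
        return pd.DataFrame(
            columns=["electrode_id", "i", "j", "k", "x", "y", "z", "intensity"]
        )
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values("intensity", ascending=False, kind="stable")
    table = table.drop_duplicates(subset=["i", "j", "k"], keep="first")
    return table.reset_index(drop=True)
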