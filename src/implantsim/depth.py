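"""Depth (SEEG-style) electrode placement along envelope-orthogonal trajectories.

A trajectory enters at a seed point on the envelope and runs along the
inward normal (surgical practice drills orthogonally to the skull). Contacts
are spaced at the IED from a target point chosen by one of two strategies:
a random feasible target when the array is shorter than the intersected
chord, or the deepest chord point (trimming contacts that would fall
outside) when it is longer. An optional arc bend displaces contacts in a
random-roll plane through the main axis following a symmetric Lanczos
window, peak deflection a fixed fraction (default 1%) of array length.

Contacts are indexed tip-first: index 0 is the deepest (target) contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import orthonormal_basis, rotation_about_axis
from .surface import SeedPoint, SurfaceMesh

__all__ = [
    "DepthTrajectory",
    "DepthArray",
    "make_trajectory",
    "place_depth_array",
    "bend_depth_array",
    "bending_profile",
    "lanczos_window",
]


@dataclass
class DepthTrajectory:
    entry_point: np.ndarray
    direction: np.ndarray  # inward unit vector (anti-parallel to outward normal)
    chord_length_mm: float

    def __post_init__(self):
        self.entry_point = np.asarray(self.entry_point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.chord_length_mm <= 0:
            raise ValueError("chord length must be positive")


@dataclass
class DepthArray:
    """Ordered contact coordinates, deepest (target) contact first."""

    contact_coords: np.ndarray
    ied_mm: float
    curved: bool = False
    max_deflection_fraction: float = 0.0
    trajectory: DepthTrajectory | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.contact_coords = np.asarray(self.contact_coords, dtype=float)

    @property
    def n_contacts(self) -> int:
        return len(self.contact_coords)

    @property
    def main_axis(self) -> np.ndarray:
        """Unit vector from the deepest to the entry-most contact."""
        v = self.contact_coords[-1] - self.contact_coords[0]
        return v / np.linalg.norm(v)

    @property
    def length_mm(self) -> float:
        return float(
            np.linalg.norm(self.contact_coords[-1] - self.contact_coords[0])
        )


def make_trajectory(mesh: SurfaceMesh, entry: SeedPoint) -> DepthTrajectory:
    """Trajectory orthogonal to the envelope at an entry seed point.

    Direction is the negated outward normal; the chord length is the
    distance from the entry point to the farthest ray-mesh intersection
    along that direction.
    """
    if entry.vertex_index is not None:
        normal = mesh.vertex_normals[entry.vertex_index]
    else:
        _, _, tri = mesh.closest_point(entry.position)
        normal = np.asarray(mesh.tm.face_normals[tri], dtype=float)
    normal = normal / np.linalg.norm(normal)
    direction = -normal
    ts = mesh.ray_intersections(entry.position, direction)
    ts = ts[ts > 1e-6]
    if len(ts) == 0:
        raise ValueError("trajectory exits the envelope immediately (tangent entry)")
    return DepthTrajectory(
        entry_point=entry.position,
        direction=direction,
        chord_length_mm=float(ts.max()),
    )


def place_depth_array(
    traj: DepthTrajectory,
    n_contacts: int,
    ied_mm: float,
    rng_seed: int | np.random.Generator = 0,
) -> DepthArray:
    """Distribute contacts uniformly along the trajectory.

    With array length L = (n_contacts - 1) * IED and chord C:

    * L <= C: the target (deepest contact) depth is drawn uniformly from
      [L, C], keeping all contacts inside the envelope;
    * L > C: the target sits at the chord end and contacts shallower than
      the entry surface are removed, leaving floor(C / IED) + 1 contacts.
    """
    if n_contacts < 2:
        raise ValueError("need at least 2 contacts")
    if ied_mm <= 0:
        raise ValueError("IED must be positive")
    chord = traj.chord_length_mm
    if chord < ied_mm:
        raise ValueError(
            f"chord ({chord:.2f} mm) shorter than one IED ({ied_mm} mm): "
            "cannot place 2 contacts"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    L = (n_contacts - 1) * ied_mm
    if L <= chord:
        target_depth = float(rng.uniform(L, chord)) if L < chord else L
        kept = n_contacts
    else:
        target_depth = chord
        kept = int(np.floor(chord / ied_mm)) + 1
    depths = target_depth - ied_mm * np.arange(kept)  # tip-first
    coords = traj.entry_point[None, :] + depths[:, None] * traj.direction[None, :]
    return DepthArray(
        contact_coords=coords,
        ied_mm=float(ied_mm),
        curved=False,
        trajectory=traj,
        provenance={"requested_contacts": n_contacts, "target_depth_mm": target_depth},
    )


def lanczos_window(t: np.ndarray) -> np.ndarray:
    """Symmetric Lanczos window on [0, 1]: sinc(2t - 1), zero at the ends,
    peak 1 at t = 0.5."""
    return np.sinc(2.0 * np.asarray(t, dtype=float) - 1.0)


def bend_depth_array(
    array: DepthArray,
    max_deflection_fraction: float = 0.01,
    rng_seed: int | np.random.Generator = 0,
) -> DepthArray:
    """Arc-shaped bend of a straight array via the symmetric Lanczos window.

    Contacts are displaced orthogonally to the main axis inside a plane
    containing the axis at a uniformly random roll angle; the displacement
    profile is the Lanczos window scaled so its peak equals
    ``max_deflection_fraction`` times the total array length. Endpoints stay
    fixed.
    """
    if max_deflection_fraction < 0:
        raise ValueError("deflection fraction must be non-negative")
    if max_deflection_fraction > 0.05:
        raise ValueError("deflection fraction above 5% is not supported")
    coords = array.contact_coords
    n = len(coords)
    if n < 3 or max_deflection_fraction == 0:
        return DepthArray(
            contact_coords=coords.copy(),
            ied_mm=array.ied_mm,
            curved=max_deflection_fraction > 0,
            max_deflection_fraction=max_deflection_fraction,
            trajectory=array.trajectory,
            provenance=dict(array.provenance),
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    axis = array.main_axis
    L = array.length_mm
    e1, _ = orthonormal_basis(axis)
    roll = float(rng.uniform(0.0, 2.0 * np.pi))
    offset_dir = rotation_about_axis(axis, roll) @ e1

    t = np.arange(n) / (n - 1)
    disp = max_deflection_fraction * L * lanczos_window(t)
    bent = coords + disp[:, None] * offset_dir[None, :]
    return DepthArray(
        contact_coords=bent,
        ied_mm=array.ied_mm,
        curved=True,
        max_deflection_fraction=max_deflection_fraction,
        trajectory=array.trajectory,
        provenance=dict(array.provenance, roll_rad=roll),
    )


def bending_profile(array: DepthArray):
    """Per-contact orthogonal distance to the main axis, normalized by length.

    Returns ``(profile, peak_position)`` where ``peak_position`` is the
    normalized distance (0..1) of the largest deflection from the deepest
    contact.
    """
    coords = array.contact_coords
    if len(coords) < 3:
        raise ValueError("need at least 3 contacts for a bending profile")
    first, last = coords[0], coords[-1]
    L = np.linalg.norm(last - first)
    if L < 1e-12:
        raise ValueError("first and last contacts coincide")
    axis = (last - first) / L
    rel = coords - first
    along = rel @ axis
    ortho = rel - along[:, None] * axis[None, :]
    profile = np.linalg.norm(ortho, axis=1) / L
    peak_position = float(along[np.argmax(profile)] / L)
    return profile, peak_position
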