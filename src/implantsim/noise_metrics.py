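"""Entropy-based quantification of CT-artifact noise.

The noise level of an array's artifacts is fingerprinted without ground
truth: each electrode's voxels are centred and axis-aligned, reduced to a
2D intensity-radius histogram (20 x 20 bins: radius 0-5 mm in 0.25 mm
steps, normalized intensity 0-1 in 0.05 steps, 2.5-97.5 intensity
percentile band), all within-array histogram pairs are cross-correlated in
2D, and the Shannon entropy (nats) of each normalized cross-correlation
image is averaged. Consistent (low-noise) artifacts give peaky
cross-correlations and low entropy; noisy arrays give flat ones and high
entropy. Entropy also depends on artifact size, so estimates are normalized
by subtracting the mean of their (electrode type, IED) size group. A real
or held-out array is matched to the best-fitting simulated noise level by
normalized mean histogram correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal, stats

from ._geometry import orthonormal_basis
from .ctsim import VoxelArtifact

__all__ = [
    "IntensityRadiusHistogram",
    "ArrayNoiseEstimate",
    "align_artifact",
    "intensity_radius_histogram",
    "xcorr2",
    "entropy_of_xcorr",
    "array_noise_entropy",
    "normalize_entropies",
    "best_fit_simulation",
    "entropy_regression",
]

RADIUS_EDGES = np.arange(0.0, 5.0 + 0.25 / 2, 0.25)  # 20 bins
INTENSITY_EDGES = np.arange(0.0, 1.0 + 0.05 / 2, 0.05)  # 20 bins
PERCENTILE_BAND = (2.5, 97.5)


@dataclass
class IntensityRadiusHistogram:
    counts: np.ndarray  # (20 radius bins, 20 intensity bins) ints
    radius_edges: np.ndarray
    intensity_edges: np.ndarray
    n_voxels_used: int


@dataclass
class ArrayNoiseEstimate:
    mean_entropy: float  # nats
    size_group: str
    n_pairs: int
    normalized_entropy: float = np.nan


def align_artifact(artifact: VoxelArtifact | tuple, axis: np.ndarray):
    """Centre an artifact at its intensity-weighted centroid and rotate its
    principal axis onto +z (rigid transform; distances preserved).

    Accepts a :class:`VoxelArtifact` or a ``(coords, intensities)`` pair;
    returns ``(aligned_coords, intensities)``.
    """
    if isinstance(artifact, VoxelArtifact):
        coords, intensities = artifact.voxel_coords, artifact.intensities
    else:
        coords, intensities = artifact
    coords = np.asarray(coords, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if len(coords) == 0:
        return coords.copy(), intensities.copy()
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    centroid = (intensities[:, None] * coords).sum(axis=0) / intensities.sum()
    e1, e2 = orthonormal_basis(axis)
    R = np.stack([e1, e2, axis])  # maps axis -> +z
    return (coords - centroid) @ R.T, intensities.copy()


def intensity_radius_histogram(coords, intensities) -> IntensityRadiusHistogram:
    """Bivariate histogram of radius (to origin) vs intensity.

    Intensities outside the artifact's own 2.5-97.5 percentile band are
    excluded before binning; bins are half-open with the last bin closed
    (``numpy.histogram2d`` convention). Raises if nothing survives.
    """
    coords = np.asarray(coords, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if not np.all(np.isfinite(intensities)):
        raise ValueError("intensities must be finite")
    if len(coords):
        lo, hi = np.percentile(intensities, PERCENTILE_BAND)
        keep = (intensities >= lo) & (intensities <= hi)
        coords, intensities = coords[keep], intensities[keep]
    if len(coords) == 0:
        raise ValueError("no voxels survive the percentile exclusion")
    radius = np.linalg.norm(coords, axis=1)
    counts, _, _ = np.histogram2d(
        radius, intensities, bins=[RADIUS_EDGES, INTENSITY_EDGES]
    )
    return IntensityRadiusHistogram(
        counts=counts.astype(int),
        radius_edges=RADIUS_EDGES.copy(),
        intensity_edges=INTENSITY_EDGES.copy(),
        n_voxels_used=int(counts.sum()),
    )


def xcorr2(
    h1: IntensityRadiusHistogram | np.ndarray, h2: IntensityRadiusHistogram | np.ndarray
) -> np.ndarray:
    """Full 2D discrete cross-correlation of two histogram count matrices."""
    a = h1.counts if isinstance(h1, IntensityRadiusHistogram) else np.asarray(h1)
    b = h2.counts if isinstance(h2, IntensityRadiusHistogram) else np.asarray(h2)
    if a.shape != b.shape:
        raise ValueError("histograms must share bin geometry")
    return signal.correlate(a.astype(float), b.astype(float), mode="full", method="direct")


def entropy_of_xcorr(xc: np.ndarray) -> float:
    """Shannon entropy (nats) of a cross-correlation image normalized to a
    probability distribution; zero cells contribute zero."""
    xc = np.asarray(xc, dtype=float)
    if np.any(xc < 0):
        raise ValueError("cross-correlation must be non-negative")
    total = xc.sum()
    if total == 0:
        raise ValueError("all-zero cross-correlation")
    p = xc.ravel() / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def array_noise_entropy(
    artifacts: list,
    axes: np.ndarray,
    size_group: str = "",
    min_electrodes: int = 2,
) -> ArrayNoiseEstimate:
    """Mean pairwise cross-correlation entropy of an array's artifacts.

    ``min_electrodes`` enforces the usability rule (grids with fewer than
    12 electrodes are discarded from noise estimation because edge-heavy
    layouts degrade the normal estimates).
    """
    if len(artifacts) < max(min_electrodes, 2):
        raise ValueError(
            f"need at least {max(min_electrodes, 2)} artifacts, got {len(artifacts)}"
        )
    hists = []
    for art, ax in zip(artifacts, np.atleast_2d(axes)):
        coords, inten = align_artifact(art, ax)
        hists.append(intensity_radius_histogram(coords, inten))
    entropies = _pairwise_xcorr_entropies(hists)
    return ArrayNoiseEstimate(
        mean_entropy=float(np.mean(entropies)),
        size_group=size_group,
        n_pairs=len(entropies),
    )


def _pairwise_xcorr_entropies(hists: list[IntensityRadiusHistogram]) -> np.ndarray:
    """Entropies of all pairwise 2D cross-correlations, FFT-accelerated.

    The circular FFT correlation on the zero-padded (39 x 39) grid is the
    full linear cross-correlation up to a cell permutation, which entropy
    ignores; negatives from floating-point round-off are clipped.
    """
    counts = np.stack([h.counts for h in hists]).astype(float)
    shape = (2 * counts.shape[1] - 1, 2 * counts.shape[2] - 1)
    F = np.fft.rfft2(counts, s=shape)
    out = []
    for i, j in combinations(range(len(counts)), 2):
        xc = np.fft.irfft2(F[i] * np.conj(F[j]), s=shape)
        np.clip(xc, 0.0, None, out=xc)
        out.append(entropy_of_xcorr(xc))
    return np.asarray(out)


def normalize_entropies(estimates: list[ArrayNoiseEstimate]) -> list[ArrayNoiseEstimate]:
    """Subtract each size group's mean entropy (in place; returns the list)."""
    groups: dict[str, list[ArrayNoiseEstimate]] = {}
    for e in estimates:
        groups.setdefault(e.size_group, []).append(e)
    for members in groups.values():
        mean = float(np.mean([e.mean_entropy for e in members]))
        for e in members:
            e.normalized_entropy = e.mean_entropy - mean
    return estimates


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def best_fit_simulation(
    target_hists: list[IntensityRadiusHistogram],
    candidate_sets: dict[int, list[IntensityRadiusHistogram]],
):
    """Best-matching simulated noise level for a target array.

    Score per candidate level = mean Pearson correlation between every
    (target, candidate) histogram pair, normalized by the mean of the full
    within-target correlation matrix (diagonal included, so a candidate set
    that copies the target scores exactly 1). Returns
    ``(best_level, scores_by_level)``.
    """
    if len(target_hists) < 2:
        raise ValueError("need at least 2 target electrodes")
    if not candidate_sets:
        raise ValueError("no candidate sets given")
    n = len(target_hists)
    within = [
        _pearson(h1.counts, h2.counts) for h1, h2 in combinations(target_hists, 2)
    ]
    norm = float(n + 2.0 * np.sum(within)) / n**2
    if norm <= 0:
        norm = 1.0
    scores = {}
    for level, cands in candidate_sets.items():
        cross = [
            _pearson(t.counts, c.counts) for t in target_hists for c in cands
        ]
        scores[level] = float(np.mean(cross)) / norm
    best = max(scores, key=lambda lv: (scores[lv], -lv))
    return best, scores


def entropy_regression(estimates_x, estimates_y):
    """Ordinary least squares y = b0 + b1 * x with an R^2 report.

    Returns ``(slope, intercept, r_squared)``.
    """
    x = np.asarray(estimates_x, dtype=float)
    y = np.asarray(estimates_y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
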