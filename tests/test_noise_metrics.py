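"""Histogram fingerprints, cross-correlation entropy, best-fit matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays as np_arrays

from implantsim.ctsim import NoiseSpec, add_noise, clean_artifact, semiaxes_for, VoxelLattice
from implantsim.noise_metrics import (
    INTENSITY_EDGES,
    RADIUS_EDGES,
    align_artifact,
    array_noise_entropy,
    best_fit_simulation,
    entropy_of_xcorr,
    entropy_regression,
    intensity_radius_histogram,
    normalize_entropies,
    xcorr2,
)


def naive_xcorr2(a, b):
    """O(n^4) textbook definition of the full 2D cross-correlation."""
    n1, m1 = a.shape
    n2, m2 = b.shape
    out = np.zeros((n1 + n2 - 1, m1 + m2 - 1))
    for s in range(-(n2 - 1), n1):
        for t in range(-(m2 - 1), m1):
            acc = 0.0
            for i in range(n2):
                for j in range(m2):
                    if 0 <= i + s < n1 and 0 <= j + t < m1:
                        acc += a[i + s, j + t] * b[i, j]
            out[s + n2 - 1, t + m2 - 1] = acc
    return out


class TestAlign:
    def test_identity_when_already_aligned(self):
        coords = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        inten = np.array([1.0, 1.0])
        out, w = align_artifact((coords, inten), np.array([0.0, 0.0, 1.0]))
        assert np.allclose(out, coords, atol=1e-12)
        assert np.array_equal(w, inten)

    def test_weighted_centroid_at_origin(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(50, 3)) + [5.0, -2.0, 1.0]
        inten = rng.uniform(0.1, 1.0, 50)
        out, w = align_artifact((coords, inten), np.array([0.0, 1.0, 0.0]))
        centroid = (w[:, None] * out).sum(0) / w.sum()
        assert np.abs(centroid).max() < 1e-9

    def test_pairwise_distances_preserved(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(30, 3))
        inten = rng.uniform(0.1, 1.0, 30)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        out, _ = align_artifact((coords, inten), axis)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(coords), pdist(out), atol=1e-9)


class TestHistogram:
    def test_single_voxel_survives_degenerate_percentiles(self):
        h = intensity_radius_histogram(np.array([[0.0, 0.0, 0.0]]), np.array([0.97]))
        assert h.n_voxels_used == 1
        assert h.counts[0, -1] == 1  # radius bin [0, 0.25), top intensity bin

    def test_bin_geometry(self):
        assert len(RADIUS_EDGES) == 21 and len(INTENSITY_EDGES) == 21
        rng = np.random.default_rng(2)
        h = intensity_radius_histogram(
            rng.normal(size=(200, 3)), rng.uniform(0, 1, 200)
        )
        assert h.counts.shape == (20, 20)

    def test_total_equals_surviving_voxel_count_oracle(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=1.5, size=(500, 3))
        inten = rng.uniform(0, 1, 500)
        h = intensity_radius_histogram(coords, inten)
        lo, hi = np.percentile(inten, [2.5, 97.5])
        keep = (inten >= lo) & (inten <= hi)
        radius = np.linalg.norm(coords[keep], axis=1)
        expect = int(np.sum(radius <= 5.0))  # 5 mm is the last (closed) edge
        # values exactly on interior edges are half-open; the count oracle
        # only needs the radial cutoff here because intensities are in [0, 1]
        assert h.n_voxels_used == expect

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="no voxels"):
            intensity_radius_histogram(np.empty((0, 3)), np.empty(0))


class TestXcorr2:
    def test_matches_naive_definition_on_toys(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            a = rng.integers(0, 5, size=(5, 5)).astype(float)
            b = rng.integers(0, 5, size=(5, 5)).astype(float)
            assert np.allclose(xcorr2(a, b), naive_xcorr2(a, b), atol=1e-9)

    def test_delta_self_correlation_single_peak(self):
        d = np.zeros((20, 20))
        d[7, 11] = 3.0
        xc = xcorr2(d, d)
        assert xc.shape == (39, 39)
        assert np.count_nonzero(xc) == 1
        assert xc.max() == pytest.approx(9.0)

    def test_argument_swap_is_coordinate_reflection(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 5, size=(6, 6)).astype(float)
        b = rng.integers(0, 5, size=(6, 6)).astype(float)
        assert np.allclose(xcorr2(a, b), xcorr2(b, a)[::-1, ::-1], atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            xcorr2(np.zeros((5, 5)), np.zeros((4, 5)))


class TestEntropy:
    def test_delta_has_zero_entropy(self):
        m = np.zeros((7, 7))
        m[3, 3] = 5.0
        assert entropy_of_xcorr(m) == 0.0

    def test_uniform_is_log_cell_count(self):
        m = np.ones((13, 11))
        assert entropy_of_xcorr(m) == pytest.approx(np.log(13 * 11))

    def test_matches_direct_formula(self):
        m = np.array([[1.0, 2.0, 0.0, 1.0]] * 4)
        p = m.ravel() / m.sum()
        ref = -sum(pi * np.log(pi) for pi in p if pi > 0)
        assert entropy_of_xcorr(m) == pytest.approx(ref, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            entropy_of_xcorr(np.zeros((3, 3)))

    @given(
        np_arrays(
            float, (6, 6),
            elements=st.floats(min_value=0, max_value=100, allow_nan=False),
        ).filter(lambda m: m.sum() > 0)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_entropy_bounds(self, m):
        h = entropy_of_xcorr(m)
        assert 0.0 <= h <= np.log(m.size) + 1e-12


class TestArrayEntropy:
    def _artifacts(self, n, noise_level, seed):
        rng = np.random.default_rng(seed)
        lat = VoxelLattice.random(rng)
        spec = semiaxes_for("grid", 10.0)
        arts = []
        for i in range(n):
            art = clean_artifact(
                rng.uniform(-40, 40, 3), np.array([0.0, 0.0, 1.0]), spec, lat
            )
            if noise_level:
                art = add_noise(art, NoiseSpec.for_level(noise_level), rng=rng)
            arts.append(art)
        return arts

    def test_mean_over_pairs_matches_sum_count_oracle(self):
        arts = self._artifacts(5, 3, seed=0)
        axes = np.tile([0.0, 0.0, 1.0], (5, 1))
        est = array_noise_entropy(arts, axes)
        assert est.n_pairs == 10
        ents = []
        for i in range(5):
            for j in range(i + 1, 5):
                ci, wi = align_artifact(arts[i], axes[i])
                cj, wj = align_artifact(arts[j], axes[j])
                hi = intensity_radius_histogram(ci, wi)
                hj = intensity_radius_histogram(cj, wj)
                ents.append(entropy_of_xcorr(xcorr2(hi, hj)))
        assert est.mean_entropy == pytest.approx(np.mean(ents), abs=1e-9)

    def test_minimum_electrode_rule(self):
        arts = self._artifacts(5, 1, seed=1)
        axes = np.tile([0.0, 0.0, 1.0], (5, 1))
        with pytest.raises(ValueError, match="at least 12"):
            array_noise_entropy(arts, axes, min_electrodes=12)

    def test_size_group_normalization_subtracts_group_mean(self):
        ests = [
            array_noise_entropy(self._artifacts(4, lv, seed=lv),
                                np.tile([0.0, 0.0, 1.0], (4, 1)),
                                size_group="grid10")
            for lv in (1, 6, 12)
        ]
        normalize_entropies(ests)
        vals = [e.normalized_entropy for e in ests]
        assert np.mean(vals) == pytest.approx(0.0, abs=1e-12)
        assert vals == sorted(vals)  # noisier arrays above the group mean


class TestBestFit:
    def test_exact_copies_score_one_and_win(self):
        rng = np.random.default_rng(6)
        target = [
            intensity_radius_histogram(rng.normal(size=(300, 3)),
                                       rng.uniform(0, 1, 300))
            for _ in range(4)
        ]
        other = [
            intensity_radius_histogram(rng.normal(scale=2.0, size=(300, 3)),
                                       rng.uniform(0, 1, 300))
            for _ in range(4)
        ]
        best, scores = best_fit_simulation(target, {1: target, 2: other})
        assert best == 1
        assert scores[1] == pytest.approx(1.0, abs=1e-9)
        assert scores[2] < scores[1]

    def test_input_validation(self):
        rng = np.random.default_rng(7)
        h = intensity_radius_histogram(rng.normal(size=(50, 3)), rng.uniform(0, 1, 50))
        with pytest.raises(ValueError):
            best_fit_simulation([h], {1: [h]})
        with pytest.raises(ValueError):
            best_fit_simulation([h, h], {})


class TestRegression:
    def test_identity_fit(self):
        x = np.arange(10.0)
        slope, intercept, r2 = entropy_regression(x, x)
        assert (slope, intercept, r2) == (pytest.approx(1.0), pytest.approx(0.0),
                                          pytest.approx(1.0))

    def test_affine_fit(self):
        x = np.arange(10.0)
        slope, intercept, r2 = entropy_regression(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            entropy_regression(np.ones(5), np.arange(5.0))
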