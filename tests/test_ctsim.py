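"""CT artifact synthesis: ellipsoid intensity model, lattice, noise."""

import numpy as np
import pytest

from implantsim.ctsim import (
    EllipsoidSpec,
    NoiseSpec,
    VoxelLattice,
    add_noise,
    clean_artifact,
    merge_artifacts,
    noise_level_variances,
    sample_noise_field,
    semiaxes_for,
    simulate_scenario_artifacts,
)


def identity_lattice():
    return VoxelLattice(origin=np.zeros(3), orientation=np.eye(3))


GRID_SPEC = EllipsoidSpec(2.2, 2.2, 1.5)


class TestSemiaxes:
    @pytest.mark.parametrize(
        "etype,ied,expect",
        [
            ("grid", 10.0, (2.2, 2.2, 1.5)),
            ("grid", 5.0, (2.2, 2.2, 1.5)),
            ("grid", 3.0, (1.1, 1.1, 1.0)),
            ("strip", 10.0, (2.2, 2.2, 1.5)),
            ("depth", 10.0, (1.25, 1.25, 1.75)),
            ("depth", 5.0, (1.25, 1.25, 1.75)),
            ("depth", 3.0, (1.1, 1.1, 1.5)),
        ],
    )
    def test_catalog_values(self, etype, ied, expect):
        spec = semiaxes_for(etype, ied)
        assert (spec.a, spec.b, spec.c) == expect

    def test_off_catalog_ied_maps_to_nearest_with_warning(self):
        with pytest.warns(UserWarning, match="nearest catalog IED"):
            spec = semiaxes_for("grid", 4.0)
        assert spec == semiaxes_for("grid", 3.0)  # 4 is nearer to 3 than to 5

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            semiaxes_for("microwire", 3.0)


class TestCleanArtifact:
    def test_center_voxel_has_intensity_one(self):
        art = clean_artifact(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                             GRID_SPEC, identity_lattice())
        at_center = np.linalg.norm(art.voxel_coords, axis=1) < 1e-9
        assert at_center.sum() == 1
        assert art.intensities[at_center][0] == pytest.approx(1.0)

    def test_boundary_voxel_excluded(self):
        # lattice point exactly at (a, 0, 0) in the electrode frame has r = 1
        lat = VoxelLattice(origin=np.zeros(3), orientation=np.eye(3), spacing_mm=1.1)
        art = clean_artifact(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                             EllipsoidSpec(2.2, 2.2, 1.5), lat)
        r = art.spec.scaled_radius(art.voxel_coords)
        assert np.all(r < 1.0)
        assert not np.any(np.all(np.isclose(art.voxel_coords, [2.2, 0, 0]), axis=1))

    def test_intensity_mass_matches_closed_form_integral(self):
        """Total intensity x voxel volume approximates the exact integral
        of (1 - r) over the ellipsoid, pi*a*b*c/3, averaged over lattice
        offsets."""
        spec = GRID_SPEC
        exact = np.pi * spec.a * spec.b * spec.c / 3.0
        rng = np.random.default_rng(0)
        masses = []
        for _ in range(8):
            lat = VoxelLattice.random(rng)
            art = clean_artifact(rng.normal(size=3), np.array([0.0, 0.0, 1.0]),
                                 spec, lat)
            masses.append(art.intensities.sum() * lat.spacing_mm**3)
        assert np.mean(masses) == pytest.approx(exact, rel=0.05)

    def test_intensity_decreases_radially(self):
        art = clean_artifact(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                             GRID_SPEC, identity_lattice())
        r = art.spec.scaled_radius(art.voxel_coords)
        order = np.argsort(r)
        assert np.all(np.diff(art.intensities[order]) <= 1e-12)

    def test_oblique_axis_alignment(self):
        axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        art = clean_artifact(np.zeros(3), axis, EllipsoidSpec(2.0, 2.0, 0.5),
                             identity_lattice())
        # flat ellipsoid: support thin along the axis, wide across it
        along = np.abs(art.voxel_coords @ axis)
        across = np.linalg.norm(
            art.voxel_coords - np.outer(art.voxel_coords @ axis, axis), axis=1
        )
        assert along.max() < 0.5
        assert across.max() > 1.5


class TestNoiseLadder:
    def test_twelve_level_default_endpoints(self):
        v = noise_level_variances(12, 0.2, 2.2)
        assert v[0] == pytest.approx(0.2)
        assert v[-1] == pytest.approx(2.2)
        assert len(v) == 12

    def test_two_levels_are_the_endpoints(self):
        assert np.allclose(noise_level_variances(2, 0.2, 2.2), [0.2, 2.2])

    def test_constant_consecutive_ratio(self):
        v = noise_level_variances(12, 0.2, 2.2)
        ratios = v[1:] / v[:-1]
        assert np.allclose(ratios, 11.0 ** (1.0 / 11.0))

    def test_spec_variance_split(self):
        for lv in range(1, 13):
            ns = NoiseSpec.for_level(lv)
            assert ns.sigma2_total == ns.sigma2_corr + ns.sigma2_uncorr
            assert ns.sigma2_corr / ns.sigma2_uncorr == pytest.approx(20.0, abs=1e-12)

    def test_invalid_ladder_rejected(self):
        with pytest.raises(ValueError):
            noise_level_variances(1, 0.2, 2.2)
        with pytest.raises(ValueError):
            noise_level_variances(12, 2.2, 0.2)


class TestAddNoise:
    def _clean(self):
        return clean_artifact(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                              GRID_SPEC, identity_lattice())

    def test_zero_variance_leaves_artifact_unchanged(self):
        art = self._clean()
        ns = NoiseSpec(level_index=0, sigma2_total=0.0, sigma2_corr=0.0,
                       sigma2_uncorr=0.0)
        noisy = add_noise(art, ns)
        assert np.array_equal(noisy.intensities, art.intensities)

    def test_total_variance_recovered(self):
        ns = NoiseSpec.for_level(8, rng_seed=0)
        rng = np.random.default_rng(0)
        field = sample_noise_field((22, 22, 22), ns, rng)
        assert field.var() == pytest.approx(ns.sigma2_total, rel=0.05)

    def test_no_negative_intensities_after_pruning(self):
        art = self._clean()
        for lv in (1, 6, 12):
            noisy = add_noise(art, NoiseSpec.for_level(lv, rng_seed=lv))
            assert noisy.intensities.min() >= 0.0

    def test_noise_can_scatter_voxels_outside_clean_support(self):
        art = self._clean()
        noisy = add_noise(art, NoiseSpec.for_level(12, rng_seed=1))
        r = art.spec.scaled_radius(noisy.voxel_coords)
        assert (r > 1.0).any()  # detached voxels around the core

    def test_reproducible_given_seed(self):
        art = self._clean()
        ns = NoiseSpec.for_level(5, rng_seed=9)
        a = add_noise(art, ns)
        b = add_noise(art, ns)
        assert np.array_equal(a.intensities, b.intensities)

    def test_correlation_signatures_of_components(self):
        """Correlated component: lag-1 autocorrelation > 0.3; uncorrelated
        component: < 0.05 (both measured on ~10,000-voxel fields)."""
        shape = (22, 22, 22)
        rng = np.random.default_rng(2)
        corr_only = NoiseSpec(0, 1.0, 1.0, 0.0)
        unc_only = NoiseSpec(0, 1.0, 0.0, 1.0)

        def lag1(f):
            a = f[:-1].ravel() - f.mean()
            b = f[1:].ravel() - f.mean()
            return (a * b).mean() / f.var()

        f_corr = sample_noise_field(shape, corr_only, rng)
        f_unc = sample_noise_field(shape, unc_only, rng)
        assert lag1(f_corr) > 0.3
        assert abs(lag1(f_unc)) < 0.05


class TestScenarioArtifacts:
    def test_shared_lattice_across_electrodes(self, fitted_4x4):
        arts = simulate_scenario_artifacts([fitted_4x4], None, lattice_seed=0)
        assert len(arts) == 16
        for a in arts[1:]:
            assert np.array_equal(a.lattice.orientation, arts[0].lattice.orientation)
            assert np.array_equal(a.lattice.origin, arts[0].lattice.origin)

    def test_all_twelve_levels_supported(self, fitted_4x4):
        for lv in (1, 12):
            arts = simulate_scenario_artifacts([fitted_4x4], lv, lattice_seed=1)
            assert all(a.noise.level_index == lv for a in arts)

    def test_depth_artifact_principal_axis_follows_trajectory(self, sphere70, sphere_seed):
        """The clean depth ellipsoid (prolate, 1.25/1.25/1.75 mm) has its
        intensity-weighted principal axis along the trajectory. Noise is
        excluded here: at an aspect ratio of 1.4 even level-1 noise swamps
        the second-moment anisotropy of a ~300-voxel cluster."""
        from implantsim.depth import make_trajectory, place_depth_array

        traj = make_trajectory(sphere70, sphere_seed)
        arr = place_depth_array(traj, 8, 5.0, rng_seed=0)
        arts = simulate_scenario_artifacts([arr], None, lattice_seed=3)
        for a in arts:
            w = a.intensities
            c = a.voxel_coords - (w[:, None] * a.voxel_coords).sum(0) / w.sum()
            cov = (w[:, None, None] * np.einsum("ij,ik->ijk", c, c)).sum(0)
            evals, evecs = np.linalg.eigh(cov)
            principal = evecs[:, -1]  # depth ellipsoid is prolate along z
            cos = abs(principal @ traj.direction)
            assert np.degrees(np.arccos(min(cos, 1.0))) < 10.0

    def test_merge_keeps_maximum_at_duplicate_sites(self):
        lat = identity_lattice()
        a1 = clean_artifact(np.zeros(3), np.array([0.0, 0.0, 1.0]), GRID_SPEC, lat,
                            electrode_id="e1")
        a2 = clean_artifact(np.array([0.5, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]),
                            GRID_SPEC, lat, electrode_id="e2")
        table = merge_artifacts([a1, a2])
        assert table.duplicated(subset=["i", "j", "k"]).sum() == 0
        # the shared site between the two centers keeps the larger intensity
        mid = table[(table.x == 0.0) & (table.y == 0.0) & (table.z == 0.0)]
        assert mid["intensity"].iloc[0] == pytest.approx(1.0)
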