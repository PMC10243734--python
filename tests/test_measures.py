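"""Particle measures: construction, varifold transport, resampling."""

import numpy as np
import pytest

from projlddmm.measures import (
    ParticleMeasure,
    ResampleKernel,
    nft_density,
    particles_from_slice,
    reduce_features,
    resample,
    transport,
    transport_chain,
)


def _toy_measure(rng, n=20, l=3, d=2):
    pts = rng.uniform(-1, 1, size=(n, d))
    w = rng.uniform(0.5, 2.0, size=n)
    counts = rng.integers(0, 4, size=(n, l)).astype(float)
    fracs = rng.dirichlet(np.ones(l + 1), size=n)[:, :l]
    return ParticleMeasure(pts, w, np.concatenate([counts, fracs], axis=1), l)


class TestConstruction:
    def test_single_tissue_pixel_with_tangle(self):
        mask = np.array([[True]])
        labels = np.array([[2]])
        mu = particles_from_slice(
            mask, np.array([[0.0, 0.0]]), labels, pixel_area=4e-6
        )
        assert mu.weights[0] == pytest.approx(4e-6)
        # count one-hot in region 2, area fraction one-hot in region 2
        np.testing.assert_array_equal(mu.features[0], [0, 1, 0, 1])

    def test_background_pixel_has_zero_weight_and_features(self):
        mask = np.array([[False, True]])
        labels = np.array([[0, 1]])
        mu = particles_from_slice(mask, np.zeros((0, 2)), labels, 1.0)
        assert mu.weights[0] == 0
        np.testing.assert_array_equal(mu.features[0], 0)

    def test_count_block_conserves_input_tangles(self, rng):
        labels = rng.integers(0, 4, size=(12, 12))
        mask = labels > 0
        pts = np.argwhere(mask)[
            rng.choice(int(mask.sum()), size=30)
        ].astype(float)
        mu = particles_from_slice(mask, pts, labels, 1.0)
        assert mu.total_counts().sum() == pytest.approx(30)


class TestTransport:
    def test_identity_map_preserves_measure(self, rng):
        mu = _toy_measure(rng)
        out = transport(mu, lambda p: p, np.ones(len(mu.weights)))
        np.testing.assert_array_equal(out.points, mu.points)
        np.testing.assert_array_equal(out.weights, mu.weights)
        np.testing.assert_array_equal(out.features, mu.features)

    def test_uniform_scaling_multiplies_weights_by_s_squared(self, rng):
        mu = _toy_measure(rng)
        s = 1.7
        out = transport(mu, lambda p: s * p, np.full(len(mu.weights), s ** 2))
        np.testing.assert_allclose(out.weights, mu.weights * s ** 2, rtol=1e-12)

    def test_count_block_invariant_under_any_map(self, rng):
        mu = _toy_measure(rng)
        out = transport(
            mu, lambda p: p + rng.normal(size=p.shape),
            rng.uniform(0.5, 2.0, len(mu.weights)),
        )
        np.testing.assert_array_equal(out.total_counts(), mu.total_counts())

    def test_negative_jacobian_rejected(self, rng):
        mu = _toy_measure(rng)
        with pytest.raises(ValueError, match="Jacobian"):
            transport(mu, lambda p: p, -np.ones(len(mu.weights)))

    def test_round_trip_weights_consistent(self, rng):
        mu = _toy_measure(rng)
        jac = rng.uniform(0.5, 2.0, len(mu.weights))
        fwd = transport(mu, lambda p: 2 * p, jac)
        back = transport(fwd, lambda p: p / 2, 1.0 / jac)
        np.testing.assert_allclose(back.weights, mu.weights, rtol=1e-10)

    def test_chain_embeds_at_z_with_in_plane_jacobian(self, rng):
        mu = _toy_measure(rng, d=2)

        def map2d(p):
            return 3.0 * p, np.full(len(p), 9.0)

        out = transport_chain(mu, map2d, z_position=1.25)
        assert out.points.shape[1] == 3
        np.testing.assert_allclose(out.points[:, 0], 1.25)
        np.testing.assert_allclose(out.weights, mu.weights * 9.0, rtol=1e-12)


class TestResample:
    def test_nearest_neighbor_on_own_sites_is_identity(self, rng):
        mu = _toy_measure(rng)
        out = resample(mu, ResampleKernel("nearest_neighbor", mu.points))
        np.testing.assert_allclose(out.weights, mu.weights, rtol=1e-12)
        np.testing.assert_allclose(out.features, mu.features, atol=1e-12)

    @pytest.mark.parametrize("kind", ["nearest_neighbor", "gaussian"])
    def test_mass_and_count_mass_conserved(self, rng, kind):
        mu = _toy_measure(rng, n=40)
        targets = rng.uniform(-1, 1, size=(7, 2))
        out = resample(mu, ResampleKernel(kind, targets, bandwidth=0.4))
        assert out.total_weight() == pytest.approx(mu.total_weight(), rel=1e-10)
        np.testing.assert_allclose(out.count_mass(), mu.count_mass(), rtol=1e-10)

    def test_two_particles_merge_to_weighted_mean_feature(self):
        mu = ParticleMeasure(
            np.array([[0.0, 0.0], [0.1, 0.0]]),
            np.array([1.0, 1.0]),
            np.array([[0.0, 1.0], [2.0, 1.0]]),
            n_regions=1,
        )
        out = resample(mu, ResampleKernel("nearest_neighbor", np.array([[0.05, 0.0]])))
        assert out.weights[0] == pytest.approx(2.0)
        assert out.features[0, 0] == pytest.approx(1.0)  # mean of counts 0 and 2

    def test_empty_targets_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            ResampleKernel("nearest_neighbor", np.zeros((0, 2)))

    def test_gaussian_density_approaches_count_area_ratio(self, rng):
        # dense unit-weight tissue grid with marked pixels: at bandwidth of
        # the pixel size the resampled density approximates count/area
        n = 30
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        pts = np.stack([yy.ravel(), xx.ravel()], 1).astype(float)
        w = np.ones(n * n)
        counts = (rng.uniform(size=n * n) < 0.2).astype(float)[:, None]
        feats = np.concatenate([counts, np.ones((n * n, 1))], axis=1)
        mu = ParticleMeasure(pts, w, feats, 1)
        out = resample(mu, ResampleKernel("gaussian", pts, bandwidth=1.0))
        total, _ = nft_density(out)
        assert np.nanmean(total) == pytest.approx(counts.mean(), rel=0.15)


class TestFeatureReduction:
    def test_dirac_returns_itself(self):
        f = np.array([1.0, 2.0, 0.5, 0.5])
        np.testing.assert_array_equal(reduce_features(f[None]), f)

    def test_equal_weights_average(self):
        f = np.array([[0.0, 1.0], [2.0, 3.0]])
        np.testing.assert_allclose(reduce_features(f), [1.0, 2.0])

    def test_weighted_first_moment(self):
        out = reduce_features(np.array([[0.0], [4.0]]), weights=[1.0, 3.0])
        assert out[0] == pytest.approx(3.0)

    def test_zero_weight_flagged_as_zeros(self):
        out = reduce_features(np.array([[5.0]]), weights=[0.0])
        np.testing.assert_array_equal(out, [0.0])


class TestDensity:
    def test_documented_example(self):
        mu = ParticleMeasure(
            np.zeros((1, 2)), np.array([2.0]),
            np.array([[3.0, 1.0, 0.0, 0.5, 0.5, 0.0]]), n_regions=3,
        )
        total, per_region = nft_density(mu)
        assert total[0] == pytest.approx(2.0)
        assert per_region[0, 0] == pytest.approx(3.0)  # 3 / (2 * 0.5)
        assert per_region[0, 1] == pytest.approx(1.0)
        assert per_region[0, 2] == 0.0

    def test_zero_counts_zero_density(self):
        mu = ParticleMeasure(
            np.zeros((1, 2)), np.array([1.5]),
            np.array([[0.0, 0.0, 0.6, 0.4]]), n_regions=2,
        )
        total, per_region = nft_density(mu)
        assert total[0] == 0.0
        np.testing.assert_array_equal(per_region[0], [0.0, 0.0])

    def test_doubling_weight_halves_density(self):
        f = np.array([[2.0, 1.0]])
        m1 = ParticleMeasure(np.zeros((1, 2)), np.array([1.0]), f, 1)
        m2 = ParticleMeasure(np.zeros((1, 2)), np.array([2.0]), f, 1)
        t1, _ = nft_density(m1)
        t2, _ = nft_density(m2)
        assert t2[0] == pytest.approx(t1[0] / 2)

    def test_counts_without_area_fraction_reported_missing(self):
        mu = ParticleMeasure(
            np.zeros((1, 2)), np.array([1.0]),
            np.array([[2.0, 0.0, 0.0, 1.0]]), n_regions=2,
        )
        _, per_region = nft_density(mu)
        assert np.isnan(per_region[0, 0])
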