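"""Scattering features, shared-PCA basis and contrast coefficients."""

import itertools

import numpy as np
import pytest

from projlddmm.contrast import (
    ScatteringConfig,
    build_basis,
    estimate_alpha,
    predict_contrast,
    scatter,
    scattering_path_count,
)
from projlddmm.grids_io import SliceImage


def _random_textured_slice(rng, n=64, channels=3, spacing=0.05):
    data = rng.uniform(0.2, 0.8, size=(n, n, channels))
    from scipy.ndimage import gaussian_filter

    for c in range(channels):
        data[..., c] = gaussian_filter(data[..., c], 1.0)
    return SliceImage(data, (spacing, spacing), (0.0, 0.0))


class TestScatter:
    def test_default_config_gives_48_channels_for_rgb(self, rng):
        sl = _random_textured_slice(rng, channels=3)
        fs = scatter(sl, ScatteringConfig(J=2, L=3, order=2), 0.1)
        assert fs.n_channels == 48

    @pytest.mark.parametrize(
        "J,L,order", [(1, 1, 1), (1, 4, 2), (2, 3, 2), (3, 2, 2), (2, 2, 1)]
    )
    def test_path_count_formula_matches_enumeration(self, J, L, order, rng):
        sl = _random_textured_slice(rng, n=32, channels=1)
        cfg = ScatteringConfig(J=J, L=L, order=order)
        fs = scatter(sl, cfg, 0.05)
        # independent enumeration of admissible paths
        paths = 1 + J * L
        if order == 2:
            paths += sum(
                1
                for (j1, l1), (j2, l2) in itertools.product(
                    itertools.product(range(J), range(L)), repeat=2
                )
                if j2 > j1
            )
        assert scattering_path_count(cfg) == paths
        assert fs.n_channels == paths

    def test_constant_input_activates_only_order_zero(self):
        sl = SliceImage(np.full((32, 32, 2), 0.6), (0.1, 0.1), (0, 0))
        fs = scatter(sl, ScatteringConfig(), 0.1)
        per_channel = scattering_path_count(ScatteringConfig())
        for c in range(2):
            block = fs.data[..., c * per_channel: (c + 1) * per_channel]
            np.testing.assert_allclose(block[..., 0], 0.6, rtol=1e-6)
            assert np.abs(block[..., 1:]).max() < 1e-6 * 0.6

    def test_translation_stability(self, rng):
        # low-passed scattering features move far less than the raw image
        sl = _random_textured_slice(rng, n=64, channels=1)
        shifted = SliceImage(
            np.roll(sl.data, 2, axis=1), sl.spacing, sl.origin
        )
        cfg = ScatteringConfig()
        f0 = scatter(sl, cfg, sl.spacing[0]).data
        f1 = scatter(shifted, cfg, sl.spacing[0]).data
        feat_change = np.linalg.norm(f1 - f0) / np.linalg.norm(f0)
        raw_change = np.linalg.norm(shifted.data - sl.data) / np.linalg.norm(sl.data)
        assert feat_change < 0.5 * raw_change

    def test_too_small_image_rejected(self):
        sl = SliceImage(np.zeros((2, 2)), (0.1, 0.1), (0, 0))
        with pytest.raises(ValueError, match="smaller"):
            scatter(sl, ScatteringConfig(J=2, L=3), 0.1)


class TestBuildBasis:
    def _stacks(self, rng, rank=None, n_slices=3):
        stacks = []
        for _ in range(n_slices):
            sl = _random_textured_slice(rng, n=32, channels=1)
            fs = scatter(sl, ScatteringConfig(), 0.05)
            if rank is not None:
                base = fs.data[..., :1]
                fs.data = np.concatenate(
                    [base * (k + 1.0) for k in range(fs.data.shape[-1])], axis=-1
                )
            stacks.append(fs)
        return stacks

    def test_loadings_orthonormal(self, rng):
        bases = build_basis(self._stacks(rng), m=6)
        G = bases[0].loadings.T @ bases[0].loadings
        np.testing.assert_allclose(G, np.eye(6), atol=1e-10)

    def test_constant_image_is_first_basis_channel(self, rng):
        bases = build_basis(self._stacks(rng), m=4)
        np.testing.assert_array_equal(bases[0].images[..., 0], 1.0)

    def test_rank_deficient_pool_advises_smaller_m(self, rng):
        with pytest.raises(ValueError, match="smaller m"):
            build_basis(self._stacks(rng, rank=1), m=3)

    def test_rank_one_pool_works_with_single_component(self, rng):
        bases = build_basis(self._stacks(rng, rank=1), m=1)
        assert bases[0].images.shape[-1] == 2

    def test_slice_permutation_leaves_loadings_fixed_up_to_sign(self, rng):
        stacks = self._stacks(rng, n_slices=4)
        b1 = build_basis(stacks, m=5)
        b2 = build_basis(stacks[::-1], m=5)
        for k in range(5):
            col1, col2 = b1[0].loadings[:, k], b2[0].loadings[:, k]
            agree = min(
                np.abs(col1 - col2).max(), np.abs(col1 + col2).max()
            )
            assert agree < 1e-8


class TestAlphaEstimation:
    @pytest.fixture
    def basis(self, rng):
        sl = _random_textured_slice(rng, n=32, channels=1)
        fs = scatter(sl, ScatteringConfig(), 0.05)
        return build_basis([fs], m=4)[0]

    def test_in_span_target_recovered_exactly(self, basis, rng):
        c = rng.standard_normal(5)
        target = basis.images @ c
        alpha = estimate_alpha(basis, target)
        np.testing.assert_allclose(alpha.alpha, c, atol=1e-8)

    def test_constant_target_with_centered_basis_loads_only_constant(self, basis):
        # mean-centre the non-constant images: a constant target then has
        # alpha = (kappa, 0, ..., 0) by the normal equations
        import dataclasses

        imgs = basis.images.copy()
        for k in range(1, imgs.shape[-1]):
            imgs[..., k] -= imgs[..., k].mean()
        centered = dataclasses.replace(basis, images=imgs)
        alpha = estimate_alpha(centered, np.full(imgs.shape[:2], 3.7))
        assert alpha.alpha[0] == pytest.approx(3.7, abs=1e-8)
        np.testing.assert_allclose(alpha.alpha[1:], 0.0, atol=1e-8)

    def test_region_weights_match_restricted_fit(self, basis, rng):
        target = rng.uniform(size=basis.images.shape[:2])
        w = np.zeros(basis.images.shape[:2])
        w[4:20, 6:25] = 1.0
        masked = estimate_alpha(basis, target, weights=w)
        # independent oracle: unweighted normal equations on the region only
        P = basis.images[4:20, 6:25].reshape(-1, basis.images.shape[-1])
        t = target[4:20, 6:25].ravel()
        expected = np.linalg.solve(P.T @ P, P.T @ t)
        np.testing.assert_allclose(masked.alpha, expected, atol=1e-8)

    def test_all_zero_weights_rejected(self, basis):
        with pytest.raises(ValueError, match="zero"):
            estimate_alpha(
                basis, np.zeros(basis.images.shape[:2]),
                weights=np.zeros(basis.images.shape[:2]),
            )

    def test_residual_orthogonal_to_basis_under_weights(self, basis, rng):
        target = rng.uniform(size=basis.images.shape[:2])
        w = rng.uniform(size=basis.images.shape[:2])
        alpha = estimate_alpha(basis, target, weights=w)
        resid = basis.images @ alpha.alpha - target
        for k in range(basis.images.shape[-1]):
            assert abs(np.sum(w * resid * basis.images[..., k])) < 1e-6


class TestPredictContrast:
    def test_constant_alpha_gives_constant_image(self, rng):
        sl = _random_textured_slice(rng, n=32, channels=1)
        basis = build_basis([scatter(sl, ScatteringConfig(), 0.05)], m=3)[0]
        out = predict_contrast(basis, np.array([1.0, 0, 0, 0]))
        np.testing.assert_allclose(out.data[..., 0], 1.0)

    def test_predict_after_estimate_reproduces_in_span_target(self, rng):
        sl = _random_textured_slice(rng, n=32, channels=1)
        basis = build_basis([scatter(sl, ScatteringConfig(), 0.05)], m=3)[0]
        target = basis.images @ np.array([0.5, -1.0, 2.0, 0.25])
        out = predict_contrast(basis, estimate_alpha(basis, target))
        np.testing.assert_allclose(out.data[..., 0], target, atol=1e-8)

    def test_out_of_span_prediction_is_orthogonal_projection(self, rng):
        sl = _random_textured_slice(rng, n=32, channels=1)
        basis = build_basis([scatter(sl, ScatteringConfig(), 0.05)], m=3)[0]
        target = rng.uniform(size=basis.images.shape[:2])
        pred = predict_contrast(basis, estimate_alpha(basis, target)).data[..., 0]
        # independent projector oracle via QR of the flattened basis
        P = basis.images.reshape(-1, 4)
        Q, _ = np.linalg.qr(P)
        proj = (Q @ (Q.T @ target.ravel())).reshape(target.shape)
        np.testing.assert_allclose(pred, proj, atol=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        sl = _random_textured_slice(rng, n=32, channels=1)
        basis = build_basis([scatter(sl, ScatteringConfig(), 0.05)], m=3)[0]
        with pytest.raises(ValueError, match="alpha"):
            predict_contrast(basis, np.ones(7))
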