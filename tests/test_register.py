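"""Registration drivers, objective gradients and evaluation metrics."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from projlddmm.flows import KernelSpec, Rigid2D, VelocityField, path_energy
from projlddmm.grids_io import ImageVolume, SliceImage, SliceStack
from projlddmm.mixture import MixtureParams
from projlddmm.phantom import PhantomConfig, make_template, simulate_sections
from projlddmm.register import (
    MatchingObjective,
    RegistrationConfig,
    dice,
    hausdorff95,
    map_labels,
    register_stack,
)


class TestMetrics:
    def test_dice_identical_and_disjoint(self):
        a = np.zeros((10, 10), bool)
        a[2:6, 2:6] = True
        assert dice(a, a) == 1.0
        b = np.zeros((10, 10), bool)
        b[7:9, 7:9] = True
        assert dice(a, b) == 0.0

    def test_dice_half_shifted_rectangle(self):
        a = np.zeros((20, 20), bool)
        a[5:15, 0:10] = True
        b = np.roll(a, 5, axis=1)
        assert dice(a, b) == pytest.approx(0.5)

    def test_hausdorff_identical_masks_zero(self):
        a = np.zeros((8, 8), bool)
        a[2:5, 2:5] = True
        assert hausdorff95(a, a, 0.5) == 0.0

    def test_hausdorff_two_pixels(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[4, 2] = True
        b[4, 5] = True
        assert hausdorff95(a, b, 0.5) == pytest.approx(1.5)

    def test_hausdorff_symmetric(self, rng):
        a = rng.uniform(size=(15, 15)) > 0.6
        b = rng.uniform(size=(15, 15)) > 0.6
        a[0, 0] = b[1, 1] = True  # guarantee non-empty
        assert hausdorff95(a, b, 0.3) == pytest.approx(hausdorff95(b, a, 0.3))

    def test_hausdorff_empty_mask_rejected(self):
        a = np.zeros((5, 5), bool)
        b = np.ones((5, 5), bool)
        with pytest.raises(ValueError, match="non-empty"):
            hausdorff95(a, b, 1.0)


def _tiny_objective(rng, n_slices=2):
    shape = (10, 16, 16)
    sp = np.array([0.5, 0.5, 0.5])
    org = -(np.array(shape) - 1) / 2 * sp
    data = gaussian_filter(np.cumsum(rng.standard_normal(shape), axis=1) * 0.1, 1.5)
    T = ImageVolume(data, sp, org)
    z = np.linspace(-1.0, 1.0, n_slices)
    obj = MatchingObjective(
        T, z, (16, 16), sp[1:], org[1:], KernelSpec(1.5), KernelSpec(1.0)
    )
    params = MixtureParams(0.5, 0.0, (0.2, 0.2, 0.2))
    targets = []
    for _ in range(n_slices):
        mu1 = rng.standard_normal((16, 16, 1)) * 0.1
        pi = rng.dirichlet((2, 1, 1), size=(16, 16))
        targets.append(
            {
                "means": (mu1, np.full((16, 16, 1), 0.5), np.zeros((16, 16, 1))),
                "pi": pi,
                "params": params,
            }
        )
    obj.set_targets(targets)
    v = VelocityField(
        np.stack(
            [gaussian_filter(rng.standard_normal(shape + (3,)), (2, 2, 2, 0)) * 0.1
             for _ in range(3)]
        ),
        sp, org, KernelSpec(1.5),
    )
    us = [
        VelocityField(
            np.stack(
                [gaussian_filter(rng.standard_normal((16, 16, 2)), (2, 2, 0)) * 0.05
                 for _ in range(2)]
            ),
            sp[1:], org[1:], KernelSpec(1.0),
        )
        for _ in range(n_slices)
    ]
    rigids = [Rigid2D(0.05, [0.1, -0.05]) for _ in range(n_slices)]
    return obj, v, us, rigids, sp, org


class TestObjectiveGradients:
    def test_directional_derivative_matches_finite_differences(self, rng):
        """The data-term adjoints must reproduce central differences of the
        discretized objective to high relative accuracy."""
        obj, v, us, rigids, sp, org = _tiny_objective(rng)
        state, g_v, g_u = obj.gradients(v, us, rigids)

        def data_E(vv, uu):
            st = obj.forward(vv, uu, rigids)
            return obj.data_cost(st["obs"])

        eps = 1e-5
        dv = gaussian_filter(
            rng.standard_normal(v.values.shape), (0, 1.5, 1.5, 1.5, 0)
        )
        dv /= np.abs(dv).max()
        uu = [u.values for u in us]
        fd = (data_E(v.values + eps * dv, uu) - data_E(v.values - eps * dv, uu)) / (
            2 * eps
        )
        an = np.sum(g_v * dv)
        assert abs(fd - an) / abs(fd) < 1e-3

        du = gaussian_filter(rng.standard_normal(uu[0].shape), (0, 1.5, 1.5, 0))
        du /= np.abs(du).max()
        up = [uu[0] + eps * du, uu[1]]
        um = [uu[0] - eps * du, uu[1]]
        fd = (data_E(v.values, up) - data_E(v.values, um)) / (2 * eps)
        an = np.sum(g_u[0] * du)
        assert abs(fd - an) / abs(fd) < 1e-3

    def test_energy_components_nonnegative_penalty(self, rng):
        obj, v, us, rigids, sp, org = _tiny_objective(rng)
        assert obj.penalties(v, us) > 0
        E, _ = obj.energy(v, us, rigids)
        assert np.isfinite(E)


@pytest.fixture(scope="module")
def identity_phantom():
    """Sections cut from the undeformed template with no artifacts."""
    cfg = PhantomConfig(
        shape=(16, 32, 32), spacing=0.25, n_sections=3, section_spacing=1.0,
        histology_factor=1,
        deform3d_amp=0.0, deform3d_amp_z=0.0, deform2d_amp=0.0,
        rigid_max_angle=0.0, rigid_max_shift=0.0,
        tear_fraction=0.0, noise_sigma=0.0, texture_amps=(0.0, 0.0, 0.0, 0.0),
        identity_contrast=True, seed=3,
    )
    vol, lab, _ = make_template(cfg)
    stack, gt = simulate_sections(vol, lab, cfg)
    return cfg, vol, lab, stack, gt


class TestRegisterStack:
    def test_identity_stack_is_a_fixed_point(self, identity_phantom):
        """Matching contrast, no distortion: the estimate must stay at the
        identity (recovered displacements well under a voxel)."""
        cfg, vol, lab, stack, gt = identity_phantom
        rcfg = RegistrationConfig(
            n_levels=1, outer_iters=(4,), contrast_on=False, mixture_on=False,
            v_steps=1, u_steps=1,
        )
        res = register_stack(vol, stack, rcfg)
        rms_v = np.sqrt(np.mean(res.phi.inverse_disp ** 2))
        assert rms_v < 0.2 * vol.spacing.min()
        for chi in res.chis:
            assert np.sqrt(np.mean(chi.inverse_disp ** 2)) < 0.2 * vol.spacing.min()
        for r in res.rigids:
            assert abs(r.angle) < 0.02
            assert np.abs(r.translation).max() < 0.2 * vol.spacing.min()

    def test_energy_trace_non_increasing_within_levels(self, identity_phantom):
        cfg, vol, lab, stack, gt = identity_phantom
        rcfg = RegistrationConfig(
            n_levels=1, outer_iters=(4,), contrast_on=False, mixture_on=False,
        )
        res = register_stack(vol, stack, rcfg)
        diffs = np.diff(res.energy_trace)
        assert np.all(diffs <= 1e-9 * np.maximum(np.abs(res.energy_trace[:-1]), 1.0))

    def test_mixture_off_identity_contrast_reduces_to_plain_ssd(
        self, identity_phantom
    ):
        """With the mixture disabled and matching modalities the objective
        is the classic penalized SSD matching problem; verified by energy
        equality against an independently computed value."""
        cfg, vol, lab, stack, gt = identity_phantom
        rcfg = RegistrationConfig(
            n_levels=1, outer_iters=(1,), contrast_on=False, mixture_on=False,
            v_steps=0, u_steps=0, rigid_steps=0, estimate_rigid=False,
        )
        res = register_stack(vol, stack, rcfg)
        # identity transforms: obs = template plane; target = the section;
        # penalties are zero, so E = sum_n |J_n - P_n I|^2 / (2 sigma_1^2)
        from projlddmm.projection import slice_volume

        expected = 0.0
        for sl in stack:
            plane = slice_volume(vol, sl.z_position).data[..., 0]
            expected += np.sum(
                (sl.data[..., 0] - plane) ** 2
            ) / (2 * res.params.sigma[0] ** 2)
        assert res.energy_trace[-1] == pytest.approx(expected, abs=1e-6)

    def test_out_of_range_sections_rejected(self, identity_phantom):
        cfg, vol, lab, stack, gt = identity_phantom
        bad = SliceStack(
            [SliceImage(s.data, s.spacing, s.origin, s.z_position + 100)
             for s in stack]
        )
        with pytest.raises(ValueError, match="z-positions"):
            register_stack(vol, bad, RegistrationConfig(n_levels=1))


class TestMapLabels:
    def _result_with(self, vol, stack, **kw):
        rcfg = RegistrationConfig(
            n_levels=1, outer_iters=(1,), contrast_on=False, mixture_on=False,
            v_steps=0, u_steps=0, rigid_steps=0, estimate_rigid=False, **kw
        )
        return register_stack(vol, stack, rcfg)

    def test_identity_result_gives_plain_label_slice(self, identity_phantom):
        cfg, vol, lab, stack, gt = identity_phantom
        res = self._result_with(vol, stack)
        out = map_labels(lab, res, 1)
        # oracle: nearest-neighbour slice of the label volume at z_1; the
        # plane falls exactly midway between two lattice planes, where the
        # documented tie-break picks the lower label value
        zi = (stack[1].z_position - vol.origin[0]) / vol.spacing[0]
        k = int(np.floor(zi))
        expected = (
            np.minimum(lab.data[k, ..., 0], lab.data[k + 1, ..., 0])
            if abs(zi - k - 0.5) < 1e-9
            else lab.data[int(round(zi)), ..., 0]
        )
        np.testing.assert_array_equal(out.data[..., 0], expected)

    def test_pure_translation_shifts_labels_on_lattice(self, identity_phantom):
        cfg, vol, lab, stack, gt = identity_phantom
        res = self._result_with(vol, stack)
        shift = np.array([vol.spacing[1], -2 * vol.spacing[2]])  # whole pixels
        res.rigids[1] = Rigid2D(0.0, shift)
        out = map_labels(lab, res, 1)
        base = map_labels(lab, res_identity := self._result_with(vol, stack), 1)
        # R^{-1} shifts sample points by -shift: labels move by +shift
        rolled = np.roll(np.roll(base.data[..., 0], 1, axis=0), -2, axis=1)
        core = out.data[2:-2, 2:-2, 0]
        np.testing.assert_array_equal(core, rolled[2:-2, 2:-2])

    def test_no_new_label_values_created(self, identity_phantom):
        cfg, vol, lab, stack, gt = identity_phantom
        res = self._result_with(vol, stack)
        out = map_labels(lab, res, 0)
        assert set(np.unique(out.data)).issubset(set(np.unique(lab.data)))

    def test_unknown_slice_index_rejected(self, identity_phantom):
        cfg, vol, lab, stack, gt = identity_phantom
        res = self._result_with(vol, stack)
        with pytest.raises(ValueError, match="slice index"):
            map_labels(lab, res, 99)
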