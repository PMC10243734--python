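"""Alternating-optimization drivers for projective registration.

The estimation problem: a dense 3D template ``I_temp`` explains a stack
of sparse 2D sections through the chain

    section_n(y)  ~  mixture( J_n^alpha(y),
                              (phi_n . P_n (I_temp o varphi^{-1}))(y) )

where ``varphi`` is a 3D diffeomorphism (flow of ``v_t``), ``P_n`` slices
at plane ``z_n``, ``phi_n = R_n o chi_n`` is a per-section rigid motion
composed with a small 2D diffeomorphism (flow of ``u_{n,t}``),
``J_n^alpha`` is the contrast predicted from the section's scattering
basis, and the three-class mixture (tissue / artifact / background)
down-weights pixels the model cannot explain.

The driver alternates, per outer iteration:

1. contrast block  — alpha_n by weighted least squares (geometry fixed);
2. mixture block   — E-step weights, M-step nuisance means;
3. geometry block  — Gauss-Newton on the rigid parameters, Hilbert
   (kernel-preconditioned) gradient steps on each u_n and on v, with
   backtracking line search on the EM surrogate plus path-energy
   penalties.

Every block weakly decreases the same surrogate given the current
weights, so the recorded energy (penalties + marginal negative
log-likelihood) is non-increasing: the alternation is a generalized EM.
All data-term gradients are exact adjoints of the discretized forward
chain (see ``_interp`` and ``flows``), verified against central finite
differences in the test suite.

Also here: label mapping through the estimated transforms and the
evaluation metrics (Dice overlap, 95th-percentile Hausdorff distance).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from . import _interp
from .contrast import (
    Coefficients,
    ScatteringConfig,
    build_basis,
    estimate_alpha,
    predict_contrast,
    scatter,
)
from .flows import (
    DiffeoMap,
    KernelSpec,
    Rigid2D,
    VelocityField,
    flow_inverse_disp,
    flow_inverse_vjp,
    path_energy,
)
from .grids_io import ImageVolume, SliceImage, SliceStack, block_downsample
from .mixture import (
    MixtureParams,
    class_means,
    e_step,
    m_step_nuisance,
    negative_log_likelihood,
    weighted_cost,
)
from .nft_quant import otsu_threshold

logger = logging.getLogger(__name__)

#: test/debug hook: called as _debug_probe(tag, energy_fn) after each block
_debug_probe = None

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "MatchingObjective",
    "register_stack",
    "map_labels",
    "dice",
    "hausdorff95",
]


@dataclasses.dataclass
class RegistrationConfig:
    """Weights, schedules and mode flags of the alternating driver."""

    reg_weight_3d: float = 30.0
    reg_weight_2d: float = 30.0
    nt3d: int = 5
    nt2d: int = 3
    kernel_width_3d: float = None  # mm; default 8 x voxel spacing
    kernel_width_2d: float = None  # mm; default 6 x pixel spacing
    n_levels: int = 3
    #: lattice coarsening per stage; default: coarse robust alignment,
    #: full-resolution robust refinement, then the mixture stage
    level_factors: tuple = (2, 1, 1)
    outer_iters: tuple = (50, 12, 4)  # per stage
    v_steps: int = 2
    u_steps: int = 1
    rigid_steps: int = 1
    m_components: int = 6
    scattering: ScatteringConfig = dataclasses.field(default_factory=ScatteringConfig)
    contrast_on: bool = True
    mixture_on: bool = True
    #: levels run without the mixture (plain weighted LS) before artifact
    #: weighting enters; None = all but the final level.  Coarse alignment
    #: first keeps boundary pixels informative instead of letting the
    #: artifact class absorb early misalignment.
    mixture_warmup_levels: int = None
    #: keep the geometry fixed on mixture-enabled stages: the mixture can
    #: explain any observation with its constant classes, which makes
    #: geometry-under-EM degenerate (e.g. deforming the template
    #: projection into constant background); geometry is estimated under
    #: the robust warmup stages, the mixture then interprets it
    freeze_geometry_after_warmup: bool = True
    #: Tukey biweight cutoff (in units of sigma) for the robust matching
    #: loss used on warmup levels when the mixture is enabled: gross
    #: outliers (tears) lose all influence while misalignment-scale
    #: residuals keep theirs.  None = plain quadratic warmup.
    warmup_robust_c: float = 6.0
    #: how often the contrast coefficients are re-estimated inside a level
    #: (0 = only at level start, geometry then optimized with alpha fixed;
    #: re-fitting every iteration lets the predictor chase geometric drift
    #: and collapses small structures)
    alpha_refit_every: int = 0
    rigid_only: bool = False  # phi_n rigid-only (no 2D diffeo)
    estimate_rigid: bool = True
    update_sigma: bool = False
    update_priors: bool = False
    tol: float = 1e-4
    sigma_floor: float = 1e-3
    init_step_v: float = 1e-6
    init_step_u: float = 1e-6

    def __post_init__(self):
        if self.reg_weight_3d < 0 or self.reg_weight_2d < 0:
            raise ValueError("energy weights must be >= 0")
        if self.level_factors is None or len(self.level_factors) != self.n_levels:
            self.level_factors = tuple(
                2 ** (self.n_levels - 1 - l) for l in range(self.n_levels)
            )
        if isinstance(self.outer_iters, int):
            self.outer_iters = (self.outer_iters,) * self.n_levels
        if len(self.outer_iters) != self.n_levels:
            self.outer_iters = tuple(self.outer_iters[:1]) * self.n_levels
        if any(k < 1 for k in self.outer_iters):
            raise ValueError("iteration counts must be >= 1")


@dataclasses.dataclass
class RegistrationResult:
    """Estimated transforms, contrast, weights and the energy trace."""

    phi: DiffeoMap
    v: VelocityField
    rigids: list
    us: list
    chis: list
    alphas: list
    bases: list
    weights: list
    params: MixtureParams
    energy_trace: np.ndarray
    trace_level_starts: np.ndarray
    z_positions: np.ndarray
    slice_spacing: np.ndarray
    slice_origin: np.ndarray
    slice_shape: tuple
    template_spacing: np.ndarray
    template_origin: np.ndarray

    def section_to_template(self, n, points2d, with_jacobian=False):
        """Map section-frame (y, x) points into the template frame.

        Applies ``chi_n^{-1} o R_n^{-1}``, embeds at ``z_n``, then the
        inverse 3D map.  With ``with_jacobian=True`` also returns the
        in-plane area scale of the composite map at each point (the
        rigid part has unit determinant; the 3D part contributes the
        area scale of the embedded plane's image).
        """

        def chain(pts):
            p1 = self.rigids[n].inverse().apply(pts)
            idx2 = (p1 - self.slice_origin) / self.slice_spacing
            p2 = p1 + _interp.sample(self.chis[n].inverse_disp, idx2)
            q = np.concatenate(
                [np.full(p2.shape[:-1] + (1,), self.z_positions[n]), p2], axis=-1
            )
            idx3 = (q - self.template_origin) / self.template_spacing
            return q + _interp.sample(self.phi.inverse_disp, idx3)

        pts = np.atleast_2d(np.asarray(points2d, dtype=float))
        out = chain(pts)
        if not with_jacobian:
            return out
        h = 1e-3
        dy = (chain(pts + [h, 0.0]) - chain(pts - [h, 0.0])) / (2 * h)
        dx = (chain(pts + [0.0, h]) - chain(pts - [0.0, h])) / (2 * h)
        area = np.linalg.norm(np.cross(dy, dx), axis=-1)
        return out, area


# ---------------------------------------------------------------------------
# the discretized objective (data term + penalties) with exact adjoints
# ---------------------------------------------------------------------------

class MatchingObjective:
    """Energy and gradients of the projective matching problem.

    Holds the template, the per-section targets (class means, mixture
    weights, noise scales) and the deformation penalties, and evaluates
    the total objective

        reg3 * |v|_V^2 + reg2 * sum_n |u_n|_U^2 + sum_n Q_n

    together with its exact gradients with respect to the velocity
    fields, as vector-Jacobian products through the semi-Lagrangian flow
    recursions and the multilinear sampling chain.
    """

    def __init__(self, template: ImageVolume, z_positions, slice_shape,
                 slice_spacing, slice_origin, kernel3, kernel2,
                 reg3=1.0, reg2=1.0):
        self.T = template.data
        self.sp3 = template.spacing
        self.org3 = template.origin
        self.z = np.asarray(z_positions, dtype=float)
        self.sp2 = np.asarray(slice_spacing, dtype=float)
        self.org2 = np.asarray(slice_origin, dtype=float)
        ax = [self.org2[a] + self.sp2[a] * np.arange(slice_shape[a]) for a in range(2)]
        g = np.meshgrid(*ax, indexing="ij")
        self.lat2 = np.stack(g, axis=-1)
        self.kernel3 = kernel3
        self.kernel2 = kernel2
        self.reg3 = reg3
        self.reg2 = reg2
        self.targets = None  # list of (means, weights, params) per section

    def set_targets(self, targets):
        """targets: per section dict(means=(mu1,mu2,mu3), pi, params)."""
        self.targets = targets

    # -- forward ------------------------------------------------------------

    def _slice_obs(self, psi_disp, chi_disp, rigid, zn, keep_cache=False):
        p1 = rigid.inverse().apply(self.lat2.reshape(-1, 2)).reshape(self.lat2.shape)
        idx2 = (p1 - self.org2) / self.sp2
        d2 = _interp.sample(chi_disp, idx2)
        p2 = p1 + d2
        q = np.concatenate(
            [np.full(p2.shape[:-1] + (1,), zn), p2], axis=-1
        )
        idx3 = (q - self.org3) / self.sp3
        d3 = _interp.sample(psi_disp, idx3)
        xsrc = q + d3
        idxT = (xsrc - self.org3) / self.sp3
        obs = _interp.sample(self.T, idxT)[..., 0]
        if not keep_cache:
            return obs, None
        return obs, {"idx2": idx2, "idx3": idx3, "idxT": idxT, "p1": p1,
                     "chi_disp": chi_disp, "psi_disp": psi_disp}

    def _slice_obs_vjp(self, cache, g_obs, need_psi=True):
        """Backprop d(obs)/d(psi_field), d(obs)/d(chi_field)."""
        g_obs = g_obs[..., None]
        _, g_idxT = _interp.sample_vjp(
            self.T, cache["idxT"], g_obs, need_values=False
        )
        g_x = g_idxT / self.sp3
        g_psi_field, g_idx3 = _interp.sample_vjp(
            cache["psi_disp"], cache["idx3"], g_x, need_values=need_psi
        )
        g_q = g_x + g_idx3 / self.sp3
        g_p2 = g_q[..., 1:]
        g_chi_field, g_idx2 = _interp.sample_vjp(
            cache["chi_disp"], cache["idx2"], g_p2
        )
        return g_psi_field, g_chi_field

    def forward(self, vvals, u_vals_list, rigids, keep_tape=False):
        psi = flow_inverse_disp(vvals, self.sp3, self.org3, keep_tape=keep_tape)
        if keep_tape:
            psi, tape3 = psi
        chis, tapes2, caches, obs_list = [], [], [], []
        for n in range(len(self.z)):
            chi = flow_inverse_disp(
                u_vals_list[n], self.sp2, self.org2, keep_tape=keep_tape
            )
            if keep_tape:
                chi, t2 = chi
                tapes2.append(t2)
            chis.append(chi)
            obs, cache = self._slice_obs(
                psi, chi, rigids[n], self.z[n], keep_cache=keep_tape
            )
            obs_list.append(obs)
            caches.append(cache)
        state = {"psi": psi, "chis": chis, "obs": obs_list}
        if keep_tape:
            state.update({"tape3": tape3, "tapes2": tapes2, "caches": caches})
        return state

    # -- energies -----------------------------------------------------------

    def data_cost(self, obs_list):
        total = 0.0
        for n, obs in enumerate(obs_list):
            means, pi, params = (
                self.targets[n]["means"],
                self.targets[n]["pi"],
                self.targets[n]["params"],
            )
            total += weighted_cost(obs[..., None], means, pi, params)
        return total

    def penalties(self, v: VelocityField, us):
        pen = self.reg3 * path_energy(v)
        for u in us:
            pen += self.reg2 * path_energy(u)
        return pen

    def energy(self, v: VelocityField, us, rigids, state=None):
        if state is None:
            state = self.forward(v.values, [u.values for u in us], rigids)
        return self.penalties(v, us) + self.data_cost(state["obs"]), state

    # -- gradients ----------------------------------------------------------

    def _g_obs(self, n, obs):
        means, pi, params = (
            self.targets[n]["means"],
            self.targets[n]["pi"],
            self.targets[n]["params"],
        )
        g = np.zeros_like(obs)
        for k in range(3):
            g += pi[..., k] * (obs - means[k][..., 0]) / params.sigma[k] ** 2
        return g

    def gradients(self, v: VelocityField, us, rigids):
        """Raw (discrete-partial) data gradients w.r.t. v and each u_n."""
        state = self.forward(
            v.values, [u.values for u in us], rigids, keep_tape=True
        )
        g_psi_total = np.zeros(v.values.shape[1:])
        g_u = []
        for n, obs in enumerate(state["obs"]):
            g_obs = self._g_obs(n, obs)
            g_psi, g_chi = self._slice_obs_vjp(state["caches"][n], g_obs)
            g_psi_total += g_psi
            g_u.append(
                flow_inverse_vjp(
                    us[n].values, self.sp2, state["tapes2"][n], g_chi
                )
            )
        g_v = flow_inverse_vjp(v.values, self.sp3, state["tape3"], g_psi_total)
        return state, g_v, g_u

    # -- rigid Gauss-Newton ------------------------------------------------

    def _slice_obs_with_p1_jacobian(self, psi_disp, chi_disp, rigid, zn):
        p1 = rigid.inverse().apply(self.lat2.reshape(-1, 2)).reshape(self.lat2.shape)
        idx2 = (p1 - self.org2) / self.sp2
        d2, j2 = _interp.sample_with_point_jacobian(chi_disp, idx2)
        p2 = p1 + d2
        A2 = np.zeros(p1.shape[:-1] + (2, 2))
        A2[..., 0, 0] = A2[..., 1, 1] = 1.0
        A2 += j2 / self.sp2[None, None, None, :]
        q = np.concatenate([np.full(p2.shape[:-1] + (1,), zn), p2], axis=-1)
        idx3 = (q - self.org3) / self.sp3
        d3, j3 = _interp.sample_with_point_jacobian(psi_disp, idx3)
        xsrc = q + d3
        B = np.zeros(q.shape[:-1] + (3, 3))
        for a in range(3):
            B[..., a, a] = 1.0
        B += j3 / self.sp3[None, None, None, :]
        idxT = (xsrc - self.org3) / self.sp3
        obs, jT = _interp.sample_with_point_jacobian(self.T, idxT)
        gradT = jT[..., 0, :] / self.sp3  # (ny, nx, 3)
        dx_dq = B  # (3, 3)
        dq_dp1 = np.zeros(q.shape[:-1] + (3, 2))
        dq_dp1[..., 1:, :] = A2
        dobs_dp1 = np.einsum(
            "...a,...ab,...bc->...c", gradT, dx_dq, dq_dp1
        )
        return obs[..., 0], p1, dobs_dp1

    def gauss_newton_rigid(self, n, psi_disp, chi_disp, rigid, max_tries=5):
        """One damped Gauss-Newton update of (angle, translation)."""
        means, pi, params = (
            self.targets[n]["means"],
            self.targets[n]["pi"],
            self.targets[n]["params"],
        )
        W = np.zeros(self.lat2.shape[:-1])
        mu_bar = np.zeros_like(W)
        for k in range(3):
            W += pi[..., k] / params.sigma[k] ** 2
            mu_bar += pi[..., k] * means[k][..., 0] / params.sigma[k] ** 2
        mu_bar = mu_bar / np.maximum(W, 1e-30)
        obs, p1, dobs_dp1 = self._slice_obs_with_p1_jacobian(
            psi_disp, chi_disp, rigid, self.z[n]
        )
        theta, t = rigid.angle, rigid.translation
        c, s = np.cos(-theta), np.sin(-theta)
        Minv = np.array([[c, s], [-s, c]])
        dM = -np.array([[-s, c], [-c, -s]])  # d/d theta of M(-theta)
        ym = self.lat2 - t
        dp1_dtheta = np.einsum("ab,...b->...a", dM, ym)
        J = np.empty(self.lat2.shape[:-1] + (3,))
        J[..., 0] = np.sum(dobs_dp1 * dp1_dtheta, axis=-1)
        J[..., 1] = -np.sum(dobs_dp1 * Minv[:, 0], axis=-1)
        J[..., 2] = -np.sum(dobs_dp1 * Minv[:, 1], axis=-1)
        r = obs - mu_bar
        q0 = 0.5 * np.sum(W * r ** 2)
        Jf = J.reshape(-1, 3)
        Wf = W.ravel()
        H = Jf.T @ (Jf * Wf[:, None])
        g = Jf.T @ (Wf * r.ravel())
        lam = 1e-3 * np.trace(H) / 3.0
        for _ in range(max_tries):
            try:
                step = np.linalg.solve(H + lam * np.eye(3), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = Rigid2D(theta + step[0], t + step[1:])
            obs_c, _ = self._slice_obs(psi_disp, chi_disp, cand, self.z[n])
            q1 = 0.5 * np.sum(W * (obs_c - mu_bar) ** 2)
            if q1 < q0:
                return cand
            lam *= 10.0
        return rigid


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _tissue_mask(sl: SliceImage, spacing):
    """Coarse tissue mask of a histology section (Otsu; tissue = dark side)."""
    ds = block_downsample(sl, spacing)
    img = ds.data.mean(axis=-1)
    try:
        mask, t = otsu_threshold(img)
    except ValueError:
        return np.ones(img.shape, dtype=bool), ds
    above, below = img[mask], img[~mask]
    if above.size and below.size and above.mean() > below.mean():
        mask = ~mask  # tissue is the darker class
    return mask, ds


def _prolong_velocity(v: VelocityField, grid_shape, spacing, origin, kernel):
    """Resample each timestep of a velocity field onto a finer lattice."""
    d = v.values.shape[-1]
    ax = [origin[a] + spacing[a] * np.arange(grid_shape[a]) for a in range(d)]
    pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    idx = (pts - v.origin) / v.spacing
    new = np.stack([_interp.sample(v.values[k], idx) for k in range(v.nt)])
    return VelocityField(new, spacing, origin, kernel)


def _line_search(eval_fn, x0, direction, step0, max_back=8, grow=1.3, E0=None):
    """Backtracking step on a callable E(x0 - step * direction).

    Returns (new_x, new_E, new_step) or (None, E0, shrunk_step) when no
    decrease was found.
    """
    if E0 is None:
        E0 = eval_fn(x0)
    step = step0
    for _ in range(max_back):
        cand = x0 - step * direction
        E1 = eval_fn(cand)
        if E1 < E0:
            return cand, E1, min(step * grow, step0 * 64.0)
        step *= 0.4
    return None, E0, step

def _obs_on_lattice(Tdata, sp3, org3, psi_disp, chi_disp, chi_sp, chi_org,
                    rigid, zn, lat2):
    """Project the template through the estimated chain onto an arbitrary
    in-plane lattice (used to fit the contrast at full resolution even
    while the matching runs on a coarsened level)."""
    p1 = rigid.inverse().apply(lat2.reshape(-1, 2)).reshape(lat2.shape)
    idx2 = (p1 - chi_org) / chi_sp
    p2 = p1 + _interp.sample(chi_disp, idx2)
    q = np.concatenate([np.full(p2.shape[:-1] + (1,), zn), p2], axis=-1)
    idx3 = (q - org3) / sp3
    x = q + _interp.sample(psi_disp, idx3)
    return _interp.sample(Tdata, (x - org3) / sp3)[..., 0]


def _zpad_volume(vol: ImageVolume, npad: int) -> ImageVolume:
    """Edge-replicate padding along z (velocity fields live on periodic
    FFT lattices; padding keeps the section planes away from the wrap)."""
    data = np.pad(vol.data, ((npad, npad), (0, 0), (0, 0), (0, 0)), mode="edge")
    origin = vol.origin.copy()
    origin[0] -= npad * vol.spacing[0]
    return ImageVolume(data, vol.spacing, origin)


def register_stack(template: ImageVolume, stack: SliceStack,
                   cfg: RegistrationConfig = None) -> RegistrationResult:
    """Jointly estimate the 3D flow, per-section motions, contrast and
    mixture weights explaining a section stack by a template.

    Runs a two-level multiresolution schedule (template coarsened 2x,
    then full resolution); within each level the alternation of the
    module docstring.  Raises on Jacobian collapse of the 3D map.
    """
    cfg = cfg or RegistrationConfig()
    z = stack.z_positions
    zmin = template.origin[0]
    zmax = template.origin[0] + (template.shape[0] - 1) * template.spacing[0]
    if z.min() < zmin or z.max() > zmax:
        raise ValueError("stack z-positions fall outside the template range")
    # pad z by the kernel support so the spectral velocity kernel cannot
    # couple the outermost section planes through the periodic boundary
    kw3_pad = cfg.kernel_width_3d or 8.0 * float(np.min(template.spacing))
    npad = int(np.ceil(2.0 * kw3_pad / template.spacing[0]))
    npad += npad % 2  # keep the padded extent divisible by the coarsening
    if npad:
        template = _zpad_volume(template, npad)

    factors = list(cfg.level_factors)
    # contrast bases once, at the template's full in-plane resolution;
    # coarser levels match against block-averaged predictions
    sp2f, org2f = template.spacing[1:], template.origin[1:]
    shape2f = template.shape[1:]
    axf = [org2f[a] + sp2f[a] * np.arange(shape2f[a]) for a in range(2)]
    lat2f = np.stack(np.meshgrid(*axf, indexing="ij"), axis=-1)
    bases, masks_fine = None, None
    if cfg.contrast_on:
        stacks_feat, masks_fine = [], []
        for sl in stack:
            stacks_feat.append(scatter(sl, cfg.scattering, sp2f))
            masks_fine.append(_tissue_mask(sl, sp2f)[0])
        bases = build_basis(stacks_feat, cfg.m_components, masks=masks_fine)
    v = None
    us = None
    rigids = [Rigid2D() for _ in range(len(stack))]
    params = None
    energy_trace = []
    trace_level_starts = []
    warmup_levels = (
        cfg.mixture_warmup_levels
        if cfg.mixture_warmup_levels is not None
        else cfg.n_levels - 1
    )

    for level, factor in enumerate(factors):
        mix_here = cfg.mixture_on and level >= warmup_levels
        trace_level_starts.append(len(energy_trace))
        tmpl = (
            block_downsample(template, template.spacing * factor)
            if factor > 1
            else template
        )
        geo_frozen = (
            cfg.freeze_geometry_after_warmup and mix_here and warmup_levels > 0
        )
        sp3, org3 = tmpl.spacing, tmpl.origin
        shape2 = tmpl.shape[1:]
        sp2, org2 = sp3[1:], org3[1:]
        kw3 = cfg.kernel_width_3d or 8.0 * float(np.min(template.spacing))
        kw2 = cfg.kernel_width_2d or 6.0 * float(np.min(template.spacing[1:]))
        k3, k2 = KernelSpec(kw3), KernelSpec(kw2)

        if v is None:
            v = VelocityField.zeros(tmpl.shape, sp3, org3, k3, cfg.nt3d)
            us = [
                VelocityField.zeros(shape2, sp2, org2, k2, cfg.nt2d)
                for _ in range(len(stack))
            ]
        else:
            v = _prolong_velocity(v, tmpl.shape, sp3, org3, k3)
            us = [
                _prolong_velocity(u, shape2, sp2, org2, k2) for u in us
            ]

        alphas, target_imgs = None, None
        masks = []
        if cfg.contrast_on:
            for mf in masks_fine:
                if factor > 1:
                    blocks = mf.reshape(
                        mf.shape[0] // factor, factor, mf.shape[1] // factor, factor
                    )
                    masks.append(blocks.mean(axis=(1, 3)) > 0.5)
                else:
                    masks.append(mf)
        else:
            target_imgs = []
            for sl in stack:
                ratio = sp2 / sl.spacing
                if np.allclose(ratio, np.rint(ratio)):
                    target_imgs.append(block_downsample(sl, sp2).data[..., 0])
                else:
                    target_imgs.append(sl.data[..., 0])

        obj = MatchingObjective(
            tmpl, z, shape2, sp2, org2, k3, k2,
            reg3=cfg.reg_weight_3d, reg2=cfg.reg_weight_2d,
        )
        state = obj.forward(v.values, [u.values for u in us], rigids)

        # initial alpha: least squares against the projected template at
        # full resolution, stratified by observed intensity over tissue
        def fit_alphas_and_predict():
            # stratified, outlier-robust (Tukey IRLS) contrast fit: tears
            # and other gross mismatches must not drag the predictor
            alphas_, preds_ = [], []
            for n in range(len(stack)):
                obs_f = _obs_on_lattice(
                    tmpl.data, sp3, org3, state["psi"],
                    state["chis"][n], sp2, org2, rigids[n], z[n], lat2f,
                )
                w0 = _alpha_weights(obs_f, masks_fine[n])
                a = estimate_alpha(bases[n], obs_f, weights=w0)
                for _ in range(2):
                    r = bases[n].images @ a.alpha - obs_f
                    mad = np.median(np.abs(r - np.median(r)))
                    scale = max(6.0 * 1.4826 * mad, 1e-6)
                    a = estimate_alpha(
                        bases[n], obs_f, weights=w0 * _tukey_weights(r, scale)
                    )
                alphas_.append(a)
                pf = predict_contrast(bases[n], alphas_[n])
                preds_.append(
                    block_downsample(pf, sp2) if factor > 1 else pf
                )
            return alphas_, preds_

        if cfg.contrast_on:
            alphas, preds = fit_alphas_and_predict()
        else:
            preds = [
                SliceImage(t, sp2, org2, z[n]) for n, t in enumerate(target_imgs)
            ]

        # nuisance initialization, refreshed per level: robust residual
        # scale over *tissue* pixels (the background matches trivially and
        # would shrink sigma below the informative misalignment scale)
        sel = masks if masks else [np.ones(shape2, bool)] * len(stack)
        res0 = np.concatenate(
            [
                (preds[n].data[..., 0] - state["obs"][n])[sel[n]].ravel()
                for n in range(len(stack))
            ]
        )
        mad = np.median(np.abs(res0 - np.median(res0)))
        sigma0 = max(1.4826 * mad, cfg.sigma_floor)
        if mix_here:
            obs_all = np.concatenate([o.ravel() for o in state["obs"]])
            obs_tis = np.concatenate(
                [state["obs"][n][sel[n]].ravel() for n in range(len(stack))]
            )
            mu_B0 = float(np.percentile(obs_all, 5))
            mu_A0 = float(np.median(obs_tis))
            params = MixtureParams(mu_A0, mu_B0, (sigma0, sigma0, sigma0))
        else:
            # single-model warmup: classes 2/3 carry no weight
            params = MixtureParams(0.0, 0.0, (sigma0, 1.0, 1.0))

        def targets_from(preds_, pis_):
            t = []
            for n in range(len(stack)):
                means = class_means(preds_[n], params)
                t.append({"means": means, "pi": pis_[n], "params": params})
            return t

        robust_warmup = (not mix_here) and cfg.mixture_on and (
            cfg.warmup_robust_c is not None
        )
        robust_scale = (
            cfg.warmup_robust_c * params.sigma[0] if robust_warmup else None
        )

        def warmup_pis():
            out = []
            for n in range(len(stack)):
                r = preds[n].data[..., 0] - state["obs"][n]
                w1 = (
                    _tukey_weights(r, robust_scale)
                    if robust_warmup
                    else np.ones(shape2)
                )
                out.append(
                    np.concatenate(
                        [w1[..., None], np.zeros(shape2 + (2,))], axis=-1
                    )
                )
            return out

        # initial weights
        if mix_here:
            pis = [
                e_step(
                    state["obs"][n][..., None],
                    class_means(preds[n], params),
                    params,
                )
                for n in range(len(stack))
            ]
        else:
            pis = warmup_pis()
        obj.set_targets(targets_from(preds, pis))

        step_v, step_u = cfg.init_step_v, cfg.init_step_u
        E_prev_window = []
        for it in range(cfg.outer_iters[level]):
            # --- (1) contrast block -------------------------------------
            refit = cfg.alpha_refit_every > 0 and it % cfg.alpha_refit_every == 0
            if cfg.contrast_on and refit:
                alphas, preds = fit_alphas_and_predict()
            # --- (2) mixture block ---------------------------------------
            if mix_here:
                new_pis = []
                for n in range(len(stack)):
                    means = class_means(preds[n], params)
                    new_pis.append(
                        e_step(state["obs"][n][..., None], means, params)
                    )
                pis = new_pis
                obs_cat = np.concatenate(
                    [state["obs"][n][..., None].reshape(-1, 1) for n in range(len(stack))]
                )
                pi_cat = np.concatenate([p.reshape(-1, 3) for p in pis])
                params = m_step_nuisance(
                    obs_cat, pi_cat, params,
                    update_sigma=cfg.update_sigma,
                    update_priors=cfg.update_priors,
                )
            if not mix_here:
                pis = warmup_pis()
            obj.set_targets(targets_from(preds, pis))

            def _probe(tag):
                if _debug_probe is None:
                    return
                st = obj.forward(v.values, [u.values for u in us], rigids)
                pen = obj.penalties(v, us)
                rho = 0.0
                maj = 0.0
                for nn in range(len(stack)):
                    rr = preds[nn].data[..., 0] - st["obs"][nn]
                    if robust_warmup:
                        rho += float(np.sum(_tukey_rho(rr, robust_scale))
                                     / (2.0 * params.sigma[0] ** 2))
                    maj += float(np.sum(pis[nn][..., 0] * rr ** 2)
                                 / (2.0 * params.sigma[0] ** 2))
                _debug_probe(tag, (pen, rho, maj))

            _probe("start")
            # --- (3) geometry block --------------------------------------
            psi = state["psi"]
            if cfg.estimate_rigid and not geo_frozen:
                for _ in range(cfg.rigid_steps):
                    for n in range(len(stack)):
                        rigids[n] = obj.gauss_newton_rigid(
                            n, psi, state["chis"][n], rigids[n]
                        )
            _probe("rigid")
            if not cfg.rigid_only and not geo_frozen:
                # per-section 2D updates with the 3D map held fixed: each
                # section's chain and surrogate are independent given psi
                psi = flow_inverse_disp(v.values, sp3, org3)
                dvol2 = float(np.prod(sp2))
                for n in range(len(stack)):
                    for _ in range(cfg.u_steps):
                        chi, tape2 = flow_inverse_disp(
                            us[n].values, sp2, org2, keep_tape=True
                        )
                        obs_n, cache = obj._slice_obs(
                            psi, chi, rigids[n], z[n], keep_cache=True
                        )
                        g_obs = obj._g_obs(n, obs_n)
                        _, g_chi = obj._slice_obs_vjp(cache, g_obs)
                        g_u = flow_inverse_vjp(us[n].values, sp2, tape2, g_chi)
                        direction = np.stack(
                            [
                                2.0 * cfg.reg_weight_2d * us[n].dt * us[n].values[k]
                                + k2.smooth(g_u[k], sp2) / (us[n].dt * dvol2)
                                for k in range(us[n].nt)
                            ]
                        )

                        def eval_u(un_vals, n=n):
                            chi_c = flow_inverse_disp(un_vals, sp2, org2)
                            obs_c, _ = obj._slice_obs(psi, chi_c, rigids[n], z[n])
                            u_obj = VelocityField(un_vals, sp2, org2, k2)
                            pen = cfg.reg_weight_2d * path_energy(u_obj)
                            return pen + _slice_Q(obj, n, obs_c)

                        E0_u = (
                            cfg.reg_weight_2d * path_energy(us[n])
                            + _slice_Q(obj, n, obs_n)
                        )
                        newv, _, step_u = _line_search(
                            eval_u, us[n].values, direction, step_u, E0=E0_u
                        )
                        if newv is not None:
                            us[n] = VelocityField(newv, sp2, org2, k2)
                        else:
                            break
            _probe("u")
            for _ in range(0 if geo_frozen else cfg.v_steps):
                state, g_v, g_u = obj.gradients(v, us, rigids)
                dvol3 = float(np.prod(sp3))
                direction = np.stack(
                    [
                        2.0 * cfg.reg_weight_3d * v.dt * v.values[k]
                        + k3.smooth(g_v[k], sp3) / (v.dt * dvol3)
                        for k in range(v.nt)
                    ]
                )

                def eval_v(vvals):
                    st = obj.forward(vvals, [u.values for u in us], rigids)
                    v_obj = VelocityField(vvals, sp3, org3, k3)
                    return (
                        cfg.reg_weight_3d * path_energy(v_obj)
                        + obj.data_cost(st["obs"])
                    )

                E0_v = (
                    cfg.reg_weight_3d * path_energy(v)
                    + obj.data_cost(state["obs"])
                )
                newv, _, step_v = _line_search(
                    eval_v, v.values, direction, step_v, E0=E0_v
                )
                if newv is not None:
                    v = VelocityField(newv, sp3, org3, k3)

            _probe("v")
            state = obj.forward(v.values, [u.values for u in us], rigids)

            # --- energy trace (penalties + marginal NLL) ------------------
            E = obj.penalties(v, us)
            for n in range(len(stack)):
                means = class_means(preds[n], params)
                if mix_here:
                    E += negative_log_likelihood(
                        state["obs"][n][..., None], means, params
                    )
                elif robust_warmup:
                    r = preds[n].data[..., 0] - state["obs"][n]
                    E += float(
                        np.sum(_tukey_rho(r, robust_scale))
                        / (2.0 * params.sigma[0] ** 2)
                    )
                else:
                    E += weighted_cost(
                        state["obs"][n][..., None], means, pis[n], params
                    )
            energy_trace.append(E)
            E_prev_window.append(E)
            if len(E_prev_window) > 4:
                E_prev_window.pop(0)
                rel = abs(E_prev_window[0] - E_prev_window[-1]) / max(
                    abs(E_prev_window[-1]), 1e-12
                )
                if rel < cfg.tol:
                    logger.info("level %d converged at iteration %d", level, it)
                    break
            if (it + 1) % 5 == 0:
                jmin = _min_jacobian(v)
                logger.info(
                    "level %d iter %d: E=%.6g, min|Dphi|=%.3f", level, it, E, jmin
                )
                if jmin <= 0:
                    raise RuntimeError(
                        "Jacobian collapse in the 3D flow; aborting registration"
                    )

    # final maps
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        from .flows import integrate_flow

        phi = integrate_flow(v)
        chis = [integrate_flow(u) for u in us]
    if np.any(phi.jacobian_det() <= 0):
        raise RuntimeError("Jacobian collapse in the final 3D map")
    state = obj.forward(v.values, [u.values for u in us], rigids)
    return RegistrationResult(
        trace_level_starts=np.asarray(trace_level_starts),
        phi=phi,
        v=v,
        rigids=rigids,
        us=us,
        chis=chis,
        alphas=alphas if cfg.contrast_on else [Coefficients([1.0])] * len(stack),
        bases=bases,
        weights=pis,
        params=params,
        energy_trace=np.asarray(energy_trace),
        z_positions=z,
        slice_spacing=sp2,
        slice_origin=org2,
        slice_shape=shape2,
        template_spacing=sp3,
        template_origin=org3,
    )


def _alpha_weights(obs, tissue_mask, pi1=None, nbins=16):
    """Intensity-stratified least-squares weights for the contrast fit.

    Tissue pixels are weighted inversely to the occupancy of their
    observed-intensity stratum, so each intensity class contributes
    equally and small subregions are not sacrificed to large uniform
    ones; background keeps unit weight.  Multiplied by the tissue
    posterior when the mixture is active.
    """
    w = np.ones_like(obs)
    if tissue_mask is not None and tissue_mask.any():
        t = obs[tissue_mask]
        lo, hi = t.min(), t.max()
        bins = np.clip(
            ((obs - lo) / (hi - lo + 1e-12) * nbins).astype(int), 0, nbins - 1
        )
        counts = np.zeros(nbins)
        np.add.at(counts, bins[tissue_mask], 1.0)
        wt = 1.0 / np.maximum(counts[bins], 1.0)
        w[tissue_mask] = wt[tissue_mask] / wt[tissue_mask].mean()
    if pi1 is not None:
        w = w * pi1
    return w


def _tukey_weights(resid, scale):
    """IRLS weights of the Tukey biweight loss (zero beyond the cutoff)."""
    t = resid / scale
    w = (1.0 - t ** 2) ** 2
    w[np.abs(t) >= 1.0] = 0.0
    return w


def _tukey_rho(resid, scale):
    """Tukey biweight loss, quadratic-comparable normalization.

    Behaves like ``resid**2`` near zero and saturates at ``scale**2 / 3``,
    so the IRLS weights of :func:`_tukey_weights` make the weighted
    quadratic cost an exact majorizer of this loss (keeping the recorded
    energy trace monotone under the warmup geometry updates).
    """
    t = np.clip((resid / scale) ** 2, 0.0, 1.0)
    return scale ** 2 / 3.0 * (1.0 - (1.0 - t) ** 3)


def _slice_Q(obj: MatchingObjective, n, obs):
    t = obj.targets[n]
    return weighted_cost(obs[..., None], t["means"], t["pi"], t["params"])


def _min_jacobian(v: VelocityField):
    from .flows import integrate_flow
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        return float(integrate_flow(v).jacobian_det().min())


# ---------------------------------------------------------------------------
# label mapping and evaluation metrics
# ---------------------------------------------------------------------------

def map_labels(labels3d: ImageVolume, result: RegistrationResult,
               slice_index: int) -> SliceImage:
    """Map a 3D label volume into a section frame through the estimated
    transforms (nearest-neighbour throughout; exact midpoints resolve to
    the lowest label value among the tied voxels)."""
    if not 0 <= slice_index < len(result.z_positions):
        raise ValueError(f"unknown slice index {slice_index}")
    ax = [
        result.slice_origin[a]
        + result.slice_spacing[a] * np.arange(result.slice_shape[a])
        for a in range(2)
    ]
    pts2 = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    pts3 = result.section_to_template(slice_index, pts2.reshape(-1, 2))
    idx = (pts3 - labels3d.origin) / labels3d.spacing
    shape3 = np.array(labels3d.shape)
    lab = np.zeros(len(idx))
    lo = np.floor(idx).astype(int)
    frac = idx - lo
    best_d = np.full(len(idx), np.inf)
    for corner in range(8):
        off = np.array([(corner >> a) & 1 for a in (2, 1, 0)])
        cand = lo + off
        inside = np.all((cand >= 0) & (cand < shape3), axis=1)
        d = np.sum(((frac - off) * labels3d.spacing) ** 2, axis=1)
        d[~inside] = np.inf
        cand_cl = np.clip(cand, 0, shape3 - 1)
        cand_lab = labels3d.data[cand_cl[:, 0], cand_cl[:, 1], cand_cl[:, 2], 0]
        with np.errstate(invalid="ignore"):
            better = d < best_d - 1e-15
            tie = np.abs(d - best_d) <= 1e-15
        take = better | (tie & (cand_lab < lab))
        lab = np.where(take, cand_lab, lab)
        best_d = np.minimum(best_d, d)
    out = lab.reshape(result.slice_shape)
    return SliceImage(
        out, result.slice_spacing, result.slice_origin,
        float(result.z_positions[slice_index]),
    )


def dice(a, b) -> float:
    """Dice overlap of two boolean masks (1.0 when both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _boundary(mask):
    mask = np.asarray(mask, dtype=bool)
    return mask & ~binary_erosion(mask, border_value=0)


def hausdorff95(a, b, spacing) -> float:
    """95th percentile of symmetric boundary nearest-distances, in mm."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("hausdorff95 requires two non-empty masks")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (a.ndim,))
    pa = np.argwhere(_boundary(a)) * spacing
    pb = np.argwhere(_boundary(b)) * spacing
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
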