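"""Velocity fields, RKHS energy, flow integration and group actions.

The deformation model is the standard flow of diffeomorphisms: a
time-indexed smooth velocity field ``v_t`` (here on a uniform lattice,
``nt`` Euler steps) generates a map through ``d/dt phi_t = v_t(phi_t)``,
``phi_0 = Id``.  Velocities live in a reproducing-kernel Hilbert space
realized by a translation-invariant Gaussian smoothing operator ``K``;
the path energy is the inverse-kernel quadratic form evaluated spectrally.

Discretization: the *inverse* map is integrated semi-Lagrangian,

    psi_{k+1}(x) = psi_k(x - dt * v_k(x)),    psi_0 = Id,

and the forward map is the same recursion run on the time-reversed,
negated velocity.  Both are stored as world-mm displacement fields.  The
recursion keeps its intermediates so that the exact vector-Jacobian
product (``flow_inverse_vjp``) of the discretized scheme is available to
the registration drivers; this is what makes registration gradients pass
a central finite-difference check rather than merely approximate it.

The Gaussian Fourier multiplier is floored at a small constant so the
inverse multiplier needed by the path energy stays finite in double
precision; the floored multiplier is itself a valid positive-definite
kernel (Gaussian plus a small multiple of the identity).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import fft as _fft

from . import _interp
from .grids_io import ImageVolume, SliceImage, interpolate

__all__ = [
    "KernelSpec",
    "VelocityField",
    "DiffeoMap",
    "Rigid2D",
    "integrate_flow",
    "deform_image",
    "path_energy",
    "hilbert_gradient_step",
]


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KernelSpec:
    """Gaussian RKHS kernel, realized as a Fourier-multiplier smoother.

    Parameters
    ----------
    width : mm; standard deviation of the Gaussian kernel.
    floor : lower bound on the Fourier multiplier (keeps the inverse
        multiplier finite; equivalent to adding ``floor`` times the
        identity to the kernel, preserving positive-definiteness).
    """

    width: float
    floor: float = 1e-6

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("kernel width must be > 0")

    def multipliers(self, grid_shape, spacing):
        key = (tuple(grid_shape), tuple(np.atleast_1d(spacing).tolist()))
        cached = getattr(self, "_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        spacing = np.broadcast_to(np.asarray(spacing, float), (len(grid_shape),))
        om2 = np.zeros(grid_shape)
        for a, n in enumerate(grid_shape):
            w = 2.0 * np.pi * np.fft.fftfreq(n, d=spacing[a])
            shape = [1] * len(grid_shape)
            shape[a] = n
            om2 = om2 + (w.reshape(shape)) ** 2
        mult = np.maximum(np.exp(-0.5 * self.width ** 2 * om2), self.floor)
        self._cache = (key, mult)
        return mult

    def smooth(self, field, spacing):
        """Apply K componentwise; ``field`` shape (*grid, d)."""
        d = field.shape[-1]
        grid_shape = field.shape[:-1]
        mult = self.multipliers(grid_shape, spacing)
        axes = tuple(range(len(grid_shape)))
        out = np.empty_like(field)
        for c in range(d):
            out[..., c] = _fft.ifftn(_fft.fftn(field[..., c], axes=axes) * mult, axes=axes).real
        return out


@dataclasses.dataclass
class VelocityField:
    """Time-indexed vector field on a lattice, world mm / unit time.

    ``values`` has shape ``(nt, *grid, d)`` with d the spatial dimension.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    kernel: KernelSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        d = self.values.shape[-1]
        if self.values.ndim != d + 2:
            raise ValueError("values must have shape (nt, *grid, d)")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(d)
        self.origin = np.asarray(self.origin, dtype=float).reshape(d)
        if self.values.shape[0] < 1:
            raise ValueError("nt must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("velocity field contains non-finite values")

    @property
    def nt(self):
        return self.values.shape[0]

    @property
    def dt(self):
        return 1.0 / self.nt

    @property
    def grid_shape(self):
        return self.values.shape[1:-1]

    @classmethod
    def zeros(cls, grid_shape, spacing, origin, kernel, nt):
        d = len(grid_shape)
        return cls(np.zeros((nt,) + tuple(grid_shape) + (d,)), spacing, origin, kernel)


@dataclasses.dataclass
class DiffeoMap:
    """Forward and inverse maps sampled on a lattice (displacements, mm)."""

    forward_disp: np.ndarray
    inverse_disp: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        d = self.forward_disp.shape[-1]
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(d)
        self.origin = np.asarray(self.origin, dtype=float).reshape(d)

    @property
    def ndim(self):
        return self.forward_disp.shape[-1]

    @property
    def grid_shape(self):
        return self.forward_disp.shape[:-1]

    def _apply(self, disp, points):
        points = np.asarray(points, dtype=float)
        idx = (points - self.origin) / self.spacing
        return points + _interp.sample(disp, idx)

    def forward_points(self, points):
        return self._apply(self.forward_disp, points)

    def inverse_points(self, points):
        return self._apply(self.inverse_disp, points)

    def jacobian_det(self):
        """Determinant of the forward map's Jacobian, central differences."""
        d = self.ndim
        lattice = _lattice_world(self.grid_shape, self.spacing, self.origin)
        fwd = lattice + self.forward_disp
        J = np.empty(self.grid_shape + (d, d))
        for c in range(d):
            grads = np.gradient(fwd[..., c], *self.spacing, edge_order=1)
            for a in range(d):
                J[..., c, a] = grads[a]
        return np.linalg.det(J)


@dataclasses.dataclass
class Rigid2D:
    """In-plane rigid (optionally affine) motion, acting on (y, x) mm points.

    The rotation is about the world origin; section lattices in this
    package are centred on the origin so the parameterization stays
    well-conditioned.
    """

    angle: float = 0.0
    translation: np.ndarray = None
    affine: np.ndarray = None  # optional extra 2x2 (replaces rotation block)

    def __post_init__(self):
        if self.translation is None:
            self.translation = np.zeros(2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=float).reshape(2, 2)

    @property
    def matrix(self):
        if self.affine is not None:
            return self.affine
        c, s = np.cos(self.angle), np.sin(self.angle)
        # rotation of (y, x) points by `angle` in the plane
        return np.array([[c, s], [-s, c]])

    def apply(self, points):
        return np.asarray(points, dtype=float) @ self.matrix.T + self.translation

    def inverse(self):
        if self.affine is not None:
            inv = np.linalg.inv(self.affine)
            return Rigid2D(0.0, -inv @ self.translation, affine=inv)
        Rt = self.matrix.T
        return Rigid2D(-self.angle, -(Rt @ self.translation))

    def to_json(self):
        return {
            "angle": float(self.angle),
            "translation": self.translation.tolist(),
            "affine": None if self.affine is None else self.affine.tolist(),
        }

    @classmethod
    def from_json(cls, d):
        aff = None if d.get("affine") is None else np.array(d["affine"])
        return cls(d["angle"], np.array(d["translation"]), affine=aff)


# ---------------------------------------------------------------------------
# flow integration
# ---------------------------------------------------------------------------

def _lattice_world(grid_shape, spacing, origin):
    ax = [origin[a] + spacing[a] * np.arange(grid_shape[a]) for a in range(len(grid_shape))]
    g = np.meshgrid(*ax, indexing="ij")
    return np.stack(g, axis=-1)


def flow_inverse_disp(values, spacing, origin, keep_tape=False):
    """Displacement field of the inverse of the flow of ``values``.

    ``values``: (nt, *grid, d) velocity sequence.  Returns ``disp`` with
    shape (*grid, d); with ``keep_tape=True`` also returns the
    intermediates needed by :func:`flow_inverse_vjp`.
    """
    nt = values.shape[0]
    d = values.shape[-1]
    grid_shape = values.shape[1:-1]
    dt = 1.0 / nt
    lattice_idx = _lattice_world(grid_shape, np.ones(d), np.zeros(d))
    disp = np.zeros(grid_shape + (d,))
    tape = []
    for k in range(nt):
        s_idx = lattice_idx - (dt / spacing) * values[k]
        if keep_tape:
            tape.append((disp, s_idx))
        disp = _interp.sample(disp, s_idx) - dt * values[k]
    if keep_tape:
        return disp, tape
    return disp


def flow_inverse_vjp(values, spacing, tape, cot_disp):
    """VJP of :func:`flow_inverse_disp` with respect to ``values``."""
    nt = values.shape[0]
    dt = 1.0 / nt
    grad_v = np.zeros_like(values)
    g = cot_disp
    for k in range(nt - 1, -1, -1):
        disp_k, s_idx = tape[k]
        grad_v[k] -= dt * g
        gv, gidx = _interp.sample_vjp(disp_k, s_idx, g)
        grad_v[k] -= (dt / spacing) * gidx
        g = gv
    return grad_v


def integrate_flow(v: VelocityField) -> DiffeoMap:
    """Integrate a velocity field to a diffeomorphism (forward + inverse).

    The forward map is obtained by running the inverse-map recursion on
    the time-reversed negated velocity; the Jacobian determinant of the
    forward map is checked for positivity and a warning is emitted if it
    fails anywhere (signalling a too-large step).
    """
    inv = flow_inverse_disp(v.values, v.spacing, v.origin)
    fwd = flow_inverse_disp(-v.values[::-1], v.spacing, v.origin)
    dmap = DiffeoMap(fwd, inv, v.spacing, v.origin)
    jac = dmap.jacobian_det()
    if np.any(jac <= 0):
        warnings.warn(
            f"non-positive Jacobian determinant (min {jac.min():.3g}) in "
            "integrated flow; velocity step too large",
            RuntimeWarning,
        )
    return dmap


def deform_image(image, dmap: DiffeoMap, fill=0.0, labels=False):
    """Group action on images: output(x) = image(inverse(x)).

    The output is sampled on the map's lattice.  Label images use
    nearest-neighbour sampling.
    """
    d = 3 if isinstance(image, ImageVolume) else 2
    if d != dmap.ndim:
        raise ValueError("image and map dimensionality differ (frame mismatch)")
    lattice = _lattice_world(dmap.grid_shape, dmap.spacing, dmap.origin)
    src = lattice + dmap.inverse_disp
    vals = interpolate(image, src, fill=fill, order=0 if labels else 1)
    if d == 3:
        return ImageVolume(vals, dmap.spacing, dmap.origin)
    return SliceImage(vals, dmap.spacing, dmap.origin, getattr(image, "z_position", 0.0))


# ---------------------------------------------------------------------------
# energy and gradient steps
# ---------------------------------------------------------------------------

def path_energy(v: VelocityField) -> float:
    """dt * sum_t <v_t, K^{-1} v_t>, evaluated spectrally.

    The inner product uses the L2 lattice quadrature (sum times voxel
    volume); by Parseval this is (voxel_volume / N) * sum over frequencies
    of |v_hat|^2 / K_hat.
    """
    grid_shape = v.grid_shape
    mult = v.kernel.multipliers(grid_shape, v.spacing)
    n = np.prod(grid_shape)
    dvol = np.prod(v.spacing)
    axes = tuple(range(len(grid_shape)))
    total = 0.0
    for k in range(v.nt):
        for c in range(v.values.shape[-1]):
            vh = _fft.fftn(v.values[k, ..., c], axes=axes)
            total += np.sum(np.abs(vh) ** 2 / mult)
    return float(v.dt * dvol / n * total)


def path_energy_gradient(v: VelocityField) -> np.ndarray:
    """L2-functional gradient of path_energy: 2 * dt * K^{-1} v_t."""
    grid_shape = v.grid_shape
    mult = v.kernel.multipliers(grid_shape, v.spacing)
    axes = tuple(range(len(grid_shape)))
    out = np.empty_like(v.values)
    for k in range(v.nt):
        for c in range(v.values.shape[-1]):
            vh = _fft.fftn(v.values[k, ..., c], axes=axes)
            out[k, ..., c] = 2.0 * v.dt * _fft.ifftn(vh / mult, axes=axes).real
    return out


def hilbert_gradient_step(v: VelocityField, raw_gradient, step, reg_weight=1.0):
    """One Hilbert (kernel-preconditioned) gradient descent update.

    ``raw_gradient`` is the L2-functional gradient of the *data* term with
    respect to each ``v_t``; the update smooths it by K and adds the
    penalty contribution in closed form:

        v <- v - step * (2 * reg_weight * dt * v + K * raw_gradient).
    """
    raw_gradient = np.asarray(raw_gradient, dtype=float)
    if raw_gradient.shape != v.values.shape:
        raise ValueError("gradient shape mismatch")
    new = np.empty_like(v.values)
    for k in range(v.nt):
        sm = v.kernel.smooth(raw_gradient[k], v.spacing)
        new[k] = v.values[k] - step * (2.0 * reg_weight * v.dt * v.values[k] + sm)
    return VelocityField(new, v.spacing, v.origin, v.kernel)
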