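"""Cross-modality contrast channel: scattering features, PCA basis, and
least-squares contrast coefficients.

Histology and MRI have unrelated intensity ranges, and plain linear
downsampling of the histology destroys exactly the meso-scale texture
that distinguishes regions sharing a mean stain intensity.  The channel
built here crosses both the resolution and contrast gaps:

1. a 2D Morlet *scattering transform* expands each section into
   translation-stable, texture-sensitive filtered images at the template
   resolution (alternating wavelet convolutions and modulus
   nonlinearities, low-passed at scale 2^J);
2. PCA over pooled tissue pixels of all sections reduces the feature
   channels to a shared m-dimensional predictive subspace (per-slice
   basis images are the slice's features projected on the shared
   loadings, plus a constant image);
3. per-slice coefficients ``alpha_n`` map the basis to template
   intensity by (weighted) least squares via the pseudo-inverse.

Path count per input channel is ``1 + J*L + L^2 * J*(J-1)/2``; the
default (J=2, L=3, order 2) on a 3-channel image yields 48 feature
images.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import fft as _fft

from .grids_io import SliceImage, block_downsample

logger = logging.getLogger(__name__)

__all__ = [
    "ScatteringConfig",
    "FeatureStack",
    "PredictiveBasis",
    "Coefficients",
    "scattering_path_count",
    "scatter",
    "build_basis",
    "estimate_alpha",
    "predict_contrast",
]


@dataclasses.dataclass
class ScatteringConfig:
    """Morlet scattering parameters: J dyadic scales, L orientations."""

    J: int = 2
    L: int = 3
    order: int = 2
    lowpass_sigma: float = 0.8  # spatial width of phi_J in px per 2^J

    def __post_init__(self):
        if self.J < 1 or self.L < 1:
            raise ValueError("J and L must be >= 1")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")


@dataclasses.dataclass
class FeatureStack:
    """Per-slice stack of scattering feature images on one lattice."""

    data: np.ndarray  # (ny, nx, M)
    spacing: np.ndarray
    origin: np.ndarray
    z_position: float
    path_names: list

    @property
    def n_channels(self):
        return self.data.shape[-1]


@dataclasses.dataclass
class PredictiveBasis:
    """Per-slice basis images psi^0 == 1, psi^1..psi^m (shared loadings)."""

    images: np.ndarray  # (ny, nx, m+1); channel 0 is the constant image
    loadings: np.ndarray  # (M, m), orthonormal columns
    mean: np.ndarray  # (M,) channel standardization
    std: np.ndarray  # (M,)
    spacing: np.ndarray
    origin: np.ndarray
    z_position: float

    @property
    def m(self):
        return self.images.shape[-1] - 1


@dataclasses.dataclass
class Coefficients:
    """Contrast coefficients alpha_n, feature space -> template intensity."""

    alpha: np.ndarray  # (m+1,)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("alpha contains non-finite values")


def scattering_path_count(cfg: ScatteringConfig) -> int:
    """Paths per input channel: 1 + J*L (+ L^2 * J*(J-1)/2 at order 2)."""
    n = 1 + cfg.J * cfg.L
    if cfg.order == 2:
        n += cfg.L ** 2 * cfg.J * (cfg.J - 1) // 2
    return n


# ---------------------------------------------------------------------------
# Morlet filter bank (Fourier domain, zero-mean band-pass wavelets)
# ---------------------------------------------------------------------------

def _filter_bank(shape, J, L, lowpass_sigma=0.8):
    ny, nx = shape
    wy = 2.0 * np.pi * np.fft.fftfreq(ny)
    wx = 2.0 * np.pi * np.fft.fftfreq(nx)
    WY, WX = np.meshgrid(wy, wx, indexing="ij")
    psis = {}
    for j in range(J):
        sigma = 0.8 * 2 ** j
        xi = 3.0 * np.pi / 4.0 / 2 ** j
        for l in range(L):
            theta = np.pi * l / L
            ky, kx = xi * np.sin(theta), xi * np.cos(theta)
            env = np.exp(-0.5 * sigma ** 2 * ((WY - ky) ** 2 + (WX - kx) ** 2))
            corr = np.exp(-0.5 * sigma ** 2 * (ky ** 2 + kx ** 2)) * np.exp(
                -0.5 * sigma ** 2 * (WY ** 2 + WX ** 2)
            )
            psis[(j, l)] = env - corr  # zero mean: psi_hat(0) = 0
    sigma_J = lowpass_sigma * 2 ** J
    phi = np.exp(-0.5 * sigma_J ** 2 * (WY ** 2 + WX ** 2))
    return psis, phi


def _bandpass_modulus(xh, psi_hat):
    return np.abs(_fft.ifft2(xh * psi_hat))


def scatter(sl: SliceImage, cfg: ScatteringConfig, target_spacing) -> FeatureStack:
    """Scattering features of one section, resampled to ``target_spacing``.

    All scattering paths up to ``cfg.order`` are computed per input
    channel (low-pass outputs at scale 2^J), then block-averaged onto the
    target lattice; channels are concatenated across input channels.
    """
    target_spacing = np.broadcast_to(np.asarray(target_spacing, dtype=float), (2,))
    if np.any(sl.spacing > target_spacing + 1e-12):
        raise ValueError("slice spacing must be <= target_spacing")
    ny, nx = sl.shape
    if min(ny, nx) < 2 ** cfg.J:
        raise ValueError(f"image smaller than 2^J = {2 ** cfg.J} pixels")
    psis, phi = _filter_bank((ny, nx), cfg.J, cfg.L, cfg.lowpass_sigma)
    channels = []
    names = []
    for c in range(sl.channels):
        x = sl.data[..., c]
        xh = _fft.fft2(x)
        # order 0
        channels.append(_fft.ifft2(xh * phi).real)
        names.append(f"ch{c}:S0")
        # order 1
        u1 = {}
        for j in range(cfg.J):
            for l in range(cfg.L):
                u = _bandpass_modulus(xh, psis[(j, l)])
                u1[(j, l)] = u
                channels.append(_fft.ifft2(_fft.fft2(u) * phi).real)
                names.append(f"ch{c}:S1(j{j},l{l})")
        # order 2 (j2 > j1)
        if cfg.order == 2:
            for j1 in range(cfg.J):
                for l1 in range(cfg.L):
                    uh = _fft.fft2(u1[(j1, l1)])
                    for j2 in range(j1 + 1, cfg.J):
                        for l2 in range(cfg.L):
                            u2 = _bandpass_modulus(uh, psis[(j2, l2)])
                            channels.append(_fft.ifft2(_fft.fft2(u2) * phi).real)
                            names.append(f"ch{c}:S2(j{j1},l{l1};j{j2},l{l2})")
    full = np.stack(channels, axis=-1)
    ratio = target_spacing / sl.spacing
    if np.allclose(ratio, np.rint(ratio), atol=1e-8):
        ds = block_downsample(
            SliceImage(full, sl.spacing, sl.origin, sl.z_position), target_spacing
        )
        data, spacing, origin = ds.data, ds.spacing, ds.origin
    else:  # non-integer ratio: sample the low-passed features on the target lattice
        from .grids_io import interpolate

        n_out = np.floor((np.array(sl.shape) - 1) * sl.spacing / target_spacing).astype(int) + 1
        tmp = SliceImage(full, sl.spacing, sl.origin, sl.z_position)
        ax = [sl.origin[a] + target_spacing[a] * np.arange(n_out[a]) for a in range(2)]
        pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
        data = interpolate(tmp, pts, fill=0.0)
        spacing, origin = target_spacing, sl.origin.copy()
    return FeatureStack(data, spacing, origin, sl.z_position, names)


# ---------------------------------------------------------------------------
# PCA basis and contrast coefficients
# ---------------------------------------------------------------------------

def build_basis(stacks, m=6, masks=None):
    """Shared-PCA predictive basis from the feature stacks of all slices.

    Channels are standardized over the pooled tissue pixels of all
    slices; a single set of PCA loadings is computed on the pooled
    pixel-by-channel matrix; each slice's basis images are its
    standardized features projected on the shared loadings, with the
    constant image prepended (channel 0).
    """
    if masks is None:
        masks = [np.ones(s.data.shape[:2], dtype=bool) for s in stacks]
    M = stacks[0].n_channels
    pooled = np.concatenate(
        [s.data[mk].reshape(-1, M) for s, mk in zip(stacks, masks)], axis=0
    )
    if pooled.shape[0] < m:
        raise ValueError("fewer pooled pixels than requested components m")
    if m >= M:
        raise ValueError("m must be smaller than the number of feature channels")
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)
    std_safe = np.where(std > 1e-12, std, 1.0)
    Xc = (pooled - mean) / std_safe
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(svals > max(1e-10 * svals[0], 1e-12)))
    if rank < m:
        raise ValueError(
            f"pooled feature matrix has rank {rank} < m={m}; choose a smaller m"
        )
    loadings = Vt[:m].T  # (M, m), orthonormal columns
    # deterministic sign: largest-magnitude entry of each column positive
    for k in range(m):
        i = np.argmax(np.abs(loadings[:, k]))
        if loadings[i, k] < 0:
            loadings[:, k] = -loadings[:, k]
    bases = []
    for s in stacks:
        Z = (s.data - mean) / std_safe
        proj = Z @ loadings  # (ny, nx, m)
        const = np.ones(proj.shape[:2] + (1,))
        bases.append(
            PredictiveBasis(
                np.concatenate([const, proj], axis=-1),
                loadings,
                mean,
                std_safe,
                s.spacing,
                s.origin,
                s.z_position,
            )
        )
    return bases


def estimate_alpha(basis: PredictiveBasis, target, weights=None,
                   cond_limit=1e8) -> Coefficients:
    """Weighted least-squares coefficients via the pseudo-inverse.

    Solves ``alpha = K^{-1} int psi(y) target(y) dy`` with
    ``K = int psi psi^T`` (discrete sums; per-pixel weights inserted in
    both integrals when provided).  A small ridge is added when the
    normal matrix is ill-conditioned.
    """
    t = target.data[..., 0] if isinstance(target, SliceImage) else np.asarray(target)
    psi = basis.images
    if t.shape != psi.shape[:2]:
        raise ValueError("target is not on the basis lattice")
    P = psi.reshape(-1, psi.shape[-1])
    tv = t.reshape(-1)
    if weights is not None:
        w = np.asarray(weights, dtype=float).reshape(-1)
        if np.any(w < 0):
            raise ValueError("weights must be >= 0")
        if w.sum() <= 0:
            raise ValueError("all-zero weights")
        K = P.T @ (P * w[:, None])
        b = P.T @ (w * tv)
    else:
        K = P.T @ P
        b = P.T @ tv
    if np.linalg.cond(K) > cond_limit:
        K = K + np.trace(K) / K.shape[0] * 1e-10 * np.eye(K.shape[0])
    return Coefficients(np.linalg.solve(K, b))


def predict_contrast(basis: PredictiveBasis, coeffs: Coefficients) -> SliceImage:
    """Linear predictor J_alpha(.) = alpha^T psi(.) on the basis lattice."""
    alpha = coeffs.alpha if isinstance(coeffs, Coefficients) else np.asarray(coeffs)
    if alpha.shape[0] != basis.images.shape[-1]:
        raise ValueError(
            f"alpha has {alpha.shape[0]} entries, basis has "
            f"{basis.images.shape[-1]} images"
        )
    data = basis.images @ alpha
    return SliceImage(data, basis.spacing, basis.origin, basis.z_position)
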