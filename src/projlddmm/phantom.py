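"""Synthetic specimen generator: template, distorted pseudo-histology
sections, tangle point processes and probability maps, with full ground
truth.

The phantom emulates the measurement chain of a sectioned-tissue study:
a multi-region 3D template volume (one MRI-like contrast channel) is
deformed by an unknown smooth 3D diffeomorphism, sliced on parallel
planes, and each section is independently distorted by a rigid motion
plus a small 2D diffeomorphism, mapped through a monotone nonlinear
contrast change into three stain-like channels carrying region-specific
band-limited texture, and corrupted by tears (missing tissue exposing
the bright slide background) and Gaussian noise.  Tangles are an
inhomogeneous Poisson process with per-region intensity.

Two of the regions are deliberately *confusable in mean stain
intensity* (the contrast nonlinearity saturates over their template
intensities) and differ only in texture carrier frequency, so that
separating them requires the scattering features rather than the
linearly downsampled image.

All outputs are deterministic for a fixed config seed, and every latent
quantity (true maps, tear masks, tangle points, landmark pairs) is
recorded in the ground-truth record.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from . import _interp
from .flows import DiffeoMap, KernelSpec, Rigid2D, VelocityField, integrate_flow
from .grids_io import ImageVolume, SliceImage, SliceStack
from .nft_quant import ProbabilityMap

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "make_template",
    "simulate_sections",
    "simulate_tangles",
    "simulate_probability_map",
    "expected_region_volumes",
]


@dataclasses.dataclass
class PhantomConfig:
    """Default study conditions for the synthetic specimen.

    Geometry is a 96 x 96 x 48 voxel block at 0.125 mm (the working
    resolution of the template), four nested regions (outer ellipsoid,
    C-shaped ring, inner ellipsoid, small sphere), and 8 sections
    0.75 mm apart.  Histology is simulated at 4x finer in-plane
    resolution (0.03125 mm).
    """

    shape: tuple = (48, 96, 96)  # (z, y, x) voxels
    spacing: float = 0.125  # mm, isotropic
    n_regions: int = 4
    region_intensities: tuple = (0.45, 0.65, 0.80, 0.95)
    background_intensity: float = 0.02
    # 3D deformation: amplitude per in-plane component, reduced along z
    # (sectioning distortion is dominantly in-plane)
    deform3d_amp: float = 0.25  # mm
    deform3d_amp_z: float = 0.10  # mm
    deform3d_smooth: float = 1.5  # mm
    # sections
    n_sections: int = 8
    section_spacing: float = 0.75  # mm
    histology_factor: int = 4  # in-plane refinement of the section lattice
    # per-section distortion
    rigid_max_angle: float = np.deg2rad(4.0)
    rigid_max_shift: float = 0.30  # mm
    deform2d_amp: float = 0.08  # mm
    deform2d_smooth: float = 1.0  # mm
    # contrast / texture
    #: texture contrast per region; the outer parenchyma is nearly smooth
    #: so its low-frequency carrier does not leak into the analysis bands
    texture_amps: tuple = (0.04, 0.10, 0.10, 0.10)
    # carriers sit at the two scattering band centres (6 and 12 c/mm at the
    # default analysis scales); regions sharing a band differ in mean stain
    texture_freqs: tuple = (1.5, 6.0, 12.0, 6.0)  # cycles/mm per region
    #: texture wave-vector orientation per region (radians; None = isotropic).
    #: the small sphere carries an oriented (fibre-like) texture so that the
    #: orientation channels separate it from the ring at the same carrier
    texture_orientations: tuple = (None, None, None, 0.0)
    texture_angular_width: float = 0.35  # radians
    texture_bandwidth: float = 3.0  # cycles/mm
    channel_gains: tuple = (1.0, 0.9, 1.1)
    # artifacts
    tear_fraction: float = 0.10  # of tissue pixels per section
    tear_radius_range: tuple = (0.25, 0.50)  # mm
    tear_value: float = 0.88  # bright: torn tissue exposes the slide
    background_value: float = 0.95
    noise_sigma: float = 0.015
    # tangles
    tangle_intensities: tuple = (1.0, 3.0, 8.0, 20.0)  # counts / mm^2
    #: bypass the stain model: sections carry raw template intensity
    identity_contrast: bool = False
    seed: int = 0

    @property
    def spacing3(self):
        return np.full(3, float(self.spacing))

    @property
    def origin3(self):
        return -(np.array(self.shape) - 1) / 2.0 * self.spacing

    @property
    def z_positions(self):
        n = self.n_sections
        return (np.arange(n) - (n - 1) / 2.0) * self.section_spacing

    @property
    def hist_spacing(self):
        return self.spacing / self.histology_factor


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows and the registration must recover."""

    phi: DiffeoMap  # true 3D map (template lattice)
    rigids: list  # per-section Rigid2D
    chis: list  # per-section 2D DiffeoMap (histology lattice)
    z_positions: np.ndarray
    labels2d: list  # per-section region labels on the histology lattice
    tissue_masks: list  # tissue (non-torn, labeled) per section
    tear_masks: list  # bool per section
    tangle_points: list  # (K, 2) world mm per section
    landmarks: list  # per section dict(y_hist (K,2), x_temp (K,3))


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------

def _region_masks(cfg, Z, Y, X):
    """Boolean masks of the four regions (later entries take precedence)."""
    # the outer region is an ellipsoid truncated by the block faces (a cut
    # tissue block: sections are full cross-sections, never pole grazes);
    # inner regions are sized so every planar cap cut by a section is at
    # least ~1 mm across (several feature-resolution elements) and no
    # section grazes a pole within the z-deformation amplitude
    e1 = (Z / 3.6) ** 2 + (Y / 4.4) ** 2 + (X / 4.4) ** 2 <= 1.0
    rad = np.sqrt(Y ** 2 + X ** 2)
    ring = (rad - 2.6) ** 2 + Z ** 2 <= 0.8 ** 2
    wedge = np.abs(np.arctan2(X, Y)) <= np.deg2rad(40.0)
    c_shape = ring & ~wedge & e1
    e3 = ((Z - 0.75) / 1.0) ** 2 + (Y / 1.6) ** 2 + (X / 1.6) ** 2 <= 1.0
    s4 = ((Z + 0.75) / 1.0) ** 2 + ((Y - 3.0) / 1.3) ** 2 + (X / 1.3) ** 2 <= 1.0
    return e1, c_shape, e3 & e1, s4 & e1


def expected_region_volumes(cfg) -> np.ndarray:
    """Analytic volumes (mm^3) of the four region primitives."""
    # outer ellipsoid truncated at the block faces +-zmax
    c = 3.6
    zmax = min((cfg.shape[0] - 1) / 2.0 * cfg.spacing, c)
    v_e1 = 2.0 * np.pi * 4.4 * 4.4 * (zmax - zmax ** 3 / (3.0 * c ** 2))
    v_c = (2.0 * np.pi * 2.6) * (np.pi * 0.8 ** 2) * (280.0 / 360.0)
    v_e3 = 4.0 / 3.0 * np.pi * 1.0 * 1.6 * 1.6
    v_s4 = 4.0 / 3.0 * np.pi * 1.0 * 1.3 * 1.3
    return np.array([v_e1 - v_c - v_e3 - v_s4, v_c, v_e3, v_s4])


def make_template(cfg: PhantomConfig):
    """Build the template volume, its label volume and interior landmarks."""
    shape = tuple(cfg.shape)
    sp, org = cfg.spacing3, cfg.origin3
    ax = [org[a] + sp[a] * np.arange(shape[a]) for a in range(3)]
    Z, Y, X = np.meshgrid(*ax, indexing="ij")
    e1, c_shape, e3, s4 = _region_masks(cfg, Z, Y, X)
    labels = np.zeros(shape, dtype=np.int16)
    labels[e1] = 1
    labels[c_shape] = 2
    labels[e3] = 3
    labels[s4] = 4
    intens = np.full(shape, cfg.background_intensity)
    for j in range(1, cfg.n_regions + 1):
        intens[labels == j] = cfg.region_intensities[j - 1]
    # slight smoothing: tissue interfaces in MRI are not voxel-sharp
    intens = gaussian_filter(intens, 0.5)
    vol = ImageVolume(intens, sp, org)
    lab = ImageVolume(labels.astype(float), sp, org)
    rng = np.random.default_rng(cfg.seed)
    landmarks = []
    for j in range(1, cfg.n_regions + 1):
        idx = np.argwhere(labels == j)
        take = idx[rng.choice(len(idx), size=min(5, len(idx)), replace=False)]
        landmarks.append(take * sp + org)
    return vol, lab, np.concatenate(landmarks, axis=0)


# ---------------------------------------------------------------------------
# random smooth fields / flows
# ---------------------------------------------------------------------------

def _smooth_noise_field(shape, spacing, width_mm, amps, rng):
    """Band-limited random vector field with per-component amplitudes."""
    d = len(shape)
    spacing = np.broadcast_to(np.asarray(spacing, float), (d,))
    out = np.empty(tuple(shape) + (d,))
    sig = width_mm / spacing
    for c in range(d):
        f = gaussian_filter(rng.standard_normal(shape), sig)
        peak = np.max(np.abs(f))
        out[..., c] = f / (peak if peak > 0 else 1.0) * amps[c]
    return out


def _random_flow(shape, spacing, origin, width_mm, amps, rng, nt=2):
    vals = np.stack(
        [_smooth_noise_field(shape, spacing, width_mm, amps, rng) for _ in range(nt)]
    )
    v = VelocityField(vals, spacing, origin, KernelSpec(width_mm))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dmap = integrate_flow(v)
    if np.any(dmap.jacobian_det() <= 0):
        raise RuntimeError("phantom deformation failed the Jacobian check")
    return dmap


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------

def _contrast_channels(i, cfg):
    """Monotone template-intensity -> 3-channel stain map.

    A double-sigmoid that plateaus over the template intensities of the
    ring (0.65) and inner ellipsoid (0.80): those two regions share a
    mean stain intensity (within the texture amplitude) and differ only
    in texture carrier frequency, while the other regions stay
    separable in the mean.
    """
    h = 1.0 / (1.0 + np.exp((i - 0.35) / 0.07))
    h = (h + 0.15 / (1.0 + np.exp((i - 0.875) / 0.03))) / 1.15
    chans = [
        0.10 + 0.85 * h,
        0.08 + 0.80 * h ** 1.15,
        0.15 + 0.75 * h ** 0.95,
    ]
    return np.stack(chans, axis=-1)


def _texture_field(shape, spacing, freq, bandwidth, rng, orientation=None,
                   angular_width=0.35):
    """Unit-variance noise band-passed around a carrier frequency.

    With ``orientation`` set, the pass band is additionally restricted to
    wave vectors near that direction (mod pi), giving a fibre-like
    anisotropic texture.
    """
    noise = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0], d=spacing)
    fx = np.fft.fftfreq(shape[1], d=spacing)
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    rad = np.sqrt(FY ** 2 + FX ** 2)
    filt = np.exp(-0.5 * ((rad - freq) / bandwidth) ** 2)
    if orientation is not None:
        ang = np.arctan2(FY, FX)
        d = np.mod(ang - orientation + np.pi / 2, np.pi) - np.pi / 2
        filt = filt * np.exp(-0.5 * (d / angular_width) ** 2)
    tex = np.fft.ifft2(np.fft.fft2(noise) * filt).real
    sd = tex.std()
    return tex / (sd if sd > 0 else 1.0)


def _nearest_label(labels_vol, points):
    idx = (points - labels_vol.origin) / labels_vol.spacing
    idx = np.clip(
        np.rint(idx), 0, np.array(labels_vol.shape) - 1
    ).astype(int)
    inside = np.ones(points.shape[:-1], dtype=bool)
    raw = (points - labels_vol.origin) / labels_vol.spacing
    for a in range(3):
        inside &= (raw[..., a] >= -0.5) & (raw[..., a] <= labels_vol.shape[a] - 0.5)
    lab = labels_vol.data[idx[..., 0], idx[..., 1], idx[..., 2], 0]
    return np.where(inside, lab, 0.0)


def simulate_sections(template: ImageVolume, labels: ImageVolume,
                      cfg: PhantomConfig):
    """Generate the distorted pseudo-histology stack and its ground truth."""
    rng = np.random.default_rng(cfg.seed + 1)
    sp3, org3 = cfg.spacing3, cfg.origin3
    phi = _random_flow(
        template.shape,
        sp3,
        org3,
        cfg.deform3d_smooth,
        (cfg.deform3d_amp_z, cfg.deform3d_amp, cfg.deform3d_amp),
        rng,
    )
    nf = cfg.shape[1] * cfg.histology_factor
    hsp = np.full(2, cfg.hist_spacing)
    horg = -(nf - 1) / 2.0 * hsp
    hax = [horg[a] + hsp[a] * np.arange(nf) for a in range(2)]
    HY, HX = np.meshgrid(*hax, indexing="ij")
    lattice = np.stack([HY, HX], axis=-1)

    slices, rigids, chis = [], [], []
    labels2d, tissue_masks, tear_masks, tangle_pts, lmk = [], [], [], [], []
    for n, zn in enumerate(cfg.z_positions):
        rig = Rigid2D(
            rng.uniform(-cfg.rigid_max_angle, cfg.rigid_max_angle),
            rng.uniform(-cfg.rigid_max_shift, cfg.rigid_max_shift, size=2),
        )
        chi = _random_flow(
            (nf, nf), hsp, horg, cfg.deform2d_smooth,
            (cfg.deform2d_amp, cfg.deform2d_amp), rng,
        )
        # histology pixel y -> template point, through the true chain
        p1 = rig.inverse().apply(lattice.reshape(-1, 2)).reshape(nf, nf, 2)
        p2 = p1 + _interp.sample(chi.inverse_disp, (p1 - horg) / hsp)
        q = np.concatenate([np.full((nf, nf, 1), zn), p2], axis=-1)
        x = q + _interp.sample(phi.inverse_disp, (q - org3) / sp3)
        tval = _interp.sample(
            template.data, (x - org3) / sp3
        )[..., 0]
        lab2 = _nearest_label(labels, x).astype(int)
        # contrast + texture
        if cfg.identity_contrast:
            channels = np.repeat(tval[..., None], 3, axis=-1)
        else:
            channels = _contrast_channels(tval, cfg)
        for j in range(1, cfg.n_regions + 1):
            mask = lab2 == j
            if not mask.any():
                continue
            tex = _texture_field(
                (nf, nf), cfg.hist_spacing, cfg.texture_freqs[j - 1],
                cfg.texture_bandwidth, rng,
                orientation=cfg.texture_orientations[j - 1],
                angular_width=cfg.texture_angular_width,
            )
            for c in range(3):
                channels[..., c][mask] += (
                    cfg.texture_amps[j - 1] * cfg.channel_gains[c] * tex[mask]
                )
        bg = lab2 == 0
        if not cfg.identity_contrast:
            channels[bg] = cfg.background_value
        # tears: discs of missing tissue stamped to the bright slide value
        tear = np.zeros((nf, nf), dtype=bool)
        tissue = ~bg
        n_tissue = int(tissue.sum())
        target = cfg.tear_fraction * n_tissue
        tissue_idx = np.argwhere(tissue)
        guard = 0
        while tear[tissue].sum() < target and guard < 400:
            guard += 1
            cy, cx = tissue_idx[rng.integers(len(tissue_idx))]
            r = rng.uniform(*cfg.tear_radius_range) / cfg.hist_spacing
            # cap the disc so the torn fraction does not overshoot the target
            remaining = target - tear[tissue].sum()
            r = min(r, max(np.sqrt(remaining / np.pi), 2.0))
            yy, xx = np.ogrid[:nf, :nf]
            tear |= ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2) & tissue
        channels[tear] = cfg.tear_value
        channels += rng.normal(0.0, cfg.noise_sigma, channels.shape)
        channels = np.clip(channels, 0.0, 1.0)
        sl = SliceImage(channels, hsp, horg, z_position=float(zn))

        mask_tissue = tissue & ~tear
        pts = simulate_tangles(
            lab2, cfg.tangle_intensities, rng, hsp, horg, mask=mask_tissue
        )
        # landmark pairs: histology pixel centres and their template points
        cand = np.argwhere(mask_tissue)
        take = cand[rng.choice(len(cand), size=min(12, len(cand)), replace=False)]
        lmk.append(
            {
                "y_hist": take * hsp + horg,
                "x_temp": x[take[:, 0], take[:, 1]],
            }
        )
        slices.append(sl)
        rigids.append(rig)
        chis.append(chi)
        labels2d.append(lab2)
        tissue_masks.append(mask_tissue)
        tear_masks.append(tear)
        tangle_pts.append(pts)
    gt = GroundTruth(
        phi, rigids, chis, np.asarray(cfg.z_positions), labels2d,
        tissue_masks, tear_masks, tangle_pts, lmk,
    )
    return SliceStack(slices), gt


# ---------------------------------------------------------------------------
# tangles and probability maps
# ---------------------------------------------------------------------------

def simulate_tangles(labels2d, intensities, rng, spacing=(1.0, 1.0),
                     origin=(0.0, 0.0), mask=None):
    """Inhomogeneous Poisson tangle points, one intensity per region.

    Counts per region are Poisson(intensity * region area); positions are
    uniform over the region's pixels (jittered within each pixel).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    labels2d = np.asarray(labels2d)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (2,))
    origin = np.asarray(origin, dtype=float).reshape(2)
    pixel_area = spacing[0] * spacing[1]
    pts = []
    for j, lam in enumerate(intensities, start=1):
        sel = labels2d == j
        if mask is not None:
            sel = sel & np.asarray(mask, dtype=bool)
        npix = int(sel.sum())
        if npix == 0 or lam <= 0:
            continue
        count = rng.poisson(lam * npix * pixel_area)
        if count == 0:
            continue
        idx = np.argwhere(sel)
        chosen = idx[rng.integers(0, npix, size=count)]
        jitter = rng.uniform(-0.5, 0.5, size=(count, 2))
        pts.append((chosen + jitter) * spacing + origin)
    if not pts:
        return np.zeros((0, 2))
    return np.concatenate(pts, axis=0)


def simulate_probability_map(points, blob_sigma, noise_sigma, shape, spacing,
                             origin=(0.0, 0.0), rng=None) -> ProbabilityMap:
    """Synthetic per-pixel tangle probability map: Gaussian bumps + noise.

    Each point becomes a bump of peak ~0.85 and width ``blob_sigma`` (mm);
    background noise is half-normal with scale ``noise_sigma``.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (2,))
    origin = np.asarray(origin, dtype=float).reshape(2)
    img = np.zeros(tuple(shape))
    points = np.atleast_2d(np.asarray(points, dtype=float)) if np.size(points) else (
        np.zeros((0, 2))
    )
    for p in points:
        idx = np.rint((p - origin) / spacing).astype(int)
        if np.all(idx >= 0) and np.all(idx < np.array(shape)):
            img[tuple(idx)] += 1.0
    sig_px = blob_sigma / spacing
    img = gaussian_filter(img, sig_px)
    peak = 1.0 / (2.0 * np.pi * sig_px[0] * sig_px[1])
    img = img / peak * 0.85
    if noise_sigma > 0:
        img = img + np.abs(rng.normal(0.0, noise_sigma, img.shape))
    return ProbabilityMap(np.clip(img, 0.0, 1.0), spacing, origin)
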