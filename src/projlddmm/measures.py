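"""Particle-measure representation of per-section pathology.

Detected tangles and sampled tissue area are carried as a discrete
measure: particle i at position ``y_i`` (mm) has weight ``w_i`` (mm^2 of
cross-sectional tissue area) and a feature vector ``f_i`` of length 2l
for l anatomical regions — the first l entries count tangles per region,
the last l give the fraction of ``w_i`` in each region.  At the finest
scale each particle is one pixel and the features are 0/1 indicators.

Maps act on measures by the varifold action: positions move, weights
scale by the (in-plane) Jacobian determinant, features ride along.
Resampling onto coarser sites redistributes mass through a kernel
``pi(source, target)`` normalized over targets per source, so total
weight and total counts are conserved; feature distributions are reduced
to their weighted first moments.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "ParticleMeasure",
    "ResampleKernel",
    "particles_from_slice",
    "transport",
    "transport_chain",
    "resample",
    "reduce_features",
    "nft_density",
]

#: fine-scale particle weight: one 2 um pixel = 4 um^2 = (0.002 mm)^2
FINE_PIXEL_AREA_MM2 = 0.002 ** 2


@dataclasses.dataclass
class ParticleMeasure:
    """Weighted particles with 2l-dimensional count/area-fraction features."""

    points: np.ndarray  # (N, 2) or (N, 3), mm
    weights: np.ndarray  # (N,), mm^2, >= 0
    features: np.ndarray  # (N, 2l)
    n_regions: int
    scale: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.features = np.asarray(self.features, dtype=float)
        l = self.n_regions
        if self.features.shape != (self.points.shape[0], 2 * l):
            raise ValueError("features must have shape (N, 2*n_regions)")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        frac_sum = self.features[:, l:].sum(axis=1)
        if np.any(frac_sum > 1.0 + 1e-9):
            raise ValueError("area fractions must sum to <= 1 per particle")

    @property
    def counts(self):
        return self.features[:, : self.n_regions]

    @property
    def fractions(self):
        return self.features[:, self.n_regions:]

    def total_counts(self):
        """Plain sum of the count block (the tangle total at scale 0)."""
        return self.counts.sum(axis=0)

    def count_mass(self):
        """Mass-weighted count functional sum_i w_i f_i^j.

        This is the quantity conserved by kernel resampling (weights move
        mass, features are reduced to weighted first moments).
        """
        return (self.weights[:, None] * self.counts).sum(axis=0)

    def total_weight(self):
        return float(self.weights.sum())

    def to_frame(self):
        l = self.n_regions
        d = self.points.shape[1]
        cols = {}
        for a, name in zip(range(d), ("z", "y", "x")[-d:] if d <= 3 else None):
            cols[name] = self.points[:, a]
        cols["w_mm2"] = self.weights
        for j in range(l):
            cols[f"count_{j + 1}"] = self.features[:, j]
        for j in range(l):
            cols[f"frac_{j + 1}"] = self.features[:, l + j]
        cols["scale"] = np.full(len(self.weights), self.scale)
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df):
        l = sum(1 for c in df.columns if c.startswith("count_"))
        pt_cols = [c for c in ("z", "y", "x") if c in df.columns]
        pts = df[pt_cols].to_numpy(dtype=float)
        feats = np.concatenate(
            [
                df[[f"count_{j + 1}" for j in range(l)]].to_numpy(dtype=float),
                df[[f"frac_{j + 1}" for j in range(l)]].to_numpy(dtype=float),
            ],
            axis=1,
        )
        scale = int(df["scale"].iloc[0]) if "scale" in df.columns else 0
        return cls(pts, df["w_mm2"].to_numpy(dtype=float), feats, l, scale)


@dataclasses.dataclass
class ResampleKernel:
    """Assignment kernel pi(source, target), normalized per source."""

    kind: str  # "nearest_neighbor" | "gaussian"
    targets: np.ndarray  # (T, d) target sites
    bandwidth: float = 0.125  # mm, gaussian only (template lattice scale)

    def __post_init__(self):
        if self.kind not in ("nearest_neighbor", "gaussian"):
            raise ValueError(f"unknown kernel kind: {self.kind}")
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        if self.targets.shape[0] == 0:
            raise ValueError("target site set is empty")
        if self.kind == "gaussian" and self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def particles_from_slice(tissue_mask, nft_points, region_labels, pixel_area,
                         spacing=None, origin=None):
    """Fine-scale (scale 0) particle measure of one section.

    One particle per pixel.  ``tissue_mask`` (ny, nx) bool; ``region_labels``
    (ny, nx) int in 0..l (0 = background); ``nft_points`` (K, 2) world-mm
    tangle positions; ``pixel_area`` in mm^2.  A tangle is counted in the
    region of the pixel containing it.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    region_labels = np.asarray(region_labels)
    ny, nx = tissue_mask.shape
    spacing = np.ones(2) if spacing is None else np.asarray(spacing, dtype=float)
    origin = np.zeros(2) if origin is None else np.asarray(origin, dtype=float)
    l = int(region_labels.max())
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    pts = np.stack([yy, xx], axis=-1).reshape(-1, 2) * spacing + origin
    w = np.where(tissue_mask.ravel(), float(pixel_area), 0.0)
    feats = np.zeros((ny * nx, 2 * l))
    lab = region_labels.ravel()
    for j in range(1, l + 1):
        feats[(lab == j) & tissue_mask.ravel(), l + j - 1] = 1.0
    nft_points = np.atleast_2d(np.asarray(nft_points, dtype=float)) if len(
        np.atleast_1d(nft_points)
    ) else np.zeros((0, 2))
    for p in nft_points:
        idx = np.rint((p - origin) / spacing).astype(int)
        idx = np.clip(idx, [0, 0], [ny - 1, nx - 1])
        flat = idx[0] * nx + idx[1]
        j = int(lab[flat])
        if w[flat] == 0:
            logger.warning("tangle at %s falls on a zero-weight pixel", p)
        if j > 0:
            feats[flat, j - 1] += 1.0
        else:
            # tangle in unlabeled area: count in the count block of the
            # nearest labeled region is undefined; keep total count by
            # assigning to region of nearest labeled pixel
            lab_idx = np.argwhere(region_labels > 0)
            if len(lab_idx):
                near = lab_idx[np.argmin(np.sum((lab_idx - idx) ** 2, axis=1))]
                feats[flat, int(region_labels[tuple(near)]) - 1] += 1.0
    return ParticleMeasure(pts, w, feats, l, scale=0)


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

def transport(mu: ParticleMeasure, point_map, jacobian_det) -> ParticleMeasure:
    """Varifold action of a map on a particle measure.

    ``point_map`` maps the (N, d) particle positions; ``jacobian_det``
    gives the in-plane Jacobian determinant of the map at each particle
    (callable or array).  Weights scale by |det|; features are carried
    unchanged.
    """
    new_pts = point_map(mu.points)
    jac = jacobian_det(mu.points) if callable(jacobian_det) else np.asarray(jacobian_det)
    jac = np.broadcast_to(np.asarray(jac, dtype=float).ravel(), (len(mu.weights),))
    if np.any(jac <= 0):
        raise ValueError("non-positive Jacobian determinant at a particle")
    return ParticleMeasure(
        new_pts, mu.weights * jac, mu.features.copy(), mu.n_regions, mu.scale
    )


def transport_chain(mu: ParticleMeasure, map2d, z_position, map3d=None) -> ParticleMeasure:
    """Section-to-volume transport: 2D map, embed at z, then 3D map.

    ``map2d`` is a callable ``points -> (points, jac)`` for the in-plane
    map (e.g. the inverse of the estimated section distortion);
    ``map3d``, if given, maps embedded 3D points and returns the in-plane
    area scale of the plane's image (sections carry area, not volume).
    """
    pts2, jac2 = map2d(mu.points)
    out = ParticleMeasure(
        pts2, mu.weights * np.abs(jac2), mu.features.copy(), mu.n_regions, mu.scale
    )
    pts3 = np.concatenate(
        [np.full((len(out.weights), 1), float(z_position)), out.points], axis=1
    )
    if map3d is None:
        return ParticleMeasure(pts3, out.weights, out.features, out.n_regions, out.scale)
    new_pts, area_scale = map3d(pts3)
    if np.any(np.asarray(area_scale) <= 0):
        raise ValueError("non-positive in-plane area scale at a particle")
    return ParticleMeasure(
        new_pts, out.weights * area_scale, out.features, out.n_regions, out.scale
    )


# ---------------------------------------------------------------------------
# resampling across scales
# ---------------------------------------------------------------------------

def resample(mu: ParticleMeasure, kernel: ResampleKernel,
             normalize="source") -> ParticleMeasure:
    """Redistribute a measure onto the kernel's target sites.

    With the default source normalization each source particle
    distributes all of its mass over targets, so total weight and total
    counts are conserved exactly.  Feature vectors at each target are the
    weighted first moments of the incoming feature distribution.
    """
    if normalize not in ("source", "target"):
        raise ValueError("normalize must be 'source' or 'target'")
    T = kernel.targets.shape[0]
    l = mu.n_regions
    w_out = np.zeros(T)
    f_acc = np.zeros((T, 2 * l))
    if kernel.kind == "nearest_neighbor":
        tree = cKDTree(kernel.targets)
        _, assign = tree.query(mu.points)
        np.add.at(w_out, assign, mu.weights)
        np.add.at(f_acc, assign, mu.weights[:, None] * mu.features)
    else:
        d2 = np.sum(
            (mu.points[:, None, :] - kernel.targets[None, :, :]) ** 2, axis=-1
        )
        pi = np.exp(-0.5 * d2 / kernel.bandwidth ** 2)
        if normalize == "source":
            norm = pi.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            pi = pi / norm
        else:
            norm = pi.sum(axis=0, keepdims=True)
            norm[norm == 0] = 1.0
            pi = pi / norm
        w_out = pi.T @ mu.weights
        f_acc = pi.T @ (mu.weights[:, None] * mu.features)
    # gamma reduction: weighted first moment of the incoming feature mixture
    feats = np.zeros_like(f_acc)
    pos = w_out > 0
    feats[pos] = f_acc[pos] / w_out[pos, None]
    return ParticleMeasure(
        kernel.targets.copy(), w_out, feats, l, scale=mu.scale + 1
    )


def reduce_features(feature_vectors, weights=None):
    """First moment per dimension of a (weighted) empirical feature mixture."""
    F = np.atleast_2d(np.asarray(feature_vectors, dtype=float))
    if weights is None:
        weights = np.ones(F.shape[0])
    w = np.asarray(weights, dtype=float).ravel()
    tot = w.sum()
    if tot <= 0:
        logger.warning("zero total weight in feature reduction; returning zeros")
        return np.zeros(F.shape[1])
    return (w[:, None] * F).sum(axis=0) / tot


def nft_density(mu: ParticleMeasure):
    """Total and per-region tangle densities at each particle.

    total density = (sum of count features) / w; per-region density j =
    f^j / (w * f^{l+j}), reported as NaN where the region fraction is 0
    (undefined) and where w = 0.
    """
    l = mu.n_regions
    N = len(mu.weights)
    total = np.full(N, np.nan)
    per_region = np.full((N, l), np.nan)
    pos = mu.weights > 0
    total[pos] = mu.counts[pos].sum(axis=1) / mu.weights[pos]
    for j in range(l):
        frac = mu.fractions[:, j]
        ok = pos & (frac > 0)
        per_region[ok, j] = mu.counts[ok, j] / (mu.weights[ok] * frac[ok])
        undef = pos & (frac == 0) & (mu.counts[:, j] > 0)
        if np.any(undef):
            logger.warning(
                "region %d: %d particles have counts but zero area fraction",
                j + 1,
                int(undef.sum()),
            )
        per_region[pos & (frac == 0) & (mu.counts[:, j] == 0), j] = 0.0
    return total, per_region
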