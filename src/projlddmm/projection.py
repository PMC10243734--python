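"""Measurement channels: planar Dirac slicing and generic z point-spreads.

The observation model composes the deformed 3D volume with a projection
``P_n`` onto section planes ``z_n``.  For histology the point-spread is a
Dirac on the plane (pure slicing); for optically sectioned modalities a
Gaussian point-spread along z mixes neighbouring planes.  Both are linear
in the volume.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grids_io import ImageVolume, SliceImage, SliceStack

__all__ = ["PointSpread", "slice_volume", "apply_pointspread"]


@dataclasses.dataclass
class PointSpread:
    """z-axis point-spread specification.

    kind: ``dirac_plane`` (pure slicing) or ``gaussian_z`` (normalized
    Gaussian weighting along z, truncated at 4 sigma).
    """

    kind: str
    z_positions: np.ndarray
    sigma_z: float = 0.0

    def __post_init__(self):
        if self.kind not in ("dirac_plane", "gaussian_z"):
            raise ValueError(f"unknown point-spread kind: {self.kind}")
        self.z_positions = np.atleast_1d(np.asarray(self.z_positions, dtype=float))
        if self.kind == "gaussian_z" and self.sigma_z <= 0:
            raise ValueError("sigma_z must be > 0 for gaussian_z")


def slice_volume(volume: ImageVolume, z: float) -> SliceImage:
    """Extract the plane I(., ., z) by 1D linear interpolation along z."""
    z0 = volume.origin[0]
    nz = volume.shape[0]
    zi = (float(z) - z0) / volume.spacing[0]
    if zi < 0 or zi > nz - 1:
        raise ValueError(
            f"plane z={z} outside volume z-range "
            f"[{z0}, {z0 + (nz - 1) * volume.spacing[0]}]"
        )
    k = int(np.floor(zi))
    k = min(k, nz - 2) if nz > 1 else 0
    f = zi - k
    data = (1.0 - f) * volume.data[k] + f * volume.data[min(k + 1, nz - 1)]
    return SliceImage(data, volume.spacing[1:], volume.origin[1:], z_position=float(z))


def apply_pointspread(volume: ImageVolume, psf: PointSpread) -> SliceStack:
    """Apply the measurement channel, one output section per z position."""
    slices = []
    if psf.kind == "dirac_plane":
        for z in psf.z_positions:
            slices.append(slice_volume(volume, z))
        return SliceStack(slices)
    # gaussian_z: normalized discrete Gaussian over lattice planes within 4 sigma
    z_planes = volume.origin[0] + volume.spacing[0] * np.arange(volume.shape[0])
    for z in psf.z_positions:
        w = np.exp(-0.5 * ((z_planes - z) / psf.sigma_z) ** 2)
        w[np.abs(z_planes - z) > 4.0 * psf.sigma_z] = 0.0
        if w.sum() <= 0:
            raise ValueError(f"gaussian_z support empty at z={z}")
        w = w / w.sum()
        data = np.tensordot(w, volume.data, axes=(0, 0))
        slices.append(
            SliceImage(data, volume.spacing[1:], volume.origin[1:], z_position=float(z))
        )
    return SliceStack(slices)
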