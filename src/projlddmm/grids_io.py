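"""Image containers, world/index conventions, resampling and file I/O.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(z, y, x)`` for volumes and ``(y, x)`` for section
  images, with an optional trailing channel axis.
* All geometry is expressed in world millimetres with a voxel-centre
  convention: the world coordinate of voxel ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing`` (components in array order).
* World points are therefore ``(z, y, x)`` triples / ``(y, x)`` pairs in mm.

Volumes round-trip through NIfTI; 2D sections through TIFF (float) or PNG
(uint8) with a JSON sidecar carrying ``spacing``/``origin``/``z_position``,
because raster-metadata dialects for those fields are unreliable.  Point
sets and particle tables are CSV; meshes are PLY via trimesh.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
import tifffile
from PIL import Image as _PILImage
from scipy.ndimage import map_coordinates

__all__ = [
    "ImageVolume",
    "SliceImage",
    "SliceStack",
    "interpolate",
    "block_downsample",
    "read_volume",
    "write_volume",
    "read_slice",
    "write_slice",
    "read_points",
    "write_points",
    "read_mesh",
    "write_mesh",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _as_channel_last(data, ndim_spatial):
    data = np.asarray(data)
    if data.ndim == ndim_spatial:
        data = data[..., None]
    if data.ndim != ndim_spatial + 1:
        raise ValueError(
            f"expected {ndim_spatial}D or {ndim_spatial + 1}D data, got shape {data.shape}"
        )
    return data


@dataclasses.dataclass
class ImageVolume:
    """An r-channel scalar field on a 3D lattice.

    ``data`` has shape ``(nz, ny, nx, r)`` (a 3D array is promoted to one
    channel).  ``spacing`` and ``origin`` are length-3 mm vectors in
    ``(z, y, x)`` order.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.data = _as_channel_last(self.data, 3).astype(np.float64, copy=False)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError("spacing components must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self):
        return self.data.shape[:3]

    @property
    def channels(self):
        return self.data.shape[3]

    def world_to_index(self, points):
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, idx):
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def lattice_world(self):
        """World coordinates of every voxel centre, shape (nz, ny, nx, 3)."""
        ax = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack(g, axis=-1)


@dataclasses.dataclass
class SliceImage:
    """A q-channel field on a 2D lattice at section plane ``z_position``."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    z_position: float = 0.0

    def __post_init__(self):
        self.data = _as_channel_last(self.data, 2).astype(np.float64, copy=False)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(2)
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        self.z_position = float(self.z_position)
        if not np.all(self.spacing > 0):
            raise ValueError("spacing components must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("slice contains non-finite values")

    @property
    def shape(self):
        return self.data.shape[:2]

    @property
    def channels(self):
        return self.data.shape[2]

    def world_to_index(self, points):
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def lattice_world(self):
        ax = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(2)]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack(g, axis=-1)


@dataclasses.dataclass
class SliceStack:
    """Ordered list of sections with strictly increasing z positions."""

    slices: list

    def __post_init__(self):
        z = [s.z_position for s in self.slices]
        if any(b <= a for a, b in zip(z, z[1:])):
            raise ValueError("slice z_positions must be strictly increasing")

    def __len__(self):
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    def __getitem__(self, i):
        return self.slices[i]

    @property
    def z_positions(self):
        return np.array([s.z_position for s in self.slices])


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def interpolate(volume, points, fill=0.0, order=1):
    """Sample a volume or slice at world-mm points.

    Trilinear (``order=1``) or nearest-neighbour (``order=0``, for label
    images) interpolation in world coordinates.  Points outside the lattice
    hull return ``fill``.

    Parameters
    ----------
    volume : ImageVolume or SliceImage
    points : (..., d) array of world coordinates (d = 3 or 2, array order)
    fill : scalar value returned outside the hull

    Returns
    -------
    (..., channels) array of sampled values.
    """
    points = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(points)):
        raise ValueError("query points must be finite")
    d = 3 if isinstance(volume, ImageVolume) else 2
    if points.shape[-1] != d:
        raise ValueError(f"points must have {d} components")
    idx = volume.world_to_index(points)
    shape = volume.shape
    outside = np.zeros(points.shape[:-1], dtype=bool)
    tol = 1e-6  # voxels; voxel centres must never round outside the hull
    for a in range(d):
        outside |= (idx[..., a] < -tol) | (idx[..., a] > shape[a] - 1 + tol)
    coords = [idx[..., a].ravel() for a in range(d)]
    out = np.empty(points.shape[:-1] + (volume.channels,))
    for c in range(volume.channels):
        vals = map_coordinates(
            volume.data[..., c], coords, order=order, mode="nearest"
        )
        out[..., c] = vals.reshape(points.shape[:-1])
    out[outside] = fill
    return out


def block_downsample(image, target_spacing):
    """Average-pool a SliceImage (or ImageVolume) onto a coarser lattice.

    ``target_spacing`` must be an integer multiple of the input spacing on
    every axis.  Each output pixel is the unweighted mean of its source
    block; the origin shifts so output pixel centres sit at block centres.
    """
    d = 3 if isinstance(image, ImageVolume) else 2
    target = np.broadcast_to(np.asarray(target_spacing, dtype=float), (d,))
    ratio = target / image.spacing
    factors = np.rint(ratio).astype(int)
    if np.any(np.abs(ratio - factors) > 1e-8) or np.any(factors < 1):
        raise ValueError(
            f"target spacing {target} is not an integer multiple of input "
            f"spacing {image.spacing}; resample via interpolate() instead"
        )
    shape = np.array(image.shape)
    trimmed = (shape // factors) * factors
    sl = tuple(slice(0, int(t)) for t in trimmed)
    data = image.data[sl]
    new_shape = []
    for a in range(d):
        new_shape += [int(trimmed[a] // factors[a]), int(factors[a])]
    new_shape.append(image.channels)
    data = data.reshape(new_shape)
    data = data.mean(axis=tuple(range(1, 2 * d, 2)))
    new_spacing = image.spacing * factors
    new_origin = image.origin + (factors - 1) / 2.0 * image.spacing
    if d == 3:
        return ImageVolume(data, new_spacing, new_origin)
    return SliceImage(data, new_spacing, new_origin, image.z_position)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_volume(path, volume):
    """Write an ImageVolume as NIfTI (data stored x-fastest)."""
    path = str(path)
    # our array is (z, y, x, c); NIfTI wants (x, y, z[, c])
    arr = np.moveaxis(volume.data, (0, 1, 2), (2, 1, 0))
    if arr.shape[-1] == 1:
        arr = arr[..., 0]
    affine = np.eye(4)
    affine[0, 0] = volume.spacing[2]
    affine[1, 1] = volume.spacing[1]
    affine[2, 2] = volume.spacing[0]
    affine[:3, 3] = volume.origin[::-1]
    nib.save(nib.Nifti1Image(arr, affine), path)


def read_volume(path):
    path = str(path)
    img = nib.load(path)
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise ValueError(f"{path}: non-axis-aligned affine not supported")
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., None]
    data = np.moveaxis(arr, (0, 1, 2), (2, 1, 0))
    spacing = np.abs(np.diag(affine[:3, :3]))[::-1]
    origin = affine[:3, 3][::-1]
    return ImageVolume(data, spacing, origin)


def _sidecar_path(path):
    return Path(str(path) + ".json")


def write_slice(path, sl):
    """Write a SliceImage as TIFF (float) or PNG (uint8) plus JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), sl.data.astype(np.float32))
    elif path.suffix.lower() == ".png":
        arr = np.clip(np.rint(sl.data * 255.0), 0, 255).astype(np.uint8)
        if arr.shape[-1] == 1:
            arr = arr[..., 0]
        _PILImage.fromarray(arr).save(str(path))
    else:
        raise ValueError(f"unsupported slice format: {path.suffix}")
    meta = {
        "spacing": sl.spacing.tolist(),
        "origin": sl.origin.tolist(),
        "z_position": sl.z_position,
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_slice(path):
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(
            f"{path}: missing JSON sidecar {sidecar.name} "
            "(required fields: spacing, origin, z_position)"
        )
    meta = json.loads(sidecar.read_text())
    for field in ("spacing", "origin", "z_position"):
        if field not in meta:
            raise ValueError(f"{sidecar}: missing required field '{field}'")
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(str(path)).astype(np.float64)
    elif path.suffix.lower() == ".png":
        data = np.asarray(_PILImage.open(str(path)), dtype=np.float64) / 255.0
    else:
        raise ValueError(f"unsupported slice format: {path.suffix}")
    return SliceImage(data, meta["spacing"], meta["origin"], meta["z_position"])


def write_points(path, df):
    """Write a point/particle table (DataFrame or (N, d) array) as CSV."""
    if not isinstance(df, pd.DataFrame):
        arr = np.atleast_2d(np.asarray(df, dtype=float))
        cols = ["z", "y", "x"][-arr.shape[1]:] if arr.shape[1] <= 3 else [
            f"c{i}" for i in range(arr.shape[1])
        ]
        df = pd.DataFrame(arr, columns=cols)
    df.to_csv(str(path), index=False)


def read_points(path):
    try:
        return pd.read_csv(str(path))
    except Exception as exc:  # pragma: no cover - message content only
        raise ValueError(f"{path}: failed to parse point CSV: {exc}") from exc


def write_mesh(path, mesh):
    """Write a trimesh.Trimesh (PLY, ascii)."""
    import trimesh

    if not isinstance(mesh, trimesh.Trimesh):
        raise TypeError("write_mesh expects a trimesh.Trimesh")
    mesh.export(str(path), encoding="ascii")


def read_mesh(path):
    import trimesh

    mesh = trimesh.load(str(path), process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path}: does not contain a triangle mesh")
    return mesh
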