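"""Volumetric image containers, TIFF I/O and geometric preprocessing.

Arrays are ordered ``(z, y, x)`` with ``z`` the slice index; after
reorientation ``z`` is the along-spike axis.  Indices are 0-based, a voxel's
physical position is ``index * voxel_size_um / 1000`` millimetres, and voxels
are cubic.  Intensities are 16-bit unsigned grayscale; 8-bit input is widened
to 16-bit without rescaling so that absolute thresholds stay comparable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi

#: Voxel edge length used by the reference scans, in micrometres.
DEFAULT_VOXEL_SIZE_UM = 77.0

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class Volume:
    """A 3D grayscale image with cubic voxels.

    Parameters
    ----------
    intensities
        ``(z, y, x)`` array of non-negative integers in the 16-bit range.
    voxel_size_um
        Physical edge length of the cubic voxel in micrometres (> 0).
    """

    intensities: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError("intensities must be a non-empty 3D (z, y, x) array")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("intensities must be an integer array")
        if arr.dtype != np.uint16:
            if arr.min() < 0 or arr.max() > 65535:
                raise ValueError("intensities must lie in [0, 65535]")
            arr = arr.astype(np.uint16)
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        self.intensities = arr
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3


@dataclass
class BinaryMask:
    """Foreground mask with the same shape and voxel semantics as its source."""

    values: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError("mask must be 3D")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        if not np.issubdtype(arr.dtype, np.integer) or arr.min() < 0 or arr.max() > 1:
            raise ValueError("mask values must be 0/1")
        self.values = arr.astype(np.uint8)
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class LabelMap:
    """Instance segmentation: 0 = background, 1..K = grain ids."""

    labels: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("labels must be integers")
        if arr.size and arr.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = arr.astype(np.int32)
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0


def _read_grayscale_tiff(path: Path) -> np.ndarray:
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        if "S" in series.axes:  # samples axis => colour image
            raise ValueError(f"{path}: non-grayscale TIFF (colour pages)")
        arr = series.asarray()
    return arr


def _promote(arr: np.ndarray, source: str) -> np.ndarray:
    if arr.dtype == np.uint16:
        return arr
    if arr.dtype == np.uint8:
        # value-preserving widening: 8-bit thresholds stay meaningful
        return arr.astype(np.uint16)
    raise ValueError(f"{source}: expected 8- or 16-bit unsigned grayscale, got {arr.dtype}")


def read_volume(path: str | Path, voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM) -> Volume:
    """Read a multi-page TIFF or a directory of single-page TIFF slices.

    Directory slices are sorted lexicographically; ascending file order
    defines ascending ``z``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES)
        if not files:
            raise ValueError(f"{path}: directory contains no TIFF slices")
        slices = []
        shape = None
        for f in files:
            page = _read_grayscale_tiff(f)
            if page.ndim != 2:
                raise ValueError(f"{f}: expected a single 2D page per slice file")
            if shape is None:
                shape = page.shape
            elif page.shape != shape:
                raise ValueError(
                    f"{f}: slice shape {page.shape} inconsistent with {shape}"
                )
            slices.append(_promote(page, str(f)))
        arr = np.stack(slices, axis=0)
    else:
        arr = _read_grayscale_tiff(path)
        if arr.ndim == 2:
            arr = arr[None, ...]
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected 2D/3D grayscale data, got ndim={arr.ndim}")
        arr = _promote(arr, str(path))
    return Volume(arr, voxel_size_um)


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a Volume as a 16-bit multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, volume.intensities, photometric="minisblack")
    return path


def write_label_map(labels: LabelMap, path: str | Path) -> Path:
    """Write a LabelMap as 16-bit multi-page TIFF; round-trips exactly."""
    if labels.n_labels > 65535:
        raise ValueError("label ids exceed the 16-bit range")
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.uint16), photometric="minisblack")
    return path


def read_label_map(path: str | Path, voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    arr = _read_grayscale_tiff(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return LabelMap(arr.astype(np.int32), voxel_size_um)


def crop_cylinder(
    volume: Volume,
    center_yx: tuple[float, float],
    radius_vox: float,
    z_range: tuple[int, int],
) -> Volume:
    """Extract the axis-aligned bounding box of a vertical cylinder.

    The cylinder axis is parallel to ``z`` through ``center_yx`` (voxel
    coordinates); voxels outside the circular cross-section are set to 0.
    Mirrors the manual step of cutting each spike's cylindrical column out
    of a multi-spike scan.
    """
    if radius_vox <= 0:
        raise ValueError("radius_vox must be positive")
    nz, ny, nx = volume.shape
    z0 = max(int(z_range[0]), 0)
    z1 = min(int(z_range[1]), nz)
    if z1 <= z0:
        raise ValueError("cylinder does not intersect the volume (empty z range)")
    cy, cx = center_yx
    yy, xx = np.ogrid[0:ny, 0:nx]
    circle = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_vox**2
    if not circle.any():
        raise ValueError("cylinder does not intersect the volume (empty cross-section)")
    ys, xs = np.nonzero(circle)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    sub = volume.intensities[z0:z1, y0:y1, x0:x1].copy()
    sub[:, ~circle[y0:y1, x0:x1]] = 0
    return Volume(sub, volume.voxel_size_um)


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix (in zyx coordinates) taking ``axis`` onto +z."""
    ez = np.array([1.0, 0.0, 0.0])  # +z in (z, y, x) ordering
    axis = axis / np.linalg.norm(axis)
    cosang = float(np.clip(axis @ ez, -1.0, 1.0))
    if cosang > 1.0 - 1e-12:
        return np.eye(3)
    k = np.cross(axis, ez)
    sinang = np.linalg.norm(k)
    if sinang < 1e-12:  # antiparallel: rotate 180 deg about y
        return np.diag([-1.0, 1.0, -1.0])
    k = k / sinang
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + sinang * kx + (1 - cosang) * (kx @ kx)


def reorient_to_vertical(
    volume: Volume,
    threshold: float,
    min_foreground: int = 100,
    identity_tol_deg: float = 0.1,
) -> tuple[Volume, dict]:
    """Rotate the spike so its principal axis aligns with +z.

    The first principal component of the above-threshold voxel coordinate
    cloud is rotated onto the z axis about the cloud centroid, with
    nearest-neighbour resampling so intensity values stay discrete.  The
    output grid is padded to contain the whole rotated input.  Tilts below
    ``identity_tol_deg`` are treated as already vertical and returned
    unresampled.

    Returns the rotated volume and a description of the applied rotation
    (``angle_deg``, ``matrix_zyx``, ``centroid_zyx``).
    """
    arr = volume.intensities
    coords = np.argwhere(arr > threshold).astype(float)
    if coords.shape[0] < min_foreground:
        raise ValueError(
            f"only {coords.shape[0]} voxels exceed the threshold; "
            f"need >= {min_foreground} to define a principal axis"
        )
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    eigval, eigvec = np.linalg.eigh(cov)
    axis = eigvec[:, np.argmax(eigval)]
    if axis[0] < 0:
        axis = -axis
    rot = _rotation_to_z(axis)
    angle_deg = math.degrees(math.acos(float(np.clip(axis[0], -1.0, 1.0))))
    if angle_deg < identity_tol_deg:
        info = {
            "angle_deg": angle_deg,
            "axis_zyx": axis.tolist(),
            "matrix_zyx": np.eye(3).tolist(),
            "centroid_zyx": centroid.tolist(),
        }
        return Volume(arr.copy(), volume.voxel_size_um), info

    corners = np.array(
        list(itertools.product(*[(0, s - 1) for s in arr.shape])), dtype=float
    )
    rotated_corners = (rot @ (corners - centroid).T).T
    mins = rotated_corners.min(axis=0)
    maxs = rotated_corners.max(axis=0)
    out_shape = tuple(int(math.ceil(mx - mn)) + 1 for mn, mx in zip(mins, maxs))
    # affine_transform maps output index p_out to input index R.T @ p_out + offset
    offset = centroid + rot.T @ mins
    out = ndi.affine_transform(
        arr,
        rot.T,
        offset=offset,
        output_shape=out_shape,
        order=0,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    info = {
        "angle_deg": angle_deg,
        "axis_zyx": axis.tolist(),
        "matrix_zyx": rot.tolist(),
        "centroid_zyx": centroid.tolist(),
    }
    return Volume(out, volume.voxel_size_um), info
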