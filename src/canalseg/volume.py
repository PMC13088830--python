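"""3D volume and binary-mask containers with NIfTI I/O, cropping and resampling.

Conventions (fixed package-wide):

* Arrays are indexed ``(z, y, x)`` — axial slices are ``data[k]``.
* ``voxel_size`` is mm per axis, ``(z, y, x)`` ordered, all components > 0.
* ``origin`` is the world position (mm, ``(z, y, x)``) of the *center* of
  voxel ``(0, 0, 0)``; the world coordinate of index ``(k, j, i)`` is
  ``origin + (k, j, i) * voxel_size`` (voxel-center convention, 0-based).
* Crop boxes are half-open index intervals ``[lo, hi)``.
* NIfTI files are written RAS+ with a diagonal affine; any input NIfTI is
  reoriented to this canonical frame on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "BinaryMask",
    "CropBox",
    "read_volume",
    "write_volume",
    "resample_volume",
    "crop_to_box",
    "tooth_crop_box",
    "binarize",
]


def _as_triple(value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,):
        raise ValueError(f"expected scalar or length-3 value, got shape {arr.shape}")
    return arr


@dataclass
class Volume3D:
    """A 3D scalar image on a regular grid.

    Attributes
    ----------
    data : (nz, ny, nx) ndarray
        Scalar values; must be finite.
    voxel_size : (3,) ndarray
        mm per axis, (z, y, x) ordered, strictly positive.
    origin : (3,) ndarray
        World position (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __init__(self, data, voxel_size, origin=(0.0, 0.0, 0.0)):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3D array, got {data.ndim}D")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume data contains non-finite values")
        vs = _as_triple(voxel_size)
        if np.any(vs <= 0):
            raise ValueError(f"voxel_size must be positive, got {vs}")
        self.data = data
        self.voxel_size = vs
        self.origin = _as_triple(origin)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of (possibly fractional) (z, y, x) indices."""
        return np.atleast_2d(np.asarray(indices, dtype=float)) * self.voxel_size + self.origin

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional (z, y, x) indices of world points (mm)."""
        return (np.atleast_2d(np.asarray(points, dtype=float)) - self.origin) / self.voxel_size

    def copy(self) -> "Volume3D":
        return type(self)(self.data.copy(), self.voxel_size.copy(), self.origin.copy())

    def same_grid(self, other: "Volume3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


class BinaryMask(Volume3D):
    """A Volume3D whose values are restricted to {0, 1} (stored uint8)."""

    def __init__(self, data, voxel_size, origin=(0.0, 0.0, 0.0)):
        data = np.asarray(data)
        if data.dtype != np.uint8:
            if not np.isin(np.unique(data), (0, 1)).all():
                raise ValueError("mask data must contain only 0 and 1")
            data = data.astype(np.uint8)
        elif data.size and data.max() > 1:
            raise ValueError("mask data must contain only 0 and 1")
        super().__init__(data, voxel_size, origin)

    @property
    def count(self) -> int:
        """Number of foreground (1) voxels."""
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * float(np.prod(self.voxel_size))

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass(frozen=True)
class CropBox:
    """Half-open per-axis index intervals [lo, hi) on a source grid."""

    lo: tuple
    hi: tuple

    def __post_init__(self):
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        if len(lo) != 3 or len(hi) != 3:
            raise ValueError("CropBox needs three axes")
        for axis, (a, b) in enumerate(zip(lo, hi)):
            if a < 0:
                raise ValueError(f"axis {axis}: lo must be >= 0, got {a}")
            if b <= a:
                raise ValueError(f"axis {axis}: hi must exceed lo, got [{a}, {b})")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def widths(self) -> tuple:
        return tuple(b - a for a, b in zip(self.lo, self.hi))

    def slices(self) -> tuple:
        return tuple(slice(a, b) for a, b in zip(self.lo, self.hi))

    def validate_for(self, vol: Volume3D) -> None:
        for axis, (b, n) in enumerate(zip(self.hi, vol.shape)):
            if b > n:
                raise ValueError(
                    f"crop box axis {axis} ends at {b} but volume extent is {n}"
                )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI-1 (RAS+, diagonal affine).

    The (z, y, x) array is transposed to the NIfTI (x, y, z) axis order;
    the affine diagonal carries the voxel size and the translation carries
    the origin. Masks are stored as uint8, float images as float32.
    """
    path = Path(path)
    data = vol.data
    if isinstance(vol, BinaryMask):
        out = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer):
        out = data.astype(np.int16)
    else:
        out = data.astype(np.float32)
    # (z, y, x) -> (x, y, z)
    arr = np.transpose(out, (2, 1, 0))
    affine = np.eye(4)
    affine[0, 0] = vol.voxel_size[2]
    affine[1, 1] = vol.voxel_size[1]
    affine[2, 2] = vol.voxel_size[0]
    affine[:3, 3] = vol.origin[::-1]
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(tuple(float(v) for v in vol.voxel_size[::-1]))
    nib.save(img, str(path))


def read_volume(path, as_mask: bool = False) -> Volume3D:
    """Read a NIfTI-1 file into a :class:`Volume3D` (or :class:`BinaryMask`).

    The image is reoriented to the canonical RAS+ frame; voxel size is taken
    from the affine column norms and the origin from its translation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(
            f"{path} is {len(img.shape)}-dimensional; only 3D volumes are supported"
        )
    affine = np.asarray(img.affine, dtype=float)
    if not np.all(np.isfinite(affine)):
        raise ValueError(f"{path} has a non-finite affine")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path} has a singular (non-invertible) affine")
    img = nib.as_closest_canonical(img)
    arr = np.asanyarray(img.dataobj)
    affine = img.affine
    voxel_xyz = np.linalg.norm(affine[:3, :3], axis=0)
    origin_xyz = affine[:3, 3]
    data = np.transpose(arr, (2, 1, 0))  # (x,y,z) -> (z,y,x)
    voxel = voxel_xyz[::-1]
    origin = origin_xyz[::-1]
    if as_mask:
        return BinaryMask(np.rint(data).astype(np.uint8), voxel, origin)
    return Volume3D(data, voxel, origin)


# ---------------------------------------------------------------------------
# Resampling / cropping
# ---------------------------------------------------------------------------

def resample_volume(vol: Volume3D, target_voxel_size, mode: str = "linear") -> Volume3D:
    """Resample onto a grid of ``target_voxel_size`` covering the same world extent.

    The output extent per axis is ``ceil(n_in * size_in / size_out)`` and the
    output origin coincides with the input origin, so resampling at the source
    voxel size is the identity. Values are interpolated at output voxel-center
    world coordinates; sites outside the input support are filled with the
    image minimum (background).
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    target = _as_triple(target_voxel_size)
    if np.any(target <= 0):
        raise ValueError(f"target voxel size must be positive, got {target}")
    n_in = np.asarray(vol.shape)
    n_out = np.ceil(n_in * vol.voxel_size / target - 1e-9).astype(int)
    n_out = np.maximum(n_out, 1)
    # output voxel-center index j maps to source index j * target / in_size
    coords = [
        np.arange(n_out[a]) * (target[a] / vol.voxel_size[a]) for a in range(3)
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    order = 1 if mode == "linear" else 0
    src = vol.data.astype(np.float32)
    fill = float(src.min()) if src.size else 0.0
    out = ndimage.map_coordinates(
        src, np.stack(grid), order=order, mode="constant", cval=fill
    )
    if isinstance(vol, BinaryMask) and mode == "nearest":
        return BinaryMask(np.rint(out).astype(np.uint8), target, vol.origin.copy())
    return Volume3D(out, target, vol.origin.copy())


def crop_to_box(vol: Volume3D, box: CropBox) -> Volume3D:
    """Extract the sub-volume of ``box``; the origin shifts by ``lo * voxel_size``."""
    box.validate_for(vol)
    data = vol.data[box.slices()].copy()
    origin = vol.origin + np.asarray(box.lo) * vol.voxel_size
    return type(vol)(data, vol.voxel_size.copy(), origin)


def tooth_crop_box(tooth_mask: BinaryMask, axial_size: int, z_margin: int = 2) -> CropBox:
    """In-plane window of ``axial_size``² centered on the mask centroid.

    The z-range is the mask's z bounding box padded by ``z_margin`` slices;
    all intervals are clamped to the grid. The in-plane window must be able
    to contain the mask's in-plane bounding box.
    """
    fg = tooth_mask.as_bool()
    if not fg.any():
        raise ValueError("cannot place a crop box around an empty mask")
    nz, ny, nx = fg.shape
    zs, ys, xs = np.nonzero(fg)
    for name, idx, n in (("y", ys, ny), ("x", xs, nx)):
        width = int(idx.max() - idx.min() + 1)
        if axial_size < width:
            raise ValueError(
                f"axial_size={axial_size} is smaller than the mask's in-plane "
                f"{name}-extent of {width}"
            )
    box_lo, box_hi = [0, 0, 0], [0, 0, 0]
    z_lo = max(0, int(zs.min()) - int(z_margin))
    z_hi = min(nz, int(zs.max()) + 1 + int(z_margin))
    box_lo[0], box_hi[0] = z_lo, z_hi
    for axis, (idx, n) in enumerate([(ys, ny), (xs, nx)], start=1):
        c = float(idx.mean())
        lo = int(round(c - axial_size / 2.0))
        lo = max(0, min(lo, n - axial_size)) if n >= axial_size else 0
        hi = min(n, lo + axial_size)
        box_lo[axis], box_hi[axis] = lo, hi
    return CropBox(tuple(box_lo), tuple(box_hi))


def binarize(vol: Volume3D, threshold: float) -> BinaryMask:
    """Threshold a volume; values >= threshold (ties included) become foreground."""
    return BinaryMask(
        (vol.data >= threshold).astype(np.uint8), vol.voxel_size.copy(), vol.origin.copy()
    )
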