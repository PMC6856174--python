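"""Volumes, label maps and the voxel geometry shared by every other module.

Conventions used throughout the package, stated once here:

* voxel indices are 0-based ``(i, j, k)`` triples into a C-ordered array;
* bounding boxes are half-open at the top: the box with lower corner
  ``(i0, j0, k0)`` and size ``(di, dj, dk)`` covers ``i0 <= i < i0 + di`` etc.;
* cubic patches are flattened in lexicographic order over the offsets
  (first axis slowest, last axis fastest — C order), so the center element
  of a radius-``r_p`` patch sits at flat position ``(n - 1) // 2``;
* patches that straddle the volume border are filled by nearest-edge
  replication;
* internal computation is 64-bit float; images are written to disk as
  float32 and label maps as uint8 with values in {0, 1}.  The signed
  {-1, +1} label convention is internal only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelMap",
    "BoundingBox",
    "PatchGeometry",
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "extract_patch",
    "extract_patches",
    "patch_offsets",
    "crop",
    "crop_labels",
    "embed",
]


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing (mm) and a reference origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume data must be 3D, got {self.data.ndim} dimensions"
            )
        if min(self.data.shape) < 1:
            raise ValueError(f"Volume shape must be positive, got {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"Voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelMap:
    """A binary segmentation aligned to a :class:`Volume`.

    ``data`` holds {0, 1} (uint8); use :meth:`signed` for the internal
    {-1, +1} representation.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"LabelMap must be 3D, got {arr.ndim} dimensions")
        values = np.unique(arr)
        if not np.all(np.isin(values, (0, 1))):
            raise ValueError(
                f"LabelMap may contain only {{0, 1}}, found values {values[:10]}"
            )
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def signed(self) -> np.ndarray:
        """Return the labels as int8 in {-1, +1} (foreground = +1)."""
        return (self.data.astype(np.int8) * 2) - 1


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned voxel box, half-open on the upper side."""

    lower: tuple[int, int, int]
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError(f"BoundingBox size must be positive, got {self.size}")

    @property
    def upper(self) -> tuple[int, int, int]:
        return tuple(lo + s for lo, s in zip(self.lower, self.size))  # type: ignore[return-value]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))  # type: ignore[return-value]

    def contains(self, shape: tuple[int, int, int]) -> bool:
        return all(lo >= 0 for lo in self.lower) and all(
            hi <= s for hi, s in zip(self.upper, shape)
        )


@dataclass(frozen=True)
class PatchGeometry:
    """Patch radius ``r_p`` and search radius ``r_s``, both in voxels.

    The feature patch has ``n = (2 r_p + 1)**3`` voxels; the search
    neighborhood supplying training voxels has ``(2 r_s + 1)**3``.
    """

    r_p: int = 4
    r_s: int = 1

    def __post_init__(self) -> None:
        if self.r_p < 1:
            raise ValueError(f"patch radius r_p must be >= 1, got {self.r_p}")
        if self.r_s < 0:
            raise ValueError(f"search radius r_s must be >= 0, got {self.r_s}")

    @property
    def n(self) -> int:
        return (2 * self.r_p + 1) ** 3

    @property
    def neighborhood_size(self) -> int:
        return (2 * self.r_s + 1) ** 3


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1 image as a :class:`Volume`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt header, truncated file, ...
        raise IOError(f"cannot read NIfTI volume from {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}D after squeezing; expected 3D")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin)


def write_volume(vol: Volume, path) -> None:
    """Write a :class:`Volume` as float32 NIfTI-1."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_label_map(path) -> LabelMap:
    """Read a binary NIfTI label map; any nonzero voxel counts as foreground."""
    vol = read_volume(path)
    return LabelMap((vol.data > 0.5).astype(np.uint8), vol.spacing, vol.origin)


def write_label_map(lab: LabelMap, path) -> None:
    img = nib.Nifti1Image(lab.data.astype(np.uint8), _affine(lab.spacing, lab.origin))
    img.header.set_zooms(lab.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Patch geometry


def patch_offsets(r: int) -> np.ndarray:
    """All ``(2r+1)**3`` integer offsets of a cubic patch, lexicographic order.

    The first axis varies slowest and the last fastest, so the zero offset
    sits at flat index ``((2r+1)**3 - 1) // 2``.
    """
    rng = np.arange(-r, r + 1)
    return np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)


def extract_patch(vol: Volume | np.ndarray, center, r_p: int) -> np.ndarray:
    """Intensities of the cubic patch of radius ``r_p`` centred at ``center``.

    Returns a flat vector of length ``(2 r_p + 1)**3`` in the package's fixed
    lexicographic order; out-of-volume voxels are filled by nearest-edge
    replication.  ``center`` must lie inside the volume.
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    center = np.asarray(center, dtype=np.intp)
    if np.any(center < 0) or np.any(center >= data.shape):
        raise IndexError(f"patch center {tuple(center)} outside volume of shape {data.shape}")
    return extract_patches(data, center[None, :], r_p)[0]


def extract_patches(data: np.ndarray, centers: np.ndarray, r_p: int) -> np.ndarray:
    """Vectorised :func:`extract_patch` for a ``(K, 3)`` array of centers.

    Returns a ``(K, n)`` float64 array.  Border voxels are edge-replicated
    by clipping the absolute indices, which is why centers themselves must
    be in bounds.
    """
    offs = patch_offsets(r_p)  # (n, 3)
    idx = centers[:, None, :] + offs[None, :, :]  # (K, n, 3)
    for ax in range(3):
        np.clip(idx[..., ax], 0, data.shape[ax] - 1, out=idx[..., ax])
    return data[idx[..., 0], idx[..., 1], idx[..., 2]].astype(np.float64)


# ---------------------------------------------------------------------------
# Cropping


def crop(vol: Volume, box: BoundingBox) -> Volume:
    """Crop a volume to a bounding box (intensities preserved exactly)."""
    if not box.contains(vol.shape):
        raise ValueError(f"bounding box {box} exceeds volume shape {vol.shape}")
    return Volume(vol.data[box.slices()].copy(), vol.spacing, vol.origin)


def crop_labels(lab: LabelMap, box: BoundingBox) -> LabelMap:
    if not box.contains(lab.shape):
        raise ValueError(f"bounding box {box} exceeds label shape {lab.shape}")
    return LabelMap(lab.data[box.slices()].copy(), lab.spacing, lab.origin)


def embed(vol: Volume, box: BoundingBox, into_shape: tuple[int, int, int], fill: float = 0.0) -> Volume:
    """Place a cropped volume back at ``box.lower`` inside a ``fill`` canvas."""
    if vol.shape != box.size:
        raise ValueError(f"volume shape {vol.shape} does not match box size {box.size}")
    out = np.full(into_shape, fill, dtype=np.float64)
    out[box.slices()] = vol.data
    return Volume(out, vol.spacing, vol.origin)
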