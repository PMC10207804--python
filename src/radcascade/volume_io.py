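"""Volume / mask I/O, grid resampling, and fixed-bin-width gray-level discretization.

Conventions
-----------
Arrays are indexed ``data[x, y, z]`` (0-based) with ``z`` the slice axis;
``spacing = (sx, sy, sz)`` in millimetres.  File reading/writing and resampling
are delegated to SimpleITK; SimpleITK's native ``[z, y, x]`` array order is
transposed at the boundary so the rest of the package never sees it.

Gray-level discretization uses a fixed bin width anchored at the ROI minimum:
``level(v) = floor((I(v) - min_ROI) / bin_width) + 1``.  Anchoring at the ROI
minimum makes the resulting levels exactly invariant under intensity shifts,
at the cost of diverging from toolkits that anchor bins at absolute zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeGrid",
    "RoiMask",
    "DiscretizedRoi",
    "VolumeFormatError",
    "DegenerateRoiError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_pair",
    "discretize_fixed_bin_width",
]


class VolumeFormatError(ValueError):
    """Raised when an image file or array violates the 3D single-channel contract."""


class DegenerateRoiError(ValueError):
    """Raised when an operation requires a nonempty ROI and the mask has no voxels."""


@dataclass
class VolumeGrid:
    """A 3D scalar intensity volume on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (Hounsfield-unit-like scalars).
    spacing : tuple of float
        Physical voxel size ``(sx, sy, sz)`` in mm; strictly positive.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected 3D volume, got {self.data.ndim}D data array"
            )
        if min(self.data.shape) < 1:
            raise VolumeFormatError(f"degenerate data shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class RoiMask:
    """A binary tumor mask congruent with a :class:`VolumeGrid`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected 3D mask, got {self.data.ndim}D data array"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def check_congruent(self, vol: VolumeGrid) -> None:
        if self.shape != vol.shape:
            raise VolumeFormatError(
                f"mask shape {self.shape} does not match volume shape {vol.shape}"
            )
        if not np.allclose(self.spacing, vol.spacing):
            raise VolumeFormatError(
                f"mask spacing {self.spacing} does not match volume spacing {vol.spacing}"
            )


@dataclass
class DiscretizedRoi:
    """Masked voxels re-binned to integer gray levels 1..Ng.

    ``level_array`` keeps the full grid (0 outside the mask) so texture
    operators can make neighborhood queries; ``levels`` is the flat list of
    in-mask levels.
    """

    level_array: np.ndarray          # int array, full grid, 0 outside mask
    mask: np.ndarray                 # bool array, same grid
    n_levels: int                    # Ng
    bin_width: float
    spacing: tuple[float, float, float]
    levels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.levels = self.level_array[self.mask]

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def cropped(self) -> "DiscretizedRoi":
        """Restrict the grid to the mask's bounding box (texture results unchanged)."""
        idx = np.argwhere(self.mask)
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        return DiscretizedRoi(
            level_array=self.level_array[sl],
            mask=self.mask[sl],
            n_levels=self.n_levels,
            bin_width=self.bin_width,
            spacing=self.spacing,
        )


# ---------------------------------------------------------------------------
# SimpleITK boundary


def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def read_volume(path) -> VolumeGrid:
    """Read a single-channel 3D image (NIfTI ``.nii``/``.nii.gz`` or NRRD).

    Spacing and origin are taken from the file header; intensities are
    returned unmodified.
    """
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # pragma: no cover - message depends on ITK
        raise VolumeFormatError(f"unreadable image file {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"expected 3D volume, got {img.GetDimension()}D image in {path}"
        )
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise VolumeFormatError(
            f"expected single-channel volume, got "
            f"{img.GetNumberOfComponentsPerPixel()} components in {path}"
        )
    data, spacing, origin = _from_sitk(img)
    if any(s <= 0 for s in spacing):
        raise VolumeFormatError(f"non-positive spacing {spacing} in {path}")
    return VolumeGrid(data=data, spacing=spacing, origin=origin)


def write_volume(vol: VolumeGrid, path) -> None:
    sitk.WriteImage(_to_sitk(vol.data, vol.spacing, vol.origin), str(path))


def read_mask(path) -> RoiMask:
    """Read a binary (0/1) mask volume."""
    vol = read_volume(path)
    return RoiMask(data=vol.data > 0.5, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: RoiMask, path) -> None:
    img = _to_sitk(mask.data.astype(np.uint8), mask.spacing, mask.origin)
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Resampling


def resample_pair(
    vol: VolumeGrid,
    mask: RoiMask,
    target_spacing: tuple[float, float, float],
) -> tuple[VolumeGrid, RoiMask]:
    """Resample a congruent volume/mask pair onto a grid with ``target_spacing``.

    The image is interpolated trilinearly, the mask by nearest neighbor
    (re-binarized at 0.5).  The new grid shares the original physical origin
    and covers the original extent; when ``target_spacing`` equals the input
    spacing the data pass through unchanged.
    """
    mask.check_congruent(vol)
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target_spacing must be positive, got {target_spacing}")

    if np.allclose(target_spacing, vol.spacing):
        return vol, mask

    old_size = np.array(vol.shape, dtype=float)
    old_sp = np.array(vol.spacing, dtype=float)
    new_sp = np.array(target_spacing, dtype=float)
    new_size = np.maximum(1, np.round(old_size * old_sp / new_sp)).astype(int)

    ref = sitk.Image([int(n) for n in new_size], sitk.sitkFloat64)
    ref.SetSpacing(target_spacing)
    ref.SetOrigin(vol.origin)

    img = _to_sitk(vol.data.astype(np.float64), vol.spacing, vol.origin)
    msk = _to_sitk(mask.data.astype(np.uint8), mask.spacing, mask.origin)

    # nearest-neighbor extrapolation keeps border voxels (whose centers can lie
    # just outside the original center grid) from being filled with a constant
    img_r = sitk.Resample(
        img, ref, sitk.Transform(), sitk.sitkLinear, 0.0,
        sitk.sitkFloat64, True,
    )
    msk_r = sitk.Resample(
        msk, ref, sitk.Transform(), sitk.sitkNearestNeighbor, 0,
        sitk.sitkUInt8, True,
    )

    vdata, vsp, vor = _from_sitk(img_r)
    mdata, _, _ = _from_sitk(msk_r)
    out_mask = RoiMask(data=mdata > 0.5, spacing=vsp, origin=vor)
    if out_mask.voxel_count == 0:
        raise DegenerateRoiError("mask is empty after resampling")
    return VolumeGrid(data=vdata, spacing=vsp, origin=vor), out_mask


# ---------------------------------------------------------------------------
# Discretization


def discretize_fixed_bin_width(
    vol: VolumeGrid, mask: RoiMask, bin_width: float
) -> DiscretizedRoi:
    """Re-bin in-mask intensities with a fixed bin width anchored at the ROI minimum.

    ``level(v) = floor((I(v) - min_ROI) / bin_width) + 1``; a constant ROI
    yields a single level (Ng = 1).
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    mask.check_congruent(vol)
    m = mask.data
    if not m.any():
        raise DegenerateRoiError("cannot discretize an empty ROI")
    intensities = vol.data[m].astype(np.float64)
    lo = intensities.min()
    levels = np.zeros(vol.shape, dtype=np.int64)
    levels[m] = np.floor((vol.data[m] - lo) / float(bin_width)).astype(np.int64) + 1
    ng = int(levels[m].max())
    return DiscretizedRoi(
        level_array=levels,
        mask=m,
        n_levels=ng,
        bin_width=float(bin_width),
        spacing=vol.spacing,
    )
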