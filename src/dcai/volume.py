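"""CT volume preprocessing: isotropic resampling and nodule cube extraction.

A scan arrives as a Hounsfield-unit voxel grid with anisotropic spacing.  The
pipeline resamples it to 1 mm isotropic resolution (trilinear), crops a
32x32x32 voxel window centred on the annotated nodule position, and windows
the intensities to [0, 1] with a standard lung window of [-1000, 400] HU.
Out-of-bounds voxels near scan borders are padded with air (-1000 HU).

Axis order is (z, y, x) with 0-based voxel indices throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

CUBE_SHAPE = (32, 32, 32)
AIR_HU = -1000.0
HU_WINDOW = (-1000.0, 400.0)


@dataclass
class CtVolume:
    """A CT scan in Hounsfield units with physical geometry.

    ``spacing`` is mm/voxel and ``origin`` the physical position (mm) of
    voxel (0, 0, 0), both in (z, y, x) order.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")


@dataclass
class NoduleCube:
    """A 32x32x32 voxel window around one nodule."""

    voxels: np.ndarray
    scan_id: str = ""
    centre_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    padded: bool = False
    normalized: bool = False

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.shape != CUBE_SHAPE:
            raise ValueError(f"cube must be {CUBE_SHAPE}, got {self.voxels.shape}")


def resample_isotropic(vol: CtVolume, interpolation_order: int = 1) -> CtVolume:
    """Resample to 1x1x1 mm/voxel; output shape = round(shape * spacing).

    Trilinear interpolation by default (``interpolation_order=1``).
    """
    if min(vol.voxels.shape) < 2:
        raise ValueError(
            f"cannot resample degenerate volume of shape {vol.voxels.shape}")
    spacing = np.asarray(vol.spacing, dtype=np.float64)
    if np.allclose(spacing, 1.0):
        return CtVolume(vol.voxels.copy(), (1.0, 1.0, 1.0), vol.origin)
    new_shape = np.rint(np.array(vol.voxels.shape) * spacing).astype(int)
    new_shape = np.maximum(new_shape, 1)
    zoom = new_shape / np.array(vol.voxels.shape)
    resampled = ndimage.zoom(vol.voxels, zoom, order=interpolation_order,
                             mode="nearest", grid_mode=True)
    return CtVolume(resampled, (1.0, 1.0, 1.0), vol.origin)


def extract_cube(vol: CtVolume, centre_mm: tuple[float, float, float],
                 scan_id: str = "", nodule_id: str = "?",
                 pad_value: float = AIR_HU) -> NoduleCube:
    """Crop the 32^3 window centred on the voxel nearest to ``centre_mm``.

    Requires an isotropic 1 mm volume.  Windows that extend past the scan
    border are padded with air HU and flagged.
    """
    if not np.allclose(vol.spacing, 1.0):
        raise ValueError("extract_cube requires an isotropic 1 mm volume; "
                         "run resample_isotropic first")
    centre = np.asarray(centre_mm, dtype=np.float64)
    idx = np.rint((centre - np.asarray(vol.origin)) /
                  np.asarray(vol.spacing)).astype(int)
    shape = np.array(vol.voxels.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError(
            f"nodule {nodule_id}: centre {tuple(centre)} mm maps to voxel "
            f"{tuple(idx)} outside volume of shape {tuple(shape)}")
    half = np.array(CUBE_SHAPE) // 2
    lo = idx - half
    hi = lo + np.array(CUBE_SHAPE)
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, shape)
    cube = np.full(CUBE_SHAPE, pad_value, dtype=np.float64)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    cube[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
        vol.voxels[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    padded = bool(np.any(lo < 0) or np.any(hi > shape))
    return NoduleCube(cube, scan_id=scan_id, centre_mm=tuple(centre),
                      padded=padded)


def normalize_hu(cube: NoduleCube, window: tuple[float, float] = HU_WINDOW
                 ) -> NoduleCube:
    """Clip to the HU window and map affinely to [0, 1]."""
    lo, hi = window
    scaled = (np.clip(cube.voxels, lo, hi) - lo) / (hi - lo)
    return NoduleCube(scaled, scan_id=cube.scan_id, centre_mm=cube.centre_mm,
                      padded=cube.padded, normalized=True)


def load_volume(path: str | Path) -> CtVolume:
    """Load a CT volume from a DICOM series directory or a NIfTI/MetaImage file.

    SimpleITK applies the DICOM rescale slope/intercept, so intensities come
    back in HU.  SimpleITK spacing is (x, y, z); it is flipped to this
    module's (z, y, x) convention.
    """
    import SimpleITK as sitk

    path = Path(path)
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        series = reader.GetGDCMSeriesFileNames(str(path))
        if not series:
            raise ValueError(f"no DICOM series found under {path}")
        reader.SetFileNames(series)
        img = reader.Execute()
    else:
        img = sitk.ReadImage(str(path))
    voxels = sitk.GetArrayFromImage(img)  # (z, y, x) already
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return CtVolume(np.asarray(voxels, dtype=np.float64), spacing, origin)


def prepare_cube(vol: CtVolume, centre_mm: tuple[float, float, float],
                 scan_id: str = "", nodule_id: str = "?") -> NoduleCube:
    """Full per-nodule pipeline: resample, extract, normalize."""
    iso = resample_isotropic(vol)
    cube = extract_cube(iso, centre_mm, scan_id=scan_id, nodule_id=nodule_id)
    return normalize_hu(cube)
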