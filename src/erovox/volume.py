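"""Calibrated density volumes and binary voxel regions.

The grid contract used by every other module lives here: arrays are indexed
``(x, y, z)`` with x running radial→ulnar, y palmar→dorsal and z along the
scanner stack (distal→proximal).  A voxel's physical center is
``index * spacing`` in mm.  "Axial" slices are fixed-z planes, "coronal"
fixed-y and "sagittal" fixed-x.

Densities are calibrated hydroxyapatite-equivalent values in mg HA/cm³.
Three on-disk formats are supported: NIfTI (.nii/.nii.gz), MetaImage
(.mha/.mhd) and multi-page TIFF with a mandatory JSON sidecar carrying
``spacing_mm``, ``slope`` and ``intercept`` (TIFF itself stores neither
spacing nor calibration, and a silently assumed spacing would corrupt every
mm-denominated step downstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = [
    "DensityVolume",
    "VoxelRegion",
    "VolumeError",
    "read_volume",
    "write_volume",
    "read_region",
]

#: default isotropic voxel size of second-generation HR-pQCT, mm
DEFAULT_SPACING_MM = 0.0607

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")
_TIFF_SUFFIXES = (".tif", ".tiff")
_MIN_DIM = 8


class VolumeError(ValueError):
    """Raised for invalid grids, missing metadata or unsupported formats."""


def _check_grid(values: np.ndarray, spacing) -> tuple[float, float, float]:
    if values.ndim != 3:
        raise VolumeError(f"expected a 3D grid, got {values.ndim}D data")
    if min(values.shape) < _MIN_DIM:
        raise VolumeError(
            f"grid dimensions {values.shape} below the {_MIN_DIM}-voxel minimum"
        )
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise VolumeError(f"spacing must be three positive floats, got {spacing}")
    return spacing


@dataclass
class DensityVolume:
    """A calibrated 3D density grid with physical spacing.

    Parameters
    ----------
    values
        Densities in mg HA/cm³, shape ``(nx, ny, nz)``; stored as float32.
    spacing
        Per-axis voxel size in mm.
    site_label
        ``"MCH"`` (metacarpal head) or ``"PB"`` (phalangeal base).
    metadata
        Free-form key/values (scan length, slice count, motion grade, ...).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (DEFAULT_SPACING_MM,) * 3
    site_label: str = "MCH"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.spacing = _check_grid(self.values, self.spacing)
        if not np.all(np.isfinite(self.values)):
            raise VolumeError("density values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class VoxelRegion:
    """A binary voxel set on the same grid as its parent volume."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (DEFAULT_SPACING_MM,) * 3
    label: str = "region"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = _check_grid(self.mask, self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing))

    def copy(self, label: str | None = None) -> "VoxelRegion":
        return VoxelRegion(self.mask.copy(), self.spacing, label or self.label)


# ---------------------------------------------------------------------------
# format detection


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        fmt = format_hint.lower()
        if fmt not in {"nifti", "metaimage", "tiff"}:
            raise VolumeError(
                f"unsupported format {format_hint!r}; supported: nifti, metaimage, tiff"
            )
        return fmt
    name = path.name.lower()
    if any(name.endswith(s) for s in _NIFTI_SUFFIXES):
        return "nifti"
    if any(name.endswith(s) for s in _META_SUFFIXES):
        return "metaimage"
    if any(name.endswith(s) for s in _TIFF_SUFFIXES):
        return "tiff"
    raise VolumeError(
        f"cannot infer format from {path.name!r}; supported: "
        "NIfTI (.nii/.nii.gz), MetaImage (.mha/.mhd), TIFF (.tif/.tiff)"
    )


def _sidecar_path(path: Path) -> Path:
    # vol.tif -> vol.json
    return path.with_suffix(".json")


# ---------------------------------------------------------------------------
# reading


def read_volume(path, format_hint: str | None = None) -> DensityVolume:
    """Read a calibrated density volume.

    TIFF input requires a ``<name>.json`` sidecar with keys ``spacing_mm``
    (3 floats), ``slope`` and ``intercept``; raw integers are mapped to
    mg HA/cm³ as ``raw * slope + intercept``.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"input file not found: {path}")
    fmt = _detect_format(path, format_hint)

    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(dtype=np.float32))
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return DensityVolume(data, spacing)

    if fmt == "metaimage":
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise VolumeError(f"non-3D MetaImage data in {path}")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
        return DensityVolume(data, tuple(img.GetSpacing()))

    # TIFF stack + sidecar
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise VolumeError(
            f"TIFF input requires a sidecar {sidecar.name} with keys "
            "spacing_mm, slope, intercept"
        )
    meta = json.loads(sidecar.read_text())
    for key in ("spacing_mm", "slope", "intercept"):
        if key not in meta:
            raise VolumeError(f"sidecar {sidecar} is missing required key {key!r}")
    raw = tifffile.imread(str(path))
    if raw.ndim != 3:
        raise VolumeError(f"non-3D TIFF data in {path}")
    values = raw.astype(np.float32) * float(meta["slope"]) + float(meta["intercept"])
    # pages are z, each page (y, x)
    return DensityVolume(values.transpose(2, 1, 0), tuple(meta["spacing_mm"]))


def read_region(path, format_hint: str | None = None, label: str = "region") -> VoxelRegion:
    """Read a mask written by :func:`write_volume` back as a VoxelRegion."""
    vol = read_volume(path, format_hint)
    return VoxelRegion(vol.values > 0.5, vol.spacing, label)


# ---------------------------------------------------------------------------
# writing


def write_volume(obj, path, format: str | None = None, *, dtype: str = "float32",
                 slope: float | None = None) -> Path:
    """Write a DensityVolume or VoxelRegion.

    Masks are written as 0/1 8-bit volumes.  Density is written as 32-bit
    float by default; ``dtype="int16"`` stores scaled integers with the
    slope/intercept recorded (TIFF sidecar or NIfTI scl fields; MetaImage has
    no calibration slot and only supports the float path).
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)

    if isinstance(obj, VoxelRegion):
        data = obj.mask.astype(np.uint8)
        spacing = obj.spacing
        out_slope = None
    elif isinstance(obj, DensityVolume):
        spacing = obj.spacing
        if dtype == "float32":
            data = obj.values.astype(np.float32)
            out_slope = None
        elif dtype == "int16":
            peak = float(np.abs(obj.values).max())
            out_slope = slope if slope is not None else max(peak, 1.0) / 32000.0
            data = np.round(obj.values / out_slope).astype(np.int16)
        else:
            raise VolumeError(f"unsupported dtype {dtype!r}; use float32 or int16")
    else:
        raise VolumeError(f"cannot write object of type {type(obj).__name__}")

    if fmt == "nifti":
        affine = np.diag(list(spacing) + [1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(spacing)
        if out_slope is not None:
            img.header["scl_slope"] = out_slope
            img.header["scl_inter"] = 0.0
        nib.save(img, str(path))
    elif fmt == "metaimage":
        if out_slope is not None:
            raise VolumeError("MetaImage cannot record a calibration slope; "
                              "use dtype='float32' or a TIFF/NIfTI target")
        img = sitk.GetImageFromArray(data.transpose(2, 1, 0))
        img.SetSpacing(tuple(spacing))
        sitk.WriteImage(img, str(path), useCompression=True)
    else:  # tiff
        tifffile.imwrite(str(path), data.transpose(2, 1, 0))
        sidecar = {
            "spacing_mm": list(spacing),
            "slope": 1.0 if out_slope is None else out_slope,
            "intercept": 0.0,
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path
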