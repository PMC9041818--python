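"""Erosion parameters from an accepted VOI.

Six parameters per erosion: volume (Er.V), depth and width in the axial
view (Er.D, Er.W), depth and length in the perpendicular view (Er.D-2,
Er.L — coronal for radial/ulnar erosions, sagittal for dorsal/palmar), and
the mean density of a 1-mm bone shell surrounding the VOI (Er.BMD).

Depth and width are read off a 2D view the way a caliper would be placed:
in the slice of maximal VOI area, the mouth chord joins the two outermost
VOI voxels on the reconstructed (filled) surface, the width is the chord
length and the depth the maximal perpendicular drop from the chord into the
bone.  This operationalizes a manual 2D measurement deterministically; slice
ties break toward the lower index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist, squareform

from . import _morphology as morph
from .volume import DensityVolume, VoxelRegion

__all__ = [
    "ErosionRecord",
    "MeasureError",
    "erosion_volume",
    "assign_quadrant",
    "depth_width_axial",
    "depth_length_perpendicular",
    "peripheral_bmd",
    "measure_erosion",
    "records_to_frame",
]

PARAMETERS = ("Er_V", "Er_D", "Er_D2", "Er_W", "Er_L", "Er_BMD")


class MeasureError(ValueError):
    pass


@dataclass
class ErosionRecord:
    id: int
    site: str
    quadrant: str
    Er_V: float       # mm3
    Er_D: float       # mm, axial view
    Er_W: float       # mm, axial view
    Er_D2: float      # mm, perpendicular view
    Er_L: float       # mm, perpendicular view
    Er_BMD: float     # mg HA/cm3
    flags: set = field(default_factory=set)
    config_hash: str = ""
    n_marrow: int | None = None


def erosion_volume(voi: VoxelRegion) -> float:
    """Er.V: voxel count times voxel volume, mm³."""
    if not voi.mask.any():
        raise MeasureError("empty VOI")
    return voi.volume_mm3


def assign_quadrant(voi: VoxelRegion, bone: VoxelRegion) -> str:
    """Quadrant of the VOI centroid about the bone centroid in the axial
    plane: +x radial, −x ulnar, +y dorsal, −y palmar; the ±45° diagonals
    break toward radial/ulnar."""
    ci = np.array(ndimage.center_of_mass(voi.mask)[:2])
    cb = np.array(ndimage.center_of_mass(bone.mask)[:2])
    dx, dy = ci - cb
    if dx == 0 and dy == 0:
        raise MeasureError("degenerate quadrant: VOI centroid on the bone axis")
    if abs(dx) >= abs(dy):
        return "radial" if dx >= 0 else "ulnar"
    return "dorsal" if dy >= 0 else "palmar"


def _chord_measures(mask2d: np.ndarray, outside2d: np.ndarray,
                    spacing2d: tuple[float, float]):
    """Mouth-chord construction on one 2D slice.

    Returns (depth, width, flags).  Width: distance between the two
    outermost mouth voxels plus one voxel (mouth voxels are VOI voxels
    4-adjacent to the outside of the filled surface).  Depth: maximal
    perpendicular distance from the chord to a VOI voxel on the bone side,
    plus one voxel.
    """
    flags: set = set()
    s_bar = float(np.mean(spacing2d))
    plus = ndimage.generate_binary_structure(2, 1)
    mouth = mask2d & ndimage.binary_dilation(outside2d, structure=plus)
    if not mouth.any():
        # VOI does not reach the free surface in this slice; fall back to the
        # VOI's own top boundary so a measurement still exists, but flag it.
        flags.add("no_mouth")
        mouth = mask2d & ~ndimage.binary_erosion(mask2d, structure=plus,
                                                 border_value=0)
    pts = np.argwhere(mouth) * np.asarray(spacing2d)
    allpts = np.argwhere(mask2d) * np.asarray(spacing2d)
    if len(pts) == 1:
        flags.add("degenerate_mouth")
        d = np.linalg.norm(allpts - pts[0], axis=1)
        return float(d.max() + s_bar), float(s_bar), flags
    dists = squareform(pdist(pts))
    i, j = np.unravel_index(np.argmax(dists), dists.shape)
    p1, p2 = pts[i], pts[j]
    width = float(dists[i, j] + s_bar)
    chord = p2 - p1
    norm = np.linalg.norm(chord)
    signed = np.cross(np.append(chord, 0.0),
                      np.c_[allpts - p1, np.zeros(len(allpts))])[:, 2] / norm
    centroid_side = np.sign(signed.sum()) or 1.0
    depth = float(max(signed * centroid_side)) + s_bar
    return depth, width, flags


def _view_slices(voi_mask: np.ndarray, axis: int):
    """Per-slice areas along the given axis; max-area slice, low-index ties."""
    other = tuple(a for a in range(3) if a != axis)
    areas = voi_mask.sum(axis=other)
    return int(np.argmax(areas)), int((areas > 0).sum())


def _slice2d(mask: np.ndarray, axis: int, index: int) -> np.ndarray:
    sl = [slice(None)] * 3
    sl[axis] = index
    return mask[tuple(sl)]


def _measure_view(voi: VoxelRegion, filled: VoxelRegion, axis: int):
    if not voi.mask.any():
        raise MeasureError("empty VOI")
    k, n_slices = _view_slices(voi.mask, axis)
    sp2d = tuple(s for a, s in enumerate(voi.spacing) if a != axis)
    depth, width, flags = _chord_measures(
        _slice2d(voi.mask, axis, k), _slice2d(~filled.mask, axis, k), sp2d)
    if n_slices == 1:
        flags.add("thin")
    return depth, width, flags


def depth_width_axial(voi: VoxelRegion, filled: VoxelRegion):
    """(Er.D, Er.W, flags) in the axial (fixed-z) slice of maximal VOI area."""
    return _measure_view(voi, filled, axis=2)


def depth_length_perpendicular(voi: VoxelRegion, filled: VoxelRegion,
                               quadrant: str):
    """(Er.D-2, Er.L, flags) in the coronal view (fixed-y) for radial/ulnar
    erosions, sagittal (fixed-x) for dorsal/palmar."""
    if quadrant in ("radial", "ulnar"):
        axis = 1
    elif quadrant in ("dorsal", "palmar"):
        axis = 0
    else:
        raise MeasureError(f"unknown quadrant {quadrant!r}")
    return _measure_view(voi, filled, axis)


def peripheral_bmd(voi: VoxelRegion, vol: DensityVolume, bone: VoxelRegion,
                   shell_mm: float = 1.0) -> float:
    """Er.BMD: mean density of the shell (dilation of the VOI minus the VOI)
    restricted to the bone mask, so marrow and background never dilute it."""
    if shell_mm <= 0:
        raise MeasureError("shell_mm must be positive")
    shell = morph.dilate_mm(voi.mask, shell_mm, voi.spacing) & ~voi.mask & bone.mask
    if not shell.any():
        raise MeasureError("empty peripheral shell")
    return float(vol.values[shell].mean())


def measure_erosion(voi: VoxelRegion, vol: DensityVolume, bone: VoxelRegion,
                    filled: VoxelRegion, *, id: int = 0, quadrant: str | None = None,
                    shell_mm: float = 1.0, config_hash: str = "",
                    n_marrow: int | None = None,
                    flags: set | None = None) -> ErosionRecord:
    """All six parameters for one erosion VOI."""
    quadrant = quadrant or assign_quadrant(voi, bone)
    er_d, er_w, f1 = depth_width_axial(voi, filled)
    er_d2, er_l, f2 = depth_length_perpendicular(voi, filled, quadrant)
    return ErosionRecord(
        id=id, site=vol.site_label, quadrant=quadrant,
        Er_V=erosion_volume(voi), Er_D=er_d, Er_W=er_w, Er_D2=er_d2, Er_L=er_l,
        Er_BMD=peripheral_bmd(voi, vol, bone, shell_mm),
        flags=(flags or set()) | f1 | f2, config_hash=config_hash,
        n_marrow=n_marrow,
    )


def records_to_frame(records: list) -> pd.DataFrame:
    rows = [{
        "id": r.id, "site": r.site, "quadrant": r.quadrant,
        "Er_V_mm3": r.Er_V, "Er_D_mm": r.Er_D, "Er_D2_mm": r.Er_D2,
        "Er_W_mm": r.Er_W, "Er_L_mm": r.Er_L, "Er_BMD_mgcm3": r.Er_BMD,
        "flags": ";".join(sorted(r.flags)),
        "n_marrow": "" if r.n_marrow is None else r.n_marrow,
        "config_hash": r.config_hash,
    } for r in records]
    return pd.DataFrame(rows, columns=[
        "id", "site", "quadrant", "Er_V_mm3", "Er_D_mm", "Er_D2_mm",
        "Er_W_mm", "Er_L_mm", "Er_BMD_mgcm3", "flags", "n_marrow",
        "config_hash"])
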