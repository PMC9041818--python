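"""Ball morphology on mm scales, implemented with exact Euclidean distance
transforms.

All mm-valued radii are converted to voxel radii via ``round(mm/spacing)``
with a floor of 1 voxel; the digital ball of radius k voxels is the set of
voxel centers within k*spacing (Euclidean, anisotropy-aware through EDT
sampling).  Thresholding a distance transform is algebraically identical to
dilation/erosion with that ball but runs in O(n) regardless of radius, which
matters for the multi-mm closing radii the surface-filling step needs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = 1e-9

#: 6-connected unit step (face neighbours) — used where an iteration count
#: must be well-defined (marrow separation, seed regrowth).
STRUCT_6 = ndimage.generate_binary_structure(3, 1)
#: 26-connected structure for foreground component labelling.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def radius_mm(mm: float, spacing) -> float:
    """Effective ball radius in mm after the round(mm/spacing), floor-1 rule."""
    s = float(min(spacing))
    return max(1, round(mm / s)) * s


def radius_vox(mm: float, spacing) -> int:
    return max(1, round(mm / float(min(spacing))))


def dilate_mm(mask: np.ndarray, mm: float, spacing) -> np.ndarray:
    """Dilation by the digital Euclidean ball of radius ``mm``."""
    if not mask.any():
        return mask.copy()
    r = radius_mm(mm, spacing)
    d = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return d <= r + _EPS


def erode_mm(mask: np.ndarray, mm: float, spacing) -> np.ndarray:
    """Erosion by the same ball; exact dual of :func:`dilate_mm`."""
    if not mask.any():
        return mask.copy()
    r = radius_mm(mm, spacing)
    d = ndimage.distance_transform_edt(mask, sampling=spacing)
    return d > r + _EPS


def border_margins_vox(mask: np.ndarray) -> list[tuple[int, int]]:
    """Per-axis (low, high) distances from the foreground to the grid border."""
    if not mask.any():
        n = min(mask.shape)
        return [(n, n)] * 3
    margins = []
    for ax in range(3):
        idx = np.flatnonzero(mask.any(axis=tuple(a for a in range(3) if a != ax)))
        margins.append((int(idx[0]), int(mask.shape[ax] - 1 - idx[-1])))
    return margins


def _pad_widths(mask: np.ndarray, rv: int) -> list[tuple[int, int]]:
    return [(max(0, rv + 2 - lo), max(0, rv + 2 - hi))
            for lo, hi in border_margins_vox(mask)]


def _crop(mask: np.ndarray, widths) -> np.ndarray:
    sl = tuple(slice(lo, mask.shape[i] - hi) for i, (lo, hi) in enumerate(widths))
    return mask[sl]


def close_mm(mask: np.ndarray, mm: float, spacing, pad: bool = True) -> np.ndarray:
    """Morphological closing by the digital ball of radius ``mm``.

    With ``pad=True`` (default) the grid is transparently padded so the
    intermediate dilation never touches the border, then cropped back; with
    ``pad=False`` a dilation reaching the border raises instead, since a
    clipped dilation silently corrupts the closing.
    """
    rv = radius_vox(mm, spacing)
    widths = _pad_widths(mask, rv)
    if any(lo or hi for lo, hi in widths):
        if not pad:
            raise ValueError(
                "closing touches the grid boundary; pad the volume by "
                f"{max(max(w) for w in widths)} voxels (or call with pad=True)"
            )
        work = np.pad(mask, widths)
    else:
        work = mask
    out = erode_mm(dilate_mm(work, mm, spacing), mm, spacing)
    if any(lo or hi for lo, hi in widths):
        out = _crop(out, widths)
    return out


def open_mm(mask: np.ndarray, mm: float, spacing) -> np.ndarray:
    """Morphological opening (erode then dilate) by the digital ball."""
    rv = radius_vox(mm, spacing)
    widths = _pad_widths(mask, rv)
    padded = any(lo or hi for lo, hi in widths)
    work = np.pad(mask, widths) if padded else mask
    out = dilate_mm(erode_mm(work, mm, spacing), mm, spacing)
    return _crop(out, widths) if padded else out


def label_26(mask: np.ndarray):
    return ndimage.label(mask, structure=STRUCT_26)


def fill_holes_6(mask: np.ndarray) -> np.ndarray:
    """Add every cavity not 6-connected to the grid border to the mask."""
    return ndimage.binary_fill_holes(mask, structure=STRUCT_6)


def geodesic_grow(seed: np.ndarray, allowed: np.ndarray, steps: int) -> np.ndarray:
    """Grow ``seed`` by ``steps`` 6-connected dilations restricted to ``allowed``."""
    if steps <= 0 or not seed.any():
        return seed & allowed
    return ndimage.binary_dilation(seed, structure=STRUCT_6, iterations=steps,
                                   mask=allowed)
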