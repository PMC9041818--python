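"""Digital metacarpal-head-like phantoms with carved erosions and known truth.

The phantom is a superellipsoid bone (``|x/a|^p + |y/b|^p + |z/c|^p <= 1``)
with a dense cortical shell and a lower-density trabecular interior, sitting
in soft-tissue background.  Surface defects are carved or added with exact
bookkeeping of the voxels involved, so detection and measurement can be
checked against closed-form geometry:

* erosions — spheres anchored on the cortical surface; with the default
  immersion (center on the surface) the carve is hemispherical, giving
  closed-form volume (2/3)πr³, depth r and opening width 2r on a locally
  flat face,
* vascular channels — narrow blind cylinders through the cortex,
* osteophytes — bony bumps; an adjacent pair creates the pseudo-concavity
  false-positive pattern,
* an optional inter-tubercle groove — a broad shallow trench along the
  stack axis, the physiological-concavity false-positive pattern.

With exponent 2 the bone is the classic ellipsoid; exponent 4 gives
near-flat quadrant facets (a fair cartoon of a condyle's broad surfaces) on
which the flat-face closed forms above hold to voxelization accuracy.
Ground truth is a pure function of the geometry: noise and repositioning
never touch it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import DEFAULT_SPACING_MM, DensityVolume

__all__ = [
    "ErosionSpec",
    "ChannelSpec",
    "OsteophyteSpec",
    "GrooveSpec",
    "PhantomSpec",
    "ErosionTruth",
    "StructureTruth",
    "PhantomTruth",
    "PhantomError",
    "generate_phantom",
    "osteophyte_pair",
    "rescan",
]


class PhantomError(ValueError):
    """Raised for degenerate or ambiguous phantom specifications."""


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise PhantomError("direction vector must be non-zero")
    return v / n


@dataclass
class ErosionSpec:
    """A spherical carve anchored on the bone surface.

    ``direction`` points from the bone center to the anchor point;
    ``center_depth_mm`` is how far below the surface the sphere center sits
    (0 = center on the surface = hemispherical opening, the default).
    """

    direction: tuple[float, float, float]
    radius_mm: float
    center_depth_mm: float = 0.0

    @property
    def quadrant(self) -> str:
        dx, dy, _ = _unit(self.direction)
        if abs(dx) >= abs(dy):
            return "radial" if dx >= 0 else "ulnar"
        return "dorsal" if dy >= 0 else "palmar"


@dataclass
class ChannelSpec:
    """A narrow blind cylinder carved inward from the surface (vascular
    channel / small cortical interruption)."""

    direction: tuple[float, float, float]
    diameter_mm: float = 0.2
    length_mm: float = 1.2


@dataclass
class OsteophyteSpec:
    """A bony bump: a ball of ``radius_mm`` protruding ``height_mm`` above
    the surface.  ``point_mm`` (relative to the bone center) overrides the
    direction-based surface anchor, letting pairs sit side by side."""

    direction: tuple[float, float, float]
    height_mm: float = 1.0
    radius_mm: float = 0.8
    point_mm: tuple[float, float, float] | None = None


@dataclass
class GrooveSpec:
    """Broad shallow trench along z on the face given by ``direction``
    (inter-tubercle groove, the physiological concavity)."""

    direction: tuple[float, float, float]
    width_mm: float = 3.0
    depth_mm: float = 0.5


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (192, 192, 192)
    spacing: tuple[float, float, float] = (DEFAULT_SPACING_MM,) * 3
    semi_axes_mm: tuple[float, float, float] = (3.6, 3.6, 4.6)
    exponent: float = 2.0
    cortical_thickness_mm: float = 2.4
    cortical_density: float = 800.0
    trabecular_density: float = 200.0
    background_density: float = 0.0
    erosions: list[ErosionSpec] = field(default_factory=list)
    channels: list[ChannelSpec] = field(default_factory=list)
    osteophytes: list[OsteophyteSpec] = field(default_factory=list)
    groove: GrooveSpec | None = None
    noise_sd: float = 50.0
    seed: int = 0

    def validate(self, threshold: float = 320.0) -> None:
        for name in ("cortical_density", "trabecular_density", "background_density"):
            if getattr(self, name) < 0:
                raise PhantomError(f"{name} must be >= 0")
        if not (self.cortical_density > threshold > self.background_density):
            raise PhantomError(
                "degenerate phantom: need cortical_density > segmentation "
                f"threshold ({threshold}) > background_density"
            )
        s = min(self.spacing)
        for ero in self.erosions:
            if ero.radius_mm < 2 * s:
                raise PhantomError(
                    f"erosion radius {ero.radius_mm} mm below 2 x spacing"
                )
            if not (0 <= ero.center_depth_mm < ero.radius_mm):
                raise PhantomError("center_depth_mm must lie in [0, radius)")
        for ost in self.osteophytes:
            if not (0 < ost.height_mm <= 2 * ost.radius_mm):
                raise PhantomError("osteophyte height must be in (0, 2*radius]")


@dataclass
class ErosionTruth:
    center_mm: tuple[float, float, float]  # sphere center, mm from grid origin
    radius_mm: float
    quadrant: str
    depth_mm: float
    width_mm: float
    analytic_volume_mm3: float
    voxel_volume_mm3: float
    mask: np.ndarray  # exact carved voxel set

    def summary(self) -> dict:
        return {
            "center_mm": [round(c, 4) for c in self.center_mm],
            "radius_mm": self.radius_mm,
            "quadrant": self.quadrant,
            "depth_mm": round(self.depth_mm, 4),
            "width_mm": round(self.width_mm, 4),
            "analytic_volume_mm3": round(self.analytic_volume_mm3, 6),
            "voxel_volume_mm3": round(self.voxel_volume_mm3, 6),
        }


@dataclass
class StructureTruth:
    kind: str  # channel | pseudo_concavity | groove
    mask: np.ndarray

    def summary(self) -> dict:
        return {"kind": self.kind, "voxel_count": int(self.mask.sum())}


@dataclass
class PhantomTruth:
    erosions: list[ErosionTruth]
    structures: list[StructureTruth]

    def summary(self) -> dict:
        return {
            "erosions": [e.summary() for e in self.erosions],
            "structures": [s.summary() for s in self.structures],
        }


# ---------------------------------------------------------------------------


def _grids_mm(spec: PhantomSpec):
    """Open coordinate grids in mm relative to the bone center."""
    center = [(n - 1) / 2.0 * s for n, s in zip(spec.shape, spec.spacing)]
    axes = [
        (np.arange(n) * s - c).astype(np.float64)
        for n, s, c in zip(spec.shape, spec.spacing, center)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True), center


def _superellipsoid(grids, semi_axes, exponent) -> np.ndarray:
    x, y, z = grids
    a, b, c = semi_axes
    p = exponent
    f = (np.abs(x) / a) ** p + (np.abs(y) / b) ** p + (np.abs(z) / c) ** p
    return f <= 1.0


def _surface_anchor(point_or_dir, semi_axes, exponent) -> np.ndarray:
    """Project a point (or scale a direction) onto the superellipsoid surface
    along the ray through the bone center."""
    p = np.asarray(point_or_dir, dtype=float)
    a = np.asarray(semi_axes, dtype=float)
    f = float(np.sum((np.abs(p) / a) ** exponent))
    if f == 0:
        raise PhantomError("surface anchor direction must be non-zero")
    return p * f ** (-1.0 / exponent)


def _sphere_mask(grids, center, radius) -> np.ndarray:
    x, y, z = grids
    return ((x - center[0]) ** 2 + (y - center[1]) ** 2
            + (z - center[2]) ** 2) <= radius ** 2


def _spherical_cap_volume(r: float, h: float) -> float:
    return math.pi * h * h * (3 * r - h) / 3.0


def generate_phantom(spec: PhantomSpec,
                     threshold: float = 320.0) -> tuple[DensityVolume, PhantomTruth]:
    """Render the phantom and its ground truth.

    Deterministic for a fixed seed; the carved voxel sets are recorded
    exactly (the material removed from bone), enabling exact oracle
    comparisons downstream.  Noise is additive Gaussian clipped at zero and
    never alters the truth.
    """
    spec.validate(threshold)
    grids, center = _grids_mm(spec)
    sa = np.asarray(spec.semi_axes_mm, dtype=float)
    inner_sa = sa - spec.cortical_thickness_mm

    outer = _superellipsoid(grids, sa, spec.exponent)
    inner = (_superellipsoid(grids, inner_sa, spec.exponent)
             if np.all(inner_sa > 0) else np.zeros(spec.shape, dtype=bool))

    bone = outer.copy()
    # osteophyte bumps are bone material too
    bump_masks = []
    for ost in spec.osteophytes:
        anchor = (_surface_anchor(ost.point_mm, sa, spec.exponent)
                  if ost.point_mm is not None
                  else _surface_anchor(ost.direction, sa, spec.exponent))
        n_out = _unit(anchor)
        c = anchor + n_out * (ost.height_mm - ost.radius_mm)
        bump = _sphere_mask(grids, c, ost.radius_mm)
        bump_masks.append(bump)
        bone |= bump

    density = np.full(spec.shape, spec.background_density, dtype=np.float32)
    density[bone] = spec.cortical_density
    density[inner] = spec.trabecular_density

    voxvol = float(np.prod(spec.spacing))
    erosion_truths: list[ErosionTruth] = []
    sphere_params = []
    for ero in spec.erosions:
        anchor = _surface_anchor(ero.direction, sa, spec.exponent)
        n_out = _unit(ero.direction)
        c = anchor - n_out * ero.center_depth_mm
        for c2, r2 in sphere_params:
            if np.linalg.norm(c - c2) <= ero.radius_mm + r2:
                raise PhantomError("overlapping erosions make the truth ambiguous")
        sphere_params.append((c, ero.radius_mm))
        sphere = _sphere_mask(grids, c, ero.radius_mm)
        carved = sphere & bone
        if not carved.any():
            raise PhantomError("erosion placement does not intersect the bone")
        if not (sphere & ~outer).any():
            raise PhantomError("erosion sphere fully inside bone: no surface opening")
        bone &= ~carved
        density[carved] = spec.background_density

        r, d = ero.radius_mm, ero.center_depth_mm
        cap_h = r - d
        analytic = 4.0 / 3.0 * math.pi * r ** 3 - _spherical_cap_volume(r, cap_h)
        vox = float(carved.sum()) * voxvol
        if r >= 8 * min(spec.spacing) and abs(vox - analytic) > 0.15 * analytic:
            raise PhantomError(
                f"voxelized erosion volume {vox:.4f} deviates more than 15% "
                f"from analytic {analytic:.4f} mm3; surface too curved for the "
                "closed-form truth (flatten with a higher exponent or use a "
                "larger bone)"
            )
        center_abs = tuple(float(ci + cc) for ci, cc in zip(c, center))
        erosion_truths.append(ErosionTruth(
            center_mm=center_abs, radius_mm=r, quadrant=ero.quadrant,
            depth_mm=d + r, width_mm=2.0 * math.sqrt(r * r - d * d),
            analytic_volume_mm3=analytic, voxel_volume_mm3=vox, mask=carved,
        ))

    structures: list[StructureTruth] = []
    x, y, z = grids
    for ch in spec.channels:
        anchor = _surface_anchor(ch.direction, sa, spec.exponent)
        u_in = -_unit(ch.direction)
        start = anchor - u_in * 0.3  # begin slightly above the surface
        px, py, pz = x - start[0], y - start[1], z - start[2]
        t = px * u_in[0] + py * u_in[1] + pz * u_in[2]
        rad2 = (px * px + py * py + pz * pz) - t * t
        cyl = (t >= 0) & (t <= ch.length_mm + 0.3) & (rad2 <= (ch.diameter_mm / 2) ** 2)
        carved = cyl & bone
        if not carved.any():
            raise PhantomError("channel placement does not intersect the bone")
        bone &= ~carved
        density[carved] = spec.background_density
        structures.append(StructureTruth("channel", carved))

    if bump_masks:
        structures.append(StructureTruth(
            "pseudo_concavity", np.logical_or.reduce(bump_masks)))

    if spec.groove is not None:
        g = spec.groove
        n_out = _unit((g.direction[0], g.direction[1], 0.0))
        anchor = _surface_anchor(n_out, sa, spec.exponent)
        radius = (g.width_mm ** 2 / 4.0 + g.depth_mm ** 2) / (2.0 * g.depth_mm)
        axis_xy = anchor[:2] + n_out[:2] * (radius - g.depth_mm)
        cyl = ((x - axis_xy[0]) ** 2 + (y - axis_xy[1]) ** 2) <= radius ** 2
        carved = cyl & bone
        if not carved.any():
            raise PhantomError("groove placement does not intersect the bone")
        bone &= ~carved
        density[carved] = spec.background_density
        structures.append(StructureTruth("groove", carved))

    border = np.zeros(spec.shape, dtype=bool)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    if (bone & border).any():
        raise PhantomError("bone (or an osteophyte) is clipped by the grid "
                           "boundary; enlarge the grid or shrink the bone")

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        density = density + rng.normal(0.0, spec.noise_sd, spec.shape).astype(np.float32)
        np.clip(density, 0.0, None, out=density)

    vol = DensityVolume(density, spec.spacing, metadata={
        "phantom_seed": spec.seed, "noise_sd": spec.noise_sd,
        "exponent": spec.exponent,
    })
    return vol, PhantomTruth(erosion_truths, structures)


def osteophyte_pair(direction, separation_mm: float = 2.2, tangent=(0.0, 0.0, 1.0),
                    height_mm: float = 1.0, radius_mm: float = 0.8,
                    semi_axes_mm=(3.6, 3.6, 4.6), exponent: float = 2.0,
                    ) -> list[OsteophyteSpec]:
    """Two osteophytes straddling the anchor point along ``tangent``; the gap
    between them is the pseudo-concavity false-positive pattern."""
    anchor = _surface_anchor(direction, semi_axes_mm, exponent)
    t = _unit(tangent)
    out = []
    for sign in (-1.0, 1.0):
        p = _surface_anchor(anchor + sign * t * separation_mm / 2.0,
                            semi_axes_mm, exponent)
        out.append(OsteophyteSpec(direction=tuple(direction), height_mm=height_mm,
                                  radius_mm=radius_mm, point_mm=tuple(p)))
    return out


# ---------------------------------------------------------------------------
# repeated "scans"


def rescan(vol: DensityVolume, translation_mm=(0.0, 0.0, 0.0),
           rotation_deg: float = 0.0, noise_sd: float = 0.0, seed: int = 0,
           bone_threshold: float = 320.0) -> DensityVolume:
    """Simulate a repeat acquisition with repositioning jitter and fresh noise.

    Rigid in-plane (about z) rotation plus translation, resampled with linear
    interpolation; whole-voxel translations at zero rotation are exact
    shifts.  Raises if the bone would be clipped by the grid boundary.
    """
    theta = math.radians(rotation_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    # rotation acts on physical (mm) coords; grid may be anisotropic
    spacing = np.asarray(vol.spacing, dtype=float)
    R = np.array([[cos_t, -sin_t, 0.0], [sin_t, cos_t, 0.0], [0.0, 0.0, 1.0]])
    S = np.diag(spacing)
    Rv = np.linalg.inv(S) @ R @ S          # rotation in voxel coordinates
    c = (np.asarray(vol.shape, dtype=float) - 1.0) / 2.0
    t_vox = np.asarray(translation_mm, dtype=float) / spacing
    A = np.linalg.inv(Rv)
    offset = c - A @ (c + t_vox)
    out = ndimage.affine_transform(vol.values, A, offset=offset, order=1,
                                   mode="constant", cval=0.0,
                                   output=np.float32)
    bone = out >= bone_threshold
    border = np.zeros(vol.shape, dtype=bool)
    border[:2], border[-2:] = True, True
    border[:, :2], border[:, -2:] = True, True
    border[:, :, :2], border[:, :, -2:] = True, True
    if (bone & border).any():
        raise PhantomError("repositioned bone is clipped by the grid boundary")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, out.shape).astype(np.float32)
        np.clip(out, 0.0, None, out=out)
    meta = dict(vol.metadata)
    meta.update({"reposition_translation_mm": tuple(float(t) for t in translation_mm),
                 "reposition_rotation_deg": float(rotation_deg),
                 "rescan_seed": seed})
    return DensityVolume(out, vol.spacing, vol.site_label, meta)
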