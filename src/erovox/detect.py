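"""Semi-automated erosion detection: threshold → marrow fill → surface-
concavity fill → contour shrink → candidate extraction → rule-based
false-positive exclusion → VOI refinement.

The pipeline mirrors how a reader works through a density stack: binarize at
the trabecular threshold, fill the marrow space to get a solid bone mask,
bridge every surface concavity with a morphological closing, peel the
contour back so partial-volume surface rinds drop out, and keep what remains
of the concavity fillings as erosion candidates.  Candidates are then run
through three automated exclusion rules (vascular channel, osteophyte
pseudo-concavity, physiological groove) and two refinements (VOI overflow,
marrow connection).  Everything is deterministic: identical input and
configuration give identical VOIs.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from . import _morphology as morph
from .measure import MeasureError, assign_quadrant
from .volume import DensityVolume, VoxelRegion

__all__ = [
    "DetectionConfig",
    "Candidate",
    "DetectionResult",
    "DetectError",
    "binarize",
    "fill_marrow",
    "fill_surface_concavities",
    "shrink_contour",
    "extract_candidates",
    "classify_false_positives",
    "refine_overflow",
    "refine_marrow_connection",
    "adjust_rotation",
    "detect_erosions",
]


class DetectError(RuntimeError):
    """Raised when a detection stage cannot produce a valid result."""


@dataclass
class DetectionConfig:
    """Tunable parameters of the detection pipeline (mm and mg HA/cm³)."""

    threshold: float = 320.0            # trabecular bone threshold
    shrink_mm: float = 0.25             # contour peel before extraction
    overflow_shrink_mm: float = 0.50    # deeper peel for overflowing VOIs
    closing_radius_mm: float = 2.0      # ball radius for concavity filling
    shell_mm: float = 1.0               # peripheral BMD shell width
    min_volume_mm3: float = 0.10
    min_slices_axial: int = 2
    min_slices_perpendicular: int = 2
    channel_max_width_mm: float = 0.5
    physio_depth_width_min: float = 0.25
    osteophyte_ring_mm: float = 1.0         # width of the reference surface ring
    osteophyte_drop_frac: float = 0.25      # min floor drop, as share of VOI depth
    candidate_trim_mm: float = 0.12         # slivers thinner than this never join a VOI
    overflow_gap_mm: float = 0.4         # ceiling-to-bone gap of a spill sheet
    overflow_frac_max: float = 0.35      # max thin-sheet share of a contained VOI
    marrow_depth_mm: float = 3.0         # deeper than this = marrow space
    connectivity_bone: int = 26
    connectivity_background: int = 6
    review_mode: str = "auto"            # auto | interactive-list

    def validate(self, spacing) -> None:
        if self.threshold <= 0:
            raise DetectError("threshold must be positive")
        if not self.shrink_mm < self.closing_radius_mm:
            raise DetectError("shrink_mm must be smaller than closing_radius_mm")
        s = min(spacing)
        for name in ("shrink_mm", "overflow_shrink_mm", "closing_radius_mm",
                     "shell_mm", "channel_max_width_mm"):
            if getattr(self, name) < s:
                raise DetectError(f"{name} below the voxel spacing {s} mm")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class Candidate:
    """One connected concavity component and its classification state."""

    id: int
    region: VoxelRegion
    quadrant: str
    flags: set = field(default_factory=set)
    status: str = "needs-review"  # auto-accept | auto-reject | needs-review
    n_marrow: int | None = None


@dataclass
class DetectionResult:
    candidates: list
    binarized: VoxelRegion
    bone: VoxelRegion
    filled: VoxelRegion
    config: DetectionConfig

    def accepted(self, review_ledger: dict | None = None) -> list:
        """Accepted candidates; a review ledger maps candidate id (as str or
        int) to "accept"/"reject" for the needs-review ones."""
        ledger = {str(k): v for k, v in (review_ledger or {}).items()}
        out = []
        for c in self.candidates:
            if c.status == "auto-accept":
                out.append(c)
            elif c.status == "needs-review" and ledger.get(str(c.id)) == "accept":
                out.append(c)
        return out


# ---------------------------------------------------------------------------
# pipeline stages


def binarize(vol: DensityVolume, threshold: float = 320.0) -> VoxelRegion:
    """Voxels at or above the density threshold (>= comparison, so a voxel at
    exactly the threshold counts as bone)."""
    mask = vol.values >= threshold
    if not mask.any():
        raise DetectError(f"no bone at threshold {threshold} mg HA/cm3")
    return VoxelRegion(mask, vol.spacing, "binarized")


def fill_marrow(binarized: VoxelRegion) -> VoxelRegion:
    """Solid bone mask: add every cavity not 6-connected to the grid border."""
    if not binarized.mask.any():
        raise DetectError("cannot fill an empty mask")
    return VoxelRegion(morph.fill_holes_6(binarized.mask), binarized.spacing,
                       "bone_mask")


def fill_surface_concavities(bone: VoxelRegion, closing_radius_mm: float = 2.0,
                             pad: bool = True) -> VoxelRegion:
    """Bridge every surface concavity by morphological closing with a digital
    ball.  Result is a superset of the bone mask and idempotent."""
    filled = morph.close_mm(bone.mask, closing_radius_mm, bone.spacing, pad=pad)
    return VoxelRegion(filled, bone.spacing, "filled")


def shrink_contour(filled: VoxelRegion, shrink_mm: float | None = 0.25) -> VoxelRegion:
    """Peel the contour back by a digital ball (round(mm/spacing), floor one
    voxel).  Pass ``shrink_mm=None`` for the identity."""
    if shrink_mm is None:
        return filled.copy("shrunk")
    out = morph.erode_mm(filled.mask, shrink_mm, filled.spacing)
    if not out.any():
        raise DetectError("structure thinner than the shrink radius")
    return VoxelRegion(out, filled.spacing, "shrunk")


def extract_candidates(filled: VoxelRegion, shrunk: VoxelRegion,
                       bone: VoxelRegion, cfg: DetectionConfig | None = None,
                       shrink_mm: float | None = None) -> list:
    """Concavity components: seed = (shrunk ∖ bone), regrown geodesically by
    the peel depth inside (filled ∖ bone), split 26-connected.

    The peel-then-regrow keeps the full concavity volume while discarding
    the sub-peel partial-volume rind over normal surface; a deeper peel
    (overflow handling) yields a smaller VOI, never a larger one.
    """
    cfg = cfg or DetectionConfig()
    if shrink_mm is None:
        shrink_mm = cfg.shrink_mm
    allowed = _candidate_space(filled.mask, bone.mask, cfg, filled.spacing)
    seed = shrunk.mask & filled.mask & ~bone.mask
    # +1 step so the regrowth can reach the lifted ceiling layer
    grown = morph.geodesic_grow(seed, allowed | seed,
                                morph.radius_vox(shrink_mm, filled.spacing) + 1)
    labels, n = morph.label_26(grown)
    out = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() < 2:  # single-voxel specks are never meaningful
            continue
        region = VoxelRegion(mask, filled.spacing, "candidate")
        try:
            quadrant = assign_quadrant(region, bone)
        except MeasureError:  # centroid exactly on the bone axis
            quadrant = "indeterminate"
        out.append(Candidate(id=len(out), region=region, quadrant=quadrant))
    return out


def _candidate_space(filled_mask, bone_mask, cfg: DetectionConfig,
                     spacing) -> np.ndarray:
    """Concavity space a VOI may occupy.

    Two voxelization corrections on top of (filled ∖ bone): slivers thinner
    than ``candidate_trim_mm`` are removed by a small opening (the closing
    surface hangs sub-resolution skirts over normal bone around every
    protrusion and concavity rim, which would otherwise attach to the VOIs
    they touch), and the free ceiling is lifted by one voxel away from bone
    (the double-binarized digital closing reconstructs a bridged ceiling
    about one voxel below the sphere-sag closed form; the supercover voxel
    layer compensates).
    """
    gap = filled_mask & ~bone_mask
    it = max(1, morph.radius_vox(cfg.candidate_trim_mm, spacing))
    space = ndimage.binary_opening(gap, structure=morph.STRUCT_6, iterations=it)
    return space | _ceiling_lift(filled_mask, bone_mask)


def _ceiling_lift(filled_mask, bone_mask) -> np.ndarray:
    return (ndimage.binary_dilation(filled_mask, structure=morph.STRUCT_6)
            & ~filled_mask
            & ~ndimage.binary_dilation(bone_mask, structure=morph.STRUCT_6))


def _bbox_extents_mm(mask: np.ndarray, spacing) -> np.ndarray:
    sl = ndimage.find_objects(mask.astype(np.int8), max_label=1)[0]
    return np.array([(s.stop - s.start) * sp for s, sp in zip(sl, spacing)])


def _bbox_spans_vox(mask: np.ndarray) -> np.ndarray:
    sl = ndimage.find_objects(mask.astype(np.int8), max_label=1)[0]
    return np.array([s.stop - s.start for s in sl])


def _max_inscribed_diameter_mm(mask: np.ndarray, spacing) -> float:
    sl = ndimage.find_objects(mask.astype(np.int8), max_label=1)[0]
    crop = np.pad(mask[sl], 1)
    d = ndimage.distance_transform_edt(crop, sampling=spacing)
    return float(2.0 * d.max())


def _floor_drop(mask, all_cands_near, bone_surface, filled_mask,
                bone_centroid, cfg, spacing):
    """How far the candidate's floor drops below the surrounding surface.

    Frame: outward normal from the bone centroid through the candidate
    mouth.  Reference level: upper quartile of the bone-surface height over
    a narrow annulus just outside the mouth's lateral extent (upper
    quartile so general surface fall-off and curvature do not drag the
    reference down; candidate-adjacent voxels — e.g. flanking osteophyte
    surfaces — are excluded).  An erosion is carved below that level by
    about its depth; a concavity suspended between outgrowths bottoms out
    at or above it.

    Returns ``(drop_mm, depth_mm)``; ``(None, depth)`` when too little
    surrounding surface is in view to judge.
    """
    sp = np.asarray(spacing, dtype=float)
    outside_near = ndimage.binary_dilation(~filled_mask,
                                           structure=morph.STRUCT_6)
    mouth = mask & outside_near
    ref_pts = mouth if mouth.any() else mask
    c_mouth = np.array(ndimage.center_of_mass(ref_pts)) * sp
    n_hat = c_mouth - np.asarray(bone_centroid) * sp
    norm = np.linalg.norm(n_hat)
    if norm == 0:
        return None, 0.0
    n_hat /= norm

    cand_t = (np.argwhere(mask) * sp - c_mouth) @ n_hat
    depth = float(-cand_t.min())
    mouth_pts = np.argwhere(ref_pts) * sp - c_mouth
    mouth_radius = float(np.linalg.norm(mouth_pts, axis=1).max())

    pts = np.argwhere(bone_surface & ~all_cands_near) * sp - c_mouth
    t = pts @ n_hat
    lat = np.sqrt(np.maximum((pts ** 2).sum(axis=1) - t ** 2, 0.0))
    sel = ((lat > mouth_radius + 0.2)
           & (lat <= mouth_radius + 0.2 + cfg.osteophyte_ring_mm)
           & (t > -(depth + 2.0)) & (t < 2.0))
    if sel.sum() < 20:
        return None, depth
    ref_level = float(np.percentile(t[sel], 75))
    return ref_level - float(cand_t.min()), depth


def classify_false_positives(cands: list, bone: VoxelRegion, filled: VoxelRegion,
                             cfg: DetectionConfig | None = None,
                             depth_map: np.ndarray | None = None,
                             dist_bone: np.ndarray | None = None) -> list:
    """Assign false-positive flags and tri-state acceptance.

    Channel rule: thin caliber (largest inscribed ball below the channel
    width) in a laterally small structure, sub-minimum volume, or failing the
    two-consecutive-slices extent requirement in the axial and perpendicular
    planes → auto-reject.  Osteophyte rule: the candidate lies on or above
    the local reference surface of the bone instead of below it — a
    concavity suspended between outgrowths, not carved into the bone →
    auto-reject.  Physiological rule: broad and shallow (depth/width below
    the configured minimum) → needs review.  Additionally sets ``overflow``
    and ``marrow_connected`` flags for the refinement stages.
    """
    cfg = cfg or DetectionConfig()
    if depth_map is None:
        depth_map = ndimage.distance_transform_edt(filled.mask,
                                                   sampling=filled.spacing)
    if dist_bone is None:
        dist_bone = ndimage.distance_transform_edt(~bone.mask,
                                                   sampling=bone.spacing)
    spacing = bone.spacing
    voxvol = float(np.prod(spacing))
    all_cands_near = np.zeros_like(bone.mask)
    for cand in cands:
        all_cands_near |= cand.region.mask
    all_cands_near = ndimage.binary_dilation(all_cands_near,
                                             structure=morph.STRUCT_26)
    bone_surface = bone.mask & ndimage.binary_dilation(~bone.mask,
                                                       structure=morph.STRUCT_6)
    bone_centroid = np.array(ndimage.center_of_mass(bone.mask))
    for cand in cands:
        mask = cand.region.mask
        cand.flags.clear()
        vol_mm3 = mask.sum() * voxvol
        spans = _bbox_spans_vox(mask)
        extents = np.sort(_bbox_extents_mm(mask, spacing))[::-1]
        caliber = _max_inscribed_diameter_mm(mask, spacing)
        thin = (caliber < cfg.channel_max_width_mm
                and extents[1] < 4 * cfg.channel_max_width_mm)
        extent_fail = (spans[2] < cfg.min_slices_axial
                       or min(spans[0], spans[1]) < cfg.min_slices_perpendicular)
        if thin or vol_mm3 < cfg.min_volume_mm3 or extent_fail:
            cand.flags.add("channel")
            cand.status = "auto-reject"
            continue
        depth = float(depth_map[mask].max())
        width = float(extents[1])
        if width > 0 and depth / width < cfg.physio_depth_width_min:
            # broad shallow groove: physiological until a reader disagrees
            cand.flags.add("physiological")
            cand.status = "needs-review"
        else:
            drop, n_depth = _floor_drop(mask, all_cands_near, bone_surface,
                                        filled.mask, bone_centroid, cfg,
                                        spacing)
            min_drop = max(cfg.osteophyte_drop_frac * n_depth,
                           2.0 * float(min(spacing)))
            if drop is not None and drop < min_drop:
                cand.flags.add("osteophyte_pseudo")
                cand.status = "auto-reject"
                continue
            cand.status = "auto-accept"
        if _overflow_fraction(mask, depth_map, dist_bone, cfg) \
                > cfg.overflow_frac_max:
            cand.flags.add("overflow")
        if depth > cfg.marrow_depth_mm:
            cand.flags.add("marrow_connected")
    return cands


def _overflow_fraction(mask, depth_map, dist_bone, cfg) -> float:
    """Share of the candidate's volume lying in thin sheets (ceiling-to-bone
    gap below the spill scale) — high when the VOI spills past the
    concavity rim over nearly-flat surface, low for a contained cavity
    whose only thin part is the rim wedge."""
    gap = depth_map[mask] + dist_bone[mask]
    return float((gap < cfg.overflow_gap_mm).mean())


def refine_overflow(cand: Candidate, filled: VoxelRegion, bone: VoxelRegion,
                    cfg: DetectionConfig | None = None) -> Candidate:
    """Re-extract an overflowing VOI with the deeper 0.50 mm contour peel.

    The refined VOI is never larger than the concavity filling; if the
    overflow criterion still fails at the deeper peel, the flag is kept and
    the candidate is marked needs-review (deeper peels make the VOI too
    small and are not used).
    """
    cfg = cfg or DetectionConfig()
    if "overflow" not in cand.flags:
        return cand
    allowed = _candidate_space(filled.mask, bone.mask, cfg, filled.spacing)
    labels, _ = morph.label_26(allowed | cand.region.mask)
    comp = labels == labels[cand.region.mask].max()
    shrunk = morph.erode_mm(filled.mask, cfg.overflow_shrink_mm, filled.spacing)
    seed = shrunk & comp & ~bone.mask
    grown = morph.geodesic_grow(
        seed, comp, morph.radius_vox(cfg.overflow_shrink_mm, filled.spacing) + 1)
    labels2, n2 = morph.label_26(grown)
    if n2 == 0:
        cand.status = "needs-review"
        return cand
    # keep the component with the largest overlap with the original VOI
    overlaps = ndimage.sum_labels(cand.region.mask, labels2, range(1, n2 + 1))
    new_mask = labels2 == (1 + int(np.argmax(overlaps)))
    new = Candidate(cand.id, VoxelRegion(new_mask, filled.spacing, "candidate"),
                    cand.quadrant, set(cand.flags), cand.status, cand.n_marrow)
    dist_bone = ndimage.distance_transform_edt(~bone.mask, sampling=bone.spacing)
    depth_map = ndimage.distance_transform_edt(filled.mask, sampling=bone.spacing)
    if _overflow_fraction(new_mask, depth_map, dist_bone, cfg) \
            > cfg.overflow_frac_max:
        new.status = "needs-review"
    else:
        new.flags.discard("overflow")
    return new


def refine_marrow_connection(cand: Candidate, marrow: VoxelRegion,
                             cfg: DetectionConfig | None = None,
                             n_override: int | None = None) -> Candidate:
    """Separate an erosion VOI from a connected marrow space.

    The candidate∪marrow set is eroded one 6-connected step at a time until
    the erosion-side component disconnects from the marrow side; the
    erosion side is then dilated the same number of steps, masked to the
    original set.  The step count ``n`` is recorded so longitudinal runs can
    reuse it (``n_override``), keeping the operation identical across
    timepoints.
    """
    cfg = cfg or DetectionConfig()
    S = cand.region.mask | marrow.mask
    touching = (cand.region.mask & ndimage.binary_dilation(
        marrow.mask, structure=morph.STRUCT_6)).any()
    if not touching and n_override is None:
        out = Candidate(cand.id, cand.region.copy(), cand.quadrant,
                        set(cand.flags) - {"marrow_connected"}, cand.status, 0)
        return out

    def _split(n):
        """Erosion-side voxels after n peeling steps (empty = still joined,
        None = the whole set vanished)."""
        eroded = ndimage.binary_erosion(S, structure=morph.STRUCT_6,
                                        iterations=n, border_value=0)
        if not eroded.any():
            return None
        labels, _ = morph.label_26(eroded)
        marrow_labels = list(set(np.unique(labels[eroded & marrow.mask])) - {0})
        return eroded & ~np.isin(labels, marrow_labels)

    if n_override is not None:
        n = n_override
        keep = _split(n) if n > 0 else (cand.region.mask & ~marrow.mask)
        if keep is None or not keep.any():
            raise DetectError(
                f"stored separation count n={n} no longer splits the VOI "
                "from the marrow space")
    else:
        # peel until the erosion body detaches from the marrow side; small
        # slivers can break off earlier, so take the peel depth where the
        # detached (non-marrow) part is largest — that is when the VOI core
        # itself comes free
        n, keep, best = None, None, 0
        eroded = S
        for k in range(1, max(S.shape)):
            eroded = ndimage.binary_erosion(eroded, structure=morph.STRUCT_6,
                                            border_value=0)
            if not eroded.any():
                break
            labels, _ = morph.label_26(eroded)
            marrow_labels = list(set(np.unique(labels[eroded & marrow.mask]))
                                 - {0})
            res = eroded & ~np.isin(labels, marrow_labels)
            if res.sum() > best:
                best, n, keep = int(res.sum()), k, res
        if n is None:
            raise DetectError("erosion inseparable from marrow space")
    grown = morph.geodesic_grow(keep, S, n) & ~marrow.mask
    new = Candidate(cand.id, VoxelRegion(grown, cand.region.spacing, "erosion"),
                    cand.quadrant, set(cand.flags) - {"marrow_connected"},
                    cand.status, n)
    return new


# ---------------------------------------------------------------------------
# longitudinal rotation adjustment


def _axial_orientation(mask: np.ndarray):
    """Principal-axis angle (deg) of the z-projected mask in the axial plane,
    plus the moment anisotropy ratio and the centroid (voxels)."""
    proj = mask.sum(axis=2).astype(float)
    total = proj.sum()
    ii, jj = np.indices(proj.shape)
    cx = (ii * proj).sum() / total
    cy = (jj * proj).sum() / total
    mu20 = ((ii - cx) ** 2 * proj).sum() / total
    mu02 = ((jj - cy) ** 2 * proj).sum() / total
    mu11 = ((ii - cx) * (jj - cy) * proj).sum() / total
    angle = 0.5 * math.degrees(math.atan2(2 * mu11, mu20 - mu02))
    common = math.hypot(mu20 - mu02, 2 * mu11)
    lam1 = (mu20 + mu02 + common) / 2
    lam2 = (mu20 + mu02 - common) / 2
    ratio = lam1 / lam2 if lam2 > 0 else np.inf
    return angle, ratio, (cx, cy)


def adjust_rotation(vol_followup: DensityVolume, vol_baseline: DensityVolume,
                    threshold: float = 320.0,
                    min_anisotropy: float = 1.05):
    """Align the follow-up volume to baseline by a pure in-plane rotation.

    The axial principal axes of the two bone masks are matched; the rotation
    is applied about the follow-up mask centroid with linear interpolation.
    Near-circular sections make the principal axis meaningless: a warning is
    issued and the identity returned.

    Returns ``(adjusted_volume, angle_deg)``.
    """
    masks = []
    for v in (vol_followup, vol_baseline):
        masks.append(fill_marrow(binarize(v, threshold)).mask)
    ang_f, ratio_f, cen_f = _axial_orientation(masks[0])
    ang_b, ratio_b, _ = _axial_orientation(masks[1])
    if min(ratio_f, ratio_b) < min_anisotropy:
        warnings.warn("near-circular axial section: principal axis is "
                      "degenerate, returning the identity", stacklevel=2)
        return DensityVolume(vol_followup.values.copy(), vol_followup.spacing,
                             vol_followup.site_label,
                             dict(vol_followup.metadata)), 0.0
    delta = ang_b - ang_f
    delta = (delta + 90.0) % 180.0 - 90.0  # principal axes are 180-ambiguous
    theta = math.radians(delta)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    spacing = np.asarray(vol_followup.spacing, dtype=float)
    R = np.array([[cos_t, -sin_t, 0.0], [sin_t, cos_t, 0.0], [0.0, 0.0, 1.0]])
    S = np.diag(spacing)
    Rv = np.linalg.inv(S) @ R @ S
    c = np.array([cen_f[0], cen_f[1], (vol_followup.shape[2] - 1) / 2.0])
    A = np.linalg.inv(Rv)
    offset = c - A @ c
    out = ndimage.affine_transform(vol_followup.values, A, offset=offset,
                                   order=1, mode="constant", cval=0.0,
                                   output=np.float32)
    meta = dict(vol_followup.metadata)
    meta["rotation_adjusted_deg"] = float(delta)
    return DensityVolume(out, vol_followup.spacing, vol_followup.site_label,
                         meta), float(delta)


# ---------------------------------------------------------------------------
# orchestration


def detect_erosions(vol: DensityVolume, cfg: DetectionConfig | None = None,
                    marrow_n_overrides: dict | None = None) -> DetectionResult:
    """Run the full detection chain on one volume.

    ``marrow_n_overrides`` maps candidate id → stored marrow-separation
    count from a previous timepoint (the "same number of size-reduction
    operations" longitudinal contract).
    """
    cfg = cfg or DetectionConfig()
    cfg.validate(vol.spacing)
    binarized = binarize(vol, cfg.threshold)
    bone = fill_marrow(binarized)
    filled = fill_surface_concavities(bone, cfg.closing_radius_mm)
    shrunk = shrink_contour(filled, cfg.shrink_mm)
    cands = extract_candidates(filled, shrunk, bone, cfg)
    depth_map = ndimage.distance_transform_edt(filled.mask, sampling=vol.spacing)
    dist_bone = ndimage.distance_transform_edt(~bone.mask, sampling=vol.spacing)
    cands = classify_false_positives(cands, bone, filled, cfg,
                                     depth_map=depth_map, dist_bone=dist_bone)
    out = []
    marrow_mask = (filled.mask & ~bone.mask) & (depth_map > cfg.marrow_depth_mm)
    marrow = VoxelRegion(marrow_mask, vol.spacing, "marrow")
    trim_steps = morph.radius_vox(cfg.candidate_trim_mm, vol.spacing)
    space = ((filled.mask & ~bone.mask) | _ceiling_lift(filled.mask, bone.mask)) \
        & ~marrow_mask
    for cand in cands:
        if cand.status != "auto-reject" and "overflow" in cand.flags:
            cand = refine_overflow(cand, filled, bone, cfg)
        if cand.status != "auto-reject" and "marrow_connected" in cand.flags:
            n_over = (marrow_n_overrides or {}).get(cand.id)
            cand = refine_marrow_connection(cand, marrow, cfg,
                                            n_override=n_over)
        if cand.status != "auto-reject":
            # undo the sliver trim at the VOI boundary: the trim exists to
            # keep closing-skirt slivers out of the candidate statistics,
            # not to peel the measured VOI
            restored = morph.geodesic_grow(cand.region.mask, space, trim_steps)
            cand.region = VoxelRegion(restored, vol.spacing, cand.region.label)
        out.append(cand)
    return DetectionResult(out, binarized, bone, filled, cfg)
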