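# Methods

`erovox` implements a semi-automated algorithm for detecting and
quantifying bone erosions in calibrated HR-pQCT density volumes of
metacarpophalangeal joints, together with the precision statistics (ICC,
RMS%CV, least significant change) used to decide when a longitudinal change
in an erosion is real. Because no patient scans ship with the package,
every stage is exercised on digital phantoms with closed-form ground truth.

## Detection model

The input is a 3D grid of hydroxyapatite-equivalent densities
(mg HA/cm³) at isotropic ~60.7 μm spacing, axes x (radial→ulnar),
y (palmar→dorsal), z (the axial scanner stack). Detection proceeds:

1. **Binarize** at the trabecular-bone threshold (default 320 mg HA/cm³,
   `>=` so a voxel exactly at threshold is bone).
2. **Fill marrow**: every cavity not 6-connected to the grid border joins
   the bone mask, producing a solid bone.
3. **Fill surface concavities**: morphological closing with a digital
   Euclidean ball (`closing_radius_mm`). The ball bridges every concavity
   whose mouth it cannot enter; the result is idempotent and a superset of
   the bone.
4. **Shrink the contour** of the filled set by `shrink_mm` (default
   0.25 mm), discarding the partial-volume rind over normal surface.
5. **Extract candidates**: the shrunk set minus bone seeds each concavity;
   the seed is regrown geodesically by the peel depth inside
   (filled ∖ bone), and 26-connected components become candidates. A
   deeper peel (used for overflow handling, below) therefore always yields
   a *smaller* VOI.
6. **Classify false positives** with three rules (all thresholds
   configurable in `DetectionConfig`):
   * *vascular channel*: largest inscribed ball below
     `channel_max_width_mm` (0.5 mm) in a laterally small structure,
     volume below `min_volume_mm3` (0.10 mm³), or extent below two
     consecutive slices in the axial and perpendicular planes →
     auto-reject;
   * *osteophyte pseudo-concavity*: the candidate's deepest point does not
     drop below the surrounding bone-surface level (a concavity suspended
     *between* outgrowths rather than carved *into* the bone) →
     auto-reject;
   * *physiological groove*: broad and shallow, depth/width below
     `physio_depth_width_min` (0.25) → needs review.

   The physiological check runs before the osteophyte check: a groove as
   broad as the quadrant facet leaves no surrounding at-level surface for
   the floor-drop reference, so it must be routed to review on its aspect
   ratio alone.
7. **Refine**: VOIs spilling past the concavity rim are re-extracted with
   the deeper `overflow_shrink_mm` peel (0.50 mm; still-overflowing VOIs
   go to review — deeper peels make the VOI too small and are not used);
   VOIs connected to the marrow space are separated by unit-step erosion
   until disconnection, then the same number of masked dilations, and that
   count is stored so longitudinal runs can reuse it.

For longitudinal pairs an optional in-plane **rotation adjustment** aligns
the axial principal axes of the two bone masks (pure rigid rotation about
the mask centroid, linear interpolation); near-circular sections make the
principal axis meaningless and return the identity with a warning.

Review semantics: candidates end as `auto-accept`, `auto-reject` or
`needs-review`; a JSON review ledger (candidate id → accept/reject)
resolves the irreducibly visual part of the published workflow.

### The two geometric discriminators

The false-positive taxonomy is published as pictures, not formulas, so the
two non-trivial rules are this package's operationalization:

* **Floor drop (osteophyte rule).** In the frame of the outward normal
  through the candidate's mouth, the reference surface level is the upper
  quartile of the bone-surface height over a narrow annulus just outside
  the mouth's lateral extent (upper quartile so surface fall-off and
  curvature do not drag the reference down; voxels adjacent to any
  candidate — e.g. the flanking osteophytes themselves — are excluded).
  An erosion floor lies below that level by roughly its depth; a
  pseudo-concavity bottoms out at it. The flag fires when the drop is
  below `osteophyte_drop_frac` (0.25) of the VOI depth. Ball-morphology
  alternatives (protrusion maps from openings, inscribed-ball wall
  thickness) were rejected: any concavity corrupts ball-based morphology
  near its own rim, so erosion rims masquerade as protrusions.
* **Thin-sheet fraction (overflow rule).** A spilled VOI is mostly a thin
  sheet hovering over nearly-flat bone; a contained cavity is thin only at
  its rim wedge. The flag fires when more than `overflow_frac_max` (0.35)
  of the VOI volume has ceiling-to-bone gap (depth below the filled
  surface plus distance to bone) under `overflow_gap_mm` (0.4 mm). On
  controlled fixtures this separates a pit-plus-trench spill (fraction
  ≈ 0.45) from clean hemispherical carves (≤ 0.27).

## Numerical choices

* **Ball morphology via distance transforms.** All mm-radius dilations,
  erosions, closings and openings threshold exact Euclidean distance
  transforms (`scipy.ndimage.distance_transform_edt`); this is
  algebraically the digital-ball operation but O(n) in the radius, which
  matters at multi-mm closing radii (structuring elements of > 100³ voxels
  would be minutes-slow). mm values convert to voxel radii by
  `round(mm/spacing)` with a floor of one voxel (0.25 mm → 4 voxels at
  60.7 μm).
* **Closing radius rule.** A ball of radius R bridging a hemispherical
  mouth of radius r sags by R − √(R² − r²); the spherical-cap volume lost
  drops below ~10 % of the carve once R ≥ 4r. Configurations therefore
  set `closing_radius_mm` to about four times the largest expected erosion
  radius (8 mm for the r ≤ 2 mm reference phantom). The library default
  stays at 2 mm, adequate only for sub-millimetre defects.
* **Ceiling lift.** On slab-pit fixtures the double-binarized digital
  closing reconstructs the bridged ceiling ~0.7 voxel below the sag closed
  form. Candidate space therefore includes one supercover voxel layer
  above the filled surface (away from bone). Consequently VOIs are
  contained in (filled ∖ bone) up to that one-voxel layer; they never
  contain bone or voxels at or above the density threshold.
* **Sliver trim.** The closing hangs sub-resolution skirts over normal
  bone around every protrusion; a small opening (`candidate_trim_mm`,
  0.12 mm) keeps them out of candidates during classification, and the
  trimmed rind is regrown onto non-rejected VOIs before measurement.
* **Connectivity.** 26 for foreground components, 6 for background flood
  fill and for every step-counted operation (marrow separation, seed
  regrowth), the standard complementary pair.
* **Padding.** Closings transparently pad the grid by the ball radius and
  crop back (`pad=True`); with `pad=False` a dilation touching the border
  raises, since a clipped dilation silently corrupts the closing.

## Measurements

Six parameters per accepted erosion. Er.V is voxel count × voxel volume.
Depth/width (axial view) and depth/length (coronal view for radial/ulnar
erosions, sagittal for dorsal/palmar) automate the published manual
calipers: in the slice of maximal VOI area (ties to the lower index), the
mouth chord joins the two outermost VOI voxels on the reconstructed
surface; width is the chord length and depth the maximal perpendicular
drop into the bone, each plus one voxel for voxel extent. Single-slice
VOIs are measured but flagged `thin`. Er.BMD is the mean density of the
shell obtained by dilating the VOI by `shell_mm` (1.0 mm), minus the VOI,
restricted to the bone mask — without the restriction the value would
depend on mouth size through included background. Quadrants follow the
VOI centroid's axial angle about the bone centroid with ±45° boundaries,
ties toward radial/ulnar.

On hemispherical carves of radius r the constructions recover Er.V within
~10 % of (2/3)πr³ and Er.D/Er.W within two voxels of r and 2r for
r ≥ 0.75 mm; the residual volume deficit is the closing-sag cap plus
voxelization.

## Precision statistics

* **ICC**: one-way random-effects single-rater ICC(1,1) =
  (BMS − WMS)/(BMS + (k−1)·WMS). The repeats are repositioned re-scans
  read by one reader, so there is no rater factor to cross; a two-way
  ICC(2,1) is available behind `model="twoway"`. Negative estimates are
  returned unclamped.
* **RMS%CV / RMS_SD**: per subject, SD over k repeats (k−1 denominator)
  and CV = 100·SD/mean; root-mean-square over subjects. Non-positive
  subject means make %CV undefined and raise (the SD branch remains
  available).
* **LSC** = 2.77 × the precision error on either scale, with 2.77 the
  literal conventional constant (1.96·√2 rounded) for bit-compatibility
  with published arithmetic.
* **Change calls**: |diff| ≤ LSCSD is `no_change` (the boundary is
  inclusive: significance requires *exceeding* the LSC); above it,
  progression/repair for size parameters, increasing/decreasing for
  Er.BMD. New erosions enter with baseline 0 and complete repairs with
  follow-up 0 for size parameters; Er.BMD is evaluated only for erosions
  measurable at both timepoints. Cumulative-probability tables use
  (i − 0.5)/n plotting positions with the ±LSCSD cutoffs attached.
* **Paired test**: two-sided Wilcoxon signed-rank (scipy), exact null for
  small tie-free samples, zeros dropped; all-zero differences give p = 1
  with a warning.

## Phantoms: what they emulate and what they do not

The generator renders a superellipsoid bone
(|x/a|^p + |y/b|^p + |z/c|^p ≤ 1) with a dense cortical shell
(800 mg HA/cm³) and a low-density trabecular interior (200 mg HA/cm³,
deliberately below threshold so the interior binarizes to background and
is recovered by marrow filling — the algorithm only needs that topology,
not real trabecular microarchitecture). Erosions are spheres anchored on
the surface (default immersion: center on the surface, i.e. hemispherical
carve with closed-form volume, depth and width on a flat facet); channels
are narrow blind cylinders; osteophytes are bump pairs whose gap forms the
pseudo-concavity pattern; an optional groove models the physiological
inter-tubercle concavity. Noise is additive Gaussian clipped at zero
(default SD 50 mg HA/cm³, small against the 480 mg HA/cm³
cortex-to-threshold margin, as in good-quality in vivo scans);
repositioning is a rigid in-plane rotation plus translation with linear
interpolation. Ground truth (exact carved voxel sets, closed-form
volumes) is a pure function of the geometry, independent of noise seed.

The reference conditions are a 192³ phantom at 60.7 μm with erosion radii
0.75/1.0/1.5/2.0 mm spanning the clinically reported size range
(mean Er.V ≈ 2 mm³), one 0.2 mm channel and one osteophyte pair; the
repeat-scan experiment uses a 128³ three-erosion phantom with sub-voxel
(≤ 0.03 mm) translations, ≤ 0.5° rotations and fresh noise per scan,
mirroring a triple-scan protocol with erosions as subjects.

Exponent-4 facets are used for these phantoms so the flat-face closed
forms hold; exponent 2 gives the classic ellipsoid, on which the generator
refuses carves whose voxelized volume deviates more than 15 % from the
flat-face closed form (surface curvature makes the closed form wrong, not
the voxelization).

Passing on these phantoms shows the morphology, bookkeeping and
statistics are correct at scanner resolution. It does not show robustness
to real trabecular texture, partial-volume and beam-hardening artifacts,
motion, or anatomical shape variation; the erosion/osteophyte
discriminator in particular assumes the outgrowths flanking a
pseudo-concavity are resolvable against the surrounding surface, and an
erosion directly abutting a large osteophyte may be mis-flagged (the
review pathway exists for such cases).

## Known limitations

* Absolute Er.V carries a systematic negative bias of a few percent from
  the closing sag (larger when the closing radius is small relative to
  the mouth); precision (repeat-scan CV) is unaffected since the bias is
  reproducible.
* Huge erosions inseparable from the marrow space raise an error rather
  than guessing a boundary. For wide cortical breaches the same-number
  dilation contract recovers the VOI only within n unit steps of the
  eroded core: the separated VOI is reproducible across timepoints (the
  point of the contract) but under-covers the rim and may include a thin
  band of shallow intramedullary space.
* The rotation adjustment is in-plane only, matching the published
  procedure; out-of-plane repositioning is handled implicitly by the
  closing's scale.
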