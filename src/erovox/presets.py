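"""Canonical phantom specifications and matching detection configurations.

These presets pin the study conditions used throughout the test-suite,
examples and the reproduction script, so every consumer exercises the same
geometry:

* :func:`mch_phantom` — a 192³ metacarpal-head-like phantom at the native
  60.7 μm voxel size with four hemispherical erosions spanning the
  clinically reported size range (r = 0.75–2.0 mm), one vascular channel
  and one osteophyte pair (pseudo-concavity).
* :func:`repro_phantom` — a smaller 128³ three-erosion phantom used for the
  repeat-scan reproducibility experiment, where per-run cost matters more
  than covering the full size range.

The matching configurations set the concavity-closing radius to four times
the largest expected erosion radius: a ball of radius R bridging a
hemispherical mouth of radius r sags by R − √(R²−r²), and the closed-form
spherical-cap loss drops below ~10 % of the carve volume once R ≥ 4r.
"""

from __future__ import annotations

from .detect import DetectionConfig
from .phantom import ChannelSpec, ErosionSpec, PhantomSpec, osteophyte_pair
from .volume import DEFAULT_SPACING_MM

__all__ = ["mch_phantom", "mch_config", "repro_phantom", "repro_config"]

_MCH_SEMI_AXES = (3.6, 3.6, 4.2)
_MCH_EXPONENT = 4.0


def mch_phantom(seed: int = 0, noise_sd: float = 50.0) -> PhantomSpec:
    """Metacarpal-head-like phantom: four erosions, one channel, one
    osteophyte pseudo-concavity, on near-flat quadrant facets."""
    return PhantomSpec(
        shape=(192, 192, 192),
        spacing=(DEFAULT_SPACING_MM,) * 3,
        semi_axes_mm=_MCH_SEMI_AXES,
        exponent=_MCH_EXPONENT,
        cortical_thickness_mm=2.4,
        erosions=[
            ErosionSpec((1, 0, 0), 0.75),    # radial
            ErosionSpec((0, 1, 0), 1.0),     # dorsal
            ErosionSpec((-1, 0, 0), 1.5),    # ulnar
            ErosionSpec((0, -1, 0), 2.0),    # palmar
        ],
        channels=[ChannelSpec((0, 0, -1), diameter_mm=0.2, length_mm=1.2)],
        osteophytes=osteophyte_pair(
            (0, 0, 1), separation_mm=2.2, tangent=(1.0, 0.0, 0.0),
            height_mm=1.0, radius_mm=0.8,
            semi_axes_mm=_MCH_SEMI_AXES, exponent=_MCH_EXPONENT),
        noise_sd=noise_sd,
        seed=seed,
    )


def mch_config() -> DetectionConfig:
    # closing radius = 4 x largest erosion radius (2.0 mm)
    return DetectionConfig(closing_radius_mm=8.0)


def repro_phantom(seed: int = 0, noise_sd: float = 50.0) -> PhantomSpec:
    """Compact phantom for the triple-scan reproducibility experiment."""
    return PhantomSpec(
        shape=(128, 128, 128),
        spacing=(DEFAULT_SPACING_MM,) * 3,
        semi_axes_mm=(2.6, 2.6, 2.6),
        exponent=4.0,
        cortical_thickness_mm=1.8,
        erosions=[
            ErosionSpec((1, 0, 0), 0.8),
            ErosionSpec((0, 1, 0), 1.0),
            ErosionSpec((-1, 0, 0), 1.2),
        ],
        noise_sd=noise_sd,
        seed=seed,
    )


def repro_config() -> DetectionConfig:
    return DetectionConfig(closing_radius_mm=4.8)
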