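"""Repeat-scan precision: ICC, RMS%CV and the least significant change.

Simulates a triple-scan reproducibility experiment on one phantom with
sub-voxel repositioning and fresh noise, then derives per-parameter
precision.  The LSC (2.77 x the precision error) is the smallest
longitudinal change the method can call real.
"""

import numpy as np
import pandas as pd

import erovox as ev
from erovox import precision, presets

spec = presets.repro_phantom(seed=21)
volume, truth = ev.generate_phantom(spec)
config = presets.repro_config()

rows = []
jitters = [((0.020, -0.031, 0.012), 0.4),
           ((-0.027, 0.018, -0.022), -0.3),
           ((0.008, 0.025, 0.030), 0.5)]
for rep, (shift, rot) in enumerate(jitters):
    scan = ev.rescan(volume, translation_mm=shift, rotation_deg=rot,
                     noise_sd=spec.noise_sd, seed=100 + rep)
    result = ev.detect_erosions(scan, config)
    for c in result.accepted():
        rec = ev.measure_erosion(c.region, scan, result.bone, result.filled,
                                 id=c.id, quadrant=c.quadrant)
        for p in ("Er_V", "Er_D", "Er_W", "Er_D2", "Er_L", "Er_BMD"):
            rows.append({"subject": c.quadrant, "repeat": rep,
                         "parameter": p, "value": getattr(rec, p)})

report = precision.precision_report(pd.DataFrame(rows))
print(report.round(3).to_string(index=False))
print("\nreading: ICC near 1 and RMS%CV below ~5% mean the repositioned "
      "re-scans agree;")
print("a follow-up change must exceed LSC_SD (absolute) or LSC_pct_CV "
      "(percent) to count as real.")
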