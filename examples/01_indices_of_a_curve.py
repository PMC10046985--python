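"""Tortuosity indices of a single vessel centerline.

Builds an analytic semicircular centerline (radius 50 px), runs the
derivative/curvature chain and prints the four geometric parameters and
the eight local tortuosity indices.  For a semicircle the closed forms
are D = 2R, L = pi R, TK = pi, TSK = pi / R, so DF should print close to
pi/2 = 1.5708.
"""

from vesseltort import curve_geometry as cg
from vesseltort import synthetic_data as sd
import math

arc = sd.gen_analytic_curve("circular_arc", {"radius": 50, "angle": math.pi})
gp, profile = cg.analyze_curve(arc.as_curve())

print("geometric parameters (px):")
for k, v in gp.as_dict().items():
    print(f"  {k:>4} = {v:.4f}")
print("tortuosity indices:")
for k, v in profile.as_dict().items():
    print(f"  {k:>4} = {v:.6f}")
print(f"closed-form DF = pi/2 = {math.pi / 2:.6f}")
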