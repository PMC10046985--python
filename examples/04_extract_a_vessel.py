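"""Extract one vessel from a rasterized tube and measure it.

Draws a width-7 dark tube along a radius-80 semicircle, then runs the
segmentation chain (binarize, close, skeletonize, prune, parametrize)
from a rough hand line, and compares the measured geometry with the
known truth.  D and L should agree within ~2%, TK within ~5%, and DF
within 2% of pi/2.
"""

import numpy as np

from vesseltort import curve_geometry as cg
from vesseltort import synthetic_data as sd
from vesseltort import vessel_extraction as vx
import math

arc = sd.gen_analytic_curve(
    "circular_arc", {"radius": 80, "angle": math.pi, "center": (150, 250), "phase": 0.3}
)
raster = sd.rasterize_vessel(arc, width_px=7, image_shape=(400, 500), noise_sd=2.0, seed=1)

# a rough hand line: every 20th true centerline pixel
hand_line = np.vstack([raster.centerline_px[::20], raster.centerline_px[-1]]).astype(float)
curve = vx.extract_vessel(raster.image, hand_line, raster.tentative_endpoints.astype(float))
gp, profile = cg.analyze_curve(curve)

t = arc.truth
print(f"{'':8}{'measured':>12}{'truth':>12}{'rel err':>10}")
for name, got, want in (
    ("D", gp.D, t.D), ("L", gp.L, t.L), ("TK", gp.TK, t.TK), ("DF", profile.DF, t.L / t.D)
):
    print(f"{name:8}{got:12.3f}{want:12.3f}{abs(got - want) / want:10.2%}")
print(f"centerline has {len(curve)} points (parameter t = 1..N)")
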