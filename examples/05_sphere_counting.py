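"""Count single-cell-derived spheres on a synthetic well-chip image.

Draws fluorescent spheres of known diameters, counts those larger than the
40 um cut-off, and reports the per-well sphere-formation rate.
"""

import numpy as np

from migchip import count_spheres

rng = np.random.default_rng(3)
true_diameters = rng.uniform(20.0, 70.0, size=30)

plane = np.zeros((200, 80 * 31), dtype=np.uint8)
yy, xx = np.mgrid[: plane.shape[0], : plane.shape[1]]
for i, d in enumerate(true_diameters):
    cx = 80 * (i + 1)
    plane[(yy - 100) ** 2 + (xx - cx) ** 2 <= (d / 2) ** 2] = 200

result = count_spheres(plane, threshold=50, pixel_size_um=1.0,
                       min_diameter_um=40.0, n_seeded_wells=1000)
expected = int((true_diameters > 40).sum())
print(f"objects detected: {len(result.diameters_um)}")
print(f"spheres > 40 um: {result.n_spheres} (ground truth {expected})")
print(f"sphere-formation rate: {result.sphere_rate:.1%} of 1000 seeded wells")
# Diameter is the equivalent-area diameter of each connected bright region;
# only spheres above 40 um count as sphere-formation events.
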