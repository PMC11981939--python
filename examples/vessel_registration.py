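"""Fiducial-free co-registration from vasculature alone.

Builds a tube phantom pair related by a known ~10-um smooth deformation,
runs the vessel pipeline (ridge filter -> constant-radius tube normalization
-> multi-scale B-spline registration), and measures how much closer the
recovered displacement field brings planted centreline landmarks.
"""

import numpy as np

from coregmatch import synth
from coregmatch.vessels import apply_field, deformable_register, normalize_vessels, ridge_filter


def true_warp(pts):
    pts = np.asarray(pts, float).reshape(-1, 3)
    out = pts.copy()
    out[:, 0] += 7 * np.sin(2 * np.pi * pts[:, 1] / 140) + 2
    out[:, 1] += 8 * np.cos(2 * np.pi * pts[:, 2] / 160)
    out[:, 2] += 6 * np.sin(2 * np.pi * pts[:, 0] / 150) - 1.5
    return out


fixed, moving, lm_fixed, lm_moving = synth.make_vessel_volume(
    seed=1, n_tubes=10, size_um=(72, 72, 72), warp=true_warp)

prep = lambda vol: normalize_vessels(ridge_filter(vol, (1.0, 2.0)),
                                     threshold=0.2, min_component_voxels=20,
                                     tube_sigma_um=2.0, rounds=2)
field = deformable_register(prep(fixed), prep(moving),
                            grid_schedule_um=(32, 16, 8), smoothing_schedule_um=(4, 2, 1),
                            max_iter=400, sampling_fraction=0.2, seed=7)

pre = np.linalg.norm(lm_moving - lm_fixed, axis=1).mean()
moved = apply_field(field, points=lm_moving, direction="moving_to_fixed")
post = np.linalg.norm(moved - lm_fixed, axis=1).mean()
print(f"final tube-volume correlation: {field.final_similarity:.3f}")
print(f"mean landmark error: {pre:.2f} um before -> {post:.2f} um after "
      f"({pre / post:.1f}x reduction)")
print("landmarks are centreline points never shown to the registration")
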