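"""Shared fixtures: synthetic warps, fiducial sets, a fitted canonical stack,
and one vessel-phantom registration reused by several test modules."""

import numpy as np
import pytest

from coregmatch import synth
from coregmatch.transforms import fit_transform_stack

# reduced stage schedule for tests that refit many times (same stage types,
# smaller lattices)
REDUCED_SCHEDULE = [
    {"type": "polynomial"},
    {"type": "z_binned", "n_bins": 2},
    {"type": "grid_tps", "n": 3},
    {"type": "exact_tps"},
]


@pytest.fixture(scope="session")
def smooth_warp():
    return synth.make_deformation(seed=11, amplitude_um=20.0, smoothness_um=300.0)


@pytest.fixture(scope="session")
def noisy_fiducials(smooth_warp):
    """500 fiducials from a smooth warp with 2-um annotation noise."""
    return synth.make_fiducials(smooth_warp, 500, noise_sd_um=2.0, seed=0)


@pytest.fixture(scope="session")
def canonical_stack(noisy_fiducials):
    return fit_transform_stack(noisy_fiducials)


def synthetic_vessel_warp(pts):
    """Smooth synthetic deformation, ~10 um mean displacement over the phantom."""
    pts = np.asarray(pts, float).reshape(-1, 3)
    out = pts.copy()
    out[:, 0] += 7 * np.sin(2 * np.pi * pts[:, 1] / 140) + 2
    out[:, 1] += 8 * np.cos(2 * np.pi * pts[:, 2] / 160)
    out[:, 2] += 6 * np.sin(2 * np.pi * pts[:, 0] / 150) - 1.5
    return out


@pytest.fixture(scope="session")
def vessel_phantom():
    """(fixed, moving, landmarks_fixed, landmarks_moving) tube phantom pair."""
    return synth.make_vessel_volume(
        seed=1, n_tubes=10, size_um=(72, 72, 72), warp=synthetic_vessel_warp
    )


@pytest.fixture(scope="session")
def vessel_registration(vessel_phantom):
    """Run the full vessel pipeline once; reused by module and acceptance tests."""
    from coregmatch.vessels import deformable_register, normalize_vessels, ridge_filter

    fixed, moving, lmf, lmm = vessel_phantom
    nf = normalize_vessels(ridge_filter(fixed, (1.0, 2.0)), 0.2, 20, 2.0, 2)
    nm = normalize_vessels(ridge_filter(moving, (1.0, 2.0)), 0.2, 20, 2.0, 2)
    field = deformable_register(
        nf,
        nm,
        grid_schedule_um=(32, 16, 8),
        smoothing_schedule_um=(4, 2, 1),
        max_iter=400,
        sampling_fraction=0.2,
        seed=7,
    )
    return field, fixed, moving, lmf, lmm
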