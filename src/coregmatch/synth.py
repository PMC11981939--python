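"""Seeded synthetic-data generators with known ground truth.

Every input the toolkit consumes can be generated here: smooth EM->2P
warps, noisy fiducial sets, multi-scan centroid scenes with planted
matches and duplicates, repeated-trial response blocks with controlled
reliability, and vessel tube phantoms for fiducial-free registration.
All generators are pure functions of their parameters and a seed.

The default scene box (1300 x 870 x 820 um) mirrors the extent of the
in vivo volume the toolkit targets, so synthetic length scales match
real ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .transforms import FiducialSet

__all__ = [
    "DEFAULT_BOX_UM",
    "Warp",
    "GroundTruthScene",
    "make_deformation",
    "make_fiducials",
    "make_centroid_scene",
    "make_response_set",
    "make_vessel_volume",
]

#: in vivo-scale bounding box, um
DEFAULT_BOX_UM = np.array([1300.0, 870.0, 820.0])


@dataclass
class Warp:
    """A smooth deterministic 3D warp: affine + quadratic + z-profile + smooth random bumps."""

    affine_A: np.ndarray
    affine_b: np.ndarray
    quad_coef: np.ndarray  # (3,) coefficient of componentwise x^2 terms
    z_amp: np.ndarray  # (3,) amplitude of sinusoidal z-dependent offset per axis
    z_freq: float  # cycles per um along z
    z_phase: np.ndarray
    bump_centers: np.ndarray  # (k, 3)
    bump_amps: np.ndarray  # (k, 3)
    smoothness_um: float
    box: np.ndarray = field(default_factory=lambda: DEFAULT_BOX_UM.copy())

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        x = np.asarray(pts, dtype=float).reshape(-1, 3)
        out = x @ self.affine_A.T + self.affine_b
        xn = x / self.box  # normalized for the quadratic term
        out = out + self.quad_coef * xn**2 * self.box
        z = x[:, 2:3]
        out = out + self.z_amp * np.sin(2 * np.pi * self.z_freq * z + self.z_phase)
        if len(self.bump_centers):
            d2 = ((x[:, None, :] - self.bump_centers[None, :, :]) ** 2).sum(-1)
            g = np.exp(-d2 / (2 * self.smoothness_um**2))
            out = out + g @ self.bump_amps
        return out

    def inverse(self, pts: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
        """Numerical inverse by affine-preconditioned fixed-point iteration."""
        p = np.asarray(pts, dtype=float).reshape(-1, 3)
        Ainv = np.linalg.inv(self.affine_A)
        q = (p - self.affine_b) @ Ainv.T
        for _ in range(max_iter):
            err = p - self(q)
            if np.max(np.abs(err)) < tol:
                break
            q = q + 0.9 * (err @ Ainv.T)
        return q


def make_deformation(
    seed: int,
    amplitude_um: float = 20.0,
    smoothness_um: float = 300.0,
    affine: str | np.ndarray = "random",
    box: np.ndarray = DEFAULT_BOX_UM,
    n_bumps: int = 40,
    quad_fraction: float = 0.3,
    z_fraction: float = 0.25,
    bump_fraction: float = 0.5,
) -> Warp:
    """A random smooth EM->2P-like warp with known closure.

    ``amplitude_um`` scales the nonlinear parts (quadratic trend,
    z-dependent offsets emulating section-shape changes, and smooth
    random bumps of correlation length ``smoothness_um``); at 0 with
    ``affine='identity'`` the warp is the affine map alone.
    """
    if amplitude_um < 0:
        raise ValueError("amplitude_um must be >= 0")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    if isinstance(affine, str):
        if affine == "identity":
            A, b = np.eye(3), np.zeros(3)
        elif affine == "random":
            # modest rotation + anisotropic scale + shear, emulating gross modality mismatch
            ang = rng.uniform(-0.08, 0.08, size=3)
            Rx = np.array([[1, 0, 0], [0, np.cos(ang[0]), -np.sin(ang[0])], [0, np.sin(ang[0]), np.cos(ang[0])]])
            Ry = np.array([[np.cos(ang[1]), 0, np.sin(ang[1])], [0, 1, 0], [-np.sin(ang[1]), 0, np.cos(ang[1])]])
            Rz = np.array([[np.cos(ang[2]), -np.sin(ang[2]), 0], [np.sin(ang[2]), np.cos(ang[2]), 0], [0, 0, 1]])
            S = np.diag(rng.uniform(0.95, 1.1, size=3))
            A = Rz @ Ry @ Rx @ S
            b = rng.uniform(-30, 30, size=3)
        else:
            raise ValueError("affine must be 'identity', 'random' or a 3x3 matrix")
    else:
        A, b = np.asarray(affine, float), np.zeros(3)
    scale = amplitude_um
    quad = rng.uniform(-1, 1, size=3) * quad_fraction * scale / np.maximum(box, 1.0)
    z_amp = rng.uniform(-1, 1, size=3) * z_fraction * scale
    z_freq = rng.uniform(2.0, 4.0) / max(box[2], 1.0)  # a few cycles over the depth
    z_phase = rng.uniform(0, 2 * np.pi, size=3)
    if scale > 0 and n_bumps > 0 and bump_fraction > 0:
        centers = rng.uniform(-0.1, 1.1, size=(n_bumps, 3)) * box
        amps = rng.normal(0, 1, size=(n_bumps, 3))
        # scale so the pointwise displacement sd of the bump field
        # ~ bump_fraction * amplitude
        probe = rng.uniform(0, 1, size=(500, 3)) * box
        d2 = ((probe[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        g = np.exp(-d2 / (2 * smoothness_um**2))
        sd = np.std(g @ amps)
        amps *= bump_fraction * scale / max(sd, 1e-12)
    else:
        centers = np.zeros((0, 3))
        amps = np.zeros((0, 3))
    return Warp(A, b, quad, z_amp, z_freq, z_phase, centers, amps, smoothness_um, box.copy())


def make_fiducials(
    warp: Callable[[np.ndarray], np.ndarray],
    n: int,
    noise_sd_um: float = 2.0,
    vessel_fraction: float = 0.32,
    seed: int = 0,
    box: np.ndarray = DEFAULT_BOX_UM,
) -> FiducialSet:
    """Uniform source landmarks in the box; targets = warp(source) + isotropic noise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    src = rng.uniform(0, 1, size=(n, 3)) * box
    dst = np.asarray(warp(src)) + rng.normal(0, noise_sd_um, size=(n, 3))
    kinds = np.where(rng.uniform(size=n) < vessel_fraction, "vessel", "soma")
    return FiducialSet.from_arrays(src, dst, kinds=list(kinds))


# ---------------------------------------------------------------------------
# centroid scenes
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthScene:
    """A multi-scan matching scene with planted truth."""

    warp: Warp
    em_table: pd.DataFrame  # em_id, x_um, y_um, z_um (EM space)
    unit_tables: dict  # scan_idx -> DataFrame(session, scan_idx, field, unit_id, x/y/z_um, 2P space)
    true_matches: pd.DataFrame  # session, scan_idx, field, unit_id, em_id
    duplicate_groups: dict  # em_id -> list of (session, scan_idx, unit_id)

    def units_frame(self) -> pd.DataFrame:
        return pd.concat(self.unit_tables.values(), ignore_index=True)


def _min_spacing_points(rng, n, box, min_spacing, max_tries=200000):
    pts = np.empty((0, 3))
    tries = 0
    while len(pts) < n and tries < max_tries:
        batch = rng.uniform(0, 1, size=(max(64, n), 3)) * box
        for p in batch:
            tries += 1
            if len(pts) == 0 or np.min(np.linalg.norm(pts - p, axis=1)) >= min_spacing:
                pts = np.vstack([pts, p])
                if len(pts) == n:
                    break
    if len(pts) < n:
        raise RuntimeError("could not place somata with the requested spacing")
    return pts


def make_centroid_scene(
    warp: Warp,
    n_em: int = 300,
    n_scans: int = 3,
    detection_rate: float = 0.8,
    jitter_sd_um: float = 2.0,
    clutter_rate: float = 0.05,
    seed: int = 0,
    box: np.ndarray = DEFAULT_BOX_UM,
    min_spacing_um: float = 15.0,
    session: int = 1,
) -> GroundTruthScene:
    """EM somata plus per-scan functional units with planted matches.

    Somata are placed with a minimum-spacing process (default 15 um,
    above the 10 um consolidation criterion, so planted truth is
    unambiguous at default jitter). Per scan, each soma is detected with
    ``detection_rate``; its unit centroid is the warped soma position
    plus isotropic jitter. Clutter units (no EM counterpart) are added
    at ``clutter_rate`` of the detected count.
    """
    for r in (detection_rate, clutter_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    somata = _min_spacing_points(rng, n_em, box, min_spacing_um)
    em_ids = np.arange(1, n_em + 1) * 100  # sparse ids, resembling nucleus ids
    em_table = pd.DataFrame(
        {"em_id": em_ids, "x_um": somata[:, 0], "y_um": somata[:, 1], "z_um": somata[:, 2]}
    )
    somata_2p = warp(somata)
    unit_tables = {}
    truth_rows = []
    dup_groups: dict = {}
    for s in range(1, n_scans + 1):
        detected = rng.uniform(size=n_em) < detection_rate
        idx = np.nonzero(detected)[0]
        pos = somata_2p[idx] + rng.normal(0, jitter_sd_um, size=(len(idx), 3))
        n_clut = int(round(clutter_rate * len(idx)))
        clut = rng.uniform(0, 1, size=(n_clut, 3)) * box
        clut = warp(clut) + rng.normal(0, jitter_sd_um, size=(n_clut, 3))
        xyz = np.vstack([pos, clut])
        unit_ids = np.arange(1, len(xyz) + 1)
        tbl = pd.DataFrame(
            {
                "session": session,
                "scan_idx": s,
                "field": 1,
                "unit_id": unit_ids,
                "x_um": xyz[:, 0],
                "y_um": xyz[:, 1],
                "z_um": xyz[:, 2],
            }
        )
        unit_tables[s] = tbl
        for u, j in zip(unit_ids[: len(idx)], idx):
            truth_rows.append(
                {"session": session, "scan_idx": s, "field": 1, "unit_id": int(u), "em_id": int(em_ids[j])}
            )
            dup_groups.setdefault(int(em_ids[j]), []).append((session, s, int(u)))
    true_matches = pd.DataFrame(truth_rows)
    return GroundTruthScene(warp, em_table, unit_tables, true_matches, dup_groups)


# ---------------------------------------------------------------------------
# response blocks
# ---------------------------------------------------------------------------


def expected_oracle_score(sigma_s: float, sigma_n: float, n_repeats: int) -> float:
    """Closed-form expected jackknife reliability for the signal+noise model
    trace_i = s + eps_i: rho = ss / sqrt((ss + sn)(ss + sn/(R-1)))."""
    ss, sn = sigma_s**2, sigma_n**2
    denom = np.sqrt((ss + sn) * (ss + sn / (n_repeats - 1)))
    return 0.0 if denom == 0 else float(ss / denom)


def make_response_set(
    n_units: int,
    n_clips: int = 6,
    n_repeats: int = 10,
    snr_grid=(0.0, 0.25, 0.5, 1.0, 2.0),
    trace_len: int = 300,
    sampling_rate: float = 30.0,
    seed: int = 0,
):
    """Repeated-trial response blocks trace_i = s + eps_i with per-unit SNR from a grid.

    Returns ``(blocks, truth)`` where truth is a DataFrame with the
    per-unit sigma_s, sigma_n and the closed-form expected oracle score.
    """
    from .reliability import ResponseBlock

    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    rng = np.random.default_rng(seed)
    snr_grid = np.asarray(snr_grid, dtype=float)
    blocks, rows = [], []
    for u in range(n_units):
        snr = snr_grid[u % len(snr_grid)]
        sigma_n = 1.0
        sigma_s = snr * sigma_n
        traces = {}
        for c in range(n_clips):
            s = rng.normal(0, sigma_s, size=trace_len) if sigma_s > 0 else np.zeros(trace_len)
            eps = rng.normal(0, sigma_n, size=(n_repeats, trace_len))
            traces[f"clip{c}"] = s[None, :] + eps
        key = (1, 1, 1, u + 1)  # session, scan_idx, field, unit_id
        blocks.append(ResponseBlock(unit_key=key, traces=traces, sampling_rate=sampling_rate))
        rows.append(
            {
                "unit_id": u + 1,
                "sigma_s": sigma_s,
                "sigma_n": sigma_n,
                "expected_oracle": expected_oracle_score(sigma_s, sigma_n, n_repeats),
            }
        )
    return blocks, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# vessel phantoms
# ---------------------------------------------------------------------------


def _random_centerlines(rng, n_tubes, size, step=1.0, min_len=0.6):
    """Smooth random polylines through a cubic volume (coordinates in voxels/um)."""
    size = np.asarray(size, dtype=float)
    lines = []
    for _ in range(n_tubes):
        p = rng.uniform(0.1, 0.9, size=3) * size
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts = [p.copy()]
        n_steps = int(min_len * size.max() / step * rng.uniform(1.0, 1.6))
        for _ in range(n_steps):
            d = d + rng.normal(0, 0.08, size=3)  # slowly turning direction
            d /= np.linalg.norm(d)
            p = p + d * step
            if ((p < -5) | (p > size + 5)).any():
                break
            pts.append(p.copy())
        if len(pts) > 5:
            lines.append(np.array(pts))
    return lines


def make_vessel_volume(
    seed: int,
    n_tubes: int = 8,
    radius_range_um=(2.0, 5.0),
    size_um=(72, 72, 72),
    warp: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    n_landmarks: int = 30,
):
    """Tube phantom pair (fixed, moving) at 1-um voxels plus landmark truth.

    ``moving(x) = fixed(warp(x))`` (pull-back resampling), so a landmark
    at fixed-space position p appears in the moving volume at
    ``warp^{-1}(p)``. Returns ``(fixed, moving, landmarks_fixed,
    landmarks_moving)`` with landmark coordinates in um; when warp is
    None the two volumes are identical.
    """
    from .vessels import VoxelVolume

    rng = np.random.default_rng(seed)
    size = np.asarray(size_um, dtype=int)
    lines = _random_centerlines(rng, n_tubes, size)
    if not lines:
        raise RuntimeError("no centerlines generated")
    vol = np.zeros(tuple(size), dtype=np.float32)
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in size], indexing="ij")
    grid = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    all_pts = []
    radii = []
    for line in lines:
        r = rng.uniform(*radius_range_um)
        all_pts.append(line)
        radii.append(np.full(len(line), r))
    pts = np.vstack(all_pts)
    rad = np.concatenate(radii)
    tree = cKDTree(pts)
    # distance of each voxel to the nearest centerline point
    d, j = tree.query(grid, k=1, workers=-1)
    prof = np.exp(-(d**2) / (2 * (rad[j] / 1.5) ** 2))
    vol = prof.reshape(tuple(size)).astype(np.float32)
    vol[vol < 1e-3] = 0.0
    fixed = VoxelVolume(vol, voxel_size=(1.0, 1.0, 1.0))
    # landmarks: sample interior centerline points
    interior = pts[((pts > 8) & (pts < size - 8)).all(axis=1)]
    k = min(n_landmarks, len(interior))
    lm_fixed = interior[rng.choice(len(interior), size=k, replace=False)]
    if warp is None:
        return fixed, VoxelVolume(vol.copy(), voxel_size=(1.0, 1.0, 1.0)), lm_fixed, lm_fixed.copy()
    coords = np.asarray(warp(grid)).reshape(tuple(size) + (3,))
    moving_vals = ndimage.map_coordinates(
        vol, [coords[..., 0], coords[..., 1], coords[..., 2]], order=1, mode="constant"
    ).astype(np.float32)
    moving = VoxelVolume(moving_vals, voxel_size=(1.0, 1.0, 1.0))
    # invert the (small) warp to place landmarks in the moving volume
    lm_moving = _invert_small_warp(warp, lm_fixed)
    return fixed, moving, lm_fixed, lm_moving


def _invert_small_warp(warp, pts, tol=1e-6, max_iter=100):
    q = np.asarray(pts, dtype=float).copy()
    for _ in range(max_iter):
        err = pts - np.asarray(warp(q))
        if np.max(np.abs(err)) < tol:
            break
        q = q + err
    return q
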