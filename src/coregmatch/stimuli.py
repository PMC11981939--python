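"""Parametric visual stimuli: Monet2 (global directional) and Trippy (local directional).

Monet2 is smoothed Gaussian noise with coherent global motion: an
i.i.d. Gaussian noise video is low-passed in time (Hamming FIR, 4 Hz)
and space (Gaussian, sigma = 3 deg), then each of 16 equal periods of a
15-s block is advected along one of 16 randomly ordered directions at
42.8 deg/s while an angular spectral filter

    G(omega; c) = sqrt(c) * H(c * omega),  H(w) = 1/2 + 1/2 cos w on |w| < pi

(omega = spectral polar angle - motion direction, wrapped to the
orientation period pi) biases orientation energy perpendicular to the
motion. At c = 2.5 the kernel's full width at half maximum is 72 deg.

Trippy is the cosine of a smooth drifting phase field: low-resolution
uniform phase noise, band-limited at 4 Hz, temporally upsampled to
60 Hz with a Hann (raised-cosine) kernel, given a linear 8*pi rad/s
drift, and spatially upsampled to the screen with a Gaussian kernel
(sigma = 22.5 deg). Frames are 1/2 + 1/2 cos(phase), so every local
feature (orientation, direction, spatial and temporal frequency) is
analytically derivable from the returned phase movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "MonitorGeometry",
    "MonetParams",
    "TrippyParams",
    "StimulusMovie",
    "orientation_kernel",
    "direction_schedule",
    "generate_monet2",
    "generate_trippy",
]


@dataclass(frozen=True)
class MonitorGeometry:
    """Monitor placement; defaults give ~3.8 deg/cm at the nearest point."""

    width_cm: float = 56.5
    height_cm: float = 31.8
    resolution_x: int = 1920
    resolution_y: int = 1080
    eye_distance_cm: float = 15.0
    deg_per_cm_at_center: float = 3.8

    def __post_init__(self):
        if min(self.width_cm, self.height_cm, self.eye_distance_cm) <= 0:
            raise ValueError("monitor dimensions must be positive")
        # small-angle consistency: deg/cm ~= (180/pi)/distance at the nearest point
        approx = np.degrees(1.0 / self.eye_distance_cm)
        if not 0.5 * approx <= self.deg_per_cm_at_center <= 2.0 * approx:
            raise ValueError("deg_per_cm_at_center inconsistent with eye distance")

    def deg_per_px(self, frame_width_px: int) -> float:
        """Degrees per rendered pixel when the frame spans the monitor width."""
        return self.deg_per_cm_at_center * self.width_cm / frame_width_px

    def px_per_deg(self, frame_width_px: int) -> float:
        return 1.0 / self.deg_per_px(frame_width_px)


@dataclass(frozen=True)
class MonetParams:
    temporal_bandwidth_hz: float = 4.0
    spatial_sigma_deg: float = 3.0
    n_directions: int = 16
    block_duration_s: float = 15.0
    speed_deg_per_s: float = 42.8
    c: float = 2.5  # orientation selectivity coefficient
    fps: float = 30.0
    frame_height: int = 90
    frame_width: int = 160
    seed: int = 0

    def __post_init__(self):
        if self.n_directions < 1 or self.c <= 0 or self.speed_deg_per_s < 0:
            raise ValueError("invalid Monet2 parameters")
        if self.fps <= 2 * self.temporal_bandwidth_hz:
            raise ValueError("fps must exceed twice the temporal bandwidth (Nyquist)")


@dataclass(frozen=True)
class TrippyParams:
    phase_bandwidth_hz: float = 4.0
    output_fps: float = 60.0
    drift_rad_per_s: float = 8.0 * np.pi
    spatial_sigma_deg: float = 22.5
    frame_height: int = 90
    frame_width: int = 160
    duration_s: float = 15.0
    grid_ny: int = 12
    grid_nx: int = 20
    noise_amplitude_rad: float = np.pi
    seed: int = 0

    def __post_init__(self):
        if self.output_fps <= 2 * self.phase_bandwidth_hz:
            raise ValueError("output_fps must exceed twice the phase bandwidth")
        if not np.isfinite(self.drift_rad_per_s):
            raise ValueError("drift must be finite")
        if self.duration_s < 1:
            raise ValueError("duration must be >= 1 s")


@dataclass
class StimulusMovie:
    """Rendered frames in [0, 1] plus per-frame metadata."""

    frames: np.ndarray  # (T, H, W)
    fps: float
    deg_per_px: float
    direction_deg: Optional[np.ndarray] = None  # Monet2: per-frame motion direction
    phase: Optional[np.ndarray] = None  # Trippy: (T, H, W) unwrapped local phase, rad
    raw_frames: Optional[np.ndarray] = None  # pre-rescaling field (Monet2 diagnostics)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite values")
        for meta in (self.direction_deg, self.phase):
            if meta is not None and len(meta) != len(self.frames):
                raise ValueError("metadata length must equal the number of frames")


def orientation_kernel(omega, c: float):
    """Angular gain G(omega; c) = sqrt(c) * H(c*omega), H the raised cosine on (-pi, pi).

    ``omega`` is the (already wrapped) difference between the spectral
    polar angle and the motion direction, in radians. Even in omega,
    maximum sqrt(c) at 0, support |omega| < pi/c.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    w = np.asarray(omega, dtype=float)
    h = np.where(np.abs(c * w) < np.pi, 0.5 + 0.5 * np.cos(c * w), 0.0)
    return np.sqrt(c) * h


def direction_schedule(n_directions: int, seed: int) -> np.ndarray:
    """Seeded random permutation of n equally spaced directions in [0, 360) degrees."""
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.permutation(np.arange(n_directions) * 360.0 / n_directions)


def _wrap_orientation(angle: np.ndarray) -> np.ndarray:
    """Wrap angles into the orientation principal interval [-pi/2, pi/2)."""
    return (angle + np.pi / 2) % np.pi - np.pi / 2


def _temporal_lowpass(video: np.ndarray, cutoff_hz: float, fps: float) -> np.ndarray:
    """Linear-phase Hamming-window FIR low-pass along the time axis.

    firwin places the -6 dB (half-amplitude) point at the cutoff.
    """
    numtaps = int(2 * round(fps / cutoff_hz)) + 1
    taps = signal.firwin(numtaps, cutoff_hz, window="hamming", fs=fps)
    return ndimage.convolve1d(video, taps, axis=0, mode="reflect")


def generate_monet2(
    params: MonetParams = MonetParams(),
    geometry: MonitorGeometry = MonitorGeometry(),
    keep_raw: bool = False,
) -> StimulusMovie:
    """Render one Monet2 block; deterministic given (params, geometry).

    Motion is implemented as Fourier-shift advection of the filtered
    noise field (exact subpixel translation on the periodic FFT domain),
    accumulated within each direction period and reset at period
    boundaries; the angular orientation filter is applied per period
    with period-pi wrapping so orientation, not direction, is biased.
    """
    p, g = params, geometry
    n_frames = int(round(p.block_duration_s * p.fps))
    # equal periods up to one-frame rounding of the boundaries
    bounds = np.round(np.linspace(0, n_frames, p.n_directions + 1)).astype(int)
    if np.any(np.diff(bounds) < 2):
        raise ValueError(
            "block too short: each of the n_directions periods needs >= 2 frames"
        )
    deg_per_px = g.deg_per_px(p.frame_width)
    rng = np.random.default_rng(p.seed)
    video = rng.standard_normal((n_frames, p.frame_height, p.frame_width))
    video = _temporal_lowpass(video, p.temporal_bandwidth_hz, p.fps)
    sigma_px = p.spatial_sigma_deg / deg_per_px
    video = ndimage.gaussian_filter(video, sigma=(0, sigma_px, sigma_px), mode="wrap")

    H, W = p.frame_height, p.frame_width
    ky = np.fft.fftfreq(H)[:, None]  # cycles / px
    kx = np.fft.fftfreq(W)[None, :]
    phi = np.arctan2(ky, kx)  # spectral polar angle
    directions = direction_schedule(p.n_directions, p.seed)
    theta_per_frame = np.repeat(directions, np.diff(bounds))
    step_px = p.speed_deg_per_s / p.fps / deg_per_px

    out = np.empty_like(video)
    for per in range(p.n_directions):
        theta = np.deg2rad(directions[per])
        gain = orientation_kernel(_wrap_orientation(phi - theta), p.c)
        gain[0, 0] = np.sqrt(p.c)  # DC: keep the mean at the kernel maximum gain
        dx, dy = step_px * np.cos(theta), step_px * np.sin(theta)
        for f, t in enumerate(range(bounds[per], bounds[per + 1])):
            # displacement accumulates within the period, resets at its start
            ramp = np.exp(-2j * np.pi * (kx * dx * f + ky * dy * f))
            out[t] = np.fft.ifft2(np.fft.fft2(video[t]) * ramp * gain).real
    lo, hi = out.min(), out.max()
    frames = (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
    return StimulusMovie(
        frames=frames,
        fps=p.fps,
        deg_per_px=deg_per_px,
        direction_deg=theta_per_frame,
        raw_frames=out if keep_raw else None,
        params={"kind": "monet2", "directions_deg": directions.tolist(), "seed": p.seed},
    )


def generate_trippy(
    params: TrippyParams = TrippyParams(),
    geometry: MonitorGeometry = MonitorGeometry(),
) -> StimulusMovie:
    """Render one Trippy block and its unwrapped phase movie.

    Phase keyframes (uniform noise on a coarse control grid) are placed
    every round(fps / (2 * bandwidth)) frames and interpolated with the
    raised-cosine (Hann) kernel, which is a partition of unity, so
    keyframes are reproduced exactly; a linear drift of
    ``drift_rad_per_s`` is added; the control grid is upsampled to the
    frame with a normalized Gaussian kernel. Frames are
    1/2 + 1/2 cos(phase) exactly.
    """
    p, g = params, geometry
    n_frames = int(round(p.duration_s * p.output_fps))
    interval = max(1, int(round(p.output_fps / (2 * p.phase_bandwidth_hz))))
    n_keys = int(np.ceil(n_frames / interval)) + 2
    rng = np.random.default_rng(p.seed)
    keys = rng.uniform(-p.noise_amplitude_rad, p.noise_amplitude_rad, size=(n_keys, p.grid_ny, p.grid_nx))

    # temporal upsampling with the Hann partition-of-unity kernel:
    # frame t between keyframes j, j+1 gets cos^2-weighted blend
    tt = np.arange(n_frames) / interval
    j = np.minimum(tt.astype(int), n_keys - 2)
    frac = tt - j
    w = 0.5 + 0.5 * np.cos(np.pi * frac)  # 1 at keyframe j, 0 at j+1
    coarse = w[:, None, None] * keys[j] + (1 - w)[:, None, None] * keys[j + 1]

    t_s = np.arange(n_frames) / p.output_fps
    coarse = coarse + (p.drift_rad_per_s * t_s)[:, None, None]

    # spatial upsampling: normalized Gaussian convolution of control impulses
    deg_per_px = g.deg_per_px(p.frame_width)
    sigma_px = p.spatial_sigma_deg / deg_per_px
    H, W = p.frame_height, p.frame_width
    ys = np.linspace(0, H - 1, p.grid_ny).round().astype(int)
    xs = np.linspace(0, W - 1, p.grid_nx).round().astype(int)
    impulse = np.zeros((H, W))
    impulse[np.ix_(ys, xs)] = 1.0
    norm = ndimage.gaussian_filter(impulse, sigma_px, mode="nearest")
    norm[norm <= 0] = 1.0
    phase = np.empty((n_frames, H, W))
    for t in range(n_frames):
        sparse = np.zeros((H, W))
        sparse[np.ix_(ys, xs)] = coarse[t]
        phase[t] = ndimage.gaussian_filter(sparse, sigma_px, mode="nearest") / norm
    frames = 0.5 + 0.5 * np.cos(phase)
    return StimulusMovie(
        frames=frames,
        fps=p.output_fps,
        deg_per_px=deg_per_px,
        phase=phase,
        params={"kind": "trippy", "seed": p.seed, "keyframe_interval": interval},
    )
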