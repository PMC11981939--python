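"""Fiducial-free co-registration of EM and 2P volumes from vasculature.

Vessels visible in both modalities are enhanced with a Hessian-based
ridge (Meijering neurite) filter, reduced to skeletons and re-grown
into tubes of constant radius (so vessel calibre differences between
modalities do not bias the similarity), and then aligned with a
multi-scale cubic B-spline free-form deformation optimized by L-BFGS
on a correlation similarity with sparse random sampling. The result is
a dense displacement field (and its fixed-point inverse) that
transports EM nucleus centroids and 2P unit centroids between spaces;
the transported centroids feed :mod:`coregmatch.matching` unchanged.

Volumes are index-ordered (z, y, x); registration requires isotropic
1-um voxels (resample first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage import feature, filters, morphology

from .errors import VolumeError

__all__ = [
    "VoxelVolume",
    "DisplacementField",
    "ridge_filter",
    "normalize_vessels",
    "initial_offset",
    "deformable_register",
    "apply_field",
    "SimpleITKBackend",
]


@dataclass
class VoxelVolume:
    """A 3D scalar grid with voxel size (um per axis, (z, y, x)) and origin (um)."""

    values: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise VolumeError("volume must be 3D")
        if not np.isfinite(self.values).all():
            raise VolumeError("volume contains non-finite values")

    @property
    def is_isotropic(self) -> bool:
        v = np.asarray(self.voxel_size, float)
        return bool(np.allclose(v, v[0], rtol=1e-3))

    def require_isotropic(self, target_um: Optional[float] = None) -> None:
        if not self.is_isotropic:
            raise VolumeError(
                f"operation requires isotropic voxels; got {self.voxel_size}. "
                "Resample with resample_isotropic() first."
            )
        if target_um is not None and not np.isclose(self.voxel_size[0], target_um, rtol=1e-3):
            raise VolumeError(f"operation requires {target_um}-um voxels; got {self.voxel_size}")


def resample_isotropic(vol: VoxelVolume, target_um: float = 1.0, order: int = 1) -> VoxelVolume:
    """Resample to isotropic voxels of ``target_um`` by spline interpolation."""
    zoom = np.asarray(vol.voxel_size, float) / target_um
    vals = ndimage.zoom(vol.values.astype(float), zoom, order=order)
    return VoxelVolume(vals, (target_um,) * 3, vol.origin)


def ridge_filter(vol: VoxelVolume, scales_um: Sequence[float] = (1.0, 2.0, 4.0)) -> VoxelVolume:
    """Multi-scale tubularity response (Meijering neurite filter), max over scales.

    Uses the eigenvalues/eigenvectors of the Hessian at each scale to
    enhance bright tubular structures; the response is nonnegative.
    """
    vol.require_isotropic()
    sigmas_vox = [s / vol.voxel_size[0] for s in scales_um]
    resp = filters.meijering(
        vol.values.astype(float), sigmas=sigmas_vox, black_ridges=False, mode="reflect"
    )
    resp = np.clip(resp, 0, None)
    return VoxelVolume(resp, vol.voxel_size, vol.origin)


def normalize_vessels(
    vol: VoxelVolume,
    threshold: float,
    min_component_voxels: int = 50,
    tube_sigma_um: float = 2.0,
    rounds: int = 2,
) -> VoxelVolume:
    """Reduce vessels to constant-radius tubes: binarize -> skeletonize -> drop
    small components -> Gaussian tube growth, repeated ``rounds`` times.

    The output tube radius depends only on ``tube_sigma_um``, not on the
    input vessel calibre, which removes modality-specific thickness and
    z-smearing differences before registration. Later rounds (which fix
    false splits in thick vessels) re-binarize at half the current peak.
    """
    vol.require_isotropic()
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    vals = vol.values.astype(float)
    sigma_vox = tube_sigma_um / vol.voxel_size[0]
    thr = threshold
    for r in range(rounds):
        mask = vals > thr
        if not mask.any():
            raise VolumeError(f"threshold {thr} yields an empty vessel mask (round {r})")
        skel = morphology.skeletonize(mask)
        # drop connected components with fewer than min_component_voxels voxels
        skel = morphology.remove_small_objects(
            skel, max_size=min_component_voxels - 1, connectivity=3
        )
        if not skel.any():
            raise VolumeError("no skeleton components survive the size filter")
        vals = ndimage.gaussian_filter(skel.astype(float), sigma_vox)
        thr = 0.5 * vals.max()
    return VoxelVolume(vals, vol.voxel_size, vol.origin)


def initial_offset(
    fixed: VoxelVolume,
    moving: VoxelVolume,
    template_size: int = 32,
    center: Optional[tuple] = None,
) -> np.ndarray:
    """Translation initialization by normalized cross-correlation template matching.

    A cubic subvolume of the moving volume (side ``template_size``,
    around ``center`` or the volume centre) is matched across the fixed
    volume. Returns the shift ``s`` (voxels, (z, y, x)) such that
    ``moving[x] ~= fixed[x - s]``, i.e. moving content sits at fixed
    position ``x - s``.
    """
    fixed.require_isotropic()
    moving.require_isotropic()
    shape = np.asarray(moving.values.shape)
    c = np.asarray(center if center is not None else shape // 2, int)
    half = template_size // 2
    lo = np.clip(c - half, 0, shape - 1)
    hi = np.minimum(lo + template_size, shape)
    template = moving.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(float)
    if template.std() == 0:
        raise VolumeError("flat template (zero variance); choose another subvolume")
    ncc = feature.match_template(fixed.values.astype(float), template, pad_input=True)
    peak = np.unravel_index(np.argmax(ncc), ncc.shape)
    # with pad_input=True the peak sits at the template centre position in
    # fixed; match_template centres even-sized templates at shape // 2
    template_center = lo + np.asarray(template.shape) // 2
    return np.asarray(template_center, float) - np.asarray(peak, float)


@dataclass
class DisplacementField:
    """Dense forward/inverse displacement grids (um) on the fixed-volume lattice.

    ``forward[z, y, x]`` is the displacement u(x) with
    moving_coord = fixed_coord + u(fixed_coord) (the resampling map);
    ``inverse`` lives on the moving lattice and maps the other way.
    """

    forward: np.ndarray  # (Z, Y, X, 3), (z, y, x) components
    inverse: np.ndarray
    spacing_um: float = 1.0
    final_similarity: Optional[float] = None

    def __post_init__(self):
        for f in (self.forward, self.inverse):
            if f.ndim != 4 or f.shape[-1] != 3:
                raise ValueError("displacement grids must be (Z, Y, X, 3)")


def _interp_field(grid: np.ndarray, pts: np.ndarray) -> np.ndarray:
    coords = (pts / 1.0).T  # already in voxel units (1-um isotropic)
    return np.stack(
        [ndimage.map_coordinates(grid[..., k], coords, order=1, mode="nearest") for k in range(3)],
        axis=-1,
    )


def apply_field(
    field: DisplacementField,
    points: Optional[np.ndarray] = None,
    volume: Optional[VoxelVolume] = None,
    direction: str = "moving_to_fixed",
):
    """Transport points, or resample a moving volume into the fixed frame.

    For points: trilinear interpolation of the requested grid at the
    query locations, added to them. ``moving_to_fixed`` (default, uses
    the inverse grid) carries moving-space centroids into fixed space;
    ``fixed_to_moving`` uses the forward grid. Out-of-domain points are
    clamped to the nearest grid value and flagged with a warning.
    """
    if (points is None) == (volume is None):
        raise ValueError("pass exactly one of points or volume")
    if volume is not None:
        vol = volume.values.astype(float)
        shape = field.forward.shape[:3]
        zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        coords = np.stack([zz, yy, xx], axis=-1) + field.forward
        vals = ndimage.map_coordinates(
            vol, [coords[..., 0], coords[..., 1], coords[..., 2]], order=1, mode="constant"
        )
        return VoxelVolume(vals, (field.spacing_um,) * 3)
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    grid = {"moving_to_fixed": field.inverse, "fixed_to_moving": field.forward}.get(direction)
    if grid is None:
        raise ValueError("direction must be 'moving_to_fixed' or 'fixed_to_moving'")
    shape = np.asarray(grid.shape[:3], float)
    out_of_domain = ((pts < 0) | (pts > shape - 1)).any(axis=1)
    if out_of_domain.any():
        warnings.warn(f"{int(out_of_domain.sum())} point(s) outside the field domain (clamped)")
    return pts + _interp_field(grid, pts)


def _invert_field(forward: np.ndarray, tol_um: float = 0.1, max_iter: int = 50) -> np.ndarray:
    """Fixed-point inversion on the grid: find v with v(y) = -u(y + v(y))."""
    shape = forward.shape[:3]
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    base = np.stack([zz, yy, xx], axis=-1)
    v = -forward.copy()
    for _ in range(max_iter):
        q = (base + v).reshape(-1, 3)
        u_at = _interp_field(forward, q).reshape(forward.shape)
        new = -u_at
        if np.max(np.linalg.norm(new - v, axis=-1)) < tol_um:
            v = new
            break
        v = new
    return v


class RegistrationBackend(Protocol):
    """Anything that can compute a forward displacement grid between two tube volumes."""

    def register(
        self, fixed: np.ndarray, moving: np.ndarray, initial_shift: np.ndarray, seed: int
    ) -> tuple[np.ndarray, float]:
        ...


class SimpleITKBackend:
    """Multi-scale cubic B-spline free-form deformation via SimpleITK.

    Coarse-to-fine control-point spacings with matched smoothing, L-BFGS
    optimization of a (negative) correlation similarity, random sampling
    of a small fraction of voxels per iteration.
    """

    def __init__(
        self,
        grid_spacing_um: Sequence[float] = (64.0, 32.0, 16.0),
        smoothing_um: Sequence[float] = (8.0, 4.0, 1.0),
        max_iter: int = 600,
        sampling_fraction: float = 0.01,
    ):
        if len(grid_spacing_um) != len(smoothing_um):
            raise ValueError("schedules must have equal length")
        self.grid_spacing_um = list(grid_spacing_um)
        self.smoothing_um = list(smoothing_um)
        self.max_iter = max_iter
        self.sampling_fraction = sampling_fraction

    def register(self, fixed, moving, initial_shift, seed):
        import SimpleITK as sitk

        f_img = sitk.GetImageFromArray(fixed.astype(np.float32))
        m_img = sitk.GetImageFromArray(moving.astype(np.float32))
        levels = len(self.grid_spacing_um)
        shrink = [max(1, 2 ** (levels - 1 - i)) for i in range(levels)]

        # initial translation: ITK physical coords are (x, y, z); ours (z, y, x)
        init = sitk.TranslationTransform(3, tuple(float(s) for s in initial_shift[::-1]))

        size_um = np.asarray(fixed.shape[::-1], float)  # (x, y, z)
        coarsest = self.grid_spacing_um[0]
        mesh = [max(1, int(round(s / coarsest))) for s in size_um]
        bspline = sitk.BSplineTransformInitializer(f_img, mesh, order=3)
        # per-level control-grid refinement relative to the coarsest spacing
        scale_factors = [max(1, int(round(coarsest / g))) for g in self.grid_spacing_um]

        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsCorrelation()
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(self.sampling_fraction, int(seed) % (2**31 - 1) or 1)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsLBFGS2(numberOfIterations=self.max_iter)
        reg.SetMovingInitialTransform(init)
        reg.SetInitialTransformAsBSpline(bspline, inPlace=True, scaleFactors=scale_factors)
        reg.SetShrinkFactorsPerLevel(shrink)
        reg.SetSmoothingSigmasPerLevel([s for s in self.smoothing_um])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
        final_bspline = reg.Execute(f_img, m_img)
        similarity = -reg.GetMetricValue()  # correlation metric is negated internally

        # resampling map fixed -> moving is init(bspline(x)); SimpleITK applies
        # composite members back-to-front, so the B-spline is added last
        total = sitk.CompositeTransform(3)
        total.AddTransform(init)
        total.AddTransform(final_bspline)
        tdf = sitk.TransformToDisplacementField(
            total,
            sitk.sitkVectorFloat64,
            f_img.GetSize(),
            f_img.GetOrigin(),
            f_img.GetSpacing(),
            f_img.GetDirection(),
        )
        fwd = sitk.GetArrayFromImage(tdf)[..., ::-1]  # vector (x,y,z) -> (z,y,x)
        return np.ascontiguousarray(fwd), float(similarity)


def deformable_register(
    fixed: VoxelVolume,
    moving: VoxelVolume,
    grid_schedule_um: Sequence[float] = (64.0, 32.0, 16.0),
    smoothing_schedule_um: Sequence[float] = (8.0, 4.0, 1.0),
    max_iter: int = 600,
    sampling_fraction: float = 0.01,
    seed: int = 0,
    initial_shift: Optional[np.ndarray] = None,
    backend: Optional[RegistrationBackend] = None,
) -> DisplacementField:
    """Multi-scale deformable registration of tube-normalized volumes.

    Both inputs must be isotropic 1-um volumes. The translation
    initialization (:func:`initial_offset`) is computed here when not
    supplied. Returns forward and inverse displacement fields on the
    fixed/moving lattices.
    """
    fixed.require_isotropic(1.0)
    moving.require_isotropic(1.0)
    if initial_shift is None:
        try:
            initial_shift = initial_offset(fixed, moving)
        except VolumeError:
            initial_shift = np.zeros(3)
    if backend is None:
        backend = SimpleITKBackend(grid_schedule_um, smoothing_schedule_um, max_iter, sampling_fraction)
    fwd, similarity = backend.register(
        fixed.values, moving.values, np.asarray(initial_shift, float), seed
    )
    inv = _invert_field(fwd)
    return DisplacementField(fwd, inv, spacing_um=1.0, final_similarity=similarity)
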