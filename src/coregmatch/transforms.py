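"""Staged fiducial-based 3D co-registration between an EM volume and a 2P structural stack.

The cross-modal transform is fitted from manually matched landmarks
("fiducials": somata and blood-vessel branch points annotated in both
volumes) as an ordered stack of stages, each fitted between the
previous stage's output and the 2P targets:

1. one global second-order polynomial (gross scale/rotation plus a
   single nonlinear term),
2. two z-binned second-order polynomial stages (5 then 21 bins) that
   remove systematic residual trends along the EM sectioning axis,
3. four thin-plate-spline stages on successively finer even n x n x n
   control-point lattices (n = 3, 5, 10, 12),
4. one exact thin-plate spline with every fiducial as a control point,
   which interpolates the remaining residuals to ~machine precision.

All coordinates are micrometres. The canonical fit direction is
EM -> 2P; the other direction is obtained numerically with
:func:`invert_transform`. Generalization error is estimated with
leave-one-out refits (:func:`loo_residuals`) because the in-sample
residual of the final exact stage is ~0 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    BinningError,
    CoregError,
    DegenerateGeometryError,
    ExtrapolationWarning,
    InsufficientDataError,
    InversionError,
)

__all__ = [
    "FiducialPair",
    "FiducialSet",
    "PolynomialStage",
    "ZBinnedPolynomialStage",
    "GridTPSStage",
    "ExactTPSStage",
    "TransformStack",
    "ResidualReport",
    "CANONICAL_SCHEDULE",
    "fit_polynomial_stage",
    "fit_z_binned_stage",
    "fit_grid_tps_stage",
    "fit_exact_tps_stage",
    "fit_transform_stack",
    "apply_transform",
    "invert_transform",
    "loo_residuals",
    "residual_report",
]

# number of 3D monomials of total degree <= 2
_N_MONOMIALS = 10


class FiducialKind(str, Enum):
    soma = "soma"
    vessel = "vessel"


@dataclass(frozen=True)
class FiducialPair:
    """One landmark annotated in both spaces (coordinates in micrometres)."""

    id: str
    kind: str
    source_xyz: np.ndarray  # EM space, after voxel -> um scaling
    target_xyz: np.ndarray  # 2P structural-stack space

    def __post_init__(self):
        src = np.asarray(self.source_xyz, dtype=float)
        dst = np.asarray(self.target_xyz, dtype=float)
        if src.shape != (3,) or dst.shape != (3,):
            raise ValueError("fiducial coordinates must be 3-vectors")
        if not (np.isfinite(src).all() and np.isfinite(dst).all()):
            raise ValueError(f"fiducial {self.id!r} has non-finite coordinates")
        FiducialKind(self.kind)  # validates
        object.__setattr__(self, "source_xyz", src)
        object.__setattr__(self, "target_xyz", dst)


class FiducialSet:
    """An ordered collection of fiducial pairs, the substrate for transform fitting."""

    def __init__(self, pairs: Sequence[FiducialPair], min_source_spacing: float = 1e-6):
        pairs = list(pairs)
        ids = [p.id for p in pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("fiducial ids must be unique within a set")
        self.pairs = pairs
        if len(pairs) >= 2 and min_source_spacing > 0:
            tree = cKDTree(self.source)
            d, _ = tree.query(self.source, k=2)
            if np.min(d[:, 1]) < min_source_spacing:
                raise DegenerateGeometryError(
                    f"duplicate source points closer than {min_source_spacing} um"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pairs]

    @property
    def kinds(self) -> list[str]:
        return [p.kind for p in self.pairs]

    @property
    def source(self) -> np.ndarray:
        return np.array([p.source_xyz for p in self.pairs], dtype=float).reshape(-1, 3)

    @property
    def target(self) -> np.ndarray:
        return np.array([p.target_xyz for p in self.pairs], dtype=float).reshape(-1, 3)

    def source_bbox(self) -> tuple[np.ndarray, np.ndarray]:
        s = self.source
        return s.min(axis=0), s.max(axis=0)

    def target_bbox(self) -> tuple[np.ndarray, np.ndarray]:
        t = self.target
        return t.min(axis=0), t.max(axis=0)

    def subset(self, indices) -> "FiducialSet":
        return FiducialSet([self.pairs[i] for i in indices], min_source_spacing=0.0)

    @classmethod
    def from_arrays(cls, source, target, kinds=None, ids=None) -> "FiducialSet":
        source = np.asarray(source, dtype=float)
        target = np.asarray(target, dtype=float)
        n = len(source)
        if kinds is None:
            kinds = ["soma"] * n
        if ids is None:
            ids = [f"f{i}" for i in range(n)]
        return cls(
            [FiducialPair(str(i), k, s, t) for i, k, s, t in zip(ids, kinds, source, target)]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FiducialSet":
        cols = ["id", "kind", "src_x_um", "src_y_um", "src_z_um", "dst_x_um", "dst_y_um", "dst_z_um"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"fiducial table missing columns: {missing}")
        src = df[["src_x_um", "src_y_um", "src_z_um"]].to_numpy(float)
        dst = df[["dst_x_um", "dst_y_um", "dst_z_um"]].to_numpy(float)
        return cls.from_arrays(src, dst, kinds=list(df["kind"]), ids=list(df["id"].astype(str)))

    def to_dataframe(self) -> pd.DataFrame:
        s, t = self.source, self.target
        return pd.DataFrame(
            {
                "id": self.ids,
                "kind": self.kinds,
                "src_x_um": s[:, 0],
                "src_y_um": s[:, 1],
                "src_z_um": s[:, 2],
                "dst_x_um": t[:, 0],
                "dst_y_um": t[:, 1],
                "dst_z_um": t[:, 2],
            }
        )


# ---------------------------------------------------------------------------
# polynomial stages
# ---------------------------------------------------------------------------


def _monomials(x: np.ndarray) -> np.ndarray:
    """Second-order 3D monomial design matrix: 1, x, y, z, x2, y2, z2, xy, xz, yz."""
    x = np.asarray(x, dtype=float).reshape(-1, 3)
    c0, c1, c2 = x[:, 0], x[:, 1], x[:, 2]
    return np.column_stack(
        [np.ones(len(x)), c0, c1, c2, c0 * c0, c1 * c1, c2 * c2, c0 * c1, c0 * c2, c1 * c2]
    )


@dataclass
class PolynomialStage:
    """Global degree-2 polynomial map R^3 -> R^3, fitted on normalized coordinates."""

    coefficients: np.ndarray  # (10, 3) acting on normalized monomials
    center: np.ndarray  # (3,)
    scale: np.ndarray  # (3,)
    degree: int = 2

    name = "polynomial"

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        return _monomials((pts - self.center) / self.scale) @ self.coefficients

    def affine_part(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (A, b) with apply(x) ~= A x + b near the data centroid."""
        lin = self.coefficients[1:4].T / self.scale  # d out / d x
        const = self.apply(self.center.reshape(1, 3))[0]
        b = const - lin @ self.center
        return lin, b

    def to_dict(self) -> dict:
        return {
            "type": self.name,
            "coefficients": self.coefficients.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "degree": self.degree,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialStage":
        return cls(
            np.asarray(d["coefficients"], float),
            np.asarray(d["center"], float),
            np.asarray(d["scale"], float),
            int(d.get("degree", 2)),
        )


def fit_polynomial_stage(source, target, degree: int = 2) -> PolynomialStage:
    """Least-squares degree-2 polynomial from ``source`` to ``target`` points.

    Coordinates are centred and scaled internally so the fit is
    translation-equivariant to numerical precision.
    """
    if degree != 2:
        raise ValueError("only degree-2 polynomial stages are supported")
    source = np.asarray(source, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    n = len(source)
    if n < _N_MONOMIALS:
        raise InsufficientDataError(
            f"need >= {_N_MONOMIALS} pairs for a degree-2 polynomial, got {n}"
        )
    center = source.mean(axis=0)
    scale = source.std(axis=0)
    scale[scale <= 0] = 1.0
    design = _monomials((source - center) / scale)
    if np.linalg.matrix_rank(design) < _N_MONOMIALS:
        raise DegenerateGeometryError(
            "source points are degenerate (coplanar/collinear) for a degree-2 fit"
        )
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    return PolynomialStage(coef, center, scale)


@dataclass
class ZBinnedPolynomialStage:
    """Per-z-bin degree-2 polynomials, linearly blended near bin edges.

    Corrects residual trends aligned with the EM sectioning (z) axis.
    Bins are equal-width in the stage's input z; a bin with too few
    members recruits pairs from a symmetrically widened window.
    """

    bin_edges: np.ndarray  # (n_bins + 1,)
    per_bin: list[PolynomialStage]
    blend_halfwidth: float = 5.0

    name = "z_binned"

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        z = pts[:, 2]
        edges = self.bin_edges
        nbins = len(self.per_bin)
        idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, nbins - 1)
        out = np.empty_like(pts)
        for b in range(nbins):
            m = idx == b
            if m.any():
                out[m] = self.per_bin[b].apply(pts[m])
        h = self.blend_halfwidth
        if h > 0:
            for b in range(nbins - 1):
                e = edges[b + 1]
                m = np.abs(z - e) < h
                if not m.any():
                    continue
                w = ((z[m] - (e - h)) / (2 * h))[:, None]  # 0 at e-h, 1 at e+h
                out[m] = (1 - w) * self.per_bin[b].apply(pts[m]) + w * self.per_bin[b + 1].apply(
                    pts[m]
                )
        return out

    def to_dict(self) -> dict:
        return {
            "type": self.name,
            "bin_edges": self.bin_edges.tolist(),
            "per_bin": [s.to_dict() for s in self.per_bin],
            "blend_halfwidth": self.blend_halfwidth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZBinnedPolynomialStage":
        return cls(
            np.asarray(d["bin_edges"], float),
            [PolynomialStage.from_dict(s) for s in d["per_bin"]],
            float(d["blend_halfwidth"]),
        )


def fit_z_binned_stage(
    source,
    target,
    n_bins: int,
    blend_halfwidth: float = 5.0,
    min_pairs_per_bin: int = 10,
) -> ZBinnedPolynomialStage:
    """Fit one degree-2 polynomial per equal-width z bin of the source points."""
    source = np.asarray(source, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(source) < min_pairs_per_bin:
        raise BinningError(
            f"only {len(source)} pairs in total; cannot populate any bin with {min_pairs_per_bin}"
        )
    z = source[:, 2]
    zmin, zmax = z.min(), z.max()
    if zmax <= zmin:
        zmax = zmin + 1.0
    edges = np.linspace(zmin, zmax, n_bins + 1)
    width = edges[1] - edges[0]
    stages = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        # half-open bins, last bin closed
        member = (z >= lo) & (z < hi) if b < n_bins - 1 else (z >= lo) & (z <= hi)
        # fallback widening: symmetric window growth until enough members
        while member.sum() < min_pairs_per_bin and (lo > zmin - width or hi < zmax + width):
            lo -= 0.1 * width
            hi += 0.1 * width
            member = (z >= lo) & (z <= hi)
        if member.sum() < min_pairs_per_bin:
            raise BinningError(f"z bin {b} empty after widening")
        stages.append(fit_polynomial_stage(source[member], target[member]))
    return ZBinnedPolynomialStage(edges, stages, blend_halfwidth)


# ---------------------------------------------------------------------------
# thin-plate-spline stages
# ---------------------------------------------------------------------------
# Kernel: first-order polyharmonic phi(r) = r, the standard 3D thin-plate
# choice, plus an affine term. The interpolation system is
#   [K + lam*I, P; P^T, 0] [w; a] = [values; 0].


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    return r


def _tps_system(nodes: np.ndarray) -> np.ndarray:
    m = len(nodes)
    K = _tps_kernel(np.linalg.norm(nodes[:, None, :] - nodes[None, :, :], axis=-1))
    P = np.column_stack([np.ones(m), nodes])
    A = np.zeros((m + 4, m + 4))
    A[:m, :m] = K
    A[:m, m:] = P
    A[m:, :m] = P.T
    return A

def _tps_basis(pts: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    K = _tps_kernel(np.linalg.norm(pts[:, None, :] - nodes[None, :, :], axis=-1))
    P = np.column_stack([np.ones(len(pts)), pts])
    return np.hstack([K, P])


@dataclass
class GridTPSStage:
    """TPS displacement field interpolating solved displacements of an even n^3 lattice.

    Node displacements are the free parameters; they are chosen by
    penalized least squares so that the interpolated field moves each
    fiducial onto its target as closely as the lattice resolution allows.
    """

    n: int
    node_rest: np.ndarray  # (m, 3) lattice coordinates
    node_displacement: np.ndarray  # (m, 3)
    weights: np.ndarray  # (m + 4, 3) TPS weights reproducing node_displacement
    regularization_weight: float

    name = "grid_tps"

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        return pts + _tps_basis(pts, self.node_rest) @ self.weights

    @property
    def mean_motion(self) -> float:
        return float(np.mean(np.linalg.norm(self.node_displacement, axis=1)))

    def to_dict(self) -> dict:
        return {
            "type": self.name,
            "n": self.n,
            "node_rest": self.node_rest.tolist(),
            "node_displacement": self.node_displacement.tolist(),
            "weights": self.weights.tolist(),
            "regularization_weight": self.regularization_weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridTPSStage":
        return cls(
            int(d["n"]),
            np.asarray(d["node_rest"], float),
            np.asarray(d["node_displacement"], float),
            np.asarray(d["weights"], float),
            float(d["regularization_weight"]),
        )


def _lattice(bbox_lo: np.ndarray, bbox_hi: np.ndarray, n: int) -> np.ndarray:
    axes = [np.linspace(bbox_lo[k], bbox_hi[k], n) for k in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([a.ravel() for a in g])


def fit_grid_tps_stage(
    source,
    target,
    n: int,
    regularization_weight: float = 1e-6,
    bbox: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> GridTPSStage:
    """Solve lattice-node displacements minimizing fiducial residuals plus an L2 penalty."""
    source = np.asarray(source, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if n < 2:
        raise ValueError("lattice resolution n must be >= 2")
    if len(source) == 0:
        raise InsufficientDataError("no pairs to fit")
    if bbox is None:
        lo, hi = source.min(axis=0), source.max(axis=0)
    else:
        lo, hi = np.asarray(bbox[0], float), np.asarray(bbox[1], float)
    span = np.maximum(hi - lo, 1e-6)
    nodes = _lattice(lo - 0.0 * span, hi + 0.0 * span, n)
    m = len(nodes)
    A = _tps_system(nodes)
    rhs = np.vstack([np.eye(m), np.zeros((4, m))])
    try:
        Ainv_m = np.linalg.solve(A, rhs)  # (m+4, m): columns give weights per unit node displacement
    except np.linalg.LinAlgError as e:  # pragma: no cover - lattice nodes are never degenerate
        raise DegenerateGeometryError("singular TPS lattice system") from e
    L = _tps_basis(source, nodes) @ Ainv_m  # (N, m)
    resid = target - source
    if regularization_weight > 0:
        G = L.T @ L
        lam = regularization_weight * np.trace(G) / m
        try:
            D = np.linalg.solve(G + lam * np.eye(m), L.T @ resid)
        except np.linalg.LinAlgError as e:
            raise DegenerateGeometryError(
                "singular grid-TPS system; increase regularization_weight"
            ) from e
    else:
        D, *_ = np.linalg.lstsq(L, resid, rcond=None)
    W = Ainv_m @ D
    return GridTPSStage(n, nodes, D, W, regularization_weight)


@dataclass
class ExactTPSStage:
    """Exact TPS interpolation with every fiducial as a control point."""

    control_points: np.ndarray  # (m, 3)
    displacements: np.ndarray  # (m, 3) target - control
    weights: np.ndarray  # (m + 4, 3)

    name = "exact_tps"

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        return pts + _tps_basis(pts, self.control_points) @ self.weights

    @property
    def affine_part(self) -> np.ndarray:
        """3x4 coefficients [b | A] of the affine term of the displacement field."""
        return self.weights[len(self.control_points):].T

    @property
    def mean_motion(self) -> float:
        return float(np.mean(np.linalg.norm(self.displacements, axis=1)))

    def to_dict(self) -> dict:
        return {
            "type": self.name,
            "control_points": self.control_points.tolist(),
            "displacements": self.displacements.tolist(),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExactTPSStage":
        return cls(
            np.asarray(d["control_points"], float),
            np.asarray(d["displacements"], float),
            np.asarray(d["weights"], float),
        )


def fit_exact_tps_stage(source, target, min_spacing: float = 1e-9) -> ExactTPSStage:
    """Interpolating TPS: reproduces every target at its control point."""
    source = np.asarray(source, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if len(source) < 4:
        raise InsufficientDataError("exact TPS needs >= 4 non-coplanar control points")
    tree = cKDTree(source)
    d, _ = tree.query(source, k=2)
    if np.min(d[:, 1]) < min_spacing:
        raise DegenerateGeometryError("duplicate control points: exact interpolation impossible")
    A = _tps_system(source)
    resid = target - source
    rhs = np.vstack([resid, np.zeros((4, 3))])
    try:
        W = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as e:
        raise DegenerateGeometryError("singular exact-TPS system") from e
    return ExactTPSStage(source, resid, W)


# ---------------------------------------------------------------------------
# the stack
# ---------------------------------------------------------------------------

#: The 8-stage schedule used for the production transform: one global
#: polynomial, z-binned polynomials with 5 and 21 bins, grid TPS with
#: n = 3, 5, 10, 12, and a final exact TPS.
CANONICAL_SCHEDULE: list[dict] = [
    {"type": "polynomial"},
    {"type": "z_binned", "n_bins": 5},
    {"type": "z_binned", "n_bins": 21},
    {"type": "grid_tps", "n": 3},
    {"type": "grid_tps", "n": 5},
    {"type": "grid_tps", "n": 10},
    {"type": "grid_tps", "n": 12},
    {"type": "exact_tps"},
]

_STAGE_TYPES = {
    "polynomial": PolynomialStage,
    "z_binned": ZBinnedPolynomialStage,
    "grid_tps": GridTPSStage,
    "exact_tps": ExactTPSStage,
}


@dataclass
class StageDiagnostics:
    stage: int
    type: str
    mean_residual_um: float
    mean_motion_um: float


@dataclass
class TransformStack:
    """Ordered composition of fitted stages with per-stage diagnostics."""

    stages: list
    diagnostics: list[StageDiagnostics]
    direction: str = "em_to_2p"
    source_bbox: Optional[tuple[np.ndarray, np.ndarray]] = None

    def apply(self, pts, up_to_stage: Optional[int] = None, warn_extrapolation: bool = True):
        return apply_transform(self, pts, up_to_stage, warn_extrapolation)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "direction": self.direction,
            "source_bbox": None
            if self.source_bbox is None
            else [self.source_bbox[0].tolist(), self.source_bbox[1].tolist()],
            "stages": [s.to_dict() for s in self.stages],
            "diagnostics": [
                {
                    "stage": d.stage,
                    "type": d.type,
                    "mean_residual_um": d.mean_residual_um,
                    "mean_motion_um": d.mean_motion_um,
                }
                for d in self.diagnostics
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformStack":
        if d.get("schema_version") != 1:
            raise ValueError(f"unsupported transform-stack schema: {d.get('schema_version')}")
        stages = [_STAGE_TYPES[s["type"]].from_dict(s) for s in d["stages"]]
        diags = [
            StageDiagnostics(x["stage"], x["type"], x["mean_residual_um"], x["mean_motion_um"])
            for x in d.get("diagnostics", [])
        ]
        bbox = d.get("source_bbox")
        if bbox is not None:
            bbox = (np.asarray(bbox[0], float), np.asarray(bbox[1], float))
        return cls(stages, diags, d.get("direction", "em_to_2p"), bbox)


def _fit_one_stage(spec: dict, cur: np.ndarray, target: np.ndarray, bbox):
    kind = spec["type"]
    if kind == "polynomial":
        return fit_polynomial_stage(cur, target)
    if kind == "z_binned":
        return fit_z_binned_stage(
            cur,
            target,
            n_bins=int(spec["n_bins"]),
            blend_halfwidth=float(spec.get("blend_halfwidth", 5.0)),
            min_pairs_per_bin=int(spec.get("min_pairs_per_bin", 10)),
        )
    if kind == "grid_tps":
        return fit_grid_tps_stage(
            cur,
            target,
            n=int(spec["n"]),
            regularization_weight=float(spec.get("regularization_weight", 1e-6)),
        )
    if kind == "exact_tps":
        return fit_exact_tps_stage(cur, target)
    raise ValueError(f"unknown stage type {kind!r}")


def fit_transform_stack(
    fiducials: FiducialSet,
    schedule: Optional[Sequence[dict]] = None,
    min_fiducials: int = 20,
    direction: str = "em_to_2p",
) -> TransformStack:
    """Fit the staged transform; stage k is fitted between the stage-(k-1)
    output of the source points and the targets.

    Diagnostics record, per stage, the mean residual after the stage and
    the mean control-point motion introduced by the stage.
    """
    if len(fiducials) < min_fiducials:
        raise InsufficientDataError(
            f"need >= {min_fiducials} fiducials for stack fitting, got {len(fiducials)}"
        )
    schedule = list(CANONICAL_SCHEDULE if schedule is None else schedule)
    src, dst = fiducials.source, fiducials.target
    cur = src
    stages, diags = [], []
    for k, spec in enumerate(schedule):
        try:
            stage = _fit_one_stage(spec, cur, dst, None)
        except CoregError as e:
            raise type(e)(f"stage {k} ({spec['type']}): {e}") from e
        new = stage.apply(cur)
        motion = float(np.mean(np.linalg.norm(new - cur, axis=1)))
        resid = float(np.mean(np.linalg.norm(new - dst, axis=1)))
        stages.append(stage)
        diags.append(StageDiagnostics(k, spec["type"], resid, motion))
        cur = new
    return TransformStack(stages, diags, direction, fiducials.source_bbox())


def apply_transform(
    stack: TransformStack,
    points,
    up_to_stage: Optional[int] = None,
    warn_extrapolation: bool = True,
) -> np.ndarray:
    """Compose the fitted stages; ``up_to_stage`` truncates the composition
    to the first ``up_to_stage`` stages (for per-stage diagnostics)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if warn_extrapolation and stack.source_bbox is not None:
        lo, hi = stack.source_bbox
        outside = ((pts < lo) | (pts > hi)).any(axis=1)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} point(s) outside the fitted bounding box; "
                "the transform extrapolates there and is less reliable",
                ExtrapolationWarning,
                stacklevel=2,
            )
    stages = stack.stages if up_to_stage is None else stack.stages[:up_to_stage]
    for stage in stages:
        pts = stage.apply(pts)
    return pts


def invert_transform(
    stack: TransformStack,
    points,
    tol: float = 1e-3,
    max_iter: int = 200,
    damping: float = 0.8,
) -> np.ndarray:
    """Map target-space points back to source space by damped fixed-point iteration.

    The iteration is preconditioned with the inverse of the global
    polynomial's affine part, so it converges for the large scale/rotation
    between the two spaces.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    first = stack.stages[0] if stack.stages else None
    if isinstance(first, PolynomialStage):
        A, b = first.affine_part()
        Ainv = np.linalg.inv(A)
        q = (p - b) @ Ainv.T
    else:
        Ainv = np.eye(3)
        q = p.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        for _ in range(max_iter):
            err = p - apply_transform(stack, q, warn_extrapolation=False)
            if np.max(np.linalg.norm(err, axis=1)) <= tol:
                return q
            q = q + damping * (err @ Ainv.T)
        err = np.linalg.norm(p - apply_transform(stack, q, warn_extrapolation=False), axis=1)
    bad = np.nonzero(err > tol)[0]
    raise InversionError(
        f"inversion did not converge for {len(bad)} point(s) within {max_iter} iterations",
        indices=bad,
    )


# ---------------------------------------------------------------------------
# residual evaluation
# ---------------------------------------------------------------------------


@dataclass
class ResidualReport:
    """Per-fiducial residuals (um) with summary statistics."""

    ids: list[str]
    residual_vectors: np.ndarray  # (n, 3), NaN rows for failed refits
    mode: str  # "in_sample" | "leave_one_out"
    failures: dict = field(default_factory=dict)  # id -> reason

    @property
    def residuals(self) -> np.ndarray:
        return np.linalg.norm(self.residual_vectors, axis=1)

    def summary(self) -> dict:
        r = self.residuals
        r = r[np.isfinite(r)]
        pct = {f"p{q}": float(np.percentile(r, q)) for q in (5, 25, 50, 75, 95)}
        return {
            "mode": self.mode,
            "n": int(len(r)),
            "n_failed": len(self.failures),
            "mean_um": float(np.mean(r)),
            "median_um": float(np.median(r)),
            **pct,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "residual_um": self.residuals,
                "dx_um": self.residual_vectors[:, 0],
                "dy_um": self.residual_vectors[:, 1],
                "dz_um": self.residual_vectors[:, 2],
                "mode": self.mode,
            }
        )


def residual_report(stack: TransformStack, fiducials: FiducialSet) -> ResidualReport:
    """In-sample residuals: distance between each transformed source fiducial and its target."""
    pred = apply_transform(stack, fiducials.source, warn_extrapolation=False)
    return ResidualReport(fiducials.ids, pred - fiducials.target, "in_sample")


def loo_residuals(
    fiducials: FiducialSet,
    schedule: Optional[Sequence[dict]] = None,
    min_fiducials: int = 21,
    subset: Optional[Sequence[int]] = None,
    progress: Optional[Callable[[int, int], None]] = None,
) -> ResidualReport:
    """Leave-one-out residuals: refit the full stack without each fiducial in
    turn and evaluate the held-out point.

    Estimates generalization error, which the in-sample residual of the
    exact final stage (~0 by construction) cannot. Refit failures are
    recorded per fiducial, not fatal. ``subset`` restricts which fiducials
    are held out (each refit still uses all the others), trading coverage
    for time on large sets.
    """
    n = len(fiducials)
    if n < min_fiducials:
        raise InsufficientDataError(f"leave-one-out needs >= {min_fiducials} fiducials, got {n}")
    held_out = list(range(n)) if subset is None else list(subset)
    vecs = np.full((len(held_out), 3), np.nan)
    failures: dict = {}
    all_ids = fiducials.ids
    ids = [all_ids[i] for i in held_out]
    for row, i in enumerate(held_out):
        keep = [j for j in range(n) if j != i]
        try:
            stack = fit_transform_stack(
                fiducials.subset(keep), schedule=schedule, min_fiducials=min_fiducials - 1
            )
            pred = apply_transform(
                stack, fiducials.pairs[i].source_xyz.reshape(1, 3), warn_extrapolation=False
            )
            vecs[row] = pred[0] - fiducials.pairs[i].target_xyz
        except CoregError as e:
            failures[all_ids[i]] = str(e)
        if progress is not None:
            progress(row + 1, len(held_out))
    return ResidualReport(ids, vecs, "leave_one_out", failures)
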