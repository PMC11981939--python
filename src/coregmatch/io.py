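"""Shared I/O: typed CSV tables, TIFF volumes with voxel-size metadata,
transform-stack JSON, response-block HDF5, and run provenance records.

Conventions used everywhere: right-handed coordinates in micrometres,
0-based voxel indexing with voxel-centre origin, (z, y, x) array order;
CSV is comma-separated UTF-8 with '.' decimals; length columns carry a
``_um`` suffix.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import SchemaError, VolumeError
from .transforms import FiducialSet, TransformStack
from .vessels import DisplacementField, VoxelVolume

__all__ = [
    "FIDUCIAL_SCHEMA",
    "CENTROID_SCHEMA",
    "UNIT_SCHEMA",
    "MATCH_SCHEMA",
    "read_table",
    "write_table",
    "read_fiducials",
    "write_fiducials",
    "read_volume",
    "write_volume",
    "save_stack",
    "load_stack",
    "save_field",
    "load_field",
    "save_response_blocks",
    "load_response_blocks",
    "write_provenance",
    "RunConfig",
]

FIDUCIAL_SCHEMA = {
    "id": str,
    "kind": str,
    "src_x_um": float,
    "src_y_um": float,
    "src_z_um": float,
    "dst_x_um": float,
    "dst_y_um": float,
    "dst_z_um": float,
}
CENTROID_SCHEMA = {"em_id": int, "x_um": float, "y_um": float, "z_um": float}
UNIT_SCHEMA = {
    "session": int,
    "scan_idx": int,
    "field": int,
    "unit_id": int,
    "x_um": float,
    "y_um": float,
    "z_um": float,
}
MATCH_SCHEMA = {
    "session": int,
    "scan_idx": int,
    "field": int,
    "unit_id": int,
    "em_id": int,
    "residual_um": float,
    "method": str,
}


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read a CSV, validate required columns and coerce dtypes.

    Extra columns are preserved untyped; a missing required column
    raises :class:`SchemaError` naming it; a malformed numeric cell
    raises with its 1-based data row number.
    """
    df = pd.read_csv(path, encoding="utf-8")
    for col, typ in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
        try:
            df[col] = df[col].astype(typ)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = int(bad[0]) + 1 if len(bad) else "?"
            raise SchemaError(f"{path}: column {col!r} malformed at data row {row}") from None
    return df


def write_table(path, df: pd.DataFrame, schema: Optional[dict] = None) -> None:
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"cannot write {path}: missing columns {missing}")
    df.to_csv(path, index=False, encoding="utf-8")


def read_fiducials(path) -> FiducialSet:
    return FiducialSet.from_dataframe(read_table(path, FIDUCIAL_SCHEMA))


def write_fiducials(path, fiducials: FiducialSet) -> None:
    write_table(path, fiducials.to_dataframe(), FIDUCIAL_SCHEMA)


# ---------------------------------------------------------------------------
# volumes (TIFF stacks + voxel-size metadata)
# ---------------------------------------------------------------------------


def write_volume(path, vol: VoxelVolume) -> None:
    """Write a TIFF stack with ImageJ-style voxel-size metadata (um)."""
    vz, vy, vx = (float(v) for v in vol.voxel_size)
    tifffile.imwrite(
        path,
        vol.values.astype(np.float32),
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )


def read_volume(path, voxel_size: Optional[tuple] = None) -> VoxelVolume:
    """Read a TIFF stack; voxel size comes from ImageJ metadata unless overridden.

    A file without voxel-size metadata requires an explicit
    ``voxel_size`` override, otherwise :class:`VolumeError` is raised.
    """
    with tifffile.TiffFile(path) as tf:
        vals = tf.asarray()
        meta = tf.imagej_metadata or {}
        vz = meta.get("spacing")
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        vx = vy = None
        if res is not None:
            num, den = res.value
            if num:
                vx = den / num
        res_y = page.tags.get("YResolution")
        if res_y is not None:
            num, den = res_y.value
            if num:
                vy = den / num
    if voxel_size is not None:
        return VoxelVolume(vals, tuple(float(v) for v in voxel_size))
    if vz is None or vx is None or vy is None:
        raise VolumeError(
            f"{path}: no voxel-size metadata; pass an explicit voxel_size override"
        )
    return VoxelVolume(vals, (float(vz), float(vy), float(vx)))


# ---------------------------------------------------------------------------
# transform stacks and displacement fields
# ---------------------------------------------------------------------------


def save_stack(path, stack: TransformStack) -> None:
    Path(path).write_text(json.dumps(stack.to_dict()), encoding="utf-8")


def load_stack(path) -> TransformStack:
    return TransformStack.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def save_field(path, field_: DisplacementField) -> None:
    """Displacement field as a 2x(Z,Y,X,3) float32 TIFF plus a JSON sidecar."""
    arr = np.stack([field_.forward, field_.inverse]).astype(np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")
    sidecar = {
        "spacing_um": field_.spacing_um,
        "final_similarity": field_.final_similarity,
        "layout": "[forward, inverse], (Z, Y, X, 3), components (z, y, x), um",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar), encoding="utf-8")


def load_field(path) -> DisplacementField:
    arr = tifffile.imread(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text(encoding="utf-8"))
    return DisplacementField(
        arr[0].astype(float),
        arr[1].astype(float),
        spacing_um=float(sidecar["spacing_um"]),
        final_similarity=sidecar.get("final_similarity"),
    )


# ---------------------------------------------------------------------------
# response blocks (HDF5: one group per unit, one dataset per clip)
# ---------------------------------------------------------------------------


def save_response_blocks(path, blocks) -> None:
    with h5py.File(path, "w") as f:
        for b in blocks:
            g = f.create_group("unit_" + "_".join(str(k) for k in b.unit_key))
            g.attrs["unit_key"] = list(b.unit_key)
            g.attrs["sampling_rate"] = b.sampling_rate
            for cid, arr in b.traces.items():
                g.create_dataset(str(cid), data=arr)


def load_response_blocks(path):
    from .reliability import ResponseBlock

    blocks = []
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            blocks.append(
                ResponseBlock(
                    unit_key=tuple(int(k) for k in g.attrs["unit_key"]),
                    traces={cid: g[cid][()] for cid in g},
                    sampling_rate=float(g.attrs["sampling_rate"]),
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# run configuration and provenance
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Parameters of one CLI run; round-trips losslessly through JSON/YAML."""

    subcommand: str
    seed: int = 0
    params: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    log_level: str = "INFO"
    schema_version: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def write_provenance(out_path, config: RunConfig) -> None:
    """Write a provenance record (config echo, seed, toolkit version) beside an output."""
    rec = {"toolkit_version": __version__, "config": config.to_dict()}
    Path(str(out_path) + ".provenance.json").write_text(json.dumps(rec, indent=2), encoding="utf-8")
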