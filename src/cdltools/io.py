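"""File formats, run configuration and manifests.

Formats (all plain text except the voxel phantom):

* point clouds: ASCII PLY (vertex-only, with ``comment rw_index``/``side``)
  or CSV/XYZ with columns x_mm,y_mm,z_mm (round window = first row unless
  a ``<name>.json`` sidecar provides ``rw_index``; ``side`` likewise),
* measurement tables / estimates / insertion results: UTF-8 CSV, comma
  separated, '.' decimal, header row mandatory; lengths in mm, angles in
  degrees,
* voxel phantoms: raw little-endian int16 + JSON header (dims, spacing,
  origin, intensity legend) - a runtime artifact, never a test fixture,
* reports and manifests: JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import ElectrodeSpec
from .geometry import LateralWallPointCloud
from .synthetic import VoxelPhantom

__all__ = [
    "read_point_cloud", "write_point_cloud",
    "read_measurement_table", "write_measurement_table",
    "write_phantom", "read_phantom",
    "RunConfig", "RunManifest", "file_sha256",
]

TABLE_COLUMNS = ("specimen_id", "method", "rater_id", "cdl_mm")


# --------------------------------------------------------------------------
# point clouds


def _read_ply(path: Path) -> LateralWallPointCloud:
    rw_index, side = 0, "right"
    with open(path, "r", encoding="utf-8") as fh:
        if fh.readline().strip() != "ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = fh.readline().split()
        if len(fmt) < 2 or fmt[1] != "ascii":
            raise ValueError(f"{path}: only ASCII PLY is supported")
        n_vertices = None
        props = []
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "comment" and len(tok) >= 3:
                if tok[1] == "rw_index":
                    rw_index = int(tok[2])
                elif tok[1] == "side":
                    side = tok[2]
            elif tok[0] == "element" and tok[1] == "vertex":
                n_vertices = int(tok[2])
            elif tok[0] == "element":
                raise ValueError(f"{path}: only vertex-only PLY is supported")
            elif tok[0] == "property":
                props.append(tok[2])
            elif tok[0] == "end_header":
                break
        if n_vertices is None:
            raise ValueError(f"{path}: missing vertex element")
        if props[:3] != ["x", "y", "z"]:
            raise ValueError(f"{path}: first vertex properties must be x y z")
        data = np.loadtxt(fh, max_rows=n_vertices, ndmin=2)
    return LateralWallPointCloud(data[:, :3], rw_index=rw_index, side=side)


def _write_ply(cloud: LateralWallPointCloud, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment rw_index {cloud.rw_index}\n")
        fh.write(f"comment side {cloud.side}\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in cloud.points:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def read_point_cloud(path) -> LateralWallPointCloud:
    """Read a lateral-wall point cloud (.ply, .csv or .xyz)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return _read_ply(path)
    if path.suffix.lower() in (".csv", ".xyz"):
        sep = "," if path.suffix.lower() == ".csv" else r"\s+"
        df = pd.read_csv(path, sep=sep, comment="#")
        cols = [c for c in df.columns
                if c.lower() in ("x", "y", "z", "x_mm", "y_mm", "z_mm")]
        if len(cols) < 3:
            raise ValueError(f"{path}: need x/y/z (or x_mm/y_mm/z_mm) columns")
        pts = df[cols[:3]].to_numpy(dtype=float)
        rw_index, side = 0, "right"
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            rw_index = int(meta.get("rw_index", 0))
            side = meta.get("side", "right")
        return LateralWallPointCloud(pts, rw_index=rw_index, side=side)
    raise ValueError(f"unsupported point-cloud format: {path.suffix}")


def write_point_cloud(cloud: LateralWallPointCloud, path) -> None:
    """Write a cloud as ASCII PLY or CSV (+ JSON sidecar for metadata)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _write_ply(cloud, path)
        return
    if path.suffix.lower() == ".csv":
        df = pd.DataFrame(cloud.points, columns=["x_mm", "y_mm", "z_mm"])
        df.to_csv(path, index=False, float_format="%.9g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"rw_index": cloud.rw_index, "side": cloud.side}, indent=1))
        return
    raise ValueError(f"unsupported point-cloud format: {path.suffix}")


# --------------------------------------------------------------------------
# tables


def read_measurement_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns and c != "cdl_mm"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_measurement_table(table: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# lengths in mm, angles in degrees; comma separated, "
                 "'.' decimal\n")
        table.to_csv(fh, index=False, float_format="%.9g")


# --------------------------------------------------------------------------
# phantoms


def write_phantom(phantom: VoxelPhantom, stem) -> None:
    """Write ``<stem>.raw`` (int16 little-endian) + ``<stem>.json`` header."""
    stem = Path(stem)
    data = np.ascontiguousarray(phantom.data.astype("<i2"))
    data.tofile(stem.with_suffix(".raw"))
    header = {
        "dims": list(phantom.data.shape),
        "spacing_mm": phantom.spacing_mm,
        "origin_mm": list(map(float, phantom.origin_mm)),
        "dtype": "int16-le",
        "order": "C (x, y, z)",
        "intensities": {"fluid": phantom.fluid_value,
                        "bone": phantom.bone_value,
                        "background": phantom.background_value},
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1))


def read_phantom(stem) -> VoxelPhantom:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".raw"), dtype="<i2")
    data = data.reshape(header["dims"])
    return VoxelPhantom(
        data=data, spacing_mm=header["spacing_mm"],
        origin_mm=np.asarray(header["origin_mm"], dtype=float),
        fluid_value=header["intensities"]["fluid"],
        bone_value=header["intensities"]["bone"],
        background_value=header["intensities"]["background"])


# --------------------------------------------------------------------------
# configuration + manifest


_CONFIG_FIELDS = {
    "seed", "electrode_length_mm", "electrode_n_contacts", "theta_full_deg",
    "threshold_lo", "threshold_hi", "voxel_spacing_mm", "pbtl_profile",
    "icc_bands", "outdir", "wall_offset_mm",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (JSON-loadable, unknown keys rejected)."""

    seed: int = 0
    electrode_length_mm: float = 31.5
    electrode_n_contacts: int = 12
    theta_full_deg: float = 900.0
    threshold_lo: float = -1024.0
    threshold_hi: float = 280.0
    voxel_spacing_mm: float = 0.2
    pbtl_profile: str = "escude-shape"
    icc_bands: str = "cicchetti"
    wall_offset_mm: float = 0.5
    outdir: str = "cdltools-out"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.theta_full_deg <= 0:
            raise ValueError("theta_full_deg must be positive")
        if not self.threshold_lo < self.threshold_hi:
            raise ValueError("threshold_lo must be < threshold_hi")
        if not 0.05 <= self.voxel_spacing_mm <= 0.5:
            raise ValueError("voxel spacing must lie in [0.05, 0.5] mm")
        ElectrodeSpec(self.electrode_length_mm, self.electrode_n_contacts)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        unknown = set(payload) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @property
    def electrode(self) -> ElectrodeSpec:
        return ElectrodeSpec(self.electrode_length_mm,
                             self.electrode_n_contacts)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Per-run provenance: config hash, version and output checksums."""

    config_hash: str
    package_version: str
    checksums: dict = field(default_factory=dict)
    timestamp: str | None = None

    def add_file(self, path) -> None:
        self.checksums[Path(path).name] = file_sha256(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1,
                                         sort_keys=True))
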