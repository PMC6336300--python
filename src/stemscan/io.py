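"""File I/O: raw scan CSV, point-cloud XYZ/PLY, reference and report tables.

Raw scan dialect: header ``phi_deg,theta_deg,range_m,intensity``, one
return per line, UTF-8, '.' decimal separator.  PLY support is the ASCII
flavour only (one float property per coordinate, optional intensity) --
enough for interchange with standard point-cloud viewers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geometry import PointCloud, ScanRecords

__all__ = [
    "read_scan_csv",
    "write_scan_csv",
    "read_xyz",
    "write_xyz",
    "read_ply",
    "write_ply",
    "read_reference_table",
    "write_reference_table",
    "read_tree_report",
    "write_tree_report",
    "write_map_grid",
]

SCAN_COLUMNS = ["phi_deg", "theta_deg", "range_m", "intensity"]
REFERENCE_COLUMNS = ["tree_id", "x_m", "y_m", "dbh_cm", "height_m"]
REPORT_COLUMNS = ["id", "x_m", "y_m", "dbh_cm", "height_m", "ground_inclination_deg", "flags"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _require_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(f"{path}: non-numeric value in column {c!r} at line {line}")
        df[c] = coerced
    return df


def read_scan_csv(path) -> ScanRecords:
    """Read raw polar returns from the scan CSV dialect."""
    df = pd.read_csv(path)
    _require_columns(df, SCAN_COLUMNS, path)
    df = _require_numeric(df, SCAN_COLUMNS, path)
    return ScanRecords.from_dataframe(df)


def write_scan_csv(path, records: ScanRecords) -> None:
    records.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def write_xyz(path, cloud: PointCloud) -> None:
    """ASCII XYZ: ``x y z [intensity]`` per line."""
    cols = [cloud.xyz]
    if cloud.intensity is not None:
        cols.append(cloud.intensity[:, None])
    np.savetxt(path, np.hstack(cols), fmt="%.6f")


def read_xyz(path) -> PointCloud:
    data = np.atleast_2d(np.loadtxt(path))
    if data.size == 0:
        return PointCloud(xyz=np.zeros((0, 3)))
    if data.shape[1] < 3:
        raise SchemaError(f"{path}: expected at least 3 columns")
    return PointCloud(
        xyz=data[:, :3],
        intensity=data[:, 3] if data.shape[1] > 3 else None,
    )


def write_ply(path, cloud: PointCloud) -> None:
    """ASCII PLY with float vertex properties (x, y, z[, intensity])."""
    n = len(cloud)
    props = ["property float x", "property float y", "property float z"]
    cols = [cloud.xyz]
    if cloud.intensity is not None:
        props.append("property float intensity")
        cols.append(cloud.intensity[:, None])
    header = "\n".join(
        [
            "ply",
            "format ascii 1.0",
            f"element vertex {n}",
            *props,
            "end_header",
        ]
    )
    body = np.hstack(cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, body, fmt="%.6f")


def read_ply(path) -> PointCloud:
    """Read the ASCII PLY flavour written by :func:`write_ply`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise SchemaError(f"{path}: not a PLY file")
        n = None
        props = []
        fmt = None
        while True:
            line = fh.readline()
            if not line:
                raise SchemaError(f"{path}: truncated header")
            line = line.strip()
            if line.startswith("format"):
                fmt = line.split()[1]
            elif line.startswith("element vertex"):
                n = int(line.split()[-1])
            elif line.startswith("property"):
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        if fmt != "ascii":
            raise SchemaError(f"{path}: only ASCII PLY is supported")
        if n is None or not {"x", "y", "z"}.issubset(props):
            raise SchemaError(f"{path}: missing vertex x/y/z properties")
        data = np.atleast_2d(np.loadtxt(fh, max_rows=n)) if n else np.zeros((0, len(props)))
    ix, iy, iz = (props.index(c) for c in ("x", "y", "z"))
    xyz = data[:, [ix, iy, iz]]
    intensity = data[:, props.index("intensity")] if "intensity" in props else None
    return PointCloud(xyz=xyz, intensity=intensity)


def read_reference_table(path) -> pd.DataFrame:
    """Read a tape-measurement reference table (schema-checked)."""
    df = pd.read_csv(path)
    _require_columns(df, REFERENCE_COLUMNS, path)
    return _require_numeric(df, REFERENCE_COLUMNS, path)


def write_reference_table(path, table: pd.DataFrame) -> None:
    _require_columns(table, REFERENCE_COLUMNS, path)
    table.to_csv(path, index=False, float_format="%.6f", columns=REFERENCE_COLUMNS)


def read_tree_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    _require_columns(df, REPORT_COLUMNS, path)
    numeric = [c for c in REPORT_COLUMNS if c != "flags"]
    return _require_numeric(df, numeric, path)


def write_tree_report(path, table: pd.DataFrame) -> None:
    _require_columns(table, REPORT_COLUMNS, path)
    table.to_csv(path, index=False, float_format="%.2f", columns=REPORT_COLUMNS)


def write_map_grid(path, map_values: np.ndarray) -> None:
    """Plain-matrix text export of a cylindrical map (NaN for no return)."""
    np.savetxt(path, map_values, fmt="%.4f")
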