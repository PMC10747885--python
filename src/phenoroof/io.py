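"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain: PNG for images and masks, a sidecar
disparity grid (text CSV, lossy to a stated number of decimals, or a
binary ``.npy`` float grid, lossless), ASCII PLY for point clouds,
per-station CSVs plus a manifest for sensor suites, YAML for
configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .core import CameraGeometry, FormatError, Scan
from .thermal import SensorSeries

__all__ = [
    "write_disparity",
    "read_disparity",
    "write_scan",
    "read_scan",
    "write_mask_png",
    "write_ply",
    "read_ply",
    "write_sensor_suite",
    "read_sensor_suite",
    "load_config_file",
    "save_config_file",
]

CSV_DECIMALS = 3  # documented precision of the text disparity dialect


def write_disparity(grid: np.ndarray, path, fmt: Optional[str] = None,
                    decimals: int = CSV_DECIMALS) -> Path:
    """Write a disparity grid.

    ``fmt='npy'`` round-trips exactly; ``fmt='csv'`` is a plain-text
    matrix rounded to ``decimals`` places (max round-trip error
    ``0.5·10^-decimals``).  The format is inferred from the suffix when
    not given.
    """
    path = Path(path)
    fmt = fmt or ("npy" if path.suffix == ".npy" else "csv")
    grid = np.asarray(grid, dtype=float)
    if fmt == "npy":
        np.save(path, grid)
    elif fmt == "csv":
        np.savetxt(path, grid, fmt=f"%.{decimals}f", delimiter=",")
    else:
        raise FormatError(f"unknown disparity format {fmt!r}")
    return path


def read_disparity(path) -> np.ndarray:
    """Read a disparity grid written by :func:`write_disparity`."""
    path = Path(path)
    try:
        if path.suffix == ".npy":
            grid = np.load(path)
        else:
            grid = np.loadtxt(path, delimiter=",", ndmin=2)
    except Exception as exc:  # corrupt file → uniform error class
        raise FormatError(f"cannot read disparity grid {path}: {exc}") from exc
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise FormatError(f"disparity grid in {path} is not 2-D")
    return grid


def write_scan(scan: Scan, directory, stem: str,
               disparity_fmt: str = "npy") -> Dict[str, Path]:
    """Write one scan as ``<stem>.png`` + disparity sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    png = directory / f"{stem}.png"
    iio.imwrite(png, scan.rgb)
    side = directory / f"{stem}_disparity.{'npy' if disparity_fmt == 'npy' else 'csv'}"
    write_disparity(scan.disparity, side, fmt=disparity_fmt)
    return {"rgb": png, "disparity": side}


def read_scan(png_path, disparity_path, geometry: CameraGeometry,
              acquired_at, label: Optional[str] = None) -> Scan:
    """Load a scan from a PNG + disparity sidecar pair.

    Dimension mismatch between the pair is a format error, caught at
    :class:`~phenoroof.core.Scan` construction.
    """
    rgb = np.asarray(iio.imread(png_path))
    if rgb.ndim == 2:
        rgb = np.repeat(rgb[:, :, None], 3, axis=2)
    rgb = rgb[:, :, :3].astype(np.uint8)
    disparity = read_disparity(disparity_path)
    return Scan(rgb=rgb, disparity=disparity, acquired_at=acquired_at,
                geometry=geometry, label=label)


def write_mask_png(mask_image: np.ndarray, path) -> Path:
    """Write an 8-bit black/white mask rendering."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(mask_image, dtype=np.uint8))
    return path


# ---------------------------------------------------------------------------
# ASCII PLY point clouds


def write_ply(path, x, y, z, height_cm) -> int:
    """ASCII PLY with per-vertex ``height_cm`` scalar; returns vertex count."""
    x, y, z, h = (np.asarray(a, dtype=float) for a in (x, y, z, height_cm))
    n = x.size
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float height_cm\n")
        fh.write("end_header\n")
        for xi, yi, zi, hi in zip(x, y, z, h):
            fh.write(f"{xi:.6f} {yi:.6f} {zi:.6f} {hi:.6f}\n")
    return n


def read_ply(path) -> pd.DataFrame:
    """Read back a point cloud written by :func:`write_ply`."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise FormatError(f"{path} is not a PLY file")
        n = None
        names: List[str] = []
        for line in fh:
            line = line.strip()
            if line.startswith("element vertex"):
                n = int(line.split()[-1])
            elif line.startswith("property"):
                names.append(line.split()[-1])
            elif line == "end_header":
                break
        if n is None:
            raise FormatError(f"{path}: missing vertex element")
        data = np.loadtxt(fh, ndmin=2)
    if data.shape != (n, len(names)):
        raise FormatError(f"{path}: vertex data does not match header")
    return pd.DataFrame(data, columns=names)


# ---------------------------------------------------------------------------
# sensor suites


def write_sensor_suite(series: Iterable[SensorSeries], directory) -> Path:
    """One CSV per station plus a station manifest.

    Station files carry ``timestamp,value_C[,humidity_pct]``; the
    manifest maps station → role/crop/variable/file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series:
        fname = f"{s.station}.csv"
        df = pd.DataFrame({"timestamp": s.values.index.strftime("%Y-%m-%dT%H:%M:%S"),
                           "value_C": s.values.to_numpy()})
        if s.extra is not None:
            for col in s.extra.columns:
                df[col] = s.extra[col].to_numpy()
        df.to_csv(directory / fname, index=False, float_format="%.4f")
        rows.append({"station": s.station, "role": s.role,
                     "crop": s.crop or "", "variable": s.variable,
                     "file": fname})
    manifest = directory / "stations.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_sensor_suite(directory,
                      column_map: Optional[Dict[str, str]] = None) -> List[SensorSeries]:
    """Load a sensor suite from a station manifest directory.

    ``column_map`` renames columns of third-party exports (e.g.
    ThingSpeak-style ``created_at``/``field1``) onto the expected
    ``timestamp``/``value_C``.
    """
    directory = Path(directory)
    manifest_path = directory / "stations.csv"
    if not manifest_path.exists():
        raise FormatError(f"no station manifest at {manifest_path}")
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    out: List[SensorSeries] = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(directory / row["file"])
        if column_map:
            df = df.rename(columns=column_map)
        if "timestamp" not in df or "value_C" not in df:
            raise FormatError(
                f"station file {row['file']} lacks timestamp/value_C columns")
        idx = pd.to_datetime(df["timestamp"])
        values = pd.Series(df["value_C"].to_numpy(dtype=float), index=idx,
                           name="value")
        extra_cols = [c for c in df.columns if c not in ("timestamp", "value_C")]
        extra = (pd.DataFrame({c: df[c].to_numpy() for c in extra_cols}, index=idx)
                 if extra_cols else None)
        out.append(SensorSeries(station=row["station"], role=row["role"],
                                crop=row["crop"] or None,
                                variable=row.get("variable", "temperature"),
                                values=values, extra=extra))
    return out


# ---------------------------------------------------------------------------
# configuration


def load_config_file(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"config {path} is not a mapping")
    return data


def save_config_file(data: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
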