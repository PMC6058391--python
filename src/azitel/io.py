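"""Readers, writers, and run plumbing.

Azimuth tables are delimited text with a header; compass azimuths (degrees
clockwise from north) are converted to the package's internal math-radian
bearings on load. Rasters are ESRI ASCII grids (cell-center registered,
rows written north to south). Geometries go out as GeoJSON, posterior
draws and benchmark tables as CSV. Every run can record a manifest with
the seed, the config hash, and package versions so outputs reproduce.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circular import compass_deg_to_math_rad, math_rad_to_compass_deg

__all__ = [
    "AzimuthTableError",
    "read_azimuth_table",
    "write_azimuth_table",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_config",
    "config_hash",
    "write_manifest",
    "polygon_to_geojson",
    "write_geojson",
]

REQUIRED_COLUMNS = ("individual", "relocation", "station_x", "station_y", "azimuth_deg")


class AzimuthTableError(ValueError):
    """Structured ingest failure; carries the offending row numbers."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


def read_azimuth_table(path, dialect: str = ",") -> pd.DataFrame:
    """Read a delimited azimuth table and attach math-radian bearings.

    Required columns: ``individual``, ``relocation``, ``station_x``,
    ``station_y`` (meters, projected), ``azimuth_deg`` (compass degrees in
    [0, 360)). Extra columns (covariates, timestamps) pass through. Adds a
    ``bearing`` column in internal math radians.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect)
    if df.empty:
        raise AzimuthTableError(f"no data rows in {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AzimuthTableError(f"missing required column(s): {missing}")
    bad_rows = []
    for col in ("station_x", "station_y", "azimuth_deg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(vals)].tolist()
        bad_rows.extend(bad)
        df[col] = vals
    out_of_range = df.index[
        np.isfinite(df["azimuth_deg"]) & ((df["azimuth_deg"] < 0) | (df["azimuth_deg"] >= 360))
    ].tolist()
    if bad_rows or out_of_range:
        # +2: header line and 1-based numbering
        lines = sorted({i + 2 for i in bad_rows + out_of_range})
        raise AzimuthTableError(f"malformed rows at line(s) {lines}", rows=lines)
    if df["individual"].isna().any() or df["relocation"].isna().any():
        raise AzimuthTableError("empty individual/relocation ids")
    df = df.copy()
    df["bearing"] = compass_deg_to_math_rad(df["azimuth_deg"].to_numpy(float))
    return df


def write_azimuth_table(df: pd.DataFrame, path, dialect: str = ",") -> None:
    out = df.copy()
    if "azimuth_deg" not in out.columns and "bearing" in out.columns:
        out["azimuth_deg"] = math_rad_to_compass_deg(out["bearing"].to_numpy(float))
    out.drop(columns=[c for c in ("bearing",) if c in out.columns]).to_csv(
        path, sep=dialect, index=False
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grids


def read_ascii_grid(path):
    """Read one ESRI ASCII grid layer -> (array, xllcorner, yllcorner, cellsize).

    The returned array is indexed south-to-north (row 0 southernmost), i.e.
    the file's row order is flipped on load.
    """
    header = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    data = np.loadtxt(lines[i:].__iter__())
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    if "nodata_value" in header:
        data = np.where(data == header["nodata_value"], np.nan, data)
    return (
        data[::-1].copy(),
        header.get("xllcorner", 0.0),
        header.get("yllcorner", 0.0),
        header.get("cellsize", 1.0),
    )


def write_ascii_grid(array, path, xllcorner=0.0, yllcorner=0.0, cellsize=1.0,
                     nodata=-9999.0) -> None:
    """Write a south-to-north indexed array as an ESRI ASCII grid."""
    arr = np.asarray(array, dtype=float)
    out = np.where(np.isfinite(arr), arr, nodata)[::-1]  # file rows run N -> S
    with open(path, "w") as fh:
        fh.write(f"ncols {arr.shape[1]}\n")
        fh.write(f"nrows {arr.shape[0]}\n")
        fh.write(f"xllcorner {xllcorner!r}\n")
        fh.write(f"yllcorner {yllcorner!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, out, fmt="%.8g")


def read_covariate_raster(paths: dict):
    """Read named ESRI ASCII layers into a CovariateRaster (shared grid)."""
    from .rsf import CovariateRaster

    layers = {}
    meta = None
    for name, p in paths.items():
        arr, x0, y0, cs = read_ascii_grid(p)
        if meta is None:
            meta = (x0, y0, cs)
        elif meta != (x0, y0, cs):
            raise ValueError(f"layer {name!r} grid does not match the first layer")
        layers[name] = arr
    x0, y0, cs = meta
    return CovariateRaster(xllcorner=x0, yllcorner=y0, cellsize=cs, layers=layers)


# ---------------------------------------------------------------------------
# Config, manifests, GeoJSON


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must hold a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, cfg: dict, seed, runtime_s: float | None = None) -> Path:
    import azitel

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "versions": {"azitel": azitel.__version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "runtime_s": runtime_s,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def polygon_to_geojson(geom, properties: dict | None = None) -> dict:
    """Shapely polygon/multipolygon (or ellipse boundary array) -> GeoJSON feature."""
    from shapely.geometry import Polygon, mapping

    if isinstance(geom, np.ndarray):
        geom = Polygon(geom)
    geom = geom.buffer(0) if not geom.is_valid else geom
    return {"type": "Feature", "geometry": mapping(geom),
            "properties": properties or {}}


def write_geojson(features, path) -> None:
    fc = {"type": "FeatureCollection", "features": list(features)}
    with open(path, "w") as fh:
        json.dump(fc, fh)
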