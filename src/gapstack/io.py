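"""File I/O: ASCII-grid rasters, occurrence CSVs, and road GeoJSON.

Rasters are read and written as single-band ESRI ASCII grids (plain text,
square cells, planar meter coordinates, row 0 = north).  Occurrence tables
are CSV with a fixed column order and ISO-8601 timestamps.  Both round-trip
losslessly at the printed precision (``%.10g``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, mapping, shape

from .grid import Grid

__all__ = [
    "read_ascii_grid", "write_ascii_grid",
    "read_occurrences", "write_occurrences",
    "read_roads_geojson", "write_roads_geojson",
    "OCCURRENCE_COLUMNS",
]

#: Canonical occurrence-table schema, in file column order.
OCCURRENCE_COLUMNS = ["species_id", "source", "x", "y", "elevation",
                      "timestamp", "site_id", "group"]

SOURCES = {"camera", "transect", "interview", "specimen"}
GROUPS = {"mammal", "resident_bird", "summer_bird", "winter_bird", "other"}

_NODATA = -9999.0


def write_ascii_grid(path: str | Path, array: np.ndarray, grid: Grid,
                     nodata: float = _NODATA, fmt: str = "%.10g") -> None:
    """Write a 2-D array as an ESRI ASCII grid (text, deterministic)."""
    arr = np.asarray(array, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError(f"array shape {arr.shape} does not match grid {grid.shape}")
    out = np.where(np.isnan(arr), nodata, arr)
    header = (f"ncols {grid.ncols}\n"
              f"nrows {grid.nrows}\n"
              f"xllcorner {grid.xmin!r}\n"
              f"yllcorner {grid.ymin!r}\n"
              f"cellsize {grid.cell_size!r}\n"
              f"NODATA_value {nodata!r}\n")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, Grid]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        arr = np.loadtxt(fh, dtype=float, ndmin=2)
    grid = Grid(xmin=header["xllcorner"], ymin=header["yllcorner"],
                cell_size=header["cellsize"],
                nrows=int(header["nrows"]), ncols=int(header["ncols"]))
    if arr.shape != grid.shape:
        raise ValueError(f"{path}: data shape {arr.shape} does not match header {grid.shape}")
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr, grid


def write_occurrences(records: pd.DataFrame, path: str | Path) -> None:
    """Write an occurrence table as CSV in the canonical column order."""
    missing = [c for c in OCCURRENCE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns {missing}")
    extra = [c for c in records.columns if c not in OCCURRENCE_COLUMNS]
    df = records[OCCURRENCE_COLUMNS + extra].copy()
    ts = pd.to_datetime(df["timestamp"])
    df["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%S")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read an occurrence CSV, validating schema and timestamps.

    Malformed timestamps are reported with the offending row index.
    """
    df = pd.read_csv(path, dtype={"species_id": str, "source": str,
                                  "site_id": str, "group": str})
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    raw = df["timestamp"]
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: malformed timestamp {raw.iloc[i]!r} at row {i}")
    df["timestamp"] = parsed
    bad_src = ~df["source"].isin(SOURCES)
    if bad_src.any():
        i = int(np.flatnonzero(bad_src.to_numpy())[0])
        raise ValueError(f"{path}: unknown source {df['source'].iloc[i]!r} at row {i}")
    bad_grp = ~df["group"].isin(GROUPS)
    if bad_grp.any():
        i = int(np.flatnonzero(bad_grp.to_numpy())[0])
        raise ValueError(f"{path}: unknown group {df['group'].iloc[i]!r} at row {i}")
    return df


def write_roads_geojson(roads: list[LineString], path: str | Path) -> None:
    fc = {"type": "FeatureCollection",
          "features": [{"type": "Feature", "properties": {"road_id": i},
                        "geometry": mapping(r)} for i, r in enumerate(roads)]}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(fc, fh, sort_keys=True, separators=(",", ":"))


def read_roads_geojson(path: str | Path) -> list[LineString]:
    with open(path) as fh:
        fc = json.load(fh)
    roads = [shape(f["geometry"]) for f in fc["features"]]
    for r in roads:
        if not isinstance(r, LineString):
            raise ValueError(f"{path}: expected LineString geometries, got {r.geom_type}")
    return roads
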