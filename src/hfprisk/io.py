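"""Readers and writers for the pipeline's on-disk formats.

Rasters are stored as ESRI ASCII grids (``.asc``) — a plain-text,
widely-supported single-band raster format. Species ranges travel as GeoJSON
FeatureCollections keyed by ``species_id``; tables are UTF-8 CSV with explicit
headers; configuration is YAML; reports are JSON carrying a schema-version
field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
import yaml
from shapely.geometry import mapping, shape

from .grid import Grid

SCHEMA_VERSION = "1.0"

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_ranges_geojson",
    "write_ranges_geojson",
    "read_yaml",
    "write_json_report",
]


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    grid: Grid,
    nodata: float = -9999,
) -> None:
    """Write a single-band raster as an ESRI ASCII grid.

    Integer arrays are written without a decimal point so that integer
    rasters round-trip exactly.
    """
    grid.validate_array(values)
    path = Path(path)
    is_int = np.issubdtype(values.dtype, np.integer)
    header = (
        f"ncols {grid.cols}\n"
        f"nrows {grid.rows}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y_bottom!r}\n"
        f"cellsize {grid.cell_km!r}\n"
        f"NODATA_value {int(nodata) if is_int else nodata!r}\n"
    )
    body = values
    if not is_int:
        body = np.where(np.isnan(values), nodata, values)
    fmt = "%d" if is_int else "%.10g"
    with path.open("w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, Grid, float]:
    """Read an ESRI ASCII grid; returns ``(values, grid, nodata)``.

    Raises ``ValueError`` if any of the six header fields is missing —
    grid geometry is never silently defaulted.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                raise ValueError(f"{path}: malformed ASCII grid header line {line!r}")
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    missing = required - set(header)
    if missing:
        raise ValueError(f"{path}: ASCII grid header missing {sorted(missing)}")
    rows, cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    grid = Grid(
        rows=rows,
        cols=cols,
        cell_km=cell,
        x0=header["xllcorner"],
        y_top=header["yllcorner"] + rows * cell,
    )
    grid.validate_array(values, str(path))
    if np.all(values == np.floor(values)) and np.all(np.abs(values) < 2**31):
        values = values.astype(np.int64)
    return values, grid, header["nodata_value"]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def write_ranges_geojson(path: str | Path, ranges: dict[str, shapely.Geometry]) -> None:
    """Write ``{species_id: geometry}`` as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"species_id": sid},
            "geometry": mapping(geom),
        }
        for sid, geom in ranges.items()
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_ranges_geojson(path: str | Path) -> dict[str, shapely.Geometry]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    out: dict[str, shapely.Geometry] = {}
    for feat in payload["features"]:
        sid = feat["properties"]["species_id"]
        if sid in out:
            raise ValueError(f"duplicate species_id {sid!r} in {path}")
        out[sid] = shape(feat["geometry"])
    return out


def read_yaml(path: str | Path) -> dict:
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_json_report(path: str | Path, report: dict) -> None:
    """Write a JSON report with the package schema-version stamped in."""
    payload = {"schema_version": SCHEMA_VERSION, **report}
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
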