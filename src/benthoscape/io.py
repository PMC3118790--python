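"""Readers and writers: waveform tables, ESRI ASCII grids, GeoJSON, configs.

All formats are plain text.  The waveform table has a one-line header
followed by one row per sounding:

    sounding_id easting northing t0 dt n i1 i2 ... in

Rasters use the ESRI ASCII grid format (cell-centre convention: row 0 is
the northern edge; ``xllcorner``/``yllcorner`` anchor the south-west corner).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from shapely.geometry import shape as shapely_shape

from benthoscape.config import BenthoscapeConfig
from benthoscape.grids import CategoricalRaster, RasterGrid
from benthoscape.simulate import Waveform

WAVEFORM_HEADER = "sounding_id easting northing t0 dt n intensities..."


class ParseError(ValueError):
    """A malformed input file, reported with its line number."""


def write_waveform_table(path: str | Path, waveforms: list[Waveform]) -> None:
    with open(path, "w") as fh:
        fh.write(WAVEFORM_HEADER + "\n")
        for w in waveforms:
            samples = " ".join(format(float(v), ".17g") for v in w.intensities)
            head = " ".join(format(float(v), ".17g")
                            for v in (w.easting, w.northing, w.t0, w.dt))
            fh.write(f"{w.sounding_id} {head} {w.intensities.size} {samples}\n")


def read_waveform_table(path: str | Path) -> list[Waveform]:
    waveforms = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sounding_id"):
            raise ParseError(f"{path}:1: expected waveform header, got {header[:40]!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            try:
                sid, e, n, t0, dt, count = parts[0], *map(float, parts[1:5]), int(parts[5])
                samples = np.array(parts[6:], dtype=float)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed waveform row ({exc})") from None
            if samples.size != count:
                raise ParseError(
                    f"{path}:{lineno}: declared {count} samples, found {samples.size}"
                )
            waveforms.append(
                Waveform(t0=t0, dt=dt, intensities=samples, sounding_id=sid,
                         easting=e, northing=n)
            )
    return waveforms


def write_ascii_grid(
    path: str | Path,
    grid: RasterGrid | CategoricalRaster,
    nodata: float = -9999,
) -> None:
    values = grid.values if isinstance(grid, RasterGrid) else grid.codes
    rows, cols = values.shape
    out = np.array(values, dtype=float)
    out[~np.isfinite(out)] = nodata
    if isinstance(grid, CategoricalRaster):
        out[grid.codes == CategoricalRaster.NODATA] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {float(grid.x0):.17g}\n")
        fh.write(f"yllcorner {float(grid.y0):.17g}\n")
        fh.write(f"cellsize {float(grid.cell_size):.17g}\n")
        fh.write(f"NODATA_value {float(nodata):.17g}\n")
        for row in out:
            fh.write(" ".join(format(float(v), ".17g") for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (values with NaN no-data, header dict)."""
    header = {}
    keys = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")
    with open(path) as fh:
        for lineno in range(1, 7):
            parts = fh.readline().split()
            if len(parts) != 2 or parts[0].lower() not in keys:
                raise ParseError(f"{path}:{lineno}: malformed ASCII grid header")
            header[parts[0].lower()] = float(parts[1])
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    expect = (int(header["nrows"]), int(header["ncols"]))
    if values.shape != expect:
        raise ParseError(f"{path}: body shape {values.shape} != header {expect}")
    values[values == header["nodata_value"]] = np.nan
    return values, header


def read_geojson_polygons(path: str | Path) -> list[tuple[object, dict]]:
    """Read polygon features; returns (shapely geometry, properties) pairs."""
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    return [(shapely_shape(f["geometry"]), f.get("properties", {})) for f in feats]


def polygons_to_pixels(
    polygons: list[tuple[object, dict]],
    raster: RasterGrid | CategoricalRaster,
    label_key: str = "label",
) -> tuple[np.ndarray, list]:
    """Cells whose centres fall inside each polygon, with the polygon labels."""
    from shapely import contains_xy

    base = raster if isinstance(raster, RasterGrid) else RasterGrid(
        np.zeros(raster.shape), raster.cell_size, raster.x0, raster.y0
    )
    rows, cols = base.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    centers = np.array([base.cell_center(int(i), int(j))
                        for i, j in zip(rr.ravel(), cc.ravel())])
    idx, labels = [], []
    for geom, props in polygons:
        inside = contains_xy(geom, centers[:, 0], centers[:, 1])
        for flat in np.flatnonzero(inside):
            idx.append((flat // cols, flat % cols))
            labels.append(props.get(label_key))
    return np.array(idx, dtype=int).reshape(-1, 2), labels


def load_config(path: str | Path) -> BenthoscapeConfig:
    with open(path) as fh:
        return BenthoscapeConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(path: str | Path, config: BenthoscapeConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def save_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
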