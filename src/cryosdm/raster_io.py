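"""Raster file I/O.

Two plain formats are supported:

* **ESRI ASCII grid** (``.asc``) — the text raster format classically used
  for distribution-model layers.  Square cells only.  The CRS is carried in
  an optional JSON sidecar ``<file>.asc.meta.json`` with key ``"crs_id"``;
  absent sidecar means geographic coordinates.
* **NetCDF** (``.nc``) — one variable per file, dimensions ``(y, x)`` with
  coordinate vectors of cell centres; read/written through xarray's scipy
  engine.  ``crs_id`` is stored as a variable attribute.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import CryosdmError, GridConflictError
from .grid import GEOGRAPHIC, EnvLayer, GridSpec


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_ascii_grid(path, name: str | None = None) -> EnvLayer:
    """Read one ``.asc`` raster into an :class:`EnvLayer`.

    The layer name defaults to the file stem.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            header: dict[str, float] = {}
            pos = fh.tell()
            for _ in range(6):
                pos = fh.tell()
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            values = np.loadtxt(fh, dtype=float, ndmin=2)
    except OSError as exc:
        raise CryosdmError(f"cannot read raster {path}: {exc}") from exc
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise CryosdmError(f"raster {path} lacks mandatory header key {key!r}")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise GridConflictError(
            f"raster {path}: body shape {values.shape} contradicts header "
            f"({n_rows}, {n_cols})"
        )
    nodata = header.get("nodata_value", -9999.0)
    cell = header["cellsize"]
    crs_id = GEOGRAPHIC
    side = _sidecar(path)
    if side.exists():
        crs_id = json.loads(side.read_text()).get("crs_id", GEOGRAPHIC)
    grid = GridSpec(
        crs_id=crs_id,
        x0=header["xllcorner"],
        y_top=header["yllcorner"] + n_rows * cell,
        dx=cell,
        dy=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        nodata_sentinel=nodata,
    )
    valid = np.isfinite(values) & (values != nodata)
    clean = np.where(valid, values, nodata)
    return EnvLayer(name=name or path.stem, values=clean, valid_mask=valid, grid=grid)


def write_ascii_grid(layer: EnvLayer, path) -> None:
    path = Path(path)
    grid = layer.grid
    if not np.isclose(grid.dx, grid.dy):
        raise CryosdmError(
            "ESRI ASCII grids require square cells; "
            f"got dx={grid.dx}, dy={grid.dy} for layer {layer.name!r}"
        )
    nodata = grid.nodata_sentinel
    body = np.where(layer.valid_mask, layer.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x0:.10g}\n")
        fh.write(f"yllcorner {grid.y_top - grid.n_rows * grid.dy:.10g}\n")
        fh.write(f"cellsize {grid.dx:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, body, fmt="%.7g")
    if grid.crs_id != GEOGRAPHIC:
        _sidecar(path).write_text(json.dumps({"crs_id": grid.crs_id}))


def read_netcdf(path, name: str | None = None) -> EnvLayer:
    """Read a single-variable NetCDF raster (dims y, x; centre coordinates)."""
    import xarray as xr

    path = Path(path)
    try:
        ds = xr.open_dataset(path, engine="scipy")
    except (OSError, ValueError) as exc:
        raise CryosdmError(f"cannot read raster {path}: {exc}") from exc
    with ds:
        data_vars = list(ds.data_vars)
        if len(data_vars) != 1:
            raise CryosdmError(
                f"raster {path} must hold exactly one variable, found {data_vars}"
            )
        var = ds[data_vars[0]]
        y = np.asarray(ds["y"].values, dtype=float)
        x = np.asarray(ds["x"].values, dtype=float)
        values = np.asarray(var.values, dtype=float)
        crs_id = str(var.attrs.get("crs_id", GEOGRAPHIC))
        nodata = float(var.attrs.get("nodata", -9999.0))
    if y.size > 1 and y[1] > y[0]:  # store north-up internally
        y = y[::-1]
        values = values[::-1]
    dy = abs(y[0] - y[1]) if y.size > 1 else abs(x[1] - x[0])
    dx = abs(x[1] - x[0]) if x.size > 1 else dy
    grid = GridSpec(
        crs_id=crs_id,
        x0=float(x[0] - dx / 2),
        y_top=float(y[0] + dy / 2),
        dx=float(dx),
        dy=float(dy),
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        nodata_sentinel=nodata,
    )
    valid = np.isfinite(values) & (values != nodata)
    return EnvLayer(
        name=name or data_vars[0],
        values=np.where(valid, values, nodata),
        valid_mask=valid,
        grid=grid,
    )


def write_netcdf(layer: EnvLayer, path) -> None:
    import xarray as xr

    grid = layer.grid
    xs = grid.x0 + (np.arange(grid.n_cols) + 0.5) * grid.dx
    ys = grid.y_top - (np.arange(grid.n_rows) + 0.5) * grid.dy
    body = np.where(layer.valid_mask, layer.values, grid.nodata_sentinel)
    da = xr.DataArray(
        body,
        dims=("y", "x"),
        coords={"y": ys, "x": xs},
        name=layer.name,
        attrs={"crs_id": grid.crs_id, "nodata": grid.nodata_sentinel},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_raster(path, name: str | None = None) -> EnvLayer:
    """Dispatch on extension: ``.asc`` → ASCII grid, ``.nc`` → NetCDF."""
    path = Path(path)
    if path.suffix == ".nc":
        return read_netcdf(path, name)
    return read_ascii_grid(path, name)
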