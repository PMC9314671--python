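"""Environmental grid preparation.

Reads raster stacks, crops them to the northern study region, reprojects
them onto the polar equal-area frame, and builds the coastal study mask
(shallow or near-shore, rocky substrate, north of the latitude cut).
"""

from __future__ import annotations

import numpy as np

from .errors import (
    ConfigurationError,
    DataError,
    EmptyDomainError,
    GridConflictError,
)
from .grid import (
    GEOGRAPHIC,
    LAEA_NORTH_POLE,
    SUBSTRATE_DEPOSITIONAL,
    SUBSTRATE_EROSIONAL,
    EnvLayer,
    GridSpec,
    ScenarioStack,
    StudyMask,
    laea_forward,
)
from .raster_io import read_raster


def load_stack(paths, names, scenario_id: str = "present") -> ScenarioStack:
    """Load rasters into one :class:`ScenarioStack` on a shared grid.

    Every file must describe the same grid; cells carrying the nodata
    sentinel are flagged invalid.
    """
    paths = list(paths)
    names = list(names)
    if len(paths) != len(names):
        raise ConfigurationError(
            f"{len(paths)} raster paths but {len(names)} layer names"
        )
    layers = [read_raster(p, n) for p, n in zip(paths, names)]
    ref = layers[0].grid
    for lyr in layers[1:]:
        ref.require_compatible(lyr.grid, what=f"layer {lyr.name!r}")
    return ScenarioStack(scenario_id, layers)


def crop_north(stack: ScenarioStack, lat_min_deg: float = 30.0) -> ScenarioStack:
    """Retain only cells whose centre latitude is >= ``lat_min_deg``.

    On geographic grids whole rows are sliced off; on projected grids the
    grid frame is kept and southern cells are invalidated.
    """
    grid = stack.grid
    _, lats = grid.centre_lonlat()
    keep = lats >= lat_min_deg
    if not keep.any():
        raise EmptyDomainError(
            f"no cell centre lies at or north of {lat_min_deg} deg latitude"
        )
    if grid.crs_id == GEOGRAPHIC:
        rows = np.where(keep.any(axis=1))[0]
        r0, r1 = rows.min(), rows.max() + 1
        new_grid = GridSpec(
            crs_id=grid.crs_id,
            x0=grid.x0,
            y_top=grid.y_top - r0 * grid.dy,
            dx=grid.dx,
            dy=grid.dy,
            n_rows=int(r1 - r0),
            n_cols=grid.n_cols,
            nodata_sentinel=grid.nodata_sentinel,
        )

        def slice_layer(lyr: EnvLayer) -> EnvLayer:
            return EnvLayer(
                name=lyr.name,
                values=lyr.values[r0:r1].copy(),
                valid_mask=lyr.valid_mask[r0:r1].copy(),
                grid=new_grid,
            )

        return stack.map_layers(slice_layer)

    def mask_layer(lyr: EnvLayer) -> EnvLayer:
        return EnvLayer(
            name=lyr.name,
            values=lyr.values.copy(),
            valid_mask=lyr.valid_mask & keep,
            grid=grid,
        )

    return stack.map_layers(mask_layer)


def cell_centre_latitudes(grid: GridSpec) -> np.ndarray:
    """Latitude (degrees) of every cell centre, shape (n_rows, n_cols)."""
    _, lats = grid.centre_lonlat()
    return lats


def reproject_equal_area(
    stack: ScenarioStack,
    target_crs: str = LAEA_NORTH_POLE,
    resolution_km: float = 50.0,
) -> ScenarioStack:
    """Resample a geographic stack onto the polar equal-area grid.

    Nearest-neighbour sampling for every layer (continuous and categorical
    alike): each target cell takes the value of the source cell containing
    its centre, and is valid only if that source cell is valid — invalid
    cells never gain values.  The output cell area is exactly
    ``resolution_km**2``.
    """
    if target_crs != LAEA_NORTH_POLE:
        raise ConfigurationError(f"unknown target CRS {target_crs!r}")
    if resolution_km <= 0:
        raise ConfigurationError("resolution_km must be positive")
    src = stack.grid
    if src.crs_id == target_crs:
        if not np.isclose(src.dx, resolution_km) or not np.isclose(src.dy, resolution_km):
            raise ConfigurationError(
                "stack already projected at a different resolution; "
                "re-gridding within the projected frame is not supported"
            )
        return stack.map_layers(lambda lyr: lyr.copy_with())
    if src.crs_id != GEOGRAPHIC:
        raise ConfigurationError(f"cannot reproject from CRS {src.crs_id!r}")

    valid_any = np.zeros(src.shape, dtype=bool)
    for lyr in stack:
        valid_any |= lyr.valid_mask
    if not valid_any.any():
        raise EmptyDomainError("stack has no valid cell to reproject")
    lons, lats = src.centre_lonlat()
    x, y = laea_forward(lons[valid_any], lats[valid_any])
    res = float(resolution_km)
    x0 = np.floor((x.min() - res) / res) * res
    y_top = np.ceil((y.max() + res) / res) * res
    n_cols = int(np.ceil((x.max() + res - x0) / res))
    n_rows = int(np.ceil((y_top - (y.min() - res)) / res))
    tgt = GridSpec(
        crs_id=target_crs,
        x0=x0,
        y_top=y_top,
        dx=res,
        dy=res,
        n_rows=n_rows,
        n_cols=n_cols,
        nodata_sentinel=src.nodata_sentinel,
    )
    tlon, tlat = tgt.centre_lonlat()
    # wrap longitudes into the source grid's range before indexing
    tlon = src.x0 + np.mod(tlon - src.x0, 360.0)
    rows, cols = src.xy_to_rowcol(tlon, tlat)
    inside = src.inside(rows, cols)
    rows_c = np.clip(rows, 0, src.n_rows - 1)
    cols_c = np.clip(cols, 0, src.n_cols - 1)

    def resample(lyr: EnvLayer) -> EnvLayer:
        vals = lyr.values[rows_c, cols_c]
        valid = inside & lyr.valid_mask[rows_c, cols_c]
        return EnvLayer(
            name=lyr.name,
            values=np.where(valid, vals, tgt.nodata_sentinel),
            valid_mask=valid,
            grid=tgt,
        )

    return stack.map_layers(resample)


def build_study_mask(
    depth: EnvLayer,
    dist_to_shore: EnvLayer,
    substrate: EnvLayer,
    lats: np.ndarray,
    depth_max_m: float = 100.0,
    shore_km: float = 10.0,
    lat_min_deg: float = 30.0,
) -> StudyMask:
    """Coastal study-area mask.

    A cell is included when it is shallow (0–``depth_max_m`` m, depth
    positive down, inclusive at both ends) **or** its centre lies within
    ``shore_km`` of the shoreline, **and** its substrate is erosional
    (rocky), **and** its centre latitude is >= ``lat_min_deg``.  Inclusion
    additionally requires validity in all three auxiliary layers.
    """
    grid = depth.grid
    grid.require_compatible(dist_to_shore.grid, "dist_to_shore")
    grid.require_compatible(substrate.grid, "substrate")
    lats = np.asarray(lats, dtype=float)
    if lats.shape != grid.shape:
        raise GridConflictError(
            f"latitude field shape {lats.shape} does not match grid {grid.shape}"
        )
    sub_vals = substrate.values[substrate.valid_mask]
    known = np.isin(sub_vals, (SUBSTRATE_EROSIONAL, SUBSTRATE_DEPOSITIONAL))
    if not known.all():
        bad = np.unique(sub_vals[~known])
        raise DataError(f"substrate codes outside erosional/depositional: {bad}")

    aux_valid = depth.valid_mask & dist_to_shore.valid_mask & substrate.valid_mask
    depth_ok = aux_valid & (depth.values >= 0) & (depth.values <= depth_max_m)
    shore_ok = aux_valid & (dist_to_shore.values <= shore_km)
    erosional = aux_valid & (substrate.values == SUBSTRATE_EROSIONAL)
    north = lats >= lat_min_deg
    included = (depth_ok | shore_ok) & erosional & north
    return StudyMask(
        included=included,
        depth_ok=depth_ok,
        shore_ok=shore_ok,
        erosional=erosional,
        north_of_lat_min=north,
        grid=grid,
    )
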