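"""Spatial frame and raster containers.

A :class:`GridSpec` is the single spatial frame that every layer, mask and
cell index in an analysis refers to: a north-up rectilinear grid in either
geographic coordinates (WGS84 longitude/latitude degrees) or the North Pole
Lambert Azimuthal Equal-Area projection (kilometres from the pole).

Coordinate reference systems are identified by short strings:

``"geographic"``
    Plate-carree lon/lat grid, cell size in decimal degrees.
``"laea_north_pole"``
    Spherical Lambert azimuthal equal-area projection centred on the North
    Pole (longitude of origin 0°E), coordinates in km.  On the sphere this
    projection is exactly area-preserving, so habitat area is cell count
    multiplied by one constant cell area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import ConfigurationError, DataError, GridConflictError

# Mean Earth radius (km), IUGG value; the spherical LAEA below uses it.
EARTH_RADIUS_KM = 6371.0088

#: nominal km per degree of latitude on the sphere
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0

GEOGRAPHIC = "geographic"
LAEA_NORTH_POLE = "laea_north_pole"

_KNOWN_CRS = (GEOGRAPHIC, LAEA_NORTH_POLE)


def laea_forward(lon_deg, lat_deg):
    """Project lon/lat (degrees) to north-polar LAEA x/y in km.

    rho = 2R sin((90 - lat)/2); x = rho sin(lon); y = -rho cos(lon).
    """
    lon = np.deg2rad(np.asarray(lon_deg, dtype=float))
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    rho = 2.0 * EARTH_RADIUS_KM * np.sin((np.pi / 2.0 - lat) / 2.0)
    return rho * np.sin(lon), -rho * np.cos(lon)


def laea_inverse(x_km, y_km):
    """Inverse of :func:`laea_forward`; returns (lon_deg, lat_deg)."""
    x = np.asarray(x_km, dtype=float)
    y = np.asarray(y_km, dtype=float)
    rho = np.hypot(x, y)
    # clamp: points beyond the antipode horizon cannot occur on valid grids
    arg = np.clip(rho / (2.0 * EARTH_RADIUS_KM), -1.0, 1.0)
    lat = np.pi / 2.0 - 2.0 * np.arcsin(arg)
    lon = np.where(rho > 0, np.arctan2(x, -y), 0.0)
    return np.rad2deg(lon), np.rad2deg(lat)


@dataclass(frozen=True)
class GridSpec:
    """North-up rectilinear grid definition.

    Parameters
    ----------
    crs_id
        ``"geographic"`` or ``"laea_north_pole"``.
    x0, y_top
        Coordinates of the outer corner of cell (row 0, col 0): left edge
        and top edge.  Degrees for geographic grids, km for projected ones.
    dx, dy
        Cell width and height (positive; rows run from y_top downward).
    n_rows, n_cols
        Grid dimensions.
    nodata_sentinel
        Value written to rasters to mark invalid cells.
    """

    crs_id: str
    x0: float
    y_top: float
    dx: float
    dy: float
    n_rows: int
    n_cols: int
    nodata_sentinel: float = -9999.0

    def __post_init__(self):
        if self.crs_id not in _KNOWN_CRS:
            raise ConfigurationError(
                f"unknown CRS identifier {self.crs_id!r}; expected one of {_KNOWN_CRS}"
            )
        if self.dx <= 0 or self.dy <= 0 or self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigurationError("grid dimensions and cell size must be positive")

    # ---- derived geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        """Area of one cell in km².

        Exact and constant for the equal-area projection; for geographic
        grids this is the nominal equatorial value (dx*dy deg² scaled), kept
        positive so the GridSpec invariant holds, but area accounting should
        be done on equal-area grids only.
        """
        if self.crs_id == LAEA_NORTH_POLE:
            return self.dx * self.dy
        return self.dx * self.dy * KM_PER_DEG**2

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all cell centres, shape (n_rows, n_cols)."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.dx
        ys = self.y_top - (np.arange(self.n_rows) + 0.5) * self.dy
        return np.meshgrid(xs, ys)

    def rowcol_to_xy(self, rows, cols):
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        return (
            self.x0 + (cols + 0.5) * self.dx,
            self.y_top - (rows + 0.5) * self.dy,
        )

    def xy_to_rowcol(self, x, y):
        """Cell index of a point; half-open cells, left/top edge inclusive.

        Returns (rows, cols) as int arrays; points outside the grid get
        indices outside [0, n_rows) / [0, n_cols).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cols = np.floor((x - self.x0) / self.dx).astype(int)
        rows = np.floor((self.y_top - y) / self.dy).astype(int)
        return rows, cols

    def inside(self, rows, cols):
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        return (rows >= 0) & (rows < self.n_rows) & (cols >= 0) & (cols < self.n_cols)

    def centre_lonlat(self) -> tuple[np.ndarray, np.ndarray]:
        """Geographic (lon, lat) of every cell centre."""
        x, y = self.cell_centres()
        if self.crs_id == GEOGRAPHIC:
            return x, y
        return laea_inverse(x, y)

    def compatible(self, other: "GridSpec") -> bool:
        return (
            self.crs_id == other.crs_id
            and self.shape == other.shape
            and np.allclose(
                [self.x0, self.y_top, self.dx, self.dy],
                [other.x0, other.y_top, other.dx, other.dy],
            )
        )

    def require_compatible(self, other: "GridSpec", what: str = "layer") -> None:
        if not self.compatible(other):
            raise GridConflictError(
                f"{what} grid {other.shape} @({other.x0},{other.y_top}) does not "
                f"match reference grid {self.shape} @({self.x0},{self.y_top})"
            )


@dataclass
class EnvLayer:
    """One named environmental variable on a grid.

    ``values`` holds per-cell reals; ``valid_mask`` is True where the value
    is meaningful.  Values under an invalid mask are never read.
    """

    name: str
    values: np.ndarray
    valid_mask: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.valid_mask.shape != self.grid.shape:
            raise GridConflictError(
                f"layer {self.name!r} shape {self.values.shape} does not match "
                f"grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise DataError(
                f"layer {self.name!r} contains non-finite values inside its valid mask"
            )

    def copy_with(self, **kw) -> "EnvLayer":
        out = EnvLayer(
            name=kw.get("name", self.name),
            values=kw.get("values", self.values.copy()),
            valid_mask=kw.get("valid_mask", self.valid_mask.copy()),
            grid=kw.get("grid", self.grid),
        )
        return out


class ScenarioStack:
    """Ordered collection of :class:`EnvLayer` on one grid for one scenario."""

    def __init__(self, scenario_id: str, layers: list[EnvLayer]):
        if not layers:
            raise GridConflictError("a ScenarioStack needs at least one layer")
        self.scenario_id = scenario_id
        grid = layers[0].grid
        names = set()
        for lyr in layers:
            grid.require_compatible(lyr.grid, what=f"layer {lyr.name!r}")
            if lyr.name in names:
                raise GridConflictError(f"duplicate layer name {lyr.name!r} in stack")
            names.add(lyr.name)
        self.grid = grid
        self._layers: dict[str, EnvLayer] = {lyr.name: lyr for lyr in layers}

    @property
    def layer_names(self) -> list[str]:
        return list(self._layers)

    def __getitem__(self, name: str) -> EnvLayer:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self) -> Iterator[EnvLayer]:
        return iter(self._layers.values())

    def __len__(self) -> int:
        return len(self._layers)

    def joint_valid_mask(self, names: list[str] | None = None) -> np.ndarray:
        """Cells valid in every (selected) layer.

        Any cell invalid in any selected covariate is excluded from
        modelling and background.
        """
        names = names if names is not None else self.layer_names
        mask = np.ones(self.grid.shape, dtype=bool)
        for n in names:
            mask &= self._layers[n].valid_mask
        return mask

    def map_layers(self, fn, scenario_id: str | None = None) -> "ScenarioStack":
        """New stack with ``fn(layer) -> EnvLayer`` applied to each layer."""
        return ScenarioStack(
            scenario_id if scenario_id is not None else self.scenario_id,
            [fn(lyr) for lyr in self],
        )


# substrate codes used in rasters: the study keeps only erosional (rocky) coast
SUBSTRATE_EROSIONAL = 1.0
SUBSTRATE_DEPOSITIONAL = 0.0


@dataclass
class StudyMask:
    """Cells retained for modelling, with per-criterion provenance."""

    included: np.ndarray
    depth_ok: np.ndarray
    shore_ok: np.ndarray
    erosional: np.ndarray
    north_of_lat_min: np.ndarray
    grid: GridSpec

    @property
    def n_cells(self) -> int:
        return int(self.included.sum())

    def cell_indices(self) -> np.ndarray:
        """(n, 2) array of (row, col) of included cells, row-major order."""
        return np.argwhere(self.included)

    def area_km2(self) -> float:
        return self.n_cells * self.grid.cell_area_km2
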