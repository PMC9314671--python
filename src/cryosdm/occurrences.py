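"""Occurrence handling: CSV input, per-cell deduplication, target-group background.

Records falling within the same grid cell count as a single occurrence for
model training, and the pooled presence cells of all modelled species form
the target-group background, so that spatial survey bias affects presences
and background alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyBackgroundError, EmptyPresenceError, SchemaError
from .grid import GridSpec, StudyMask

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    lon: float
    lat: float
    year: int | None = None
    source: str = ""


@dataclass
class PresenceCells:
    """Deduplicated, mask-resolved presences for one species.

    ``cells`` holds (row, col) tuples inside the study mask; ``n_raw``
    counts raw records before deduplication; ``n_outside_mask`` counts
    records dropped because they fell outside the masked study area.
    """

    species: str
    cells: set[tuple[int, int]]
    n_raw: int
    n_outside_mask: int = 0

    @property
    def n(self) -> int:
        return len(self.cells)

    def cell_array(self) -> np.ndarray:
        """(n, 2) row/col array in deterministic (row-major) order."""
        return np.array(sorted(self.cells), dtype=int).reshape(-1, 2)


@dataclass
class BackgroundCells:
    cells: set[tuple[int, int]]

    @property
    def n(self) -> int:
        return len(self.cells)

    def cell_array(self) -> np.ndarray:
        return np.array(sorted(self.cells), dtype=int).reshape(-1, 2)


def read_occurrences(path, min_year: int | None = None) -> list[OccurrenceRecord]:
    """Read an occurrence CSV (``species,longitude,latitude[,year,source]``).

    Rows with unparseable or out-of-range coordinates are skipped with a
    logged count.  ``min_year`` optionally drops records older than a year
    (off by default; most compiled records are modern, and models train on
    all of them unless asked otherwise).
    """
    df = pd.read_csv(path)
    required = {"species", "longitude", "latitude"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"occurrence file {path} lacks columns {sorted(missing)}")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    ok = lon.between(-180, 180) & lat.between(-90, 90)
    years = (
        pd.to_numeric(df["year"], errors="coerce")
        if "year" in df.columns
        else pd.Series([np.nan] * len(df))
    )
    if min_year is not None:
        ok &= years >= min_year
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("skipped %d occurrence rows with invalid coordinates%s",
                    n_bad, "" if min_year is None else " or year")
    records = []
    sources = df["source"] if "source" in df.columns else None
    for i in np.where(ok.to_numpy())[0]:
        yr = years.iloc[i]
        records.append(
            OccurrenceRecord(
                species=str(df["species"].iloc[i]),
                lon=float(lon.iloc[i]),
                lat=float(lat.iloc[i]),
                year=int(yr) if np.isfinite(yr) else None,
                source=str(sources.iloc[i]) if sources is not None else "",
            )
        )
    return records


def dedup_to_cells(
    records: list[OccurrenceRecord], grid: GridSpec, mask: StudyMask
) -> PresenceCells:
    """Resolve records to unique masked grid cells.

    Cell assignment uses half-open cell intervals (left/top edge inclusive).
    Records landing outside the study mask — on land, too deep and far from
    shore, depositional substrate, or south of the latitude cut — are
    dropped and counted in ``n_outside_mask``.
    """
    if not records:
        raise EmptyPresenceError("no occurrence records supplied")
    species = records[0].species
    for r in records:
        if r.species != species:
            raise SchemaError(
                f"dedup_to_cells expects a single species; got {species!r} and {r.species!r}"
            )
    lons = np.array([r.lon for r in records])
    lats = np.array([r.lat for r in records])
    if grid.crs_id == "geographic":
        rows, cols = grid.xy_to_rowcol(lons, lats)
    else:
        from .grid import laea_forward

        x, y = laea_forward(lons, lats)
        rows, cols = grid.xy_to_rowcol(x, y)
    inside = grid.inside(rows, cols)
    in_mask = np.zeros(len(records), dtype=bool)
    in_mask[inside] = mask.included[rows[inside], cols[inside]]
    cells = {(int(r), int(c)) for r, c in zip(rows[in_mask], cols[in_mask])}
    n_out = int((~in_mask).sum())
    if n_out:
        log.info("%s: %d of %d records fall outside the study mask and were dropped",
                 species, n_out, len(records))
    if not cells:
        raise EmptyPresenceError(
            f"species {species!r}: no record survives masking; unmodellable"
        )
    return PresenceCells(species=species, cells=cells, n_raw=len(records),
                         n_outside_mask=n_out)


def target_group_background(all_species: list[PresenceCells]) -> BackgroundCells:
    """Union of every species' presence cells (the modelled species included)."""
    cells: set[tuple[int, int]] = set()
    for pc in all_species:
        cells |= pc.cells
    if not cells:
        raise EmptyBackgroundError("target-group background is empty")
    return BackgroundCells(cells=cells)


def presence_table(pc: PresenceCells, grid: GridSpec) -> pd.DataFrame:
    """Audit table of presence cells with cell-centre coordinates."""
    arr = pc.cell_array()
    x, y = grid.rowcol_to_xy(arr[:, 0], arr[:, 1])
    if grid.crs_id == "geographic":
        lon, lat = x, y
    else:
        from .grid import laea_inverse

        lon, lat = laea_inverse(x, y)
    return pd.DataFrame(
        {
            "species": pc.species,
            "cell_row": arr[:, 0],
            "cell_col": arr[:, 1],
            "lon": lon,
            "lat": lat,
        }
    )
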