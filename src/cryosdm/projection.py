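"""Range projection: thresholding, stacking, change maps, area accounting.

Continuous suitability maps are binarised at each species' max-SSS
threshold (inclusive: suitability >= threshold counts as presence),
stacked within thermal-affinity categories as a cellwise union, and
summarised as occupied area — cell count times the constant equal-area
cell size — northwards of each 10-degree latitude cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StackingError, SummaryError, UndefinedChangeError
from .grid import StudyMask

DEFAULT_LAT_CUTOFFS = (30, 40, 50, 60, 70, 80)

CHANGE_ABSENT = 0
CHANGE_STABLE = 1
CHANGE_LOSS = 2
CHANGE_GAIN = 3


@dataclass
class RangeProjection:
    """One species' projection under one scenario."""

    species: str
    scenario_id: str
    suitability: np.ndarray  # per-cell real (nodata outside mask is fine)
    binary: np.ndarray  # per-cell {0,1}
    threshold: float


@dataclass
class StackedProjection:
    """Union of member species' binary maps for one category and scenario."""

    category: str
    scenario_id: str
    binary: np.ndarray


def apply_threshold(
    suitability: np.ndarray, threshold: float, mask: StudyMask
) -> np.ndarray:
    """Binary map: 1 where suitability >= threshold inside the study mask."""
    if not np.isfinite(threshold):
        raise UndefinedChangeError(f"threshold must be finite, got {threshold}")
    return ((suitability >= threshold) & mask.included).astype(np.int8)


def stack_binary(maps: list[np.ndarray]) -> np.ndarray:
    """Cellwise union of binary maps (1 where at least one species occurs)."""
    if not maps:
        raise StackingError("cannot stack an empty list of maps")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise StackingError(f"map shapes differ: {m.shape} vs {shape}")
    return (np.sum(maps, axis=0) > 0).astype(np.int8)


def change_classification(present: np.ndarray, future: np.ndarray) -> np.ndarray:
    """Per-cell range change: absent 0->0, stable 1->1, loss 1->0, gain 0->1."""
    if present.shape != future.shape:
        raise StackingError(f"map shapes differ: {present.shape} vs {future.shape}")
    p = present > 0
    f = future > 0
    out = np.full(p.shape, CHANGE_ABSENT, dtype=np.int8)
    out[p & f] = CHANGE_STABLE
    out[p & ~f] = CHANGE_LOSS
    out[~p & f] = CHANGE_GAIN
    return out


def area_above_latitude(
    values: np.ndarray, lats: np.ndarray, cutoff_deg: float, cell_area_km2: float
) -> float:
    """Sum of per-cell values at/above the latitude cut, times cell area.

    Works for binary maps (occupied area) and probabilistic maps (expected
    area) alike.
    """
    if values.shape != lats.shape:
        raise SummaryError(f"map shape {values.shape} != latitude shape {lats.shape}")
    sel = lats >= cutoff_deg
    return float(values[sel].sum() * cell_area_km2)


def percent_change(area_present: float, area_future: float) -> float:
    """100 * (future - present) / present; undefined for zero present area."""
    if area_present <= 0:
        raise UndefinedChangeError("percent change undefined for zero present-day area")
    return 100.0 * (area_future - area_present) / area_present


def summarise(
    projections: dict[tuple[str, str], RangeProjection],
    categories: dict[str, str],
    lats: np.ndarray,
    cell_area_km2: float,
    lat_cutoffs=DEFAULT_LAT_CUTOFFS,
    stack_categories: tuple[str, ...] = ("cryophilic", "cryotolerant"),
    present_id: str = "present",
    probabilistic: bool = False,
) -> pd.DataFrame:
    """Area table per species and per stacked category.

    ``projections`` maps (species, scenario_id) to a projection; every
    species needs a present-day entry.  Stacks are built per category for
    the categories in ``stack_categories`` (cryophobic species are
    reported individually, never stacked, because their trends diverge).
    Columns: name, kind, category, scenario_id, lat_cutoff_deg, area_km2,
    pct_change_vs_present.
    """
    species = sorted({sp for sp, _ in projections})
    scenarios = sorted({sc for _, sc in projections})
    for sp in species:
        if (sp, present_id) not in projections:
            raise SummaryError(f"species {sp!r} lacks a {present_id!r} projection")

    def values_of(proj: RangeProjection) -> np.ndarray:
        return proj.suitability if probabilistic else proj.binary

    rows = []

    def add_rows(name, kind, category, value_maps: dict[str, np.ndarray]):
        present_areas = {
            c: area_above_latitude(value_maps[present_id], lats, c, cell_area_km2)
            for c in lat_cutoffs
        }
        for sc in scenarios:
            if sc not in value_maps:
                continue
            for c in lat_cutoffs:
                area = area_above_latitude(value_maps[sc], lats, c, cell_area_km2)
                pct = np.nan
                if sc != present_id and present_areas[c] > 0:
                    pct = percent_change(present_areas[c], area)
                rows.append(
                    {
                        "name": name,
                        "kind": kind,
                        "category": category,
                        "scenario_id": sc,
                        "lat_cutoff_deg": c,
                        "area_km2": area,
                        "pct_change_vs_present": pct,
                    }
                )

    for sp in species:
        maps = {
            sc: values_of(projections[(sp, sc)])
            for sc in scenarios
            if (sp, sc) in projections
        }
        add_rows(sp, "species", categories.get(sp, ""), maps)

    if not probabilistic:
        for cat in stack_categories:
            members = [sp for sp in species if categories.get(sp) == cat]
            if not members:
                continue
            maps = {}
            for sc in scenarios:
                member_maps = [
                    projections[(sp, sc)].binary
                    for sp in members
                    if (sp, sc) in projections
                ]
                if member_maps:
                    maps[sc] = stack_binary(member_maps)
            add_rows(f"stacked_{cat}", "stack", cat, maps)

    return pd.DataFrame(rows)
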