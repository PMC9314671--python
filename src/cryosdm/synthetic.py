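"""Synthetic seascapes, climate scenarios, and virtual species.

The generator produces a closed, self-consistent world in which the whole
pipeline can be exercised and validated against known truth:

* a smoothed random land/sea field with depth increasing offshore,
  shore-distance and patchy erosional/depositional substrate;
* five environmental layers mirroring the benthic variable suite used for
  Arctic marine-forest modelling (long-term minimum/maximum bottom
  temperature, mean bottom salinity, minimum/maximum ice thickness) with a
  latitudinal temperature gradient and ice negatively coupled to
  temperature;
* warming scenarios (uniform temperature offset, multiplicative ice
  reduction) standing in for the RCP layer sets;
* virtual species whose true suitability is a known product of logistic
  responses, in three thermal-affinity archetypes — cryophilic (confined
  to sub-zero minimum temperatures, ice-associated), cryotolerant (broad
  tolerance with a warm southern limit) and cryophobic (excluded from
  sub-zero water);
* biased presence sampling emulating survey effort concentrated at
  accessible southern latitudes.

All stochastic operations take explicit seeds and are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError, SamplingError, SeedError
from .grid import (
    GEOGRAPHIC,
    KM_PER_DEG,
    SUBSTRATE_DEPOSITIONAL,
    SUBSTRATE_EROSIONAL,
    EnvLayer,
    GridSpec,
    ScenarioStack,
)
from .occurrences import OccurrenceRecord

LAYER_NAMES = (
    "lt_min_bottom_temp",
    "lt_max_bottom_temp",
    "mean_bottom_salinity",
    "lt_min_ice_thickness",
    "lt_max_ice_thickness",
)

CATEGORIES = ("cryophilic", "cryotolerant", "cryophobic")


def _smooth_field(rng, shape, corr_cells: float) -> np.ndarray:
    """Standardised kernel-smoothed white noise (unit variance, zero mean)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_cells)
    return (f - f.mean()) / f.std()


@dataclass
class Seascape:
    depth: EnvLayer  # m, positive down; nodata on land
    dist_to_shore: EnvLayer  # km from cell centre to nearest land cell centre
    substrate: EnvLayer  # erosional=1 / depositional=0
    sea: np.ndarray  # boolean
    grid: GridSpec


@dataclass(frozen=True)
class ScenarioParams:
    """Field-generation and scenario-perturbation parameters."""

    delta_temp_C: float = 0.0
    ice_scale: float = 1.0
    noise_sd: float = 1.5  # deg C, spatial noise on temperature fields
    spatial_corr_length: float = 6.0  # degrees, physical smoothing radius
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.ice_scale <= 1.0):
            raise ParameterError("ice_scale must lie in [0, 1]")
        if self.spatial_corr_length <= 0:
            raise ParameterError("spatial_corr_length must be positive")


def generate_seascape(
    n_rows: int,
    n_cols: int,
    seed: int,
    lat_min: float = 25.0,
    lat_max: float = 85.0,
    lon_min: float = -180.0,
    land_frac: float = 0.35,
    corr_deg: float = 6.0,
    depth_slope_m_per_km: float = 1.5,
    erosional_frac: float = 0.6,
) -> Seascape:
    """Generate land/sea, depth, shore distance and substrate layers.

    The grid is geographic with square cells spanning ``lat_min``–
    ``lat_max``.  Depth is zero in sea cells adjacent to land and grows
    linearly with distance offshore (with multiplicative spatial noise);
    distance-to-shore uses an equirectangular metric (km per degree of
    longitude evaluated at the mid-latitude).  Substrate is assigned in
    contiguous erosional/depositional patches from an independent smoothed
    field.
    """
    cell_deg = (lat_max - lat_min) / n_rows
    grid = GridSpec(
        crs_id=GEOGRAPHIC,
        x0=lon_min,
        y_top=lat_max,
        dx=cell_deg,
        dy=cell_deg,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    rng = np.random.default_rng(seed)
    corr_cells = max(corr_deg / cell_deg, 1.0)
    sea = None
    for _ in range(10):
        f = _smooth_field(rng, grid.shape, corr_cells)
        thresh = np.quantile(f, 1.0 - land_frac)
        land = f > thresh
        if land.any() and (~land).any():
            sea = ~land
            break
    if sea is None:
        raise SeedError("could not draw a mixed land/sea field in 10 attempts")

    dy_km = cell_deg * KM_PER_DEG
    mid_lat = 0.5 * (lat_min + lat_max)
    dx_km = dy_km * np.cos(np.deg2rad(mid_lat))
    dist = ndimage.distance_transform_edt(sea, sampling=(dy_km, dx_km))

    adj_km = max(dx_km, dy_km)  # any 4-adjacent sea cell is within this
    depth = depth_slope_m_per_km * np.maximum(0.0, dist - adj_km)
    depth *= np.clip(1.0 + 0.25 * _smooth_field(rng, grid.shape, corr_cells), 0.1, None)

    sub_field = _smooth_field(rng, grid.shape, corr_cells)
    erosional = sub_field <= np.quantile(sub_field, erosional_frac)
    substrate = np.where(erosional, SUBSTRATE_EROSIONAL, SUBSTRATE_DEPOSITIONAL)

    def sea_layer(name, vals):
        return EnvLayer(
            name=name,
            values=np.where(sea, vals, grid.nodata_sentinel),
            valid_mask=sea.copy(),
            grid=grid,
        )

    return Seascape(
        depth=sea_layer("depth", depth),
        dist_to_shore=sea_layer("dist_to_shore", dist),
        substrate=sea_layer("substrate", substrate),
        sea=sea,
        grid=grid,
    )


def generate_env(
    seascape: Seascape,
    params: ScenarioParams,
    latitude_gradient: float = -0.65,
    temp_south: float = 14.0,
    temp_floor: float = -2.0,
    temp_mid_lat: float = 45.0,
    seasonal_offset: float = 6.0,
    freezing_offset: float = 0.0,
    ice_per_degree: float = 0.5,
) -> ScenarioStack:
    """Present-day environmental stack on the seascape's grid.

    Minimum bottom temperature follows a sigmoid latitudinal profile —
    warm (``temp_south``) at the southern edge, dropping at up to
    ``latitude_gradient`` deg C per degree around ``temp_mid_lat`` and
    plateauing near the freezing point (``temp_floor``) across the high
    Arctic, as real benthic minima do — plus smoothed spatial noise.  The
    maximum sits a seasonal offset above it.  Maximum ice thickness is
    max(0, freezing_offset - t_min) * ice_per_degree with multiplicative
    variability — zero wherever the minimum temperature exceeds the
    freezing offset — and minimum ice is a regionally varying fraction of
    it.  Salinity is an independent shorter-range field.
    """
    grid = seascape.grid
    rng = np.random.default_rng(params.seed)
    _, lats = grid.centre_lonlat()
    sigma = max(params.spatial_corr_length / grid.dy, 1.0)

    from scipy.special import expit

    span = temp_south - temp_floor
    width = span / (4.0 * abs(latitude_gradient))  # max slope = gradient
    t_min = (
        temp_floor
        + span * expit((temp_mid_lat - lats) / width)
        + params.noise_sd * _smooth_field(rng, grid.shape, sigma)
    )
    t_max = t_min + seasonal_offset + 0.5 * np.abs(_smooth_field(rng, grid.shape, sigma))
    # ice varies substantially around its thermal envelope (winds, currents,
    # freshwater input), so ice carries signal not recoverable from
    # temperature alone
    ice_noise = np.clip(1.0 + 0.9 * _smooth_field(rng, grid.shape, sigma), 0.0, None)
    ice_max = ice_per_degree * np.maximum(0.0, freezing_offset - t_min) * ice_noise
    # the winter-minimum share of maximum ice varies regionally, so the two
    # ice layers are correlated but far from collinear
    ice_frac = np.clip(
        0.45 + 0.25 * _smooth_field(rng, grid.shape, max(sigma / 2.0, 1.0)), 0.02, 0.95
    )
    ice_min = ice_max * ice_frac
    # salinity: independent field with shorter-range structure (river plumes,
    # local mixing) than the basin-scale temperature noise
    salinity = 32.0 + 2.5 * _smooth_field(rng, grid.shape, max(sigma / 2.0, 1.0))

    sea = seascape.sea

    def sea_layer(name, vals):
        return EnvLayer(
            name=name,
            values=np.where(sea, vals, grid.nodata_sentinel),
            valid_mask=sea.copy(),
            grid=grid,
        )

    return ScenarioStack(
        "present",
        [
            sea_layer("lt_min_bottom_temp", t_min),
            sea_layer("lt_max_bottom_temp", t_max),
            sea_layer("mean_bottom_salinity", salinity),
            sea_layer("lt_min_ice_thickness", ice_min),
            sea_layer("lt_max_ice_thickness", ice_max),
        ],
    )


def apply_scenario(
    present: ScenarioStack, params: ScenarioParams, scenario_id: str = "future"
) -> ScenarioStack:
    """Warmed scenario: temperatures + delta, ice scaled down, salinity kept."""

    def transform(lyr: EnvLayer) -> EnvLayer:
        vals = lyr.values.copy()
        if "temp" in lyr.name:
            vals = np.where(lyr.valid_mask, vals + params.delta_temp_C, vals)
        elif "ice" in lyr.name:
            vals = np.where(lyr.valid_mask, vals * params.ice_scale, vals)
        return EnvLayer(
            name=lyr.name, values=vals, valid_mask=lyr.valid_mask.copy(), grid=lyr.grid
        )

    return present.map_layers(transform, scenario_id=scenario_id)


# Scenario suite standing in for the RCP x horizon layer sets.  The
# strongest case (rcp85_2100) is the +3 deg C / 70% ice-loss world used for
# trend-recovery checks.
DEFAULT_SCENARIOS: dict[str, ScenarioParams] = {
    "rcp26_2050": ScenarioParams(delta_temp_C=0.6, ice_scale=0.88),
    "rcp45_2050": ScenarioParams(delta_temp_C=1.0, ice_scale=0.80),
    "rcp60_2050": ScenarioParams(delta_temp_C=1.3, ice_scale=0.74),
    "rcp85_2050": ScenarioParams(delta_temp_C=1.8, ice_scale=0.62),
    "rcp26_2100": ScenarioParams(delta_temp_C=1.0, ice_scale=0.80),
    "rcp45_2100": ScenarioParams(delta_temp_C=2.0, ice_scale=0.55),
    "rcp60_2100": ScenarioParams(delta_temp_C=2.5, ice_scale=0.45),
    "rcp85_2100": ScenarioParams(delta_temp_C=3.0, ice_scale=0.30),
}


@dataclass
class VirtualSpecies:
    """A species with a known multiplicative logistic niche.

    ``response`` maps covariate name to (midpoint, slope): the factor is
    1 / (1 + exp(-slope * (x - midpoint))); negative slope = decreasing.
    True suitability is the product over responses, in [0, 1].
    """

    name: str
    category: str
    response: dict[str, tuple[float, float]]

    def true_suitability(self, stack: ScenarioStack) -> np.ndarray:
        """Per-cell truth on the stack's grid; NaN where any layer is invalid."""
        from scipy.special import expit

        valid = stack.joint_valid_mask(list(self.response))
        suit = np.ones(stack.grid.shape)
        for cov, (mid, slope) in self.response.items():
            x = stack[cov].values
            suit *= expit(slope * (x - mid))
        return np.where(valid, suit, np.nan)

    def true_range(self, stack: ScenarioStack) -> np.ndarray:
        """Boolean map of the true range (suitability > 0.5)."""
        s = self.true_suitability(stack)
        return np.isfinite(s) & (s > 0.5)


_DEFAULT_RESPONSES = {
    # cryophilic: confined below 0 deg C minimum temperature (the midpoint
    # pins the range boundary; the gentle slope leaves ice as the dominant
    # driver, as for Arctic-endemic seaweeds whose phenology tracks ice
    # cover)
    "cryophilic": {
        "lt_min_bottom_temp": (0.0, -0.6),
        "lt_max_ice_thickness": (1.2, 6.0),
        "mean_bottom_salinity": (33.0, 0.5),
    },
    # cryotolerant: broad thermal plateau with a warm southern limit on
    # maximum temperature; distribution shaped mainly by salinity, the
    # dominant driver for species tolerant of a wide temperature range.
    # The salinity direction alternates per species (fully-marine vs
    # brackish-tolerant), keeping the pooled community background neutral
    # in salinity — without that heterogeneity the target-group background
    # would itself be salinity-enriched and every below-average species
    # would be fitted with an inverted response.
    "cryotolerant": {
        "lt_max_bottom_temp": (18.0, -0.6),
        "mean_bottom_salinity": (33.0, 1.1),
    },
    # cryophobic: excluded from sub-zero minimum temperatures (midpoint 0,
    # increasing); broad warm archetype with a salinity preference of
    # per-species direction, as for cold-temperate macroalgae
    "cryophobic": {
        "lt_min_bottom_temp": (0.0, 0.8),
        "mean_bottom_salinity": (33.0, 1.0),
    },
}


def make_virtual_species(
    category: str,
    stack: ScenarioStack,
    response_params: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    name: str | None = None,
) -> VirtualSpecies:
    """Create a virtual species of one archetype and verify its invariants.

    Without explicit ``response_params`` the archetype defaults are jittered
    per species (seeded): slopes scaled by U(0.85, 1.2) and the thermal
    midpoint shifted within the side of 0 deg C that preserves the
    archetype's confinement (cryophilic ranges stay inside sub-zero water,
    cryophobic ranges inside above-zero water, exactly).
    """
    if category not in CATEGORIES:
        raise ParameterError(f"unknown category {category!r}")
    rng = np.random.default_rng(seed)
    if response_params is None:
        # midpoint jitter scaled to each covariate's typical field variation
        jitter_scale = {
            "lt_max_bottom_temp": 1.0,
            "mean_bottom_salinity": 0.75,
            "lt_max_ice_thickness": 0.2,
        }
        response_params = {}
        for cov, (mid, slope) in _DEFAULT_RESPONSES[category].items():
            slope *= rng.uniform(0.85, 1.2)
            if cov == "lt_min_bottom_temp" and category == "cryophilic":
                mid = -rng.uniform(0.0, 0.6)
            elif cov == "lt_min_bottom_temp" and category == "cryophobic":
                mid = rng.uniform(0.0, 0.6)
            elif cov == "mean_bottom_salinity":
                # fully-marine vs brackish-tolerant, equal odds; midpoint
                # mirrored about the basin mean so contrast stays comparable
                direction = 1.0 if rng.random() < 0.5 else -1.0
                slope *= direction
                mid = 32.0 + direction + rng.uniform(-1.0, 1.0) * jitter_scale[cov]
            else:
                mid += rng.uniform(-1.0, 1.0) * jitter_scale[cov]
            response_params[cov] = (mid, slope)
    vs = VirtualSpecies(
        name=name or f"{category}_vs{seed}", category=category, response=response_params
    )
    rng_map = vs.true_range(stack)
    if not rng_map.any():
        raise ParameterError(
            f"virtual species {vs.name!r}: true range empty on this stack"
        )
    t_min = stack["lt_min_bottom_temp"].values
    if category == "cryophilic" and not np.all(t_min[rng_map] < 0):
        raise ParameterError(f"{vs.name!r}: cryophilic range leaks above 0 deg C")
    if category == "cryophobic" and not np.all(t_min[rng_map] > 0):
        raise ParameterError(f"{vs.name!r}: cryophobic range leaks below 0 deg C")
    return vs


def default_bias_field(grid: GridSpec, efold_deg: float = 60.0) -> np.ndarray:
    """South-heavy survey-effort weights (exponential decay with latitude)."""
    _, lats = grid.centre_lonlat()
    return np.exp(-(lats - lats.min()) / efold_deg)


def sample_presences(
    vs: VirtualSpecies,
    stack: ScenarioStack,
    n: int,
    bias_field: np.ndarray | None = None,
    seed: int = 0,
    domain: np.ndarray | None = None,
) -> list[OccurrenceRecord]:
    """Draw ``n`` presence cells without replacement, prob ∝ truth × bias.

    ``domain`` restricts the candidate cells (boolean grid; default: all
    cells where the truth is defined).  Records are placed at cell centres
    with uniform jitter inside the cell.
    """
    if n < 1:
        raise SamplingError("n must be >= 1")
    grid = stack.grid
    suit = vs.true_suitability(stack)
    cand = np.isfinite(suit)
    if domain is not None:
        cand &= np.asarray(domain, dtype=bool)
    w = np.where(cand, np.nan_to_num(suit), 0.0)
    if bias_field is not None:
        w = w * np.asarray(bias_field)
    flat = w.ravel()
    available = int((flat > 0).sum())
    if n > available:
        raise SamplingError(
            f"{vs.name!r}: requested {n} presences but only {available} "
            "cells have positive sampling weight"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    rows, cols = np.unravel_index(idx, grid.shape)
    x, y = grid.rowcol_to_xy(rows, cols)
    jx = rng.uniform(-0.49, 0.49, size=n) * grid.dx
    jy = rng.uniform(-0.49, 0.49, size=n) * grid.dy
    if grid.crs_id == GEOGRAPHIC:
        lon, lat = x + jx, y + jy
    else:
        from .grid import laea_inverse

        lon, lat = laea_inverse(x + jx, y + jy)
    return [
        OccurrenceRecord(species=vs.name, lon=float(lo), lat=float(la))
        for lo, la in zip(lon, lat)
    ]


# Default virtual community mirroring the modelled community's structure:
# two cryophilic, three cryotolerant and three cryophobic species, with
# presence sample sizes inside the 150-400 range typical of curated
# macroalgal records.
DEFAULT_COMMUNITY: tuple[tuple[str, int], ...] = (
    ("cryophilic", 160),
    ("cryophilic", 200),
    ("cryotolerant", 300),
    ("cryotolerant", 250),
    ("cryotolerant", 180),
    ("cryophobic", 350),
    ("cryophobic", 220),
    ("cryophobic", 160),
)


@dataclass
class SyntheticWorld:
    """A complete generated study system."""

    seascape: Seascape
    stacks: dict[str, ScenarioStack]  # scenario_id -> stack (incl. "present")
    species: list[VirtualSpecies]
    categories: dict[str, str]  # species name -> category
    records: dict[str, list[OccurrenceRecord]]
    master_seed: int


def build_synthetic_world(
    master_seed: int,
    n_rows: int = 60,
    n_cols: int = 360,
    scenario_ids: tuple[str, ...] = tuple(DEFAULT_SCENARIOS),
    community: tuple[tuple[str, int], ...] = DEFAULT_COMMUNITY,
    sample_domain: np.ndarray | None = None,
) -> SyntheticWorld:
    """Generate seascape, scenario suite, virtual community and presences.

    Presence sampling is restricted to ``sample_domain``; by default this
    is the coastal habitat band (shallow-or-nearshore, erosional, north of
    30 deg) computed on the geographic grid, since seaweeds are substrate-
    and light-limited and surveys are coastal.  Sampling is biased
    south-heavy via :func:`default_bias_field`.  All seeds derive
    deterministically from ``master_seed``.
    """
    rng = np.random.default_rng(master_seed)
    seascape = generate_seascape(n_rows, n_cols, seed=int(rng.integers(2**31)))
    present = generate_env(
        seascape, ScenarioParams(seed=int(rng.integers(2**31)))
    )
    if sample_domain is None:
        from .env_grid import build_study_mask, cell_centre_latitudes

        habitat = build_study_mask(
            seascape.depth,
            seascape.dist_to_shore,
            seascape.substrate,
            cell_centre_latitudes(seascape.grid),
        )
        sample_domain = habitat.included
    stacks = {"present": present}
    for sid in scenario_ids:
        stacks[sid] = apply_scenario(present, DEFAULT_SCENARIOS[sid], scenario_id=sid)
    bias = default_bias_field(seascape.grid)
    species: list[VirtualSpecies] = []
    categories: dict[str, str] = {}
    records: dict[str, list[OccurrenceRecord]] = {}
    counters: dict[str, int] = {}
    for cat, n_pres in community:
        counters[cat] = counters.get(cat, 0) + 1
        name = f"{cat}_{counters[cat]}"
        vs = make_virtual_species(
            cat, present, seed=int(rng.integers(2**31)), name=name
        )
        species.append(vs)
        categories[name] = cat
        records[name] = sample_presences(
            vs,
            present,
            n_pres,
            bias_field=bias,
            seed=int(rng.integers(2**31)),
            domain=sample_domain,
        )
    return SyntheticWorld(
        seascape=seascape,
        stacks=stacks,
        species=species,
        categories=categories,
        records=records,
        master_seed=master_seed,
    )
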