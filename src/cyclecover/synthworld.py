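"""Synthetic world and synthetic migratory species with known ground truth.

The generator builds everything the pipeline consumes — spatially
autocorrelated climate layers with a requested correlation structure, a
protected-area set mixing polygon and point-only records, an exhaustive
country partition — plus migratory species whose seasonal niches are known
logistic-linear functions of the climate, so parameter recovery and
coverage arithmetic can be verified end to end without any downloads.

The world is a flat Cartesian plane in km: the "longitude"/"latitude"
record columns carry plane coordinates and every cleaning rule treats them
exactly as it would geographic coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.special import expit

from .countries import CountryPartition
from .grid import ClimateStack, Grid, write_ascii_grid
from .occurrences import COLUMNS, Season
from .protection import PARecord, ProtectedAreaSet

#: Order of the corruption kinds in ``corruption_proportions``.
CORRUPTION_KINDS = ("missing_coords", "zero_zero", "coarse_uncertainty", "duplicate")


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic world.

    Climate layers are smoothed white noise (Gaussian blur of iid normal
    fields, ``smoothing_sigma_cells`` standard deviations), decorrelated and
    then re-mixed so the requested pairwise correlations are realized in the
    generated sample.  Protected areas are random circles accumulated until
    they cover ``pa_area_fraction`` of the world; a ``pa_point_fraction``
    share of them is stored as point + reported-area records (as in the
    global PA inventory, where ~9% of sites are point-only), the default
    area fraction being the 16% global terrestrial PA share.  Countries are
    the Voronoi cells of random seed points on the lattice.
    """

    grid_nrows: int = 100
    grid_ncols: int = 100
    cell_area_km2: float = 21.625
    n_climate_layers: int = 8
    collinear_pairs: tuple[tuple[int, int, float], ...] = ()
    pa_area_fraction: float = 0.16
    pa_point_fraction: float = 0.09
    n_countries: int = 10
    smoothing_sigma_cells: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nrows < 8 or self.grid_ncols < 8:
            raise ValueError("grid must be at least 8x8 for checkerboard partitioning")
        if self.n_climate_layers < 2:
            raise ValueError("need at least two climate layers")
        for frac, name in ((self.pa_area_fraction, "pa_area_fraction"),
                           (self.pa_point_fraction, "pa_point_fraction")):
            if not (0 <= frac <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_countries < 1 or self.n_countries > self.grid_nrows * self.grid_ncols:
            raise ValueError("n_countries must be in [1, n_cells]")
        for i, j, rho in self.collinear_pairs:
            if i == j or not (0 <= i < self.n_climate_layers) \
                    or not (0 <= j < self.n_climate_layers):
                raise ValueError("collinear pair indices must be distinct valid layers")
            if not (-1 < rho < 1):
                raise ValueError("target correlations must lie in (-1, 1)")


@dataclass(frozen=True)
class SeasonNiche:
    """Logistic-linear seasonal niche: logit(suitability) = b0 + Σ w·layer."""

    intercept: float
    weights: dict[str, float]


@dataclass(frozen=True)
class SpeciesSimConfig:
    """Parameters of one synthetic migratory species.

    ``contamination`` is the fraction of emitted records corrupted, split
    over the four corruption kinds (missing coordinates, (0,0) coordinates,
    coordinate uncertainty above 10 km, exact duplicates) in
    ``corruption_proportions`` (equal shares by default, so every cleaning
    rule is exercised).  Clean-record uncertainties are lognormal with the
    given median and log-sd, capped just under the 10-km cleaning cut.
    """

    name: str
    niche: dict[Season, SeasonNiche]
    records_per_season: int = 200
    contamination: float = 0.0
    corruption_proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    uncertainty_median_m: float = 300.0
    uncertainty_log_sigma: float = 1.0
    truth_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.niche:
            raise ValueError("species needs at least one seasonal niche")
        if not (0 <= self.contamination <= 1):
            raise ValueError("contamination must lie in [0, 1]")
        if abs(sum(self.corruption_proportions) - 1.0) > 1e-9:
            raise ValueError("corruption proportions must sum to 1")
        if self.records_per_season < 1:
            raise ValueError("records_per_season must be positive")


@dataclass
class World:
    grid: Grid
    config: WorldConfig
    climate: ClimateStack
    pas: ProtectedAreaSet
    countries: CountryPartition


# -- climate ---------------------------------------------------------------

def _correlation_matrix(config: WorldConfig) -> np.ndarray:
    C = np.eye(config.n_climate_layers)
    for i, j, rho in config.collinear_pairs:
        C[i, j] = C[j, i] = rho
    eig = np.linalg.eigvalsh(C)
    if eig.min() <= 1e-10:
        raise ValueError("requested correlation structure is not positive definite")
    return C


def _generate_climate(grid: Grid, config: WorldConfig, rng: np.random.Generator
                      ) -> ClimateStack:
    L = config.n_climate_layers
    fields = np.empty((grid.n_cells, L))
    for k in range(L):
        f = gaussian_filter(rng.standard_normal(grid.shape),
                            sigma=config.smoothing_sigma_cells, mode="reflect")
        fields[:, k] = f.ravel()
    # decorrelate the smoothed fields exactly, then impose the target structure
    fields -= fields.mean(axis=0)
    Q, R = np.linalg.qr(fields)
    Q = Q * np.sign(np.diag(R))  # deterministic sign convention
    Z = Q * math.sqrt(grid.n_cells)  # unit sample variance, exactly orthogonal
    C = _correlation_matrix(config)
    Y = Z @ np.linalg.cholesky(C).T
    layers = {f"bio{k + 1:02d}": Y[:, k].reshape(grid.shape) for k in range(L)}
    return ClimateStack(grid, layers)


# -- protected areas -------------------------------------------------------

def _generate_pas(grid: Grid, config: WorldConfig, rng: np.random.Generator
                  ) -> ProtectedAreaSet:
    if config.pa_area_fraction == 0:
        return ProtectedAreaSet([])
    world_box = grid.extent_box()
    target = config.pa_area_fraction * grid.total_area_km2
    cs = grid.cell_size_km
    union = shapely.Polygon()
    circles: list[tuple[float, float, float]] = []  # (cx, cy, r)
    while union.area < target:
        cx = grid.x0 + rng.uniform(0, grid.width_km)
        cy = grid.y0 + rng.uniform(0, grid.height_km)
        r = rng.uniform(2.0, 6.0) * cs
        cand = shapely.Point(cx, cy).buffer(r, quad_segs=16).intersection(world_box)
        new_union = union.union(cand)
        if new_union.area >= target:
            # shrink the final circle so realized coverage lands on target
            lo, hi = 0.0, r
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                a = union.union(
                    shapely.Point(cx, cy).buffer(mid, quad_segs=16)
                    .intersection(world_box)).area
                if a < target:
                    lo = mid
                else:
                    hi = mid
            r = hi
            new_union = union.union(
                shapely.Point(cx, cy).buffer(r, quad_segs=16).intersection(world_box))
        union = new_union
        circles.append((cx, cy, r))

    records: list[PARecord] = []
    as_point = rng.random(len(circles)) < config.pa_point_fraction
    for (cx, cy, r), pt in zip(circles, as_point):
        if pt:
            records.append(PARecord(geometry=shapely.Point(cx, cy),
                                    status="Designated", designation="National Park",
                                    reported_area_km2=math.pi * r * r))
        else:
            records.append(PARecord(
                geometry=shapely.Point(cx, cy).buffer(r, quad_segs=16),
                status="Designated", designation="National Park"))
    return ProtectedAreaSet(records)


# -- countries -------------------------------------------------------------

def _generate_countries(grid: Grid, config: WorldConfig, rng: np.random.Generator
                        ) -> CountryPartition:
    flat = rng.choice(grid.n_cells, size=config.n_countries, replace=False)
    rows, cols = np.divmod(flat, grid.ncols)
    sx, sy = grid.cell_center(rows, cols)
    tree = cKDTree(np.column_stack([sx, sy]))
    X, Y = grid.cell_centers()
    _, labels = tree.query(np.column_stack([X.ravel(), Y.ravel()]))
    ids = [f"country_{k:02d}" for k in range(config.n_countries)]
    return CountryPartition(grid, labels.reshape(grid.shape), ids)


# -- world -----------------------------------------------------------------

def generate_world(config: WorldConfig) -> World:
    """Generate the full synthetic world from one seeded configuration.

    The same config (including seed) always yields bit-identical output.
    Raises on a non-positive-definite correlation request.
    """
    rng = np.random.default_rng(config.seed)
    grid = Grid(nrows=config.grid_nrows, ncols=config.grid_ncols,
                cell_area_km2=config.cell_area_km2)
    climate = _generate_climate(grid, config, rng)
    pas = _generate_pas(grid, config, rng)
    countries = _generate_countries(grid, config, rng)
    return World(grid=grid, config=config, climate=climate, pas=pas,
                 countries=countries)


# -- species ---------------------------------------------------------------

def truth_suitability(world: World, niche: SeasonNiche) -> np.ndarray:
    """Inverse-logit of the seasonal linear predictor on the climate layers."""
    eta = np.full(world.grid.shape, niche.intercept, dtype=float)
    for name, w in niche.weights.items():
        eta += w * world.climate.layers[name]
    return expit(eta)


def _season_dates(season: Season, n: int, rng: np.random.Generator) -> list[str]:
    months = rng.choice(season.months, size=n)
    days = rng.integers(1, 29, size=n)
    years = np.where(months == 12, 2019, 2020)  # Dec opens the S1 window
    return [f"{y:04d}-{m:02d}-{d:02d}" for y, m, d in zip(years, months, days)]


def simulate_species(world: World, config: SpeciesSimConfig
                     ) -> tuple[pd.DataFrame, dict[Season, np.ndarray],
                                dict[Season, np.ndarray]]:
    """Emit occurrence records plus per-season truth maps for one species.

    Clean records are drawn per season with probability proportional to the
    truth suitability, jittered uniformly within their cell, dated inside
    the season window, with sub-10-km uncertainties.  A ``contamination``
    fraction of each season's records is then corrupted (appended after the
    clean rows) according to ``corruption_proportions``.  Returns
    (records, suitability maps, binary truth maps); the binary truth map is
    suitability > ``truth_threshold``.
    """
    rng = np.random.default_rng(config.seed)
    grid, mask = world.grid, world.climate.mask
    cs = grid.cell_size_km
    suit_maps: dict[Season, np.ndarray] = {}
    binary_maps: dict[Season, np.ndarray] = {}
    frames: list[pd.DataFrame] = []

    for season, niche in config.niche.items():
        suit = truth_suitability(world, niche)
        suit_maps[season] = suit
        binary_maps[season] = (suit > config.truth_threshold) & mask

        n_total = config.records_per_season
        n_bad = int(round(config.contamination * n_total))
        n_clean = n_total - n_bad
        if n_bad > 0 and n_clean == 0:
            raise ValueError("contamination leaves no clean records to duplicate")

        p = (suit * mask).ravel()
        p = p / p.sum()
        flat = rng.choice(grid.n_cells, size=n_clean, replace=True, p=p)
        rows, cols = np.divmod(flat, grid.ncols)
        x, y = grid.cell_center(rows, cols)
        x = x + rng.uniform(-0.5, 0.5, size=n_clean) * cs
        y = y + rng.uniform(-0.5, 0.5, size=n_clean) * cs
        unc = np.exp(rng.normal(math.log(config.uncertainty_median_m),
                                config.uncertainty_log_sigma, size=n_clean))
        unc = np.clip(unc, 1.0, 9_999.0)
        clean = pd.DataFrame({
            "species": config.name, "longitude": x, "latitude": y,
            "event_date": _season_dates(season, n_clean, rng),
            "coordinate_uncertainty_m": unc,
        })

        corrupted: list[pd.DataFrame] = []
        counts = rng.multinomial(n_bad, config.corruption_proportions) if n_bad else [0] * 4
        for kind, n_k in zip(CORRUPTION_KINDS, counts):
            if n_k == 0:
                continue
            if kind == "duplicate":
                picks = rng.integers(0, n_clean, size=n_k)
                corrupted.append(clean.iloc[picks].copy())
                continue
            bx = grid.x0 + rng.uniform(0, grid.width_km, size=n_k)
            by = grid.y0 + rng.uniform(0, grid.height_km, size=n_k)
            bunc = np.clip(np.exp(rng.normal(math.log(config.uncertainty_median_m),
                                             config.uncertainty_log_sigma, size=n_k)),
                           1.0, 9_999.0)
            bad = pd.DataFrame({
                "species": config.name, "longitude": bx, "latitude": by,
                "event_date": _season_dates(season, n_k, rng),
                "coordinate_uncertainty_m": bunc,
            })
            if kind == "missing_coords":
                bad["longitude"] = np.nan
                bad["latitude"] = np.nan
            elif kind == "zero_zero":
                bad["longitude"] = 0.0
                bad["latitude"] = 0.0
            elif kind == "coarse_uncertainty":
                bad["coordinate_uncertainty_m"] = rng.uniform(10_001, 100_000, size=n_k)
            corrupted.append(bad)

        frames.append(pd.concat([clean, *corrupted], ignore_index=True))

    records = pd.concat(frames, ignore_index=True)[COLUMNS]
    return records, suit_maps, binary_maps


# -- disk output -----------------------------------------------------------

def write_world(world: World, directory) -> None:
    """Write the world as text layers: ASCII grids, GeoJSON and CSV."""
    import json
    import os

    from shapely.geometry import mapping

    os.makedirs(directory, exist_ok=True)
    for name, arr in world.climate.layers.items():
        write_ascii_grid(os.path.join(directory, f"climate_{name}.asc"), arr, world.grid)
    world.pas.to_geojson(os.path.join(directory, "pa_polygons.geojson"))
    world.pas.points_to_csv(os.path.join(directory, "pa_points.csv"))
    feats = []
    for cid in world.countries.ids:
        rows, cols = np.nonzero(world.countries.mask_of(cid))
        geom = shapely.unary_union(world.grid.cell_boxes(rows, cols))
        feats.append({"type": "Feature", "geometry": mapping(geom),
                      "properties": {"country": cid}})
    with open(os.path.join(directory, "countries.geojson"), "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
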