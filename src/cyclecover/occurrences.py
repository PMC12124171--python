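"""Occurrence-record cleaning, season assignment and modelling datasets.

Raw presence-only records (GBIF-style rows with species, coordinates, an
event date and a coordinate uncertainty in metres) pass through a fixed
sequence of cleaning rules, are split into four three-month seasons
(Dec–Feb, Mar–May, Jun–Aug, Sep–Nov), snapped to grid cells and
deduplicated per cell.  Species–season sets with too few unique cells, and
species left with fewer than two seasons, are dropped before modelling.

The rule order is fixed (missing coordinates → (0,0) coordinates → coarse
uncertainty → exact duplicates → unparseable dates) so the audit counts are
reproducible; every removal is counted exactly once.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid

#: Canonical column names for occurrence tables.
COLUMNS = ["species", "longitude", "latitude", "event_date", "coordinate_uncertainty_m"]

REMOVAL_RULES = [
    "removed_missing_coords",
    "removed_zero_zero",
    "removed_coarse_uncertainty",
    "removed_duplicate",
    "removed_unparseable_date",
]


class Season(enum.Enum):
    """Three-month seasons; December opens the first bin with Jan/Feb."""

    S1 = "S1"  # Dec–Feb
    S2 = "S2"  # Mar–May
    S3 = "S3"  # Jun–Aug
    S4 = "S4"  # Sep–Nov

    @classmethod
    def from_month(cls, month: int) -> "Season":
        return _SEASON_OF_MONTH[int(month)]

    @property
    def months(self) -> tuple[int, int, int]:
        return {
            Season.S1: (12, 1, 2),
            Season.S2: (3, 4, 5),
            Season.S3: (6, 7, 8),
            Season.S4: (9, 10, 11),
        }[self]


_SEASON_OF_MONTH = {m: s for s in Season for m in s.months}


def assign_season(event_date) -> Season:
    """Season of a calendar date (month-only mapping, one global calendar)."""
    ts = pd.Timestamp(event_date)
    return Season.from_month(ts.month)


@dataclass(frozen=True)
class CleaningConfig:
    """Cleaning and retention thresholds.

    ``max_uncertainty_m`` drops coarsely georeferenced records (default 10 km);
    ``min_records_per_season`` is the minimum number of unique occupied cells a
    species–season needs to be modelled (default 30); species surviving in
    fewer than ``min_seasons_per_species`` seasons are dropped entirely
    (default 2, so seasonal coverages can be compared).
    """

    max_uncertainty_m: float = 10_000.0
    min_records_per_season: int = 30
    min_seasons_per_species: int = 2

    def __post_init__(self) -> None:
        if self.max_uncertainty_m <= 0 or self.min_records_per_season <= 0 \
                or self.min_seasons_per_species <= 0:
            raise ValueError("all cleaning thresholds must be positive")


@dataclass
class SeasonalOccurrenceSet:
    """Deduplicated occupied cells for one species–season, with provenance."""

    species: str
    season: Season
    cells: np.ndarray  # (n, 2) unique (row, col)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def clean_records(records: pd.DataFrame, config: CleaningConfig | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cleaning rules; return (cleaned records, per-species audit).

    Rules, in order: records without spatial information; records at exactly
    (0, 0); coordinate uncertainty above ``max_uncertainty_m`` (missing
    uncertainty is retained); exact duplicate rows (first kept); rows whose
    event date cannot be parsed.  The audit table has one row per species
    with ``n_raw``, one column per rule, and ``n_retained``; counts always
    conserve: raw = retained + Σ removed.
    """
    config = config or CleaningConfig()
    df = records.copy()
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"occurrence table lacks columns {missing_cols}")

    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    unc = pd.to_numeric(df["coordinate_uncertainty_m"], errors="coerce")

    removed = pd.DataFrame(index=df.index, columns=REMOVAL_RULES, dtype=bool)
    removed[:] = False

    alive = pd.Series(True, index=df.index)

    rule = ~lon.notna() | ~lat.notna() | ~np.isfinite(lon.fillna(np.inf)) | ~np.isfinite(lat.fillna(np.inf))
    removed.loc[alive & rule, "removed_missing_coords"] = True
    alive &= ~rule

    rule = (lon == 0) & (lat == 0)
    removed.loc[alive & rule, "removed_zero_zero"] = True
    alive &= ~rule

    rule = unc > config.max_uncertainty_m  # NaN uncertainty compares False -> retained
    removed.loc[alive & rule, "removed_coarse_uncertainty"] = True
    alive &= ~rule

    dup = df.loc[alive].duplicated(keep="first")
    removed.loc[dup.index[dup], "removed_duplicate"] = True
    alive.loc[dup.index[dup]] = False

    dates = pd.to_datetime(df.loc[alive, "event_date"], errors="coerce", format="mixed")
    bad = dates.isna()
    removed.loc[bad.index[bad], "removed_unparseable_date"] = True
    alive.loc[bad.index[bad]] = False

    audit = removed.groupby(df["species"]).sum().astype(int)
    audit.insert(0, "n_raw", df.groupby("species").size())
    audit["n_retained"] = audit["n_raw"] - audit[REMOVAL_RULES].sum(axis=1)
    cleaned = df.loc[alive].copy()
    cleaned["longitude"] = lon.loc[alive]
    cleaned["latitude"] = lat.loc[alive]
    cleaned["coordinate_uncertainty_m"] = unc.loc[alive]
    return cleaned, audit.reset_index()


def prepare_seasonal_datasets(cleaned: pd.DataFrame, grid: Grid,
                              config: CleaningConfig | None = None
                              ) -> tuple[list[SeasonalOccurrenceSet], pd.DataFrame]:
    """Snap cleaned records to cells and apply the retention rules.

    Records outside the grid extent are dropped (audited).  Per species and
    season, duplicate cells collapse to one "unique occurrence"; sets with
    fewer than ``min_records_per_season`` unique cells are dropped, then
    species with fewer than ``min_seasons_per_species`` surviving seasons are
    dropped entirely.  Returns the surviving sets and a species×season audit
    of raw records / unique cells / survival.
    """
    config = config or CleaningConfig()
    df = cleaned.copy()
    dates = pd.to_datetime(df["event_date"], errors="raise", format="mixed")
    df["season"] = [Season.from_month(m).value for m in dates.dt.month]

    inside = grid.contains(df["longitude"].to_numpy(), df["latitude"].to_numpy())
    n_outside = int((~inside).sum())
    df = df.loc[inside].copy()
    rows, cols = grid.cell_of(df["longitude"].to_numpy(), df["latitude"].to_numpy())
    df["row"], df["col"] = rows, cols

    sets: list[SeasonalOccurrenceSet] = []
    audit_rows = []
    by_species: dict[str, list[SeasonalOccurrenceSet]] = {}
    for (species, season), part in df.groupby(["species", "season"], sort=True):
        cells = np.unique(part[["row", "col"]].to_numpy(), axis=0)
        keep = len(cells) >= config.min_records_per_season
        occ = SeasonalOccurrenceSet(
            species=species, season=Season(season), cells=cells,
            counts={"n_records": len(part), "n_unique_cells": len(cells),
                    "n_outside_grid_total": n_outside},
        )
        audit_rows.append({"species": species, "season": season,
                           "n_records": len(part), "n_unique_cells": len(cells),
                           "season_retained": keep})
        if keep:
            by_species.setdefault(species, []).append(occ)

    audit = pd.DataFrame(audit_rows)
    retained_species = {sp for sp, occs in by_species.items()
                        if len(occs) >= config.min_seasons_per_species}
    if len(audit):
        audit["species_retained"] = audit["species"].isin(retained_species)
        audit["n_outside_grid_total"] = n_outside
    for sp in sorted(retained_species):
        sets.extend(by_species[sp])
    return sets, audit
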