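"""Representation targets, coverage statistics and gap summaries.

A species–season range is "adequately covered" when the percentage of its
range inside protected areas reaches a size-dependent representation
target: 100% for ranges under 1,000 km², the current global terrestrial PA
share (16%) above 250,000 km², and a log-linear interpolation in between.
The gap is target − coverage (negative when a species exceeds its target).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrences import Season
from .protection import ProtectionRaster

GAP_CLASSES = (">10%", ">5%", "1–5%", "<1%")


@dataclass(frozen=True)
class TargetPolicy:
    """Knots of the log-linear representation-target rule.

    Ranges below ``full_protection_area_km2`` (default 1,000 km²) must be
    fully protected; ranges above ``capped_area_km2`` (default 250,000 km²)
    need only ``capped_target_pct`` (default 16%, the global terrestrial PA
    share); between the knots the target falls linearly in log10(area).
    """

    full_protection_area_km2: float = 1_000.0
    capped_area_km2: float = 250_000.0
    full_target_pct: float = 100.0
    capped_target_pct: float = 16.0

    def __post_init__(self) -> None:
        if not (0 < self.full_protection_area_km2 < self.capped_area_km2):
            raise ValueError("need 0 < full_protection_area < capped_area")
        if not (self.capped_target_pct < self.full_target_pct):
            raise ValueError("need capped_target < full_target")


def representation_target(range_area_km2: float, policy: TargetPolicy | None = None) -> float:
    """Representation target (%) for a range of the given area (km²)."""
    policy = policy or TargetPolicy()
    a = float(range_area_km2)
    if not (a > 0) or not math.isfinite(a):
        raise ValueError("range area must be positive and finite")
    if a < policy.full_protection_area_km2:
        return policy.full_target_pct
    if a > policy.capped_area_km2:
        return policy.capped_target_pct
    lo, hi = math.log10(policy.full_protection_area_km2), math.log10(policy.capped_area_km2)
    w = (math.log10(a) - lo) / (hi - lo)
    return policy.full_target_pct + w * (policy.capped_target_pct - policy.full_target_pct)


def classify_gap(gap_pct: float) -> str:
    """Mutually exclusive gap class from the reporting thresholds 10/5/1."""
    if gap_pct > 10:
        return ">10%"
    if gap_pct > 5:
        return ">5%"
    if gap_pct < 1:
        return "<1%"
    return "1–5%"


@dataclass
class GapRecord:
    """Coverage vs. target for one species–season."""

    species: str
    season: Season
    range_area_km2: float
    coverage_pct: float
    target_pct: float

    @property
    def gap_pct(self) -> float:
        return self.target_pct - self.coverage_pct

    @property
    def meets_target(self) -> bool:
        return self.coverage_pct >= self.target_pct

    @property
    def gap_class(self) -> str:
        return classify_gap(self.gap_pct)


def coverage_stats(binary_map: np.ndarray, protection: ProtectionRaster,
                   policy: TargetPolicy | None = None, species: str = "",
                   season: Season | None = None) -> GapRecord:
    """GapRecord for one seasonal binary range map over the protection raster.

    Range area is suitable-cell count × cell area; coverage is the
    percentage of suitable cells whose protected flag is set.
    """
    policy = policy or TargetPolicy()
    mask = np.asarray(binary_map, dtype=bool)
    if mask.shape != protection.grid.shape:
        raise ValueError("binary map shape does not match protection grid")
    n_suitable = int(mask.sum())
    if n_suitable == 0:
        raise ValueError("empty range: no suitable cells")
    n_protected = int((mask & protection.flag).sum())
    area = n_suitable * protection.grid.cell_area_km2
    coverage = 100.0 * n_protected / n_suitable
    return GapRecord(species=species, season=season, range_area_km2=area,
                     coverage_pct=coverage, target_pct=representation_target(area, policy))


@dataclass
class AnnualSummary:
    """Species-level summary across its available seasons."""

    species: str
    year_round_coverage_pct: float
    mean_seasonal_coverage_pct: float
    seasonal_variation_pct: float  # max - min seasonal coverage
    n_seasons: int
    n_seasons_meeting: int

    @property
    def category(self) -> str:
        if self.n_seasons_meeting == self.n_seasons:
            return "all seasons"
        if self.n_seasons_meeting == 1:
            return "one season only"
        if self.n_seasons_meeting == 0:
            return "no season"
        return "other"


def species_annual_summary(records: dict[Season, GapRecord],
                           binary_maps: dict[Season, np.ndarray],
                           protection: ProtectionRaster,
                           year_round_mode: str = "union") -> AnnualSummary:
    """Annual summary from the per-season gap records of one species.

    The year-round distribution is the union of the seasonal binary maps
    (default); ``year_round_mode="mean"`` instead averages the seasonal
    coverages.  Both quantities are reported either way.  Seasonal variation
    is max − min coverage over the species' available seasons.
    """
    if len(records) < 2:
        raise ValueError("annual summary needs at least two seasons")
    if set(records) != set(binary_maps):
        raise ValueError("records and binary maps must cover the same seasons")
    if year_round_mode not in ("union", "mean"):
        raise ValueError("year_round_mode must be 'union' or 'mean'")
    coverages = [r.coverage_pct for r in records.values()]
    mean_cov = float(np.mean(coverages))
    union = np.zeros(protection.grid.shape, dtype=bool)
    for m in binary_maps.values():
        union |= np.asarray(m, dtype=bool)
    union_cov = 100.0 * (union & protection.flag).sum() / union.sum()
    species = next(iter(records.values())).species
    return AnnualSummary(
        species=species,
        year_round_coverage_pct=float(union_cov if year_round_mode == "union" else mean_cov),
        mean_seasonal_coverage_pct=mean_cov,
        seasonal_variation_pct=float(max(coverages) - min(coverages)),
        n_seasons=len(records),
        n_seasons_meeting=sum(r.meets_target for r in records.values()),
    )


def gap_records_frame(records: list[GapRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "species": r.species,
        "season": r.season.value if r.season is not None else "",
        "range_area_km2": r.range_area_km2,
        "coverage_pct": r.coverage_pct,
        "target_pct": r.target_pct,
        "gap_pct": r.gap_pct,
        "meets_target": r.meets_target,
        "gap_class": r.gap_class,
    } for r in records])


def gap_class_table(records: list[GapRecord]) -> pd.DataFrame:
    """Per-season cumulative gap-class counts (>10%, >5%, <1%, meeting).

    The >5% column includes the >10% species, matching the usual cumulative
    presentation of representation-gap tables.
    """
    df = gap_records_frame(records)
    out = []
    for season, part in df.groupby("season", sort=True):
        out.append({
            "season": season,
            "n_gap_gt10": int((part["gap_pct"] > 10).sum()),
            "n_gap_gt5": int((part["gap_pct"] > 5).sum()),
            "n_gap_lt1": int((part["gap_pct"] < 1).sum()),
            "n_meeting_target": int(part["meets_target"].sum()),
            "n_species": len(part),
        })
    return pd.DataFrame(out)
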