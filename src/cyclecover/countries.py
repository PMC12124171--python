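"""Per-country target attainment for seasonal ranges.

Each country is treated as an independent unit responsible for the species
within its borders: a species "occurs" in a country when at least one
suitable cell falls inside it, and its national attainment is judged on the
clipped range.  By default the representation target is recomputed from the
within-country range area (a small national range demands a high national
target); the alternative semantics — applying the target percentage derived
from the species' global range — is available via ``target_mode="global"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaps import TargetPolicy, representation_target
from .grid import Grid
from .occurrences import Season
from .protection import ProtectionRaster


@dataclass
class CountryPartition:
    """Exhaustive, disjoint assignment of grid cells to countries.

    ``labels`` holds, per cell, an index into ``ids``; every valid cell
    belongs to exactly one country by construction.
    """

    grid: Grid
    labels: np.ndarray  # (nrows, ncols) int indices into ids
    ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        if self.labels.min() < 0 or self.labels.max() >= len(self.ids):
            raise ValueError("labels reference unknown countries")

    def mask_of(self, country_id: str) -> np.ndarray:
        return self.labels == self.ids.index(country_id)

    def cell_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=len(self.ids))
        return dict(zip(self.ids, counts.tolist()))


def country_attainment(binary_map: np.ndarray, protection: ProtectionRaster,
                       partition: CountryPartition,
                       policy: TargetPolicy | None = None,
                       target_mode: str = "within") -> pd.DataFrame:
    """Per-country presence/coverage/target flags for one species–season map.

    Returns one row per country with ``present``, the clipped range area,
    within-country coverage, the applicable target and ``meets``.  Absent
    species get ``present=False`` and NaN statistics.
    """
    if target_mode not in ("within", "global"):
        raise ValueError("target_mode must be 'within' or 'global'")
    policy = policy or TargetPolicy()
    mask = np.asarray(binary_map, dtype=bool)
    if mask.shape != partition.grid.shape:
        raise ValueError("binary map shape does not match partition grid")
    cell_area = partition.grid.cell_area_km2
    global_area = mask.sum() * cell_area
    global_target = representation_target(global_area, policy) if global_area > 0 else np.nan

    n_countries = len(partition.ids)
    lab = partition.labels.ravel()
    suitable = np.bincount(lab, weights=mask.ravel(), minlength=n_countries)
    prot = np.bincount(lab, weights=(mask & protection.flag).ravel(), minlength=n_countries)

    rows = []
    for i, cid in enumerate(partition.ids):
        n_suit = int(suitable[i])
        if n_suit == 0:
            rows.append({"country": cid, "present": False, "range_area_km2": np.nan,
                         "coverage_pct": np.nan, "target_pct": np.nan, "meets": False})
            continue
        area = n_suit * cell_area
        coverage = 100.0 * prot[i] / n_suit
        target = representation_target(area, policy) if target_mode == "within" else global_target
        rows.append({"country": cid, "present": True, "range_area_km2": area,
                     "coverage_pct": coverage, "target_pct": target,
                     "meets": bool(coverage >= target)})
    return pd.DataFrame(rows)


def country_summary(attainment_by_season: dict[Season, dict[str, pd.DataFrame]]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-species attainment into country-season summaries.

    ``attainment_by_season[season][species]`` is a frame from
    :func:`country_attainment`.  Returns (per country-season rows with the
    proportion of suitable species meeting their target — NaN when no
    species is suitable — and a per-country frame with the seasonal
    variation of that proportion, max − min over seasons with at least one
    suitable species).
    """
    rows = []
    for season, by_species in attainment_by_season.items():
        frames = list(by_species.values())
        if not frames:
            continue
        countries = frames[0]["country"]
        present = np.column_stack([f["present"].to_numpy() for f in frames])
        meets = np.column_stack([f["meets"].to_numpy() for f in frames])
        n_suitable = present.sum(axis=1)
        n_meeting = (present & meets).sum(axis=1)
        for cid, ns, nm in zip(countries, n_suitable, n_meeting):
            rows.append({"country": cid, "season": season.value,
                         "n_suitable_species": int(ns), "n_meeting_target": int(nm),
                         "proportion_meeting_pct":
                             100.0 * nm / ns if ns > 0 else np.nan})
    summary = pd.DataFrame(rows)
    variation_rows = []
    for cid, part in summary.groupby("country", sort=True):
        props = part.loc[part["n_suitable_species"] > 0, "proportion_meeting_pct"]
        variation_rows.append({
            "country": cid,
            "n_seasons_with_species": len(props),
            "seasonal_variation_pct":
                float(props.max() - props.min()) if len(props) else np.nan,
        })
    return summary, pd.DataFrame(variation_rows)
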