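import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclecover import (
    Grid,
    ProtectionRaster,
    Season,
    TargetPolicy,
    coverage_stats,
    gap_class_table,
    representation_target,
    species_annual_summary,
)
from cyclecover.gaps import GapRecord, classify_gap


class TestRepresentationTarget:
    def test_small_ranges_need_full_protection(self):
        assert representation_target(500.0) == 100.0

    def test_large_ranges_capped_at_global_pa_share(self):
        assert representation_target(300_000.0) == 16.0

    def test_log_midpoint_interpolates_halfway(self):
        area = 10 ** ((math.log10(1_000) + math.log10(250_000)) / 2)  # ~15,811 km2
        assert representation_target(area) == pytest.approx(58.0, abs=1e-9)

    def test_continuous_at_both_knots(self):
        assert representation_target(1_000.0) == pytest.approx(100.0)
        assert representation_target(250_000.0) == pytest.approx(16.0)
        assert representation_target(math.nextafter(1_000.0, 0)) == 100.0
        assert representation_target(math.nextafter(250_000.0, math.inf)) == 16.0

    @settings(deadline=None, max_examples=100)
    @given(st.floats(min_value=1.0, max_value=1e7),
           st.floats(min_value=1.0, max_value=1e7))
    def test_monotone_non_increasing_and_bounded(self, a, b):
        lo, hi = sorted([a, b])
        t_lo, t_hi = representation_target(lo), representation_target(hi)
        assert t_lo >= t_hi
        assert 16.0 <= t_lo <= 100.0 and 16.0 <= t_hi <= 100.0

    def test_non_positive_area_rejected(self):
        for bad in (0.0, -5.0, math.nan):
            with pytest.raises(ValueError):
                representation_target(bad)


def _protection(grid, protected_cells):
    fraction = np.zeros(grid.shape)
    for r, c in protected_cells:
        fraction[r, c] = 1.0
    return ProtectionRaster(grid, fraction)


class TestCoverageStats:
    grid = Grid(nrows=8, ncols=8, cell_area_km2=21.625)

    def test_coverage_arithmetic(self):
        mask = np.zeros(self.grid.shape, dtype=bool)
        mask[0, :5] = mask[1, :5] = True  # 10 suitable cells
        prot = _protection(self.grid, [(0, 0), (0, 1), (1, 0), (1, 1)])
        rec = coverage_stats(mask, prot, species="s", season=Season.S1)
        assert rec.coverage_pct == pytest.approx(40.0)
        assert rec.range_area_km2 == pytest.approx(10 * 21.625)
        assert rec.target_pct == 100.0  # 216 km2 < 1,000 km2

    def test_gap_class_binning(self):
        assert classify_gap(16 - 4) == ">10%"
        assert classify_gap(8.0) == ">5%"
        assert classify_gap(3.0) == "1–5%"
        assert classify_gap(0.5) == "<1%"
        assert classify_gap(-20.0) == "<1%"

    def test_every_gap_falls_in_exactly_one_class(self):
        for gap in np.linspace(-50, 50, 1001):
            assert sum(classify_gap(gap) == c for c in
                       (">10%", ">5%", "1–5%", "<1%")) == 1

    def test_meets_target_is_weak_inequality(self):
        rec = GapRecord("s", Season.S1, 1e6, coverage_pct=16.0, target_pct=16.0)
        assert rec.meets_target and rec.gap_pct == 0.0

    def test_empty_range_rejected(self):
        prot = _protection(self.grid, [])
        with pytest.raises(ValueError, match="empty range"):
            coverage_stats(np.zeros(self.grid.shape, dtype=bool), prot)


class TestAnnualSummary:
    grid = Grid(nrows=8, ncols=8, cell_area_km2=21.625)

    def _record(self, cov, target=16.0):
        return GapRecord("s", Season.S1, 1e6, coverage_pct=cov, target_pct=target)

    def _maps(self, *cell_lists):
        maps = {}
        for season, cells in zip(Season, cell_lists):
            m = np.zeros(self.grid.shape, dtype=bool)
            for r, c in cells:
                m[r, c] = True
            maps[season] = m
        return maps

    def test_seasonal_variation_is_max_minus_min(self):
        prot = _protection(self.grid, [(0, 0)])
        maps = self._maps([(0, 0), (0, 1)], [(2, 2), (2, 3)])
        recs = {Season.S1: self._record(45.0), Season.S2: self._record(10.0)}
        summary = species_annual_summary(recs, dict(zip(recs, maps.values())), prot)
        assert summary.seasonal_variation_pct == pytest.approx(35.0)

    def test_categories_from_meeting_counts(self):
        prot = _protection(self.grid, [(0, 0)])
        maps = dict(zip([Season.S1, Season.S2], self._maps([(0, 0)], [(1, 1)]).values()))
        all_meet = {Season.S1: self._record(50.0), Season.S2: self._record(20.0)}
        none_meet = {Season.S1: self._record(5.0), Season.S2: self._record(2.0)}
        one_meets = {Season.S1: self._record(50.0), Season.S2: self._record(2.0)}
        assert species_annual_summary(all_meet, maps, prot).category == "all seasons"
        assert species_annual_summary(none_meet, maps, prot).category == "no season"
        assert species_annual_summary(one_meets, maps, prot).category == "one season only"

    def test_union_of_identical_maps_equals_each_season(self):
        prot = _protection(self.grid, [(0, 0)])
        m = np.zeros(self.grid.shape, dtype=bool)
        m[0, 0] = m[0, 1] = True
        maps = {Season.S1: m, Season.S2: m.copy()}
        recs = {Season.S1: self._record(50.0), Season.S2: self._record(50.0)}
        summary = species_annual_summary(recs, maps, prot)
        assert summary.year_round_coverage_pct == pytest.approx(50.0)

    def test_mean_mode_averages_seasonal_coverages(self):
        prot = _protection(self.grid, [(0, 0)])
        maps = dict(zip([Season.S1, Season.S2],
                        self._maps([(0, 0)], [(1, 1)]).values()))
        recs = {Season.S1: self._record(30.0), Season.S2: self._record(10.0)}
        s = species_annual_summary(recs, maps, prot, year_round_mode="mean")
        assert s.year_round_coverage_pct == pytest.approx(20.0)

    def test_single_season_rejected(self):
        prot = _protection(self.grid, [])
        with pytest.raises(ValueError, match="two seasons"):
            species_annual_summary({Season.S1: self._record(10.0)},
                                   {Season.S1: np.zeros(self.grid.shape, bool)}, prot)


def test_gap_class_table_counts_are_cumulative():
    recs = [GapRecord("a", Season.S1, 1e6, coverage_pct=1.0, target_pct=16.0),   # gap 15
            GapRecord("b", Season.S1, 1e6, coverage_pct=8.0, target_pct=16.0),   # gap 8
            GapRecord("c", Season.S1, 1e6, coverage_pct=20.0, target_pct=16.0)]  # gap -4
    table = gap_class_table(recs).set_index("season")
    assert table.loc["S1", "n_gap_gt10"] == 1
    assert table.loc["S1", "n_gap_gt5"] == 2  # includes the >10% species
    assert table.loc["S1", "n_gap_lt1"] == 1
    assert table.loc["S1", "n_meeting_target"] == 1
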