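import json
import math

import numpy as np
import pytest
from shapely.geometry import box

from paguard.grid import BoolRaster, GridSpec, dilate_one_pixel, rasterize
from paguard.protection import (
    PARecord,
    ProtectionCategory,
    centroid_to_circle,
    classify_protection,
    filter_pa,
    loss_by_protection,
    pa_records_from_geojson,
    pa_records_to_geojson,
    species_protection_summary,
)
from paguard.rangechange import classify_change


GRID = GridSpec(12, 12, 10.0)


def pa(pa_id="p", year=1960, status="current", iucn="II", geom=None, centroid=None, area=None):
    return PARecord(
        pa_id=pa_id,
        year_established=year,
        status=status,
        iucn_category=iucn,
        geometry=geom,
        centroid=centroid,
        reported_area_km2=area,
    )


class TestFilterPA:
    def test_unassigned_category_dropped(self):
        assert filter_pa([pa(iucn="unassigned", geom=box(0, -20, 20, 0))]) == []

    def test_centroid_without_area_dropped(self):
        assert filter_pa([pa(centroid=(50.0, -50.0), area=None)]) == []

    def test_non_current_dropped(self):
        assert filter_pa([pa(status="proposed", geom=box(0, -20, 20, 0))]) == []

    def test_valid_polygon_and_centroid_retained(self):
        records = [
            pa("poly", geom=box(0, -20, 20, 0)),
            pa("cent", centroid=(50.0, -50.0), area=400.0),
        ]
        assert [r.pa_id for r in filter_pa(records)] == ["poly", "cent"]


class TestCentroidToCircle:
    @pytest.mark.parametrize("area,radius", [(math.pi, 1.0), (100 * math.pi, 10.0)])
    def test_radius_formula(self, area, radius):
        poly = centroid_to_circle((0.0, 0.0), area)
        maxx = poly.bounds[2]
        assert maxx == pytest.approx(radius, abs=1e-12)

    def test_64gon_area_within_half_percent(self):
        area = 1234.5
        poly = centroid_to_circle((3.0, -7.0), area)
        assert abs(poly.area - area) / area < 0.005

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            centroid_to_circle((0.0, 0.0), 0.0)


class TestClassifyProtection:
    def test_single_old_pa_gives_p70_buffer_never(self):
        rec = pa(year=1960, geom=box(40, -80, 80, -40))
        pmap = classify_protection([rec], GRID)
        core = rasterize(rec.geometry, GRID)
        ring = dilate_one_pixel(core).values & ~core.values
        assert np.all(pmap.categories[core.values] == ProtectionCategory.P70)
        assert np.all(pmap.categories[ring] == ProtectionCategory.BUFFER)
        outside = ~dilate_one_pixel(core).values
        assert np.all(pmap.categories[outside] == ProtectionCategory.NEVER)

    def test_earliest_protection_wins_in_overlap(self):
        old = pa("old", year=1960, geom=box(20, -60, 60, -20))
        new = pa("new", year=1990, geom=box(40, -80, 80, -40))
        pmap = classify_protection([old, new], GRID)
        overlap = (rasterize(old.geometry, GRID) & rasterize(new.geometry, GRID)).values
        assert overlap.any()
        assert np.all(pmap.categories[overlap] == ProtectionCategory.P70)

    def test_post_recent_pa_ignored(self):
        rec = pa(year=2019, geom=box(40, -80, 80, -40))
        pmap = classify_protection([rec], GRID)
        assert np.all(pmap.categories == ProtectionCategory.NEVER)

    def test_random_set_matches_bruteforce_rules(self):
        rng = np.random.default_rng(5)
        records = []
        for k in range(6):
            x0, y0 = rng.uniform(0, 90), -rng.uniform(0, 90)
            records.append(
                pa(f"p{k}", year=int(rng.integers(1950, 2016)),
                   geom=box(x0, y0 - rng.uniform(15, 40), x0 + rng.uniform(15, 40), y0))
            )
        pmap = classify_protection(records, GRID)
        p70 = np.zeros(GRID.shape, dtype=bool)
        p15 = np.zeros(GRID.shape, dtype=bool)
        for rec in records:
            m = rasterize(rec.geometry, GRID).values
            if rec.year_established <= 1970:
                p70 |= m
            elif rec.year_established <= 2015:
                p15 |= m
        p15 &= ~p70
        prot = p70 | p15
        buf = dilate_one_pixel(BoolRaster(GRID, prot)).values & ~prot
        expected = np.full(GRID.shape, int(ProtectionCategory.NEVER))
        expected[buf] = ProtectionCategory.BUFFER
        expected[p15] = ProtectionCategory.P15
        expected[p70] = ProtectionCategory.P70
        assert np.array_equal(pmap.categories, expected)

    def test_partition_is_exhaustive_and_exclusive(self):
        rec = pa(year=1980, geom=box(30, -70, 70, -30))
        pmap = classify_protection([rec], GRID)
        counts = sum(
            (pmap.categories == c).sum()
            for c in ProtectionCategory
        )
        assert counts == GRID.n_rows * GRID.n_cols


class TestSpeciesProtectionSummary:
    def test_range_entirely_inside_old_pa(self):
        rec = pa(year=1950, geom=box(0, -120, 120, 0))
        pmap = classify_protection([rec], GRID)
        rng_mask = BoolRaster(GRID, np.ones(GRID.shape, dtype=bool))
        s = species_protection_summary(rng_mask, rng_mask, pmap, "sp")
        assert s.prop_protected_1970 == 1.0
        assert s.prop_protected_2015 == 1.0
        assert s.delta_prop == 0.0

    def test_no_overlap_gives_zero(self):
        rec = pa(year=1950, geom=box(0, -30, 30, 0))
        pmap = classify_protection([rec], GRID)
        mask = np.zeros(GRID.shape, dtype=bool)
        mask[10:, 10:] = True
        r = BoolRaster(GRID, mask)
        s = species_protection_summary(r, r, pmap, "sp")
        assert s.prop_protected_1970 == 0.0
        assert s.prop_protected_2015 == 0.0

    def test_matches_bruteforce_intersections(self):
        rng = np.random.default_rng(8)
        old = pa("o", year=1955, geom=box(10, -70, 60, -10))
        new = pa("n", year=2000, geom=box(50, -110, 110, -60))
        pmap = classify_protection([old, new], GRID)
        past = BoolRaster(GRID, rng.random(GRID.shape) < 0.5)
        recent = BoolRaster(GRID, rng.random(GRID.shape) < 0.5)
        s = species_protection_summary(past, recent, pmap, "sp")
        p70 = pmap.categories == ProtectionCategory.P70
        prot15 = np.isin(
            pmap.categories, [ProtectionCategory.P70, ProtectionCategory.P15]
        )
        assert s.prop_protected_1970 == (past.values & p70).sum() / past.count()
        assert s.prop_protected_2015 == (recent.values & prot15).sum() / recent.count()
        assert s.extent_P70_km2 == (past.values & p70).sum() * 100.0

    def test_empty_range_flagged_missing(self):
        pmap = classify_protection([pa(geom=box(0, -30, 30, 0))], GRID)
        empty = BoolRaster.zeros(GRID)
        with pytest.warns(UserWarning):
            s = species_protection_summary(empty, empty, pmap, "sp")
        assert math.isnan(s.prop_protected_1970)


class TestLossByProtection:
    def test_all_loss_outside_pas(self):
        pmap = classify_protection([pa(geom=box(0, -30, 30, 0))], GRID)
        past = np.zeros(GRID.shape, dtype=bool)
        past[8:, 8:] = True
        change = classify_change(BoolRaster(GRID, past), BoolRaster.zeros(GRID))
        d = loss_by_protection(change, pmap)
        assert d.share_never == 1.0
        assert d.share_P70 == 0.0

    def test_no_loss_is_flagged_undefined(self):
        pmap = classify_protection([pa(geom=box(0, -30, 30, 0))], GRID)
        full = BoolRaster(GRID, np.ones(GRID.shape, dtype=bool))
        change = classify_change(full, full)
        d = loss_by_protection(change, pmap)
        assert not d.defined

    def test_shares_sum_to_one_and_match_tally(self):
        rng = np.random.default_rng(3)
        records = [
            pa("a", year=1960, geom=box(10, -60, 50, -10)),
            pa("b", year=1990, geom=box(60, -110, 110, -60)),
        ]
        pmap = classify_protection(records, GRID)
        past = BoolRaster(GRID, rng.random(GRID.shape) < 0.7)
        recent = BoolRaster(GRID, past.values & (rng.random(GRID.shape) < 0.5))
        change = classify_change(past, recent)
        d = loss_by_protection(change, pmap)
        assert d.share_P70 + d.share_P15 + d.share_never == pytest.approx(1.0)
        lost = change.lost.values
        assert d.area_lost_P70_km2 == (
            lost & (pmap.categories == ProtectionCategory.P70)
        ).sum() * 100.0

    def test_buffer_counts_in_never_stratum(self):
        rec = pa(year=1960, geom=box(40, -80, 80, -40))
        pmap = classify_protection([rec], GRID)
        buf = pmap.categories == ProtectionCategory.BUFFER
        past = BoolRaster(GRID, buf)
        change = classify_change(past, BoolRaster.zeros(GRID))
        d = loss_by_protection(change, pmap)
        assert d.share_never == 1.0


class TestGeoJSONRoundTrip:
    def test_polygon_and_centroid_records(self):
        records = [
            pa("poly", year=1965, geom=box(0, -20, 20, 0), area=400.0),
            pa("cent", year=1999, centroid=(55.0, -45.0), area=314.0),
        ]
        back = pa_records_from_geojson(
            json.loads(json.dumps(pa_records_to_geojson(records)))
        )
        assert [r.pa_id for r in back] == ["poly", "cent"]
        assert back[0].geometry.equals(records[0].geometry)
        assert back[1].centroid == (55.0, -45.0)
        assert back[1].reported_area_km2 == 314.0
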