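"""Equal-area grids: incidence building, quantile classes, dominant drivers."""

import json
import math

import numpy as np
import pytest

from rlikit.backcast import (
    ChangeDirection,
    ChangeRecord,
    DriverGroup,
)
from rlikit.model import CategoryState, RedListCategory
from rlikit.spatial import (
    GridSpec,
    build_incidence,
    dominant_driver,
    incidence_from_geojson,
    incidence_from_pairs,
    richness_quantiles,
)


def det_change(sid, driver, interval=(2004, 2022)):
    return ChangeRecord(
        species_id=sid,
        interval=interval,
        from_state=CategoryState(RedListCategory.LC),
        to_state=CategoryState(RedListCategory.NT),
        genuine=True,
        direction=ChangeDirection.DETERIORATION,
        driver_group=driver,
    )


class TestGridSpec:
    @pytest.mark.parametrize("area", [865.0, 7775.0])
    def test_presets_have_square_cells_of_requested_area(self, area):
        grid = GridSpec(cell_area=area)
        assert grid.cell_size == pytest.approx(math.sqrt(area))

    def test_cell_area_must_be_positive(self):
        with pytest.raises(ValueError):
            GridSpec(cell_area=0)

    def test_centroid_inverts_cell_lookup(self):
        grid = GridSpec(cell_area=7775.0)
        cell = grid.cell_of(-70.0, -10.0)
        lon, lat = grid.cell_centroid_lonlat(cell)
        assert grid.cell_of(lon, lat) == cell


class TestIncidence:
    def test_disjoint_single_cell_ranges(self):
        inc = incidence_from_pairs([("a", (0, 0)), ("b", (5, 5))])
        assert inc.richness() == {(0, 0): 1, (5, 5): 1}

    def test_duplicates_collapse(self):
        inc = incidence_from_pairs([("a", (0, 0)), ("a", (0, 0))])
        assert inc.richness() == {(0, 0): 1}

    def test_stacked_species_max_richness(self):
        inc = incidence_from_pairs([(f"s{i}", (3, 3)) for i in range(61)])
        assert max(inc.richness().values()) == 61

    def test_double_counting_identity(self):
        rng = np.random.default_rng(5)
        pairs = {
            (f"s{i}", (int(c), int(r)))
            for i in range(30)
            for c, r in rng.integers(0, 6, size=(rng.integers(1, 8), 2))
        }
        inc = incidence_from_pairs(sorted(pairs))
        total_richness = sum(inc.richness().values())
        per_species = sum(len(inc.species_cells(f"s{i}")) for i in range(30))
        assert total_richness == per_species


class TestGeoJSON:
    def make_square(self, lon0, lat0, dlon, dlat, sid, **props):
        return {
            "type": "Feature",
            "properties": {"species_id": sid, **props},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[
                    [lon0, lat0], [lon0 + dlon, lat0], [lon0 + dlon, lat0 + dlat],
                    [lon0, lat0 + dlat], [lon0, lat0],
                ]],
            },
        }

    def test_polygon_spanning_multiple_cells(self):
        grid = GridSpec(cell_area=7775.0)
        # ~2x2 cells worth of ground near the equator
        size_deg = 2 * grid.cell_size / 111.0
        fc = {"type": "FeatureCollection",
              "features": [self.make_square(0.01, 0.01, size_deg, size_deg, "a")]}
        inc = incidence_from_geojson(fc, grid)
        assert len(inc.species_cells("a")) >= 4

    def test_invalid_geometry_skipped_and_counted(self):
        bowtie = {
            "type": "Feature",
            "properties": {"species_id": "bad"},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[0, 0], [2, 2], [2, 0], [0, 2], [0, 0]]],
            },
        }
        fc = {"type": "FeatureCollection", "features": [bowtie]}
        with pytest.warns(UserWarning, match="invalid geometry"):
            inc = incidence_from_geojson(fc, GridSpec(cell_area=7775.0))
        assert inc.n_skipped_features == 1
        assert inc.cells == {}

    def test_presence_origin_filters(self):
        grid = GridSpec(cell_area=7775.0)
        fc = {
            "type": "FeatureCollection",
            "features": [
                self.make_square(0, 0, 0.5, 0.5, "extinct_here", presence=5),
                self.make_square(0, 0, 0.5, 0.5, "introduced", origin=3),
                self.make_square(0, 0, 0.5, 0.5, "native", presence=1, origin=1),
            ],
        }
        inc = incidence_from_geojson(fc, grid)
        species = set().union(*inc.cells.values())
        assert species == {"native"}

    def test_build_incidence_dispatches_both_modes(self):
        from_pairs = build_incidence([("a", (0, 0))])
        assert from_pairs.richness() == {(0, 0): 1}
        fc = {"type": "FeatureCollection",
              "features": [self.make_square(10, 10, 0.2, 0.2, "b")]}
        from_geo = build_incidence(json.dumps(fc), GridSpec(cell_area=7775.0))
        assert len(from_geo.species_cells("b")) >= 1


def oracle_classes(richness_by_cell, k):
    """Sort-and-slice oracle: class = 1 + number of k-quantile cuts
    strictly below the cell's richness."""
    values = np.array(sorted(richness_by_cell.values()), dtype=float)
    cuts = [np.quantile(values, i / k) for i in range(1, k)]
    return {
        cell: 1 + sum(1 for c in cuts if c < r)
        for cell, r in richness_by_cell.items()
    }


class TestRichnessQuantiles:
    def test_uniform_distinct_richness(self):
        inc = incidence_from_pairs(
            [(f"s{i}_{j}", (j, 0)) for j in range(100) for i in range(j + 1)]
        )
        classes = richness_quantiles(inc, k=10)
        # cell j has richness j+1; deciles of 1..100 split ranks evenly
        for j in range(100):
            assert classes[(j, 0)] == min(j // 10 + 1, 10)

    def test_all_equal_richness_single_class(self):
        inc = incidence_from_pairs([("a", (i, 0)) for i in range(7)])
        with pytest.warns(UserWarning, match="merged"):
            classes = richness_quantiles(inc, k=10)
        assert set(classes.values()) == {1}

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(3, 60))
            richness = rng.integers(1, 40, size=n)
            pairs = [
                (f"s{c}_{i}", (c, 0)) for c in range(n) for i in range(richness[c])
            ]
            inc = incidence_from_pairs(pairs)
            k = int(rng.choice([4, 5, 10]))
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                classes = richness_quantiles(inc, k=k)
            assert classes == oracle_classes(inc.richness(), k)

    def test_classes_order_isomorphic_to_richness(self):
        rng = np.random.default_rng(3)
        richness = rng.integers(1, 30, size=40)
        pairs = [(f"s{c}_{i}", (c, 0)) for c in range(40) for i in range(richness[c])]
        inc = incidence_from_pairs(pairs)
        classes = richness_quantiles(inc)
        rich = inc.richness()
        cells = list(rich)
        for a in cells:
            for b in cells:
                if rich[a] <= rich[b]:
                    assert classes[a] <= classes[b]

    def test_fibonacci_fixture_with_k5(self):
        richness = [1, 1, 2, 3, 5, 8, 13, 21, 34, 55]
        pairs = [(f"s{c}_{i}", (c, 0)) for c, r in enumerate(richness) for i in range(r)]
        inc = incidence_from_pairs(pairs)
        classes = richness_quantiles(inc, k=5)
        assert classes == oracle_classes(inc.richness(), 5)


class TestDominantDriver:
    def setup_method(self):
        self.interval = (2004, 2022)

    def test_clear_majority(self):
        inc = incidence_from_pairs([(f"s{i}", (0, 0)) for i in range(4)])
        changes = [det_change(f"s{i}", DriverGroup.DISEASE) for i in range(3)]
        changes.append(det_change("s3", DriverGroup.CLIMATE_CHANGE))
        (cell,) = dominant_driver(inc, changes, self.interval).values()
        assert cell.drivers == (DriverGroup.DISEASE,)
        assert not cell.tie_flag and not cell.star_flag

    def test_two_way_tie(self):
        inc = incidence_from_pairs([(f"s{i}", (0, 0)) for i in range(4)])
        changes = [det_change(f"s{i}", DriverGroup.DISEASE) for i in range(2)]
        changes += [det_change(f"s{i}", DriverGroup.CLIMATE_CHANGE) for i in (2, 3)]
        (cell,) = dominant_driver(inc, changes, self.interval).values()
        assert set(cell.drivers) == {DriverGroup.DISEASE, DriverGroup.CLIMATE_CHANGE}
        assert cell.tie_flag and not cell.star_flag

    def test_undetermined_dominant_stars(self):
        inc = incidence_from_pairs([("s0", (0, 0))])
        changes = [det_change("s0", DriverGroup.UNDETERMINED)]
        (cell,) = dominant_driver(inc, changes, self.interval).values()
        assert cell.star_flag

    def test_three_way_tie_stars(self):
        inc = incidence_from_pairs([(f"s{i}", (0, 0)) for i in range(3)])
        changes = [
            det_change("s0", DriverGroup.DISEASE),
            det_change("s1", DriverGroup.CLIMATE_CHANGE),
            det_change("s2", DriverGroup.HABITAT_LOSS_DEGRADATION),
        ]
        (cell,) = dominant_driver(inc, changes, self.interval).values()
        assert cell.star_flag and len(cell.drivers) == 3

    def test_only_deteriorations_in_interval_count(self):
        inc = incidence_from_pairs([("s0", (0, 0)), ("s1", (0, 0))])
        changes = [
            det_change("s0", DriverGroup.DISEASE, interval=(1980, 2004)),
        ]
        assert dominant_driver(inc, changes, self.interval) == {}

    def test_permutation_invariance(self):
        inc = incidence_from_pairs([(f"s{i}", (0, 0)) for i in range(5)])
        changes = [det_change(f"s{i}", DriverGroup.DISEASE) for i in range(3)]
        changes += [det_change(f"s{i}", DriverGroup.CLIMATE_CHANGE) for i in (3, 4)]
        forward = dominant_driver(inc, changes, self.interval)
        backward = dominant_driver(inc, list(reversed(changes)), self.interval)
        assert forward == backward
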