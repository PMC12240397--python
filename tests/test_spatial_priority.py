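"""Grid construction, point counting, quantile classes, Chao completeness,
priority scoring and polygon-overlap statistics."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from floragap.spatial_priority import (
    Grid,
    build_grid,
    cell_completeness,
    chao1_richness,
    classify_quantiles,
    compute_priorities,
    count_points_in_cells,
    overlap_stats,
    priority_score,
    top_cells,
)


def _occ(lons, lats, species):
    return pd.DataFrame(
        {"decimalLongitude": lons, "decimalLatitude": lats, "species": species}
    )


def test_two_degree_grid_over_four_degree_extent():
    grid = build_grid((0, 0, 4, 4), 2.0)
    assert grid.n_cells == 4


def test_one_degree_grid_has_four_times_the_cells():
    extent = (0, 0, 6, 4)
    assert build_grid(extent, 1.0).n_cells == 4 * build_grid(extent, 2.0).n_cells


def test_unsupported_resolution_rejected():
    with pytest.raises(ValueError, match="resolution"):
        build_grid((0, 0, 4, 4), 0.3)


def test_shared_edge_point_in_exactly_one_cell():
    grid = build_grid((0, 0, 4, 4), 2.0)
    ids = grid.point_to_cell(np.array([2.0]), np.array([1.0]))
    assert ids[0] == 1  # half-open rule: x = 2 belongs to the right-hand cell
    all_ids = [grid.point_to_cell(np.array([2.0]), np.array([2.0]))[0]]
    assert len(set(all_ids)) == 1


def test_counts_and_observed_richness():
    grid = build_grid((0, 0, 4, 4), 2.0)
    counts = count_points_in_cells(
        _occ([0.5, 0.7, 1.1], [0.5, 0.9, 0.2], ["a", "a", "b"]), grid
    )
    row = counts.table.set_index("cell_id").loc[0]
    assert row["n_records"] == 3 and row["s_obs"] == 2
    assert counts.table["n_records"].sum() == 3


def test_malformed_coordinates_rejected_with_count():
    grid = build_grid((0, 0, 4, 4), 2.0)
    counts = count_points_in_cells(
        _occ([0.5, "oops", 9.0], [0.5, 1.0, 1.0], ["a", "b", "c"]), grid
    )
    assert counts.n_rejected == 1
    assert counts.n_outside == 1
    assert counts.table["n_records"].sum() == 1


def test_point_in_cell_matches_brute_force():
    rng = np.random.default_rng(6)
    extent = (-10.0, -5.0, 10.0, 5.0)
    lons = rng.uniform(-12, 12, 1000)
    lats = rng.uniform(-6, 6, 1000)
    grid = build_grid(extent, 1.0)
    counts = count_points_in_cells(
        _occ(lons, lats, [f"s{i % 17}" for i in range(1000)]), grid
    )
    # brute-force double loop over cells and points
    brute = np.zeros(grid.n_cells, dtype=int)
    outside = 0
    for x, y in zip(lons, lats):
        hit = False
        for cid in range(grid.n_cells):
            x0, y0, x1, y1 = grid.cell_bounds(cid)
            if x0 <= x < x1 and y0 <= y < y1:
                brute[cid] += 1
                hit = True
                break
        outside += not hit
    assert np.array_equal(counts.table["n_records"].to_numpy(), brute)
    assert counts.n_outside == outside


def test_conservation_across_resolutions():
    rng = np.random.default_rng(10)
    occ = _occ(rng.uniform(0, 8, 500), rng.uniform(0, 8, 500),
               [f"s{i % 9}" for i in range(500)])
    for res in (0.5, 1.0, 2.0, "geohash156"):
        grid = build_grid((0, 0, 8, 8), res)
        counts = count_points_in_cells(occ, grid)
        assert counts.table["n_records"].sum() + counts.n_outside == 500


def test_quantile_classes_are_deciles():
    classes = classify_quantiles(np.arange(1, 101), 10)
    sizes = np.bincount(classes)[1:]
    assert np.all(sizes == 10)


def test_all_equal_values_fall_in_lowest_class():
    classes = classify_quantiles(np.full(40, 3.0), 10)
    assert np.all(classes == 1)


def test_quantile_class_sizes_near_equal_for_distinct_values():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=200)
    classes = classify_quantiles(vals, 10)
    sizes = np.bincount(classes, minlength=11)[1:]
    assert np.max(np.abs(sizes - 20)) <= 1


def test_chao1_closed_forms():
    # f1 = 4, f2 = 2, S_obs = 10 -> S_est = 14, completeness 71.4%
    abundances = Counter({f"s{i}": 1 for i in range(4)})
    abundances.update({f"d{i}": 2 for i in range(2)})
    abundances.update({f"m{i}": 5 for i in range(4)})
    assert chao1_richness(abundances.values()) == pytest.approx(14.0)
    assert cell_completeness(abundances, min_records=1) == pytest.approx(71.4, abs=0.05)


def test_every_species_seen_thrice_is_complete():
    abundances = Counter({f"s{i}": 3 for i in range(7)})
    assert cell_completeness(abundances, min_records=1) == pytest.approx(100.0)


def test_empty_or_sparse_cell_is_missing():
    assert cell_completeness(Counter()) is None
    assert cell_completeness(Counter({"a": 2}), min_records=5) is None


def test_priority_extremes():
    assert priority_score(1, 0.0) == 10  # mean deficit 0.95 rounds half-up
    assert priority_score(10, 100.0) == 0
    assert priority_score(5, None) == 8  # missing completeness = full deficit


def test_priority_monotone_in_both_deficits():
    rng = np.random.default_rng(3)
    for _ in range(200):
        d1, d2 = sorted(rng.integers(1, 11, size=2))
        c1, c2 = sorted(rng.uniform(0, 100, size=2))
        # lower density class and lower completeness never decrease priority
        assert priority_score(d1, c1) >= priority_score(d2, c2)


def test_priority_scale_free_in_record_counts():
    rng = np.random.default_rng(8)
    grid = build_grid((0, 0, 10, 10), 1.0)
    lons = rng.uniform(0, 10, 2000)
    lats = rng.uniform(0, 10, 2000)
    species = [f"s{i % 40}" for i in range(2000)]
    base = compute_priorities(count_points_in_cells(_occ(lons, lats, species), grid))
    tripled = compute_priorities(
        count_points_in_cells(
            _occ(np.tile(lons, 3), np.tile(lats, 3), species * 3), grid
        )
    )
    assert np.array_equal(base["density_class"], tripled["density_class"])


def test_overlap_counts_and_duplicate_idempotence():
    grid = build_grid((0, 0, 6, 5), 1.0)
    cells = grid.frame()
    cells["priority"] = 10
    cells["n_records"] = 0
    top = top_cells(cells, 30)
    pa_layer = [{"geometry": box(0, 4, 6, 5)}]  # exactly the top row: 6 cells
    summary = overlap_stats(top, pa_layer, grid, "PA")
    assert (summary.n_overlapping, summary.pct_overlap) == (6, pytest.approx(20.0))
    doubled = overlap_stats(top, pa_layer * 2, grid, "PA")
    assert doubled.n_overlapping == 6


def test_edge_touching_polygon_does_not_overlap():
    grid = build_grid((0, 0, 2, 2), 1.0)
    cells = grid.frame()
    cells["priority"] = 10
    cells["n_records"] = 0
    # polygon sharing only the boundary x = 2 with the grid
    summary = overlap_stats(top_cells(cells, 4), [{"geometry": box(2, 0, 3, 2)}], grid)
    assert summary.n_overlapping == 0


def test_empty_layer_gives_zero_percent():
    grid = build_grid((0, 0, 2, 2), 1.0)
    cells = grid.frame()
    cells["priority"] = 5
    cells["n_records"] = 0
    summary = overlap_stats(top_cells(cells, 4), [], grid)
    assert summary.pct_overlap == 0.0
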