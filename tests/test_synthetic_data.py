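"""Generator contracts: determinism, curve shape, discordance and spatial layout."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from shapely.ops import unary_union

from floragap.discovery_curves import decade_starts
from floragap.synthetic_data import (
    SpatialConfig,
    SyntheticConfig,
    generate_effort_and_density,
    generate_name_table,
    generate_spatial_layers,
    growth_fraction,
)


def test_same_seed_gives_byte_identical_tables():
    cfg = SyntheticConfig(seed=42, n_strata=2, true_asymptote=200)
    a = generate_name_table(cfg).table
    b = generate_name_table(cfg).table
    pd.testing.assert_frame_equal(a, b)
    assert a.to_csv(index=False) == b.to_csv(index=False)


def test_no_synonyms_means_one_row_per_species():
    cfg = SyntheticConfig(
        seed=5, n_strata=1, true_asymptote=150, synonym_rate=0.0,
        discordance_rate=0.0, infraspecific_rate=0.0,
    )
    table = generate_name_table(cfg).table
    assert (table["status"] == "accepted").all()
    assert table["accepted_id"].is_unique
    # every name year equals the basionym year: all-names == basionyms
    votes = table["basionym_year_flora"]
    years = table["year_primary"].fillna(table["year_fallback"])
    assert (votes == years).all()


def test_gompertz_truncation_matches_generating_curve():
    # oracle: the generating curve evaluated at the window end bounds the
    # expected described fraction
    cfg = SyntheticConfig(seed=7, n_strata=1, true_asymptote=500,
                          discovery_shape="gompertz", synonym_rate=0.0)
    truth = generate_name_table(cfg).truth["strata"]
    n_described = next(iter(truth.values()))["n_described"]
    frac_end = growth_fraction(cfg.n_decades, "gompertz", cfg.shape_params, cfg.n_decades)
    assert n_described <= 500
    assert n_described >= 0.95 * 500
    # binomial fluctuation around the curve value stays within 5 SD
    sd = np.sqrt(500 * frac_end * (1 - frac_end))
    assert abs(n_described - 500 * frac_end) <= 5 * sd


def test_invalid_shape_rejected():
    with pytest.raises(ValueError, match="discovery_shape"):
        SyntheticConfig(discovery_shape="cubic")


def test_cumulative_curve_monotone_and_bounded(name_table, default_cfg):
    for stratum, info in name_table.truth["strata"].items():
        per_decade = np.array(info["described_per_decade"])
        cum = np.cumsum(per_decade)
        assert np.all(np.diff(cum) >= 0)
        assert cum[-1] <= info["true_asymptote"]


def test_discordance_rate_within_three_se(name_table, default_cfg):
    total_species = sum(i["n_described"] for i in name_table.truth["strata"].values())
    discordant = sum(i["n_discordant"] for i in name_table.truth["strata"].values())
    p = default_cfg.discordance_rate
    se = np.sqrt(p * (1 - p) * total_species)
    assert abs(discordant - p * total_species) <= 3 * se


def test_constant_effort_schedule_reproduced():
    cfg = SyntheticConfig(seed=1, effort_schedule=5)
    effort, density = generate_effort_and_density(cfg)
    assert (effort["taxonomists"] == 5).all()
    assert len(effort) == len(decade_starts(cfg.window))


def test_density_series_positive_and_monotone():
    cfg = SyntheticConfig(seed=9, n_strata=3)
    _, density = generate_effort_and_density(cfg)
    for col in density.columns.drop("decade_start"):
        vals = density[col].to_numpy()
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) > 0)


def test_effort_driven_counts_track_taxonomist_numbers():
    n_dec = len(decade_starts())
    rng = np.random.default_rng(3)
    schedule = rng.integers(0, 40, size=n_dec)
    cfg = SyntheticConfig(
        seed=13, n_strata=1, true_asymptote=2000,
        discovery_shape="effort_driven", effort_schedule=schedule.tolist(),
        synonym_rate=0.0,
    )
    truth = generate_name_table(cfg).truth["strata"]
    described = np.array(next(iter(truth.values()))["described_per_decade"], dtype=float)
    rho, _ = spearmanr(schedule, described)
    assert rho > 0
    # decades with zero taxonomists force zero descriptions
    assert np.all(described[schedule == 0] == 0)


def test_spatial_points_inside_extent_and_truth_consistent():
    cfg = SyntheticConfig(seed=21, spatial=SpatialConfig(n_occurrences=1500))
    layers = generate_spatial_layers(cfg)
    lon0, lat0, lon1, lat1 = cfg.spatial.extent
    occ = layers.occurrences
    assert occ["decimalLongitude"].between(lon0, lon1).all()
    assert occ["decimalLatitude"].between(lat0, lat1).all()
    assert sum(c["n_records"] for c in layers.truth["cells"].values()) == len(occ)


def test_zero_pa_fraction_gives_empty_layer():
    cfg = SyntheticConfig(seed=2, spatial=SpatialConfig(pa_fraction=0.0))
    layers = generate_spatial_layers(cfg)
    assert layers.protected_areas == []


def test_configured_ti_coverage_realized():
    # Monte-Carlo area check: fraction of uniform points inside the TI layer
    cfg = SyntheticConfig(seed=8, spatial=SpatialConfig(ti_fraction=0.30))
    layers = generate_spatial_layers(cfg)
    union = unary_union([r["geometry"] for r in layers.indigenous_lands])
    lon0, lat0, lon1, lat1 = cfg.spatial.extent
    extent_area = (lon1 - lon0) * (lat1 - lat0)
    assert union.area / extent_area == pytest.approx(0.30, abs=1e-9)
    rng = np.random.default_rng(0)
    pts = np.column_stack(
        [rng.uniform(lon0, lon1, 20000), rng.uniform(lat0, lat1, 20000)]
    )
    from shapely.geometry import Point
    from shapely.strtree import STRtree

    tree = STRtree([r["geometry"] for r in layers.indigenous_lands])
    inside = sum(len(tree.query(Point(x, y), predicate="within")) > 0 for x, y in pts)
    assert 0.28 <= inside / 20000 <= 0.32
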