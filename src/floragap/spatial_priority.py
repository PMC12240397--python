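"""Grid-based collection density, inventory completeness and discovery priority.

Occurrence records are binned into a regular degree grid (or a ~156 km
geohash-equivalent grid) with a half-open [min, max) boundary convention so
every point lands in exactly one cell.  Per-cell richness is estimated with
a Chao-type nonparametric estimator from singleton/doubleton counts, the
record-count distribution is cut into equal-count (quantile) classes, and a
0-10 priority score combines the density and completeness deficits —
sparsely collected, incompletely inventoried cells score highest.  Overlap
statistics report how many of the top-priority cells intersect a polygon
layer (protected areas, Indigenous lands) with positive area.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape
from shapely.validation import make_valid

__all__ = [
    "GEOHASH156_DEG",
    "Grid",
    "GridCounts",
    "OverlapSummary",
    "build_grid",
    "count_points_in_cells",
    "classify_quantiles",
    "chao1_richness",
    "cell_completeness",
    "priority_score",
    "compute_priorities",
    "top_cells",
    "overlap_stats",
    "assign_domains",
    "read_geojson",
    "write_cells_geojson",
]

# geohash precision-3 cells are 1.40625 deg x 1.40625 deg (~156 km at the equator)
GEOHASH156_DEG = 1.40625

_RESOLUTIONS = {0.1: 0.1, 0.5: 0.5, 1.0: 1.0, 2.0: 2.0, "geohash156": GEOHASH156_DEG}


@dataclass
class Grid:
    """Regular rectangular grid tiling an extent with half-open cells."""

    extent: tuple[float, float, float, float]
    res_deg: float
    ncols: int = field(init=False)
    nrows: int = field(init=False)

    def __post_init__(self) -> None:
        lon0, lat0, lon1, lat1 = self.extent
        if lon1 <= lon0 or lat1 <= lat0:
            raise ValueError("extent must have positive width and height")
        self.ncols = int(np.ceil((lon1 - lon0) / self.res_deg - 1e-9))
        self.nrows = int(np.ceil((lat1 - lat0) / self.res_deg - 1e-9))

    @property
    def n_cells(self) -> int:
        return self.ncols * self.nrows

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        row, col = divmod(cell_id, self.ncols)
        lon0, lat0, _, _ = self.extent
        x0 = lon0 + col * self.res_deg
        y0 = lat0 + row * self.res_deg
        return (x0, y0, x0 + self.res_deg, y0 + self.res_deg)

    def cell_box(self, cell_id: int):
        return box(*self.cell_bounds(cell_id))

    def point_to_cell(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Cell id per point; -1 for points outside the extent (half-open)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lon0, lat0, lon1, lat1 = self.extent
        col = np.floor((lon - lon0) / self.res_deg).astype(int)
        row = np.floor((lat - lat0) / self.res_deg).astype(int)
        inside = (lon >= lon0) & (lon < lon1) & (lat >= lat0) & (lat < lat1)
        ids = row * self.ncols + col
        return np.where(inside, ids, -1)

    def frame(self) -> pd.DataFrame:
        ids = np.arange(self.n_cells)
        bounds = np.array([self.cell_bounds(i) for i in ids])
        return pd.DataFrame(
            {
                "cell_id": ids,
                "lon_min": bounds[:, 0],
                "lat_min": bounds[:, 1],
                "lon_max": bounds[:, 2],
                "lat_max": bounds[:, 3],
            }
        )


def build_grid(extent, resolution) -> Grid:
    """Build a grid at one of the supported resolutions.

    ``resolution`` is 0.1, 0.5, 1.0 or 2.0 (degrees) or the string
    ``"geohash156"`` for ~156 km cells.
    """
    if resolution not in _RESOLUTIONS:
        raise ValueError(
            f"unsupported resolution {resolution!r}; choose from {sorted(map(str, _RESOLUTIONS))}"
        )
    return Grid(extent=tuple(extent), res_deg=_RESOLUTIONS[resolution])


@dataclass
class GridCounts:
    """Per-cell record counts, observed richness and species abundances."""

    grid: Grid
    table: pd.DataFrame
    species_counts: dict[int, Counter]
    n_outside: int
    n_rejected: int


def count_points_in_cells(
    occurrences: pd.DataFrame,
    grid: Grid,
    lon_col: str = "decimalLongitude",
    lat_col: str = "decimalLatitude",
    species_col: str = "species",
) -> GridCounts:
    """Exact point-in-cell assignment of occurrence records.

    Rows with malformed coordinates are rejected (counted); points outside
    the extent are reported separately.
    """
    lon = pd.to_numeric(occurrences[lon_col], errors="coerce")
    lat = pd.to_numeric(occurrences[lat_col], errors="coerce")
    ok = lon.notna() & lat.notna()
    n_rejected = int((~ok).sum())
    lon_v = lon[ok].to_numpy()
    lat_v = lat[ok].to_numpy()
    species = occurrences.loc[ok, species_col].to_numpy()
    ids = grid.point_to_cell(lon_v, lat_v)
    n_outside = int(np.sum(ids < 0))
    species_counts: dict[int, Counter] = {}
    for cid, sp in zip(ids, species):
        if cid < 0:
            continue
        species_counts.setdefault(int(cid), Counter())[sp] += 1
    table = grid.frame()
    table["n_records"] = [
        sum(species_counts.get(i, Counter()).values()) for i in table["cell_id"]
    ]
    table["s_obs"] = [len(species_counts.get(i, Counter())) for i in table["cell_id"]]
    return GridCounts(
        grid=grid, table=table, species_counts=species_counts,
        n_outside=n_outside, n_rejected=n_rejected,
    )


def classify_quantiles(values, n_classes: int = 10) -> np.ndarray:
    """Equal-count (quantile) classes 1..n_classes, ties to the lower class."""
    values = np.asarray(values, dtype=float)
    if len(values) < n_classes:
        warnings.warn(
            f"only {len(values)} values for {n_classes} classes: degenerate classing",
            stacklevel=2,
        )
    qs = np.quantile(values, np.arange(1, n_classes) / n_classes)
    # class = 1 + number of boundaries strictly below the value
    return 1 + np.searchsorted(qs, values, side="left")


def chao1_richness(abundances) -> float:
    """Chao1 estimate S_obs + f1^2/(2 f2) with the bias-corrected f2=0 form."""
    counts = np.asarray(list(abundances), dtype=int)
    counts = counts[counts > 0]
    s_obs = len(counts)
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def cell_completeness(species_abundances: Counter | dict, min_records: int = 5) -> float | None:
    """Percent completeness 100 S_obs / S_est for one cell.

    Returns ``None`` (missing) for empty cells or cells with fewer than
    ``min_records`` records, where the estimator is unreliable.
    """
    if not species_abundances:
        return None
    counts = list(species_abundances.values())
    if sum(counts) < min_records:
        return None
    s_est = chao1_richness(counts)
    return 100.0 * len(counts) / s_est


def priority_score(density_class: int, completeness: float | None) -> int:
    """0-10 discovery priority from density and completeness deficits.

    Equal-weight mean of (1 - density_class/10) and (1 - completeness/100),
    missing completeness treated as a full deficit, scaled to 0-10 and
    rounded half-up.  Lower density or lower completeness never decreases
    the score.
    """
    d_deficit = 1.0 - density_class / 10.0
    missing = completeness is None or (isinstance(completeness, float) and np.isnan(completeness))
    c_deficit = 1.0 if missing else 1.0 - completeness / 100.0
    raw = 10.0 * (d_deficit + c_deficit) / 2.0
    return int(np.floor(raw + 0.5))


def compute_priorities(
    counts: GridCounts, n_classes: int = 10, min_records: int = 5
) -> pd.DataFrame:
    """Attach density class, completeness and priority to the cell table."""
    table = counts.table.copy()
    table["density_class"] = classify_quantiles(table["n_records"].to_numpy(), n_classes)
    table["completeness"] = [
        cell_completeness(counts.species_counts.get(i, Counter()), min_records)
        for i in table["cell_id"]
    ]
    table["priority"] = [
        priority_score(dc, comp)
        for dc, comp in zip(table["density_class"], table["completeness"])
    ]
    return table


def top_cells(priorities: pd.DataFrame, n_top: int = 30) -> pd.DataFrame:
    """The n_top highest-priority cells (deterministic tie-break by fewer
    records, then cell id)."""
    ordered = priorities.sort_values(
        ["priority", "n_records", "cell_id"], ascending=[False, True, True]
    )
    return ordered.head(n_top).reset_index(drop=True)


@dataclass
class OverlapSummary:
    layer: str
    n_top: int
    n_overlapping: int
    per_domain: dict[str, int] = field(default_factory=dict)

    @property
    def pct_overlap(self) -> float:
        return 100.0 * self.n_overlapping / self.n_top if self.n_top else 0.0


def _clean_geometries(records: list[dict]) -> list:
    geoms = []
    n_bad = 0
    for rec in records:
        g = rec["geometry"] if isinstance(rec, dict) else rec
        if not g.is_valid:
            g = make_valid(g)
            if not g.is_valid or g.is_empty:
                n_bad += 1
                continue
        geoms.append(g)
    if n_bad:
        warnings.warn(f"{n_bad} invalid geometry(ies) rejected", stacklevel=3)
    return geoms


def overlap_stats(
    cells: pd.DataFrame,
    layer_records: list[dict],
    grid: Grid,
    layer: str = "PA",
    domain_col: str | None = None,
) -> OverlapSummary:
    """Fraction of top cells whose rectangle intersects the layer with
    positive area.  Duplicate polygons do not change the result (union
    semantics); invalid geometries are repaired where possible."""
    geoms = _clean_geometries(layer_records)
    n_overlap = 0
    per_domain: dict[str, int] = {}
    for _, row in cells.iterrows():
        cell_geom = grid.cell_box(int(row["cell_id"]))
        hit = any(
            cell_geom.intersects(g) and cell_geom.intersection(g).area > 0
            for g in geoms
        )
        if hit:
            n_overlap += 1
            if domain_col and domain_col in row.index and pd.notna(row[domain_col]):
                per_domain[row[domain_col]] = per_domain.get(row[domain_col], 0) + 1
    return OverlapSummary(
        layer=layer, n_top=len(cells), n_overlapping=n_overlap, per_domain=per_domain
    )


def assign_domains(
    priorities: pd.DataFrame, domain_records: list[dict], grid: Grid,
    name_key: str = "domain",
) -> pd.DataFrame:
    """Majority-area domain membership per cell."""
    table = priorities.copy()
    domains = []
    for _, row in table.iterrows():
        cell_geom = grid.cell_box(int(row["cell_id"]))
        best_name, best_area = None, 0.0
        for rec in domain_records:
            area = cell_geom.intersection(rec["geometry"]).area
            if area > best_area:
                best_area = area
                best_name = rec.get("properties", {}).get(name_key)
        domains.append(best_name)
    table["domain"] = domains
    return table


def read_geojson(path) -> list[dict]:
    """Read a GeoJSON FeatureCollection into (geometry, properties) records."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return [
        {"geometry": shape(feat["geometry"]), "properties": feat.get("properties", {})}
        for feat in payload.get("features", [])
    ]


def write_cells_geojson(path, cells: pd.DataFrame, grid: Grid) -> None:
    """Write the per-cell priority layer as GeoJSON (WGS84)."""
    features = []
    for _, row in cells.iterrows():
        props = {
            k: (None if pd.isna(v) else (v.item() if hasattr(v, "item") else v))
            for k, v in row.items()
        }
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(grid.cell_box(int(row["cell_id"]))),
                "properties": props,
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
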