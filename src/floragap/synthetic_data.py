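"""Synthetic pipeline inputs with known ground truth.

Every downstream stage (nomenclature assembly, decade binning, growth-model
fitting, effort modelling, regressions, priority mapping) is exercised
against data generated here, where the true asymptote, the per-decade effort
schedule, the synonym/basionym structure and the per-cell species layout are
all known exactly.

The generator emulates, on a toy scale, the shape of real nomenclatural and
occurrence inputs: a right-censored discovery curve approaching a known
asymptote N* per stratum, a finite author pool per decade, three per-source
basionym-year columns that occasionally disagree, monotone population-density
series, and spatially clustered occurrence records over toy polygon layers.
Description dates are drawn by inverting the chosen growth curve
(inverse-CDF sampling), which guarantees the asymptotic shape the fitters
assume.  All randomness flows from one seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from floragap.discovery_curves import DEFAULT_WINDOW, decade_index, decade_starts

DOMAINS = ("Amazonia", "Atlantic Forest", "Caatinga", "Cerrado", "Pampa", "Pantanal")
HABITS = ("tree", "shrub", "herb", "climber", "liana")
FAMILIES = (
    "Fabaceae",
    "Orchidaceae",
    "Asteraceae",
    "Rubiaceae",
    "Melastomataceae",
    "Myrtaceae",
    "Bromeliaceae",
    "Poaceae",
)

SHAPES = ("gompertz", "logistic", "weibull", "effort_driven")

__all__ = [
    "SyntheticConfig",
    "SpatialConfig",
    "NameTable",
    "SpatialLayers",
    "generate_name_table",
    "generate_effort_and_density",
    "generate_spatial_layers",
    "growth_fraction",
    "write_geojson",
]


@dataclass
class SpatialConfig:
    """Toy landscape: a rectangular WGS84 extent with clustered occurrences."""

    extent: tuple[float, float, float, float] = (-70.0, -20.0, -40.0, 0.0)
    n_clusters: int = 8
    cluster_sd_deg: float = 1.0
    n_occurrences: int = 5000
    n_species: int = 300
    pa_fraction: float = 0.19
    ti_fraction: float = 0.135

    def __post_init__(self) -> None:
        lon0, lat0, lon1, lat1 = self.extent
        if lon1 <= lon0 or lat1 <= lat0:
            raise ValueError("extent must have positive width and height")
        for name in ("pa_fraction", "ti_fraction"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_strata: int = 2
    true_asymptote: int | Sequence[int] = 500
    start_year: int = DEFAULT_WINDOW[0]
    end_year: int = DEFAULT_WINDOW[1]
    discovery_shape: str = "gompertz"
    shape_params: dict = field(default_factory=dict)
    effort_schedule: Sequence[int] | int = 12
    effort_rate: float = 0.012
    synonym_rate: float = 0.5
    discordance_rate: float = 0.05
    infraspecific_rate: float = 0.1
    missing_primary_rate: float = 0.05
    second_author_prob: float = 0.3
    spatial: SpatialConfig = field(default_factory=SpatialConfig)

    def __post_init__(self) -> None:
        if self.discovery_shape not in SHAPES:
            raise ValueError(
                f"unknown discovery_shape {self.discovery_shape!r}; choose from {SHAPES}"
            )
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")
        if self.synonym_rate < 0:
            raise ValueError("synonym_rate must be >= 0")
        for name in ("discordance_rate", "infraspecific_rate", "missing_primary_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.asymptotes) < 1:
            raise ValueError("true asymptote must be >= 1")

    @property
    def window(self) -> tuple[int, int]:
        return (self.start_year, self.end_year)

    @property
    def asymptotes(self) -> list[int]:
        if np.isscalar(self.true_asymptote):
            return [int(self.true_asymptote)] * self.n_strata
        vals = list(self.true_asymptote)
        if len(vals) != self.n_strata:
            raise ValueError("true_asymptote length must match n_strata")
        return [int(v) for v in vals]

    @property
    def n_decades(self) -> int:
        return len(decade_starts(self.window))

    def effort_per_decade(self) -> np.ndarray:
        n = self.n_decades
        if np.isscalar(self.effort_schedule):
            return np.full(n, int(self.effort_schedule))
        sched = np.asarray(self.effort_schedule, dtype=int)
        if len(sched) != n:
            raise ValueError(f"effort_schedule must have {n} entries, got {len(sched)}")
        if np.any(sched < 0):
            raise ValueError("effort_schedule entries must be >= 0")
        return sched

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# discovery-curve shapes (continuous time in decade units, t in [0, n])

def growth_fraction(t, shape: str, params: dict | None = None, n_decades: int = 27):
    """Fraction of the species pool expected described by decade-time *t*.

    Default shape parameters place the inflection mid-window so the series is
    clearly right-censored but close to its asymptote by the final decade.
    """
    p = dict(params or {})
    t = np.asarray(t, dtype=float)
    mid = p.get("c", n_decades * 12 / 27)
    if shape == "gompertz":
        b = p.get("b", 0.25)
        return np.exp(-np.exp(-b * (t - mid)))
    if shape == "logistic":
        b = p.get("b", 0.35)
        return 1.0 / (1.0 + np.exp(-b * (t - mid)))
    if shape == "weibull":
        b = p.get("b", n_decades * 14 / 27)
        c = p.get("c", 2.5)
        return 1.0 - np.exp(-((t / b) ** c))
    raise ValueError(f"no closed-form curve for shape {shape!r}")


def _invert_fraction(u: np.ndarray, shape: str, params: dict, n_decades: int) -> np.ndarray:
    """Inverse of :func:`growth_fraction` (u in (0,1) -> decade-time)."""
    p = dict(params or {})
    mid = p.get("c", n_decades * 12 / 27)
    if shape == "gompertz":
        b = p.get("b", 0.25)
        return mid - np.log(-np.log(u)) / b
    if shape == "logistic":
        b = p.get("b", 0.35)
        return mid - np.log(1.0 / u - 1.0) / b
    if shape == "weibull":
        b = p.get("b", n_decades * 14 / 27)
        c = p.get("c", 2.5)
        return b * (-np.log(1.0 - u)) ** (1.0 / c)
    raise ValueError(f"no inverse curve for shape {shape!r}")


def _decade_time_to_year(t: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    first = decade_starts(window)[0]
    years = np.floor(first + 10.0 * t).astype(int)
    return np.clip(years, window[0], window[1])


@dataclass
class NameTable:
    """Generated raw name table plus its ground truth."""

    table: pd.DataFrame
    truth: dict

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False, encoding="utf-8")


def _draw_description_years(
    cfg: SyntheticConfig, n_star: int, rng: np.random.Generator
) -> np.ndarray:
    """Description year for each of the N* species; -1 = still undescribed."""
    n_dec = cfg.n_decades
    if cfg.discovery_shape == "effort_driven":
        effort = cfg.effort_per_decade()
        starts = decade_starts(cfg.window)
        years = np.full(n_star, -1, dtype=int)
        undescribed = list(range(n_star))
        for i in range(n_dec):
            if not undescribed:
                break
            p = 1.0 - np.exp(-cfg.effort_rate * effort[i])
            mask = rng.random(len(undescribed)) < p
            chosen = [s for s, m in zip(undescribed, mask) if m]
            lo = max(starts[i], cfg.start_year)
            hi = min(starts[i] + 9, cfg.end_year)
            years[chosen] = rng.integers(lo, hi + 1, size=len(chosen))
            undescribed = [s for s, m in zip(undescribed, mask) if not m]
        return years
    u = rng.random(n_star)
    t = _invert_fraction(np.clip(u, 1e-12, 1 - 1e-12), cfg.discovery_shape,
                         cfg.shape_params, n_dec)
    years = np.full(n_star, -1, dtype=int)
    described = t <= n_dec
    years[described] = _decade_time_to_year(t[described], cfg.window)
    return years


def _assign_authors(
    years: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    pool: list[str],
) -> list[str]:
    """Authorship strings drawn from the finite per-decade author pool.

    Names published in decade i are authored round-robin by that decade's
    active authors (the first T_i of the pool), so whenever a decade holds at
    least T_i names every active author appears and the downstream distinct
    count recovers T_i exactly.
    """
    effort = cfg.effort_per_decade()
    idx = decade_index(years, cfg.window)
    order = np.argsort(idx, kind="stable")
    counters = np.zeros(cfg.n_decades, dtype=int)
    out = [""] * len(years)
    for j in order:
        i = idx[j]
        if i < 0:
            continue
        t_i = effort[i]
        if t_i == 0:
            out[j] = pool[0]  # should not happen: no descriptions at zero effort
            continue
        lead = pool[counters[i] % t_i]
        counters[i] += 1
        if t_i > 1 and rng.random() < cfg.second_author_prob:
            other = pool[int(rng.integers(0, t_i))]
            if other != lead:
                out[j] = f"{lead} & {other}"
                continue
        out[j] = lead
    return out


def generate_name_table(cfg: SyntheticConfig) -> NameTable:
    """Generate the raw name-level table for all strata.

    Each accepted species has exactly one earliest name (its basionym row)
    and a Poisson(synonym_rate) number of later synonyms whose years are
    uniform between the basionym year and the end of the window.  Three
    per-source basionym-year columns agree except with probability
    ``discordance_rate``, in which case one randomly chosen source is
    perturbed upward by 1-5 years.
    """
    rng = cfg.rng()
    pool = [f"auth{k:03d}" for k in range(int(np.max(cfg.effort_per_decade())) or 1)]
    rows = []
    truth: dict = {"strata": {}, "seed": cfg.seed}
    for s, n_star in enumerate(cfg.asymptotes):
        stratum = DOMAINS[s % len(DOMAINS)]
        years = _draw_description_years(cfg, n_star, rng)
        described = np.flatnonzero(years > 0)
        authors = _assign_authors(years, cfg, rng, pool)
        n_discordant = 0
        for k in described:
            sp_id = f"s{s}sp{k:05d}"
            year = int(years[k])
            family = FAMILIES[k % len(FAMILIES)]
            habit = HABITS[int(rng.integers(0, len(HABITS)))]
            votes = [year, year, year]
            if rng.random() < cfg.discordance_rate:
                votes[int(rng.integers(0, 3))] = year + int(rng.integers(1, 6))
                n_discordant += 1
            year_primary: float | int = year
            year_fallback: float | int = np.nan
            if rng.random() < cfg.missing_primary_rate:
                year_primary, year_fallback = np.nan, year
            rows.append(
                {
                    "name_id": f"{sp_id}a",
                    "scientific_name": f"Genus{s} species{k}",
                    "authorship": authors[k],
                    "rank": "species",
                    "status": "accepted",
                    "accepted_id": sp_id,
                    "family": family,
                    "year_primary": year_primary,
                    "year_fallback": year_fallback,
                    "basionym_year_flora": votes[0],
                    "basionym_year_tropicos": votes[1],
                    "basionym_year_wcvp": votes[2],
                    "domains": stratum,
                    "habit": habit,
                    "native": True,
                }
            )
            n_syn = int(rng.poisson(cfg.synonym_rate))
            for m in range(n_syn):
                syn_year = int(rng.integers(year, cfg.end_year + 1))
                rows.append(
                    {
                        "name_id": f"{sp_id}syn{m}",
                        "scientific_name": f"Genus{s} synonymum{k}_{m}",
                        "authorship": pool[int(rng.integers(0, len(pool)))],
                        "rank": "species",
                        "status": "synonym",
                        "accepted_id": sp_id,
                        "family": family,
                        "year_primary": syn_year,
                        "year_fallback": np.nan,
                        "basionym_year_flora": np.nan,
                        "basionym_year_tropicos": np.nan,
                        "basionym_year_wcvp": np.nan,
                        "domains": stratum,
                        "habit": habit,
                        "native": True,
                    }
                )
            if rng.random() < cfg.infraspecific_rate:
                inf_year = int(rng.integers(year, cfg.end_year + 1))
                rows.append(
                    {
                        "name_id": f"{sp_id}inf",
                        "scientific_name": f"Genus{s} species{k} var. minor",
                        "authorship": pool[int(rng.integers(0, len(pool)))],
                        "rank": "infraspecific",
                        "status": "accepted",
                        "accepted_id": sp_id,
                        "family": family,
                        "year_primary": inf_year,
                        "year_fallback": np.nan,
                        "basionym_year_flora": np.nan,
                        "basionym_year_tropicos": np.nan,
                        "basionym_year_wcvp": np.nan,
                        "domains": stratum,
                        "habit": habit,
                        "native": True,
                    }
                )
        series = np.bincount(
            decade_index(years[described], cfg.window), minlength=cfg.n_decades
        )
        truth["strata"][stratum] = {
            "true_asymptote": n_star,
            "n_described": int(len(described)),
            "described_per_decade": series.tolist(),
            "n_discordant": n_discordant,
            "species_years": {f"s{s}sp{k:05d}": int(years[k]) for k in described},
        }
    table = pd.DataFrame(rows)
    return NameTable(table=table, truth=truth)


def generate_effort_and_density(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-decade taxonomist counts and monotone population-density series.

    Density grows multiplicatively (rate drawn per decade, never negative)
    from a stratum-specific baseline, emulating census series that rise
    monotonically over the window.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    starts = decade_starts(cfg.window)
    effort = pd.DataFrame({"decade_start": starts, "taxonomists": cfg.effort_per_decade()})
    density = pd.DataFrame({"decade_start": starts})
    for s in range(cfg.n_strata):
        stratum = DOMAINS[s % len(DOMAINS)]
        base = 0.1 * (1 + s)
        rates = rng.uniform(0.05, 0.25, size=len(starts))
        density[stratum] = base * np.cumprod(1.0 + rates)
    return effort, density


@dataclass
class SpatialLayers:
    """Generated occurrences, toy polygon layers and per-cell ground truth."""

    occurrences: pd.DataFrame
    domains: list[dict]
    protected_areas: list[dict]
    indigenous_lands: list[dict]
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.occurrences.to_csv(outdir / "occurrences.csv", index=False)
        write_geojson(outdir / "domains.geojson", self.domains)
        write_geojson(outdir / "protected_areas.geojson", self.protected_areas)
        write_geojson(outdir / "indigenous_lands.geojson", self.indigenous_lands)


def _strip_layer(extent, fraction: float, name_prefix: str, n_strips: int = 3) -> list[dict]:
    """Disjoint vertical strips covering exactly *fraction* of the extent area."""
    lon0, lat0, lon1, lat1 = extent
    if fraction <= 0:
        return []
    width = (lon1 - lon0) * fraction
    n_strips = max(1, n_strips)
    strip_w = width / n_strips
    gap = ((lon1 - lon0) - width) / (n_strips + 1)
    geoms = []
    x = lon0 + gap
    for i in range(n_strips):
        geoms.append(
            {
                "geometry": box(x, lat0, x + strip_w, lat1),
                "properties": {"name": f"{name_prefix}_{i}"},
            }
        )
        x += strip_w + gap
    return geoms


def generate_spatial_layers(cfg: SyntheticConfig, truth_resolution: float = 1.0) -> SpatialLayers:
    """Clustered occurrence points over a toy landscape with PA/TI strips.

    PA and TI layers are built as disjoint rectangle strips whose summed area
    equals the configured fraction of the extent exactly.  Ground truth
    records, per cell of a ``truth_resolution``-degree grid anchored at the
    extent corner, the record count and distinct-species count computed by an
    independent floor-division pass at generation time.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    sp = cfg.spatial
    lon0, lat0, lon1, lat1 = sp.extent
    n = sp.n_occurrences
    n_species = sp.n_species
    if sp.n_clusters > 0:
        centers = np.column_stack(
            [rng.uniform(lon0, lon1, sp.n_clusters), rng.uniform(lat0, lat1, sp.n_clusters)]
        )
        species_cluster = rng.integers(0, sp.n_clusters, size=n_species)
        abundance = rng.lognormal(mean=0.0, sigma=1.0, size=n_species)
        abundance /= abundance.sum()
        species_idx = rng.choice(n_species, size=n, p=abundance)
        lon = np.empty(n)
        lat = np.empty(n)
        for j in range(n):
            c = centers[species_cluster[species_idx[j]]]
            while True:
                x = rng.normal(c[0], sp.cluster_sd_deg)
                y = rng.normal(c[1], sp.cluster_sd_deg)
                if lon0 <= x < lon1 and lat0 <= y < lat1:
                    lon[j], lat[j] = x, y
                    break
    else:
        lon = rng.uniform(lon0, lon1, n)
        lat = rng.uniform(lat0, lat1, n)
        species_idx = rng.integers(0, n_species, size=n)
    years = rng.integers(cfg.start_year, cfg.end_year + 1, size=n)
    occ = pd.DataFrame(
        {
            "species": [f"occsp{k:05d}" for k in species_idx],
            "decimalLatitude": lat,
            "decimalLongitude": lon,
            "year": years,
        }
    )
    # independent per-cell truth by direct floor division
    res = truth_resolution
    ix = np.floor((lon - lon0) / res).astype(int)
    iy = np.floor((lat - lat0) / res).astype(int)
    cell_truth: dict[str, dict] = {}
    for j in range(n):
        key = f"{ix[j]}_{iy[j]}"
        entry = cell_truth.setdefault(key, {"n_records": 0, "species": set()})
        entry["n_records"] += 1
        entry["species"].add(int(species_idx[j]))
    truth = {
        "resolution": res,
        "cells": {
            k: {"n_records": v["n_records"], "s_obs": len(v["species"])}
            for k, v in cell_truth.items()
        },
    }
    n_dom = max(1, cfg.n_strata)
    dom_w = (lon1 - lon0) / n_dom
    domains = [
        {
            "geometry": box(lon0 + i * dom_w, lat0, lon0 + (i + 1) * dom_w, lat1),
            "properties": {"domain": DOMAINS[i % len(DOMAINS)]},
        }
        for i in range(n_dom)
    ]
    pas = _strip_layer(sp.extent, sp.pa_fraction, "PA")
    tis = _strip_layer(sp.extent, sp.ti_fraction, "TI", n_strips=2)
    return SpatialLayers(
        occurrences=occ,
        domains=domains,
        protected_areas=pas,
        indigenous_lands=tis,
        truth=truth,
    )


def write_geojson(path, records: list[dict]) -> None:
    """Write (geometry, properties) records as a WGS84 GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(rec["geometry"]),
            "properties": rec.get("properties", {}),
        }
        for rec in records
    ]
    payload = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
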