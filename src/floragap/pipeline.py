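"""End-to-end orchestration: simulate -> datasets -> fits -> averaging ->
regressions -> priority map, driven by one declarative config dict.

Each stage reads only the artifacts of earlier stages from the output
directory and writes its own delimited-text/GeoJSON artifacts, so stages
never mutate one another's inputs.  A manifest records the package version,
the seed and a hash of the config; identical config + seed reproduces
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

import floragap
from floragap import synthetic_data as synth
from floragap import nomenclature
from floragap.discovery_curves import DEFAULT_WINDOW, bin_by_decade, count_taxonomists, decade_starts
from floragap.effort_model import fit_effort_model_tiers
from floragap.growth_models import MODELS, ModelFit, akaike_weights, fit_growth_model, fits_to_frame
from floragap.model_averaging import aggregate, average_models
from floragap.predictor_regressions import best_family, window_modes
from floragap import spatial_priority as spatial

__all__ = ["DEFAULT_CONFIG", "run", "config_hash"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {},            # SyntheticConfig overrides; empty dict -> defaults
    "window": list(DEFAULT_WINDOW),
    "dataset_mode": "both",     # all_names | basionyms | both
    "strata_by": "domain",      # domain | family | habit | none
    "family_min_species": 500,
    "models": list(MODELS),
    "criterion": "aicc",
    "pool_effort": False,
    "spatial": {"resolution": 1.0, "n_top": 30, "min_records": 5, "n_classes": 10},
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def stage_simulate(config: dict, outdir: Path) -> dict:
    scfg_kwargs = dict(config.get("synthetic") or {})
    if "spatial" in scfg_kwargs:
        scfg_kwargs["spatial"] = synth.SpatialConfig(**scfg_kwargs["spatial"])
    scfg = synth.SyntheticConfig(seed=config["seed"], **scfg_kwargs)
    names = synth.generate_name_table(scfg)
    effort, density = synth.generate_effort_and_density(scfg)
    layers = synth.generate_spatial_layers(scfg)
    names.write_csv(outdir / "names.csv")
    effort.to_csv(outdir / "effort.csv", index=False)
    density.to_csv(outdir / "density.csv", index=False)
    layers.write(outdir)
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(names.truth, fh, sort_keys=True)
    return {"config": scfg, "truth": names.truth}


def _strata_series(datasets, config) -> dict:
    """Per-stratum decade series for each dataset mode."""
    window = tuple(config["window"])
    by = None if config["strata_by"] == "none" else config["strata_by"]
    modes = (
        ["all_names", "basionyms"]
        if config["dataset_mode"] == "both"
        else [config["dataset_mode"]]
    )
    out: dict[tuple[str, str], object] = {}
    keep = None
    if by == "family":
        sizes = datasets.species.groupby("family").size()
        keep = set(sizes[sizes > config["family_min_species"]].index)
    for mode in modes:
        years_by = (
            datasets.all_name_years(by) if mode == "all_names" else datasets.basionym_years(by)
        )
        for stratum, years in sorted(years_by.items()):
            if keep is not None and stratum not in keep:
                continue
            out[(stratum, mode)] = bin_by_decade(years, window, stratum=stratum)
    return out


def stage_build_datasets(config: dict, outdir: Path) -> dict:
    records = nomenclature.load_names(outdir / "names.csv")
    datasets = nomenclature.build_datasets(records)
    series = _strata_series(datasets, config)
    frames = [s.to_frame().assign(dataset=mode) for (_, mode), s in series.items()]
    pd.concat(frames, ignore_index=True).to_csv(outdir / "decade_series.csv", index=False)
    return {"records": records, "datasets": datasets, "series": series}


def _effort_series_for(records, datasets, stratum, config):
    window = tuple(config["window"])
    names = datasets.names
    if config["strata_by"] == "domain":
        mask = names["domains"].fillna("").str.split("|").map(
            lambda ds: stratum in [d.strip() for d in ds]
        )
        sub = names[mask]
    elif config["strata_by"] in {"family", "habit"}:
        sub = names[names[config["strata_by"]] == stratum]
    else:
        sub = names
    return count_taxonomists(sub.dropna(subset=["resolved_year"]), window, stratum=stratum)


def stage_fit(config: dict, built: dict, outdir: Path) -> dict:
    fits: dict[tuple[str, str], list[ModelFit]] = {}
    efforts: dict[tuple[str, str], dict] = {}
    rows = []
    for (stratum, mode), series in built["series"].items():
        model_fits = [fit_growth_model(series, m) for m in config["models"]]
        fits[(stratum, mode)] = model_fits
        frame = fits_to_frame(model_fits)
        frame.insert(0, "dataset", mode)
        frame.insert(0, "stratum", stratum)
        rows.append(frame)
        eff = _effort_series_for(built["records"], built["datasets"], stratum, config)
        if np.sum(eff.taxonomists > 0) >= 6:
            tiers = fit_effort_model_tiers(series, eff)
            efforts[(stratum, mode)] = tiers
            for tier, ef in tiers.items():
                rows.append(
                    pd.DataFrame(
                        [{
                            "stratum": stratum, "dataset": mode,
                            "model": f"taxonomic_effort_{tier}",
                            "asymptote": ef.n_total, "rss": ef.rss,
                            "aic": ef.aic, "bic": ef.bic,
                            "converged": ef.converged,
                        }]
                    )
                )
    pd.concat(rows, ignore_index=True).to_csv(outdir / "fits.csv", index=False)
    return {"growth": fits, "effort": efforts}


def _pooled_candidates(growth_fits, effort_tiers, pool_effort: bool):
    cands = list(growth_fits)
    if pool_effort and effort_tiers:
        ef = effort_tiers["dense"]
        if ef.converged:
            cands.append(
                ModelFit(
                    model_id="taxonomic_effort", params=None, n=ef.n, k=ef.k,
                    rss=ef.rss, aic=ef.aic, aicc=ef.aic, bic=ef.bic,
                    asymptote=ef.n_total, asymptote_se=None, converged=True,
                )
            )
    return cands


def stage_average(config: dict, built: dict, fitted: dict, outdir: Path) -> dict:
    estimates = {}
    for (stratum, mode), growth_fits in fitted["growth"].items():
        series = built["series"][(stratum, mode)]
        cands = _pooled_candidates(
            growth_fits, fitted["effort"].get((stratum, mode)), config["pool_effort"]
        )
        try:
            weights = akaike_weights(cands, criterion=config["criterion"])
            est = average_models(cands, weights, s_obs=series.total, stratum=stratum)
        except ValueError:
            continue
        estimates[(stratum, mode)] = est
    reports = {}
    frames = []
    for mode in sorted({m for _, m in estimates}):
        per_mode = [e for (s, m), e in sorted(estimates.items()) if m == mode]
        rep = aggregate(per_mode)
        reports[mode] = rep
        frame = rep.table.assign(dataset=mode)
        frames.append(frame)
    if frames:
        combined = pd.concat(frames, ignore_index=True)
        combined.to_csv(outdir / "estimates.csv", index=False)
        totals = {
            mode: {
                "total_remaining": rep.total_remaining,
                "total_remaining_upper": rep.total_remaining_upper,
                "total_media": rep.total_media,
            }
            for mode, rep in reports.items()
        }
        with open(outdir / "totals.json", "w", encoding="utf-8") as fh:
            json.dump(totals, fh, sort_keys=True, indent=1)
    return {"estimates": estimates, "reports": reports}


def stage_regress(config: dict, built: dict, outdir: Path) -> pd.DataFrame:
    density = pd.read_csv(outdir / "density.csv")
    window = tuple(config["window"])
    starts = decade_starts(window)
    rows = []
    for (stratum, mode), series in built["series"].items():
        predictors = {}
        if stratum in density.columns:
            predictors["population_density"] = density[stratum].to_numpy()
        eff = _effort_series_for(built["records"], built["datasets"], stratum, config)
        predictors["taxonomists"] = eff.taxonomists.astype(float)
        _, cum_full, _, recent = window_modes(series)
        recent_mask = series.decade_start >= 1961
        for pname, x in predictors.items():
            if len(x) != len(starts):
                continue
            for resp_mode, xv, yv in (
                ("cumulative", x, cum_full),
                ("per_decade", x[recent_mask], recent),
            ):
                try:
                    fit = best_family(xv, yv, predictor=pname,
                                      response_mode=resp_mode, window=window)
                except Exception:
                    continue
                rows.append(
                    {
                        "stratum": stratum, "dataset": mode, "predictor": pname,
                        "response_mode": resp_mode, "family": fit.family,
                        "r2": fit.r2,
                    }
                )
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "regressions.csv", index=False)
    return frame


def stage_map_priority(config: dict, outdir: Path) -> dict:
    occ = pd.read_csv(outdir / "occurrences.csv")
    sp_cfg = config["spatial"]
    domains = spatial.read_geojson(outdir / "domains.geojson")
    pas = spatial.read_geojson(outdir / "protected_areas.geojson")
    tis = spatial.read_geojson(outdir / "indigenous_lands.geojson")
    lon0 = occ["decimalLongitude"].min()
    lat0 = occ["decimalLatitude"].min()
    extent = sp_cfg.get("extent")
    if extent is None:
        # snap the extent outward to integer degrees so cells tile cleanly
        extent = (
            float(np.floor(lon0)), float(np.floor(lat0)),
            float(np.ceil(occ["decimalLongitude"].max())),
            float(np.ceil(occ["decimalLatitude"].max())),
        )
    grid = spatial.build_grid(extent, sp_cfg["resolution"])
    counts = spatial.count_points_in_cells(occ, grid)
    priorities = spatial.compute_priorities(
        counts, n_classes=sp_cfg["n_classes"], min_records=sp_cfg["min_records"]
    )
    priorities = spatial.assign_domains(priorities, domains, grid)
    top = spatial.top_cells(priorities, sp_cfg["n_top"])
    pa_overlap = spatial.overlap_stats(top, pas, grid, layer="PA", domain_col="domain")
    ti_overlap = spatial.overlap_stats(top, tis, grid, layer="TI", domain_col="domain")
    priorities.to_csv(outdir / "cells.csv", index=False)
    spatial.write_cells_geojson(outdir / "priority.geojson", priorities, grid)
    overlaps = {
        s.layer: {
            "n_top": s.n_top, "n_overlapping": s.n_overlapping,
            "pct_overlap": s.pct_overlap, "per_domain": s.per_domain,
        }
        for s in (pa_overlap, ti_overlap)
    }
    with open(outdir / "overlap.json", "w", encoding="utf-8") as fh:
        json.dump(overlaps, fh, sort_keys=True, indent=1)
    return {"priorities": priorities, "top": top, "overlaps": overlaps, "grid": grid}


def run(config: dict | None = None, outdir="runs/out") -> dict:
    """Execute every stage and write a manifest; returns in-memory artifacts."""
    config = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"config": config}
    artifacts["simulate"] = stage_simulate(config, outdir)
    built = stage_build_datasets(config, outdir)
    artifacts["build"] = built
    fitted = stage_fit(config, built, outdir)
    artifacts["fit"] = fitted
    artifacts["average"] = stage_average(config, built, fitted, outdir)
    artifacts["regress"] = stage_regress(config, built, outdir)
    artifacts["spatial"] = stage_map_priority(config, outdir)
    manifest = {
        "package": "floragap",
        "version": floragap.__version__,
        "seed": config["seed"],
        "config_hash": config_hash(config),
        "config": config,
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    artifacts["manifest"] = manifest
    return artifacts
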