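# floragap

Estimating how many species of a megadiverse flora remain undescribed — and
where to look for them.

`floragap` is a Python toolkit for the *Linnean shortfall* problem in
botanical inventories, built around the discovery record of Brazilian
angiosperms (1753–2020, six phytogeographic domains). It is aimed at
taxonomists, biodiversity informaticians and conservation planners who want
to turn name-level nomenclatural tables and occurrence records into
defensible estimates of undescribed richness and maps of discovery priority.

## What it computes

**Discovery curves.** From a raw name table (accepted names, synonyms,
infraspecifics, with publication years and up-to-three per-source
basionym-year assignments) the package assembles two datasets: *basionyms*
(one earliest name per accepted species — genuine additions to the
inventory) and *all names* (every published name — total nomenclatural
activity). Description years are binned into calendar decades
([1751–1760] … [2011–2020], 27 bins for the default window) per stratum
(domain, family, or habit).

**Asymptotic richness.** Four growth models are fitted to each cumulative
series *y(t)* on the decade index *t*:

- Gompertz 3P: `y = a·exp(−exp(−b(t−c)))`
- Gompertz 4P: `y = d + (a−d)·exp(−exp(−b(t−c)))`
- Logistic 3P: `y = a / (1 + exp(−b(t−c)))`
- Weibull growth: `y = a·(1 − exp(−(t/b)^c))`

The asymptote *a* is read as the total (described + undescribed) richness.
Model support uses Gaussian-error AIC/AICc/BIC and Akaike weights
`w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)`; the model-averaged asymptote
`θ̄ = Σ w_i a_i` carries an unconditional standard error
`se_u = √(Σ w_i (se_i² + (a_i − θ̄)²))`. Remaining species are `θ̄ − S_obs`
and the Completeness Index is `100·S_obs/θ̄`.

**Taxonomic effort.** A discovery model links per-decade descriptions to the
number of active taxonomists *T_i* (counted from tokenized authorship
strings) and the shrinking undescribed pool:
`D̂_i = (a + b·s_i)·T_i·(N_T − C_{i−1})`, estimated by profiled nonlinear
least squares over the total pool `N_T`.

**Predictors.** Best-of-five trendline regressions (linear, logarithmic,
exponential, power, quadratic, compared by r²) of species counts on human
population density and taxonomist numbers, over both the full cumulative
window and recent per-decade counts.

**Discovery-priority mapping.** Occurrence records are binned into a degree
(or ~156 km geohash-equivalent) grid; per-cell completeness comes from a
Chao-type incidence estimator; record density is classed into equal-count
deciles; a 0–10 priority score combines the density and completeness
deficits; and overlap statistics report how many top-priority cells
intersect protected-area and Indigenous-land polygon layers.

A first-class synthetic-data generator produces every input with known
ground truth (true asymptote per stratum, author pool per decade,
per-cell richness, exact PA/TI area fractions), so the whole pipeline is
testable end to end without any external download.

## Worked example

```python
from floragap.synthetic_data import SyntheticConfig, generate_name_table
from floragap.nomenclature import load_names, build_datasets
from floragap.discovery_curves import bin_by_decade
from floragap.growth_models import MODELS, fit_growth_model, akaike_weights
from floragap.model_averaging import average_models

cfg = SyntheticConfig(seed=1, n_strata=1, true_asymptote=500,
                      shape_params={"c": 18})   # inflection late in the window
generate_name_table(cfg).write_csv("names.csv")

records = load_names("names.csv")
datasets = build_datasets(records)
years = datasets.basionym_years("domain")["Amazonia"]
series = bin_by_decade(years, stratum="Amazonia")

fits = [fit_growth_model(series, m) for m in MODELS]
weights = akaike_weights(fits, criterion="aicc")
est = average_models(fits, weights, s_obs=series.total, stratum="Amazonia")
```

Output:

```
gompertz3p  asymptote=  494.7  AICc=   56.9  weight=0.820
gompertz4p  asymptote=  494.7  AICc=   60.0  weight=0.180
logistic3p  asymptote=  450.3  AICc=  122.1  weight=0.000
weibull     asymptote=  438.4  AICc=  130.4  weight=0.000
averaged asymptote = 494.7 +/- 3.4
described so far   = 451
remaining          = 43.7  (upper 50.3)
completeness       = 91.2%
```

The generator's true pool was 500 species, of which 451 had been "described"
by the window end; the Gompertz fits dominate the Akaike weights and the
averaged asymptote recovers the truth within ~1%, giving an estimated 44
species still awaiting description and a 91.2%-complete inventory.

## Command line

```bash
floragap run-all --config run.yaml --outdir runs/demo --seed 7
```

Subcommands `simulate`, `build-datasets`, `fit`, `average`, `regress` and
`map-priority` run individual stages; `run-all` chains them and writes a
manifest (package version, seed, config hash) alongside the delimited-text
and GeoJSON artifacts. Identical config + seed reproduces byte-identical
outputs.

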