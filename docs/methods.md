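# Methods

## The estimation problem

A regional taxonomic catalogue grows as new species are described. If the
cumulative count of first descriptions is approaching a ceiling, that
ceiling — the asymptote of the discovery curve — can be read as the total
richness of the region, described plus undescribed. `floragap` estimates
that asymptote per stratum (phytogeographic domain, large family, or habit),
converts it into remaining-species and completeness figures, and maps where
the undescribed species are most likely to be found.

Two name-level datasets drive the curves. The *basionym* dataset keeps one
earliest validly published name per currently accepted species, so its curve
tracks genuine additions to the inventory. The *all names* dataset keeps
every published name — synonyms and infraspecifics included — so its curve
tracks total nomenclatural activity (splitting, lumping, transfers). The
basionym curve is the one whose asymptote answers "how many species are
there?"; the all-names curve contextualises effort. Both are maintained
throughout, and every estimate is computed for each.

### Nomenclatural cleaning

Loading a raw name table applies a fixed protocol: genus- and section-rank
rows and non-native rows are dropped; legacy family names are remapped to
their APG IV families via a fixed table (e.g. Caesalpiniaceae, Leguminosae
and Mimosaceae → Fabaceae); the publication year resolves from the primary
year field, else a fallback reference-derived field, else the row is flagged
missing. When up to three nomenclatural sources assign different basionym
years to a species, majority rule decides; when all three disagree the
*earliest* voted year wins and the row is flagged `conflict` — a basionym is
by definition the earliest name, and flagged rows are reported separately so
the convention can be audited. A species recorded in k domains contributes
to all k domain strata; domain strata therefore overlap and their totals
exceed the national total by design. Families, by contrast, partition
species exactly.

### Decade binning

Decades are the calendar intervals [1751–1760] … [2011–2020]; the default
window 1753–2020 spans n = 27 bins, with 1753–1760 in the first. The
model-fitting abscissa is the integer decade index t = 1..n rather than the
calendar year: it keeps the nonlinear optimisation well conditioned and is
equivalent up to an affine reparameterisation of the location/rate
parameters.

## Growth models and multimodel inference

Four asymptotic forms are fitted to each cumulative series by ordinary
least squares (parameterisations in the README). Right-censored discovery
series make these fits fragile, so each fit multi-starts from an asymptote
grid {1.05, 1.2, 1.5, 2, 4} × max(cumulative) with location/rate starts
taken from the curve geometry (the abscissa nearest half the candidate
asymptote); non-convergence and non-finite asymptotes are captured in the
fit report, never raised. The asymptote's standard error comes from the
least-squares covariance; a singular covariance yields an absent SE while
the fit itself may still stand.

Support is scored with Gaussian-error criteria, AIC = n·ln(RSS/n) + 2k,
AICc = AIC + 2k(k+1)/(n−k−1), BIC = n·ln(RSS/n) + k·ln(n), with k = curve
parameters + 1 for the residual variance. The weighting criterion defaults
to AICc (appropriate at n = 27 with k up to 5); AIC and BIC are always
computed and selectable. Two numerical edge cases are fixed by convention:

- RSS = 0 (an exact fit) is reported with a −inf criterion sentinel; such a
  fit takes the entire Akaike weight (the limit of the Gaussian criterion),
  shared equally if several fits are exact.
- A constant cumulative series identifies nothing but its plateau; the fit
  short-circuits to asymptote = the constant with degenerate shape
  parameters rather than letting the optimiser wander an unidentified ridge.

Akaike weights are `w_i ∝ exp(−Δ_i/2)` over converged fits (non-converged
fits get weight zero); they are invariant to adding a constant to every
criterion. The averaged asymptote is `θ̄ = Σ w_i a_i` with unconditional
standard error `se_u = √(Σ w_i (se_i² + (a_i − θ̄)²))`, combining
within-model variance and between-model spread; the 95% interval is
θ̄ ± 1.96·se_u. A positive-weight fit lacking an SE contributes the largest
available variance among its peers (conservative inflation — dropping the
term would understate uncertainty; the estimate is flagged). By default only
the four growth models enter the average; a config flag pools the
taxonomic-effort estimate as a fifth candidate weighted by its own
criterion, since its AIC/BIC are computed on the same Gaussian form.

Completeness is `100·S_obs/(S_obs + remaining)`; the conservative variant
divides by the upper confidence bound of the asymptote instead. Per-stratum
figures aggregate by exact summation, with a per-stratum *media* defined as
the midpoint of the remaining estimate and its upper bound.

## The taxonomic-effort model

Description output should scale with the people doing the describing and
with what is left to describe. The per-decade expectation is

    D̂_i = (a + b·s_i) · T_i · (N_T − C_{i−1}),   C_0 = 0,

with T_i the distinct describing authors in decade i, N_T the total pool,
and (a + b·s_i) a per-taxonomist efficiency allowed to drift linearly over
the window. s_i is the decade index scaled to [0, 1], which decouples the
conditioning of a and b. Authors are tokenized from authorship strings
(separators "&", ",", " et "; in "A ex B" citations only the publishing
author after "ex" is kept, standard botanical citation semantics) and
counted distinctly per decade.

The objective is ordinary least squares on per-decade counts, keeping
AIC/BIC commensurable with the growth models; a Poisson likelihood is
available behind `objective="poisson"`. For fixed N_T the model is linear in
(a, b), so those are profiled out by a linear solve and the problem reduces
to one dimension in N_T. Two search tiers are reported: *coarse* (the
multi-start grid {1.05, 1.2, 1.5, 2, 4} × C_final alone) and *dense* (a
60-point geometric grid to 10 × C_final plus a bounded scalar refinement
bracketed by the best grid point's neighbours — the RSS profile in N_T can
be multimodal, so refinement never leaves its bracket). Known model
algebra, used as test oracles: doubling T while halving a leaves D̂
unchanged (scale non-identifiability), and with b = 0 and constant T the
noiseless cumulative trajectory is the monomolecular curve
C_i = N_T(1 − (1 − aT)^i).

## Predictor regressions

Species counts are regressed on human population density and taxonomist
numbers with the five spreadsheet-trendline families; the best family is the
applicable one with maximal r², ties broken by fewer parameters then family
name (order-invariant). Exponential and power fits are log-linearisations
and their r² is reported on the transformed scale — the trendline
convention — with the back-transformed r² kept as a diagnostic. Degenerate
constant responses report r² = 0. Two windows are analysed: the cumulative
series over the full window, and raw per-decade counts for the six decades
from 1961 on, which expose recent fluctuations the cumulative series
smooths away.

## Priority mapping

Occurrences are assigned to a regular degree grid (0.1°, 0.5°, 1°, 2°, or
1.40625° ≈ 156 km matching geohash precision-3 cells) with a half-open
[min, max) convention so boundary points land in exactly one cell.
Rectangular degree cells approximate the published geohash cells; the
geohash-equivalent resolution is provided for fidelity. Per-cell
completeness uses the Chao1 estimator S_obs + f1²/(2·f2) (bias-corrected
f1(f1−1)/2 when f2 = 0) on record abundances, set to missing below a
configurable record floor (default 5) where the estimator is unreliable.
Record counts are cut into equal-count decile classes (ties to the lower
class). The priority score is the equal-weight mean of the density deficit
(1 − class/10) and the completeness deficit (1 − completeness/100, missing
treated as full deficit), scaled to 0–10 and rounded half-up; the combiner
weights are configurable since no canonical weighting exists. Overlap
statistics count a top-priority cell (default top 30) as overlapping a
polygon layer only when the intersection has positive area — edge-touching
does not count — with invalid geometries repaired where possible and union
semantics making duplicated polygons harmless.

## Synthetic data: what it emulates and what it does not

The generator draws each species' description date by inverting the chosen
growth curve (inverse-CDF sampling), so the cumulative basionym curve has
exactly the asymptotic shape the fitters assume, right-censored at the
window end; default shape parameters place the inflection mid-window.
The `effort_driven` shape instead describes species decade by decade with
per-species probability 1 − exp(−rate·T_i), so zero-effort decades force
zero descriptions. Synonym counts are Poisson (default mean 0.5 per
species) with years uniform between the basionym year and the window end —
no empirical synonym-age model is claimed. Three per-source basionym-year
columns agree except with the configured discordance probability (default
5%), when one source is perturbed upward. Authorship strings are drawn from
a finite per-decade author pool, round-robin so well-populated decades
realise the schedule exactly. Occurrences are Gaussian clusters with
lognormal species abundances over a toy rectangular landscape; PA/TI layers
are disjoint rectangle strips whose summed area equals the configured
fraction exactly. All randomness flows from one seeded generator; identical
seeds give byte-identical outputs.

What passing tests therefore show: the estimators recover known truth when
their assumptions hold, the arithmetic and bookkeeping are exact, and the
pipeline is deterministic. What they do not show: robustness to real
nomenclatural noise (homonyms, orthographic variants, author-initial
collisions), to discovery histories that switch regimes (wars, funding
cycles), or to the strong spatial sampling biases of real herbarium data.

## Problem sizes and defaults

The shipped tests and examples use strata of 300–3000 species over 27
decades, 200 replicates for growth-model recovery (Gaussian noise of 1% of
the asymptote; recovery within 5% required in ≥95%), 100 replicates for
effort-model recovery (2% relative noise, trend-free well-specified setting;
pool within 10% in ≥90%), and end-to-end runs with two strata of 300
species and 5000 occurrence points — sizes at which every documented
property is comfortably testable on a single CPU while the statistical
checks retain power.

## Known limitations

- The asymptote of a discovery curve is an extrapolation; regime changes in
  effort or taxonomy break it, and all estimates inherit that fragility.
- The effort model's efficiency term and error model follow one documented
  interpretation of the effort-discovery literature; the function is
  isolated so an alternative form can be substituted.
- Author tokenization does not resolve identities (initials collisions,
  spelling variants), so taxonomist counts are an upper bound per decade.
- Degree cells are not equal-area; at Brazilian latitudes the distortion is
  modest but real. No reprojection is performed.
- The per-species "density within range at description year" predictor is
  accepted as an input column but not derived from occurrence data.
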