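# Methods

## The analysis

`synchroscope` estimates spatial population synchrony — the tendency of
separated populations to fluctuate together — and asks what structures it:
distance, shared climate (the Moran effect), habitat similarity, dispersal
ability, and time.

**Growth rates.** Raw counts confound interannual fluctuation with long-term
trends, so counts are converted to yearly growth rates
`r_t = ln(N_t + 1) − ln(N_{t−1} + 1)`; the +1 offset keeps zero counts
usable. A growth rate exists only when both years were surveyed. Natural log
is used throughout (correlation is invariant to the base; fixing it makes
growth-rate tables reproducible).

**Pairwise synchrony.** For each species and each unordered pair of sites
within 100 km, synchrony is the Pearson correlation of the two growth-rate
series inside a 10-year moving window stepped one year at a time. A window
`[y, y+9]` uses the growth rates for years `y+1 … y+9` (both years of every
rate lie inside the window), so at most 9 rates are shared. A pair-window is
excluded, with a recorded reason code, when

* the pair is over 100 km apart (`distance_gt_max`),
* fewer than 7 growth-rate years are shared (`too_few_shared_years`),
* either site's counts in the window contain a zero followed by a positive
  count at the next surveyed year — colonisation chains inflate correlations
  (`zero_then_positive`), or
* either growth-rate vector is constant (`zero_variance`).

Pairs are enumerated per species over the sites that monitor that species;
when more than `max_pairs` (default 10,000) pairs remain they are subsampled
uniformly with a recorded seed. The zero-then-positive rule is applied per
window (the pattern must fall inside the window, gaps allowed); whether it
should instead be applied once per whole series is genuinely ambiguous, so
both the threshold and this behaviour are parameters.

**Climate synchrony.** Sites are snapped to 5-km grid cells (half-open floor
convention); the Pearson correlation of raw seasonal values — mean
temperature and mean precipitation for each of four seasons, eight variables
— is computed per pair per window with no growth-rate transform. Pair
distance always uses the raw site coordinates, not the snapped cells. Pairs
sharing a cell have identical series and keep r = 1 wherever the series
varies.

**Pair covariates.** Euclidean distance (km), mean northing (km), and
habitat similarity: the Renkonen index `Σ_i min(p_i, q_i)` over
biotope-proportion vectors (1 = identical composition), or a same-type
indicator when habitat is a single categorical type. Habitat composition is
consumed directly as per-site proportion vectors; GIS buffer extraction is
out of scope.

**Species attributes.** Specialism (generalist vs specialist) and mobility
(rank or dispersal distance) are external inputs. Mean abundance is the
arithmetic mean count over a recent year range. Abundance change between two
non-overlapping 10-year windows is classified twice: by the sign of the mean
difference for all species, and again keeping only species significant under
a two-sample t-test (Welch by default; Student selectable — the choice is
not determined by the source methodology). An exact zero difference is
classed *decrease* with a warning (a deterministic tie-break for a
measure-zero event). Species enter the analysis only when at least 75% of
study years have ≥ 50 surveyed sites.

**Inference.** One row per species × pair × window joins population
synchrony to climate synchrony (wide), covariates and attributes. Models are
linear mixed models with species and pair id as crossed random intercepts
(optionally taxonomic family, removed again when its variance estimates on
the boundary), continuous predictors standardised to zero mean and unit
sample SD. The eight climate variables are screened jointly in an
all-species model; those with permutation p < 0.05 become covariates of the
attribute models. Each attribute is tested in its own pair of models: main
effect (average synchrony) and attribute × mid-year interaction (trend in
synchrony), the window mid-year being continuous (`y + 4.5`).

Because pairwise rows are heavily dependent, significance comes from
permutation F-tests: the predictor is shuffled, the model refitted, the Wald
F of the focal term recorded, and `p = (1 + #{F_b ≥ F_obs}) / (B + 1)`
(add-one rule; B = 1000 by default, smaller in the bundled experiments).
Species-level attributes are permuted as whole-species blocks — rows within
a species are only exchangeable as a block under the null, so row-level
shuffling would be anti-conservative; row-level predictors (climate
synchrony) are shuffled across rows. Observed and permuted statistics come
from the same code path.

## The REML engine

Crossed random intercepts give marginal covariance
`V = σ²(I + Σ_k λ_k Z_k Z_kᵀ)` with variance ratios `λ_k = σ_k²/σ²`. The
solver profiles out the fixed effects and σ², and minimises the REML
criterion `(n−p)·log σ̂² + log|H| + log|XᵀH⁻¹X|` over `log λ` (Nelder-Mead),
with all linear algebra on the q×q random-effect cross-product via the
Woodbury identity (q = total random-effect levels). After one O(n(p+q)²)
pass, each criterion evaluation is O(q³) and replacing one predictor column
costs O(n(p+q)) — which is what makes a *full REML refit at every
permutation* affordable (milliseconds at the scales used here). A variance
ratio below 1e-5 is flagged singular; for the droppable family factor this
triggers a refit without it. Wald F uses the estimated coefficient
covariance (marginal, not sequential); denominator degrees of freedom are
irrelevant because the reference distribution is the permutation one.
Warm-started permutation refits use a looser Nelder-Mead stop rule (the F
statistic is flat in λ near the optimum). The engine agrees with statsmodels
MixedLM to ~1e-5 on shared fits (see tests).

## The synthetic-data generator

No public generative model exists for the monitoring data this analysis
targets; the simulator is this package's own design and emulates only the
statistical structure the analysis assumes:

* **Landscape** — sites uniform in a square region (default 60–80 km),
  Dirichlet habitat proportions over ≤ 10 biotopes.
* **Climate** — for each year, season and variable, a zero-mean Gaussian
  random field over occupied 5-km cell centroids with covariance
  `field_sd²·exp(−d/φ(year))`, sampled exactly via the eigendecomposition
  square root (robust in the fully-correlated limit where a jittered
  Cholesky is not); mean levels 8 (temperature) and 80 (precipitation) are
  added for realism. A linear trend in φ plants a dynamic Moran effect.
* **Populations** — Gompertz dynamics on log abundance
  `x_{t+1} = a_i + b·x_t + c_t·ε_{i,t} + η_{i,t} + trend·t` with `b = 0.3`,
  `a_i` set so the equilibrium is the site's carrying capacity (base
  abundance × habitat suitability), ε the site-matched climate anomaly
  (by default the mean of the eight seasonal anomalies, so every seasonal
  variable is informative; per-variable weights allow single-variable
  forcing), η independent site noise. Dispersal then mixes abundance on the
  natural scale, `N'_i = (1−m_i)N_i + Σ_j m_j w_{ji} N_j` with
  `w_{ji} ∝ exp(−d_{ji}/α)` row-normalised and no self-term — mass-conserving
  for uniform m. Density-dependent emigration optionally raises `m_i` with
  `log1p(N_i)`, capped below 1. Observed counts are Poisson, so structural
  zeros arise naturally and exercise the zero-then-positive filter; survey
  gaps are missing-at-random site-years.
* **Seeding** — one master seed is split into named substreams (landscape /
  climate / dynamics / observation / gaps / species), so paired scenario
  contrasts (e.g. with vs without dispersal) share every noise stream.

What the generator does **not** emulate: observer effort variation,
spatially structured habitat change, density-dependent detection,
within-season phenology, or real climate seasonality — so green tests here
show the *pipeline* recovers planted structure, not that the ecological
conclusions transfer to any particular real scheme.

## Planted-truth experiment conditions

The bundled experiments (in `synchroscope.scenarios`, exercised by the test
suite and `scripts/acceptance.py`) fix these conditions:

* **Null calibration** — 10 species × 50 pairs × 5 windows, species/pair
  intercept SDs 0.1, residual SD 0.2, attribute independent of everything;
  200 replicates at B = 199 must reject at α = 0.05 with rate in the
  binomial 99% band [0.02, 0.09], and the p-values must pass a
  Kolmogorov–Smirnov uniformity check at 1%.
* **Dispersal contrast** — one species, 30 sites / 25 years, c = 0.2,
  site noise 0.3, α = 25 km; emigration 0 vs 0.3 with shared streams.
* **Mobility gradient** — 12 species × 30 sites × 30 years; mobility rank
  1…12 maps to emigration 0…0.7 (α = 25 km) under weak forcing (c = 0.1), so
  dispersal alone creates a ≥ 0.1 mean-synchrony gap between mobility
  extremes.
* **Dynamic Moran** — 4 species × 30 sites × 30 years, φ rising 10 → 120 km,
  no dispersal, in a strong-forcing regime (c = 1.5, site noise 0.05,
  equilibrium abundance 500). The strong regime is deliberate: window-level
  climate realisations are common noise shared by every pair, and with
  weaker forcing that noise swamps the planted population-synchrony trend at
  desk scale, making the climate-covariate shrinkage property unobservable.
* **Generalist trend** — 10 species (half generalists) × 30 sites × 25
  years under a long-range field (φ = 300 km); generalists' climate
  sensitivity ramps 0.25 + 0.032/yr, yielding a generalist-only synchrony
  trend ≥ 0.01 r-units/yr; specialists stay flat at c = 0.4.

These scales (tens of sites, ≤ 100 subsampled pairs, B = 99–199 in the
replicated experiments) were chosen as the smallest at which the planted
effects dominate sampling noise; the production defaults (B = 1000,
max_pairs = 10,000) remain available.

## Numerical choices and edge cases

* Zero-variance vectors yield a *dropped* record with a reason code, never a
  NaN or an error, keeping model tables clean and the accounting exact:
  eligible pair-windows = kept + dropped.
* Pair ids are canonicalised lexicographically (`site_a < site_b`).
* CSV floats are written with 12 significant digits; re-running a pipeline
  from its manifest reproduces every output byte-identically.
* Welch's test falls back to "significant iff means differ" when both
  windows have zero variance.
* `standardise` uses the n−1 sample SD and is idempotent to 1e-10.
* Permutation tests require B ≥ 19 (α = 0.05 is unresolvable below that);
  failed permutation refits are dropped and counted, with a warning above
  1%.

## Known limitations

* The F reference distribution holds the row set fixed; covariate selection
  and attribute testing are done on the same data (as in the source
  workflow), which is mildly anti-conservative for the attribute models.
* The collinearity screen is a pairwise |r| > 0.7 warning, not a VIF.
* No quadratic time effects, spline correlograms, or phylogenetic covariance
  beyond an optional family intercept.
* The simulator's Gompertz/exponential-kernel structure is one convenient
  choice; recovery results say nothing about model misspecification under
  other dynamics.
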