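# Methods

`cachalot` re-implements, as a tested and reusable pipeline, the analysis
chain used to map the seasonal distribution of satellite-tracked sperm
whales in the south-west Indian Ocean: telemetry track filtering, kernel
home ranges, environmental-background pseudo-absence generation, a
multi-algorithm species-distribution-model (SDM) bench with stacked
prediction and uncertainty maps, and a diel analysis of binned dive
records. Every stage is validated against a synthetic study system in
which the truth is known by construction.

## Track processing

Raw Argos-style fixes `(id, timestamp, lon, lat)` are cleaned in a fixed
order: timestamp de-duplication, then a **sequential forward-pass speed
filter** (a fix is kept only if the great-circle speed from the last
*retained* fix is ≤ 7 km/h — the McConnell-style single pass, the
simplest contract consistent with a plain speed threshold), then a
**land filter** (nearest bathymetry cell ≥ 0 m removes the fix; off-grid
fixes are dropped with a warning by default), then a month-based
**season split** (wet: December–March; dry: April–November) and the rule
that an (individual, season) group with fewer than 10 locations is
discarded whole. All distances use the haversine formula on a sphere of
radius 6,371 km.

Per-(individual, season) summaries report the number of locations, the
duration in days, the summed leg distance and the mean horizontal speed.
Speed is the **mean of legwise speeds** by default; total distance over
total duration is available via `speed_mode="overall"`. The bundled
21-whale movement table reproduces the published per-season means under
the legwise convention at printed precision (speeds to within one unit
of the last printed digit, since the per-row inputs are themselves
rounded to that digit).

A departure detector flags the first time a distance-from-origin series
exceeds a threshold (default 100 km) and stays above it for a sustain
window (default 2 days); a series that ends while still above the
threshold counts as departed. The published analysis marked departures
visually, so this rule is this package's own operationalization.

## Kernel home ranges

Utilization distributions are Gaussian-kernel densities of pooled
per-season locations, computed on a **Lambert azimuthal equal-area
projection** centred on the point centroid — degrees are anisotropic at
20°S, and the projection makes densities and areas true spherical km².
The bandwidth starts at the bivariate-normal reference value
`h_ref = sigma_hat * n^(-1/6)`, `sigma_hat = sqrt((var_x + var_y)/2)`, and is
shrunk through multipliers 1.0, 0.9, …, 0.1. The original choice among
multipliers was visual; as a reproducible default the package selects
the smallest multiplier whose 90% region has at most 3 disjoint
fragments and still covers at least 90% of the points. (The coverage
floor cannot meaningfully exceed ~0.9: a level-0.9 highest-density
region covers about 90% of the sample by construction.) A manual mode
returns the full diagnostics table instead of choosing.

The KDE grid uses cells of `h/10` padded at least `3.5 h` beyond the
point extent and is renormalized to unit mass, so the mass-1 invariant
holds to ~1e-15 at every bandwidth. Probability regions are
highest-density regions: the density threshold is chosen so the
superlevel set holds the requested mass; areas are cell counts × cell
area; polygons are traced at the threshold. On simulated bivariate
normal samples the 50%/90% areas converge to the closed forms
`2π·ln 2` and `2π·ln 10` (within ~1% at n = 10,000 with `h = 0.5 h_ref`;
the kernel inflates areas by the factor `1 + h²`, ~1% at that h). The
locations are pooled per season rather than averaged per individual —
the simplest reading of a per-season kernel analysis — and that choice
is configurable only by calling the estimator per individual.

## Environmental layers

Monthly covariate grids are averaged cellwise into wet/dry seasonal
stacks (missing cells average over the months present). Seafloor slope
comes from bathymetry via **Horn's 8-neighbour stencil** with odd-
reflection padding (border cells reduce to one-sided differences),
with per-row metre cell sizes so the east–west step shrinks with
latitude. Predictors are min–max scaled to [0, 1] with the (min, max)
recorded and replayed on prediction grids; constant layers are rejected
as uninformative. Collinearity is screened with variance inflation
factors (`VIF_j = 1/(1 − R²_j)`, regression with intercept; threshold 4).
Point extraction is **nearest-cell** (matching the raster semantics of
presence/absence cells, not bilinear smoothing); off-grid or
missing-cell points are flagged invalid, never silently dropped. The
default stack carries nine layers (SST, SSH, U, V, current velocity,
MLD, bottom temperature, bathymetry, derived slope); the modelling
variable set is a configuration choice. In the pipeline the VIF screen
reports rather than drops: a presence/pseudo-absence design polarized
along a coupled covariate pair (like the synthetic SSH–bottom-
temperature contrast) can push its VIFs past the threshold, and
removing a generative driver automatically would be worse than
flagging it.

## Pseudo-absences

Only presences are observed in telemetry. Following the
environmental-profiling family of methods, a **correlation PCA** (each
variable standardized) of all valid ocean cells defines a 2-D
environmental background; the presence locations are snapped to unique
cells, scored in that plane, and their **convex hull** (optionally
inflated, or a Mahalanobis-quantile ellipse instead) defines the
environmentally favourable region. Pseudo-absences are drawn uniformly
**without replacement from the grid cells whose scores fall outside**
the envelope, in equal number to the presences, with 10 replicate runs
by default under per-run seeds derived from one master seed. Sampling
over cells (not continuous space) means pseudo-absences inherit exact
covariate values; no geographic buffer is applied because the criterion
is environmental, not geographic. Hull boundaries count as inside, so a
cell environmentally identical to a presence can never be sampled.

## SDM bench

Each run's design (presences = 1, pseudo-absences = 0; scaled
covariates) is split 80/20 with stratification. Fourteen learners in
seven families are fitted with 10-fold × 3-repeat stratified
cross-validation and evaluated on the held-out 20% with accuracy,
kappa, sensitivity, specificity, TSS (= sensitivity + specificity − 1)
and F1, all computed from first-principles confusion counts (positive
class = presence; probability threshold 0.5). Several of the original
R learners have no exact scikit-learn counterpart and are registered as
documented nearest-equivalents:

| name | implementation | fidelity |
|---|---|---|
| RF | `RandomForestClassifier` | exact |
| GBM | `GradientBoostingClassifier` | exact |
| GAM | cubic-spline basis + logistic | equivalent |
| MARS | greedy hinge-basis logistic (degree-1 adaptive splines) | equivalent |
| NB | `GaussianNB` | exact |
| BayesGLM | ridge logistic (Gaussian-prior GLM) | equivalent |
| LMT | gradient-boosted stumps | equivalent |
| C5.0 | entropy CART | equivalent |
| KNN | k-nearest neighbours (k = 5) | exact |
| KKNN | distance-weighted KNN (k = 7) | equivalent |
| LDA / QDA | discriminant analysis | exact |
| SVMradial / SVMlinear | Platt-calibrated SVC | exact |

The registry is pluggable, failures are isolated per algorithm, and the
best model is chosen by the highest mean of the six held-out metrics
(ties broken by TSS). The forest's `mtry` (features considered per
split) is tuned by CV accuracy over the caret-style default grid of
three values evenly spanning [2, p] (ties to the smallest value; the
degenerate one-feature forest is deliberately not in the default grid);
production forests use 500 trees (the R `randomForest` default), while
CV sweeps use 100 trees for tractability. **Stacking** trains a
logistic meta-learner on the base models' out-of-fold probabilities
(common stratified folds) and refits the bases on the full training
split. Tuned-RF and stacking metrics are compared per metric across
runs with a Kruskal–Wallis rank test.

Per-run probability maps (scaling replayed from the design) are averaged
cellwise across runs; uncertainty is the coefficient of variation
(sample SD / mean, percent), undefined where the mean is zero. Variable
importance is permutation importance on the held-out split (mean drop
in accuracy over 10 seeded shuffles).

## Diel dive analysis

Summary messages bin maximum dive depth at 100 m edges (14 bins, the
last open above 1,300 m) and maximum duration at 5 min edges (open
above 65 min). Bin labels are taken as upper edges (a configurable
convention); decoding returns half-open intervals `(lower, upper]`, and
the open top bins use 1,400 m / 70 min as midpoint proxies. Each record
is classified **day or night by the geometric solar elevation** at its
time and position (NOAA/Meeus low-precision ephemeris, implemented in
`cachalot.solar`; elevation exactly 0° counts as night; a civil-twilight
threshold of −6° is available). The diel comparison restricts depths to
deep dives (> 200 m) and applies a Kruskal–Wallis two-group test; the
duration comparison uses all dives by default, matching an unrestricted
duration contrast. Duration-profile summaries report the proportion of
short (< 10 min) and long (40–60 min, inclusive) dives.

## Synthetic study system

The generator exists so every stage above can be tested against a known
truth; all generators are bit-deterministic given their seeds.

**Covariate fields.** Each layer is white noise smoothed with a Gaussian
kernel at its stated correlation length (in cells), normalized to unit
pointwise variance and mapped into the layer's value range by
`mid + half·tanh(z/sigma)` — so longer correlation lengths give smoother
*and flatter* fields, vanishing to a constant in the infinite-length
limit. Layers can load on a **shared large-scale latent field**; by
default SSH (+0.8) and bottom temperature (−0.8) co-vary through it
(realized cellwise correlation about −0.6).
This mirrors real ocean covariates, where large-scale thermocline/steric
structure makes surface height and deep temperature co-vary, and it is
what gives a 2-D PCA background a stable leading direction aligned with
the niche-defining gradient — with mutually independent equal-variance
fields the PCA plane is an arbitrary rotation and the envelope technique
degrades, which is a genuine limitation of the method, not of the
implementation. Bathymetry gets island-like Gaussian seamounts that
break the surface, so land filtering is exercisable; slope is derived
from the synthetic bathymetry with the production slope operator.

**Truth surface.** Habitat suitability is an explicit logistic function
of 0–1 scaled layers. The recovery experiment uses strong signal
(+5 on SSH, −4 on bottom temperature, intercept −0.5).

**Tracks.** Biased correlated random walks: per-step speeds are gamma
distributed around 2.9 km/h (the wet-season scale of the tracked
whales) truncated to [0.2, 5.5] km/h; headings follow a von Mises turn
process mixed toward the local suitability-gradient direction; sampling
times are jittered first and each step spans its actual interval;
recorded fixes add isotropic Gaussian noise (0.5 km SD, clipped at
2 SD) and, with probability 0.02, an implausible 80 km jump. The
truncation and noise clipping guarantee that outlier-free fixes stay
below the 7 km/h filter at the default sampling rate. The whales'
actual movement process is unknown; this walk is a test harness, not an
inference about the animals.

**Dives.** Maximum depths are two-component mixtures per diel phase:
deep modes at 1,146 m (day) and 816 m (night), SD 200 m — the reported
deep-dive phase means — and shallow modes at 80/70 m (SD 35/30 m),
placed well below the 200 m deep-dive threshold so the deep subset is
not contaminated by the shallow tail. Durations mix a short mode
(7 ± 2 min, 20%) and a long mode (41 ± 8 min) shared across phases,
reproducing ~20% of dives under 10 min, ~45% between 40 and 60 min and
a ~34 min overall mean. Records carry timestamps uniform over a date
range at 57.5°E, 20.3°S, so the diel phase comes from real solar
geometry.

**Occurrences for the recovery experiment** are grid cells sampled with
probability proportional to suitability, restricted to the favourable
~55% of the ocean (the species occupies its favourable habitat — the
assumption the envelope technique itself makes; it also mirrors a
widespread predicted distribution). Before sampling, the truth surface
is prevalence-calibrated: its logit is shifted so the median ocean cell
has suitability 0.5. With random fields a fixed intercept turns realized
prevalence into a lottery — one realization mostly favourable, the next
mostly hostile — and the calibration keeps the validation condition
comparable across seeds without touching the coefficients. Sampling is
with replacement, as telemetry revisits favourable cells.

## Truth-recovery experiment

`cachalot.recovery.parameter_recovery` runs the full chain on a
100 × 100-cell stack: occurrences (n = 500) → background PCA → convex
hull envelope → 10 pseudo-absence runs → 80/20 split → `mtry` tuned once
by 10 × 3 CV on the first run and applied to all runs (tuning is a
single step; re-tuning per run lets CV ties flip `mtry` between runs and
manufactures artificial cross-run map variability) → 500-tree forests →
per-run maps → cellwise mean and CV. Success is measured as the Pearson
correlation between the mean map and the truth surface over ocean
cells, the permutation-importance ranks of the generative covariates,
and the median cellwise CV. Because the classifier estimates
P(presence | environment) against envelope-external pseudo-absences —
a monotone but saturating transform of the truth — the correlation
plateaus in the high 0.8s rather than approaching 1; and because CV is
a ratio, cells with near-zero probability carry intrinsically large CV,
so a map dominated by confident absence would push the median CV to
tens of percent regardless of stability.

## What the synthetic tests do and do not show

Passing tests demonstrate that the machinery is internally correct:
filters implement their contracts, the KDE matches Gaussian closed
forms, metrics match the confusion-matrix algebra, the pseudo-absence
contract holds exactly, the bench recovers a known surface and its
drivers, and the diel test has the right power and size. They do not
show that real sperm-whale distributions are predicted well: real Argos
errors are not isotropic Gaussian with rare jumps, real covariates have
richer cross-correlation and seasonality than one shared latent, and
real whale movement is not a biased random walk. The published
real-data metric values depend on the original tracking data and ocean
products and are deliberately not targets here.

## Numerical choices and degenerate inputs

- Probability-to-label threshold 0.5 everywhere; positive class is
  presence.
- Single-class truth vectors yield NaN sensitivity/specificity with a
  warning rather than an exception; empty inputs raise.
- Identical day/night samples short-circuit the rank tests to p = 1
  (the chi-square approximation is undefined under zero variance).
- Constant covariate layers, degenerate grids, all-identical points,
  and insufficient outside-envelope cells raise immediately with
  actionable messages.
- Per-run and per-season seeds derive from one master seed via
  `SeedSequence` and stay below 2³¹.

## Pipeline

`cachalot.pipeline.run_pipeline` (and the `cachalot` CLI) executes
simulate → tracks → homerange → pabs → fit → predict → dive from one
YAML-able config, writing CSV/JSON products and a manifest with seeds,
per-stage row counts and output checksums; a rerun with the same config
and seed is bit-identical. The default demo config is scaled for
interactive use (80 × 80 grid, 4 individuals per season, 3 runs, a
3-algorithm registry subset); the full 14-algorithm bench and
10-run protocol are configuration switches, and the problem sizes used
by the validation experiments (100 × 100 grid, 500 occurrences,
10 runs) are this package's choices for a convincing-but-interactive
truth-recovery demonstration.
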