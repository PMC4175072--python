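# Methods

This note documents the models implemented in `firereg`, the choices made
where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Site-level severity model

The reconstruction treats a site's dated trees as a fixed panel: both
percentage metrics for every fire at a site share the same denominator —
all retained (non-excluded) dated trees — so calls are comparable across
that site's fire sequence. The establishment window is half-open,
`(fire_year, fire_year + 40]`.

Classification precedence, where the two metrics could disagree (e.g. 85%
remnant but 50% establishment): the zero-establishment exclusion is
evaluated first, then high (< 20% remnant AND > 80% establishment), then
low (≥ 80% remnant AND ≤ 20% establishment), with moderate as the
residual class. The "21–79%" description of moderate severity is read as
that residual, not as a conjunction — the alternative (requiring *both*
metrics in 21–79) would leave combinations such as 85/50 unclassifiable.
Boundary cases use the inclusive reading: exactly 80% remnant with 20%
establishment is a low call.

The historical cutoff defaults to 1920 (effective fire exclusion);
sources describing this system quote both 1915 and 1920, so the value is
configurable (`cutoff_year`). Ambiguous scar-year ranges (1859–60 style,
from dormant-season scars) are dated to the range start; an optional
`merge_window=1` merges dormant/ambiguous scars in adjacent calendar
years into one event at the earlier year. Recorder status for the
composite chronology follows the standard convention: a tree records from
its first scar onward.

### Age corrections

Establishment year = inner ring year − pith offset − coring-height
offset. Coring-height offsets are species-wise medians from destructively
sampled juveniles (ponderosa 4 yr, Douglas-fir 9, lodgepole 8, aspen 1,
limber 9), optionally overridden per (species, elevation band, aspect
class) stratum. The pith offset uses the circle-segment geometry of the
innermost visible ring arc: radius `r = h/2 + L²/(8h)` from chord `L` and
arc height `h`, divided by the mean inner-ring width and rounded to the
nearest integer (rounding direction is not dictated by the geometry; the
choice is isolated in `duncan_pith_offset` and can be swapped). Cores
with more than 20 years estimated to pith are excluded — exactly 20 is
retained. Trees below 4 cm dbh (too small to core) are excluded from all
severity metrics.

## Landscape model

Terrain covariates come from the elevation grid: Horn 3×3 finite
differences for slope and aspect, a Zevenbergen–Thorne quadratic-surface
Laplacian for curvature, Euclidean cell-center distances for feature
distances with a 0.1-ha minimum patch size (8-connectivity). The "arcsine
aspect transform" is under-specified in the source tradition; it is
implemented as arcsin(northness) = arcsin(cos aspect) and flagged here.

The classifier is a single CART grown on Gini impurity (scikit-learn's
exhaustive split search) and pruned by the cross-validation protocol:
per fold, the cost-complexity subtree with the best held-out accuracy is
recorded (ties broken toward the smaller subtree); the full-data tree is
pruned to the rounded mean of those best sizes. Reported PCC (percentage
correctly classified) and AUC score the pruned tree against the site
labels; AUC uses the midrank (Mann–Whitney) statistic, so ties in scores
count one half. Class priors default to class frequencies, with a
balanced-priors switch (`balanced_priors=True`) for the heavily
imbalanced case (low-severity sites are rare). An ensemble ("n = 5000
trees") appears in some descriptions of this analysis; the mapped product
is a single two-split rule, so a single grown-and-pruned tree is the
implementation here.

Rule application is pointwise: a cell is low-severity iff elevation
≤ 2263 m OR slope ≤ 4°, with nodata propagated. Areas are hectares at
cell_size²/10 000; grids are cell-center registered, row 0 at the
north-west origin.

## Raster comparisons

MTBS classes binarize as {1,2} → low, {3,4} → mixed; the internal regime
codes (1 = low, 3 = mixed) are fixed points of that mapping, making
binarization idempotent. The per-fire test is a two-cell χ²
goodness-of-fit with df = 1 and no continuity correction by default
(switchable); it is flagged invalid whenever an expected count is zero
rather than reporting a spurious statistic. Pixels outside the historical
map's extent are dropped from both observed and expected counts.

Behavior classification is surface vs crown/torch from the crown-activity
band; an intensity-only mode thresholds at 33 000 kW/m (moderate) and
40 000 kW/m (high) — these are approximate median fireline intensities of
moderate- and high-severity fire and are config defaults, not constants
of nature. Verification samples cells uniformly without replacement
within a perimeter (default 500 points, seed mandatory) and applies the
tie-corrected Kruskal–Wallis chi-square approximation with df = k−1.

## Synthetic-data generators

`simulate_site_history` is a stochastic stand simulator, not a
process-based fire model. Per site:

- **Fire years** follow a Weibull renewal process (shape 2 by default,
  scale set from the mean interval), giving the quasi-periodic intervals
  fire-history data show; low-severity regimes default to a 15-yr mean
  interval, mixed regimes to 45 yr.
- **Fire effects**: severity per event is drawn from `severity_mix`
  (0.4/0.3/0.3 low/moderate/high for mixed regimes; always low for
  low-only regimes). Canopy mortality is uniform within
  severity-specific ranges (low 0–10%, moderate 25–75%, high 85–100%);
  juvenile trees (< 20 yr) additionally die with probability 0.9 in any
  fire — the surface-fire thinning that keeps frequently burned stands
  open and old.
- **Demography**: an initial cohort of 2000 canopy trees predating the
  span (a stand-scale site at realistic open-forest densities),
  background recruitment of 0.2 canopy candidates per year, a constant
  background mortality hazard of 0.3%/yr so old remnants persist, and an
  establishment pulse (mean 200 trees, exponentially decaying arrival
  over ≤ 30 yr) after each moderate/high fire so cohorts fall inside the
  40-yr window by construction.
- **Fire exclusion**: the renewal process stops at 1920 by default,
  reproducing the documented structure of the system — a centuries-long
  fire record truncated by suppression, followed by a fire-free
  recruitment era to the 2012 sampling year. Setting
  `fire_exclusion_year=None` gives a stationary regime instead.
- **Sampling** mirrors the two-part field protocol: a 50-tree
  age-structure sample of live survivors ≥ 20 yr old (the ~4 cm dbh
  coring threshold) that always includes the 5 oldest trees, plus a
  systematic collection of every fire-scarred tree whose wood is still
  sampleable — alive, or dead within the last 200 years (snag/stump
  persistence). Fire-scar chronologies in this field come largely from
  dead material; without it, stand-replacing fires would erase their own
  evidence and mixed-severity sites would be undatable.

Scar probability is 0.5 per surviving adult per fire. All generators are
pure functions of (parameters, seed).

The landscape generator produces a Gaussian-smoothed random elevation
field rescaled to the montane band (1800–3000 m), derives slope from it,
labels the true regime by the elevation/slope rule exactly, and flips
sampled-site labels with probability `label_noise` (default 5%). The
observed-fire generator matches the historical binary regime per cell
with a set concordance and draws the thematic class uniformly within the
binary outcome. The behavior generator draws crown activity per cell
(P(crown) 0.2 given low, 0.8 given mixed by default) and lognormal
fireline intensity (σ = 0.5) with locations set so the surface and
crown/torch class means default to 14 020 and 43 620 kW/m.

### What the generators do not emulate

Spatially contiguous multi-site fires (sites are independent), climate
forcing of fire years, species composition and species-specific fire
resistance, seed-source limitation, insect mortality, and measurement
error in cross-dating. Passing recovery tests therefore show that the
classification rules invert the generative regime structure they encode —
not that the rules are robust to every process shaping real stands. The
establishment-pulse magnitudes in particular are chosen for classifier
identifiability and are not estimates of any historical system.

## Numerical choices and degenerate inputs

- Percentages are exact ratios of integer counts; conservation checks
  (proportions, areas, crossmap categories, histograms) hold to 0.1
  percentage points or better.
- MFI is undefined (None) with fewer than two fires; a site with no
  retained calls raises rather than guessing a regime.
- Distance transforms return +inf (with a warning) when no feature patch
  survives the minimum-area filter; all-nodata summaries return empty
  tables with a warning.
- CART fold assignment is a seeded permutation, so fits are deterministic
  given the seed; thresholds agree with an exhaustive Gini search to
  scikit-learn's float32 feature precision.
- Kruskal–Wallis with a single group is reported as undefined (NaN);
  all-identical values give H = 0 rather than a 0/0 tie correction.

## Problem sizes

The test suite and acceptance script use 100 + 100 simulated sites for
regime recovery, 500 sites × 20 landscapes for rule recovery, 150×150
grids for rasters, and exhaustive 101×101 grids for the rubric oracle —
sizes at which every check runs in seconds while keeping Monte-Carlo
envelopes tight.

## Known limitations

The severity rubric's thresholds are sharp; sites whose true structure
sits near the 80/20 boundaries classify with sampling noise, which is
visible in the few percent of synthetic low-severity sites recovered as
mixed. The landscape model is a single rule and inherits CART's axis-
aligned bias. The χ² comparison treats pixels as independent, which
overstates effective sample size for spatially autocorrelated burn
mosaics — a reason its results are read as broad departure indices, not
pixel-level inference.
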