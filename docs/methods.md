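# Methods

This note records the models, the synthetic study system, the numerical
choices, and the limits of what the tests demonstrate.

## Study system emulated by the generator

The synthetic landscape is a planar (metre-coordinate) rectangle, 80 × 80
km by default at 500 m resolution, split by a straight coastline into a
marine west and terrestrial east; the colony sits on a rock on the marine
side, ~3 km offshore, so birds cross water to reach land. Terrestrial land
cover is carved into spatially autocorrelated patches (a Gaussian random
field smoothed over 3 cells and thresholded at the class-mix quantiles:
agricultural 0.45, other 0.30, urban 0.15, coastal 0.10 by default), and
each cell carries a raw integer code from its category's code list so the
reclassification stage has real work to do. Landfills are interior land
cells and harbours coast-adjacent land cells, both within foraging reach of
the colony.

Birds are central-place foragers: they rest at the colony, then commute in
a near-straight line (8–14 m s⁻¹, low turning) to a destination cell drawn
with probability ∝ exp(β*_habitat) within 25 km, perform area-restricted
search there (0.1–3 m s⁻¹, high turning, tethered within 600 m) for 0.5–2
h, and commute back, about 3 trips per day. Trip type (terrestrial 85 %,
marine 6.5 %, mixed 8.5 %) constrains the destination pool; terrestrial
destinations lie inside the inland rhumb-line fan (45–135°), mixed ones
outside it. The commuting and foraging speed ranges are disjoint by
contract, which is what makes behavioural-state recovery a well-posed test
rather than a judgement call. The default sample sizes mirror the tracked
2021 cohorts of the three study species (10 great black-backed, 12
herring, 31 lesser black-backed gulls) with device intervals of 300/120/60
s; tests and the validation script run smaller configurations (2–4 birds,
2–3 days; stated in each test) to keep a full run in seconds. The truth
path is simulated at 10 s resolution and resampled to each device
interval.

Corruption is planted, not incidental: a configurable fraction of fixes
(2 % by default) get ≤ 3 satellites, a position spike implying > 30 m s⁻¹,
or a cleared validity flag, at least two indices apart so removals cannot
interact. Legitimate fixes never exceed 14 m s⁻¹, so the cleaning filters
should achieve precision = recall = 1 — and the tests require exactly that.

What the generator does **not** emulate: tides (the marine mask is static),
weather, device battery cycling (gaps are only those induced by sampling
intervals), GPS position noise on good fixes, temporal habitat dynamics,
or demographic turnover. Passing tests therefore demonstrate the
correctness of the algorithms under clean study conditions, not robustness
to every field pathology.

## Preprocessing

The speed filter recomputes speed against the last *retained* fix, so one
spike removes one fix rather than cascading; this is standard telemetry
practice. Thinning is greedy forward selection: from the last accepted fix,
accept the candidate whose gap is nearest the 30 min target among those
within ±12 min; sparser data pass through untouched, so only
high-resolution devices are thinned. The colony-associated window defaults
to the span of the supplied data and is overridable per bird;
explicit exclusion windows support removing known anomalous excursions.
All timestamps are UTC; windows are half-open `[start, end)`.

## Behavioural clustering

The four-state classifier is a 4-component bivariate Gaussian mixture over
(v, θ), standardised to z-scores before EM because θ ∈ [0, π] while v spans
tens of m s⁻¹. Initialisation is deterministic (quadrants of the
per-variable medians), covariances carry a 10⁻⁶ ridge, and convergence is a
relative log-likelihood change < 10⁻⁸ or 500 iterations; the log-likelihood
trace is stored so monotonicity is assertable. After convergence each
variable gets a delimiter where the two adjacent marginal component
densities cross (closed-form quadratic; midpoint fallback), and components
are labelled L/H per variable against the delimiters — if that labelling is
not a bijection onto {HL, HH, LL, LH}, components are assigned to quadrants
by optimal matching. The full EMbC machinery (reliability weights,
uncertainty propagation) is deliberately not reproduced: only the four
labels are consumed downstream, and no pre- or post-smoothing is applied.
Fixes at trip boundaries with undefined θ inherit the nearest labelled
neighbour's state. Groups (species × trip type) under 50 kinematic points
fall back to the pooled species model, with a warning.

## Home ranges

UDs are isotropic Gaussian KDEs evaluated at cell centres and renormalised
to unit mass; the grid defaults to cell = h_ref/4 with a 3·h_ref margin.
Two evaluation paths exist — exact summation and binned
histogram-plus-Gaussian-filter — selected by problem size; they agree to a
total-variation distance well under the isopleth resolution. Isopleths are
highest-density cell sets (smallest prefix of density-sorted cells reaching
the level), so 50 % ⊆ 95 % holds by construction; polygon counts use
8-connected components.

The minimum stable bandwidth shrinks h geometrically (factor 0.9) from
h_ref until the 95 % region first fragments beyond its topology at h_ref,
then brackets the break point by log-scale bisection to a relative
tolerance of 0.01 and returns the smallest still-unbroken h. The break-up
criterion is configurable (relative to the h_ref polygon count by default;
an absolute cap is available); a floor of 0.02·h_ref guards degenerate
cases, and break-up at h_ref itself is flagged. Bhattacharyya affinity
resamples both UDs mass-conservingly (exact rectangle-overlap operators)
onto the union grid at the finer cell size before Σ√(f₁f₂).

## Selection models

**RSF.** The weighted likelihood uses the stated 1:20 use:available weights
(configurable). The random-intercept logistic marginal likelihood is
maximised with a per-cluster Laplace approximation: inner Newton iterations
find each bird's intercept mode (vectorised across birds), the outer
L-BFGS-B optimises (β, log σ). The β covariance comes from the joint
observed information at the mode with the intercepts profiled out (Schur
complement). The implementation reproduces lme4::glmer estimates, standard
errors and variance components to four decimals on a reference dataset
(frozen in the test suite). When σ̂² collapses below 10⁻⁵ the model
degrades to a weighted GLM with cluster-robust covariance and t(G−1)
critical values — the few-cluster small-sample correction. Separation
(a habitat used exclusively) is detected and warned about rather than
silently inflating coefficients. "Entire daily range" availability is the
MCP over all of a bird's retained fixes — per-day MCPs are underdetermined
for sparse devices — and callers may supply a known availability polygon
instead, which the simulation studies use (below). Birds with < 100 use
fixes are excluded. Fixes from incomplete trips are retained for selection
analyses; only trip statistics are restricted to complete trips.

**iSSF.** Strata of 1 observed + 20 random steps; random step lengths from
a gamma fit (location fixed at 0) and turns from a von Mises fit (uniform
fallback when κ̂ < 0.1) to the bird's own observed steps. The conditional
logistic likelihood is maximised by Newton–Raphson with step halving;
statsmodels' ConditionalLogit is kept as an independent cross-check in the
tests, never as the implementation. Habitats absent from every stratum are
reported as absent (no coefficient); dummies constant within every stratum
are inestimable and reported as 0 with infinite variance; |β̂| > 12 flags a
monotone likelihood. Step-length and turn covariates are not added to the
linear predictor (habitat-only model); random slopes are out of scope.

**Contrasts and fit metrics.** Marginal means are cell linear predictors
with random effects at zero, back-transformed with delta-method intervals;
pairwise contrasts are computed on the link scale with Tukey studentized-
range adjustment by default (Bonferroni or none available). AUC is the rank
statistic of fitted probabilities (fixed effects plus estimated
intercepts); R²_marginal = σ²_f/(σ²_f + σ²_α + π²/3) and R²_conditional =
(σ²_f + σ²_α)/(σ²_f + σ²_α + π²/3).

## Niche statistics

Population proportions q_j pool fix counts across individuals
(count-weighted), matching the multinomial resampling null; a mean-of-
proportions alternative is available. The Monte Carlo null redraws each
individual's n_i fixes from Multinomial(n_i, q) **and recomputes the pooled
q from the resampled counts** before recomputing mean PS — resampling
against the fixed observed q mis-centres the null and makes the test badly
conservative (we measured mean p ≈ 0.64 under the null before this
choice). The p-value is one-sided towards specialisation with the +1
correction, resolution 1/(R+1) at R = 999. Pianka bands use half-open
intervals [0, 0.40) low, [0.40, 0.61) intermediate, [0.61, 1] high, so the
unprinted gaps 0.39–0.40 and 0.60–0.61 fall to the lower band's closure.
The foraging-range model is REML with a bird random intercept; contrast
degrees of freedom use the between-bird approximation df = n_birds −
n_species (a Satterthwaite-style surrogate; exact Satterthwaite is not
available for this fit), with an OLS fallback when the bird variance is
inestimable.

## Design of the validation experiments

Three choices in the recovery experiments deserve explanation:

* **Continuous-space use sampling.** RSF recovery draws use fixes by
  rejection sampling from the density ∝ exp(β*) over the reachable disc —
  the exact point process an RSF models. Sampling habitat *cells* and
  jittering instead subtly mismatches an area-uniform availability sample
  at the disc boundary and measurably mis-centres null estimates.
* **Known availability for calibration.** The null-coverage and
  coefficient-recovery checks supply the true availability disc rather
  than the per-bird MCP: the convex hull of a finite sample under-covers
  its domain near the boundary, and the induced bias does not shrink
  relative to the standard error as n grows. That bias is a documented
  property of hull-based availability designs, not of the estimator, and
  the MCP path keeps its own geometric and end-to-end tests.
* **Inland step-selection arena.** iSSF recovery simulates strata directly
  from the conditional-logistic data-generating process on a nearly
  all-land landscape with dense landfill sites, starting at a landfill. A
  free walk on the coastal landscape drifts over the sea, where strata are
  habitat-constant and carry no information about the landfill
  coefficient, leaving it weakly identified at any feasible n.

## Numerical and degenerate-input conventions

Raster cells are half-open, row-major from the top-left corner, so every
point maps to one cell; points beyond the raster are marine by convention
(logged). Distal trip points tie-break to the earliest fix. Zero-variance
kinematics, zero-area extents, empty colony polygons, single-class
responses and sub-minimum group sizes raise typed errors or warnings
rather than producing silent numbers. All randomness flows from explicit
integer seeds; every simulation, fit and Monte Carlo procedure is
bit-reproducible under a fixed seed, and the pipeline manifest (parameters,
seeds, per-filter row counts, stage timings) is emitted with every run.

## Known limitations

The Laplace approximation can understate intercept-variance uncertainty at
very few clusters (the fallback's t(G−1) intervals mitigate but do not
remove this). The binned KDE path differs from exact summation by up to the
cell size near sharp modes. The minimum-bandwidth schedule (geometric decay
+ bisection) is one reading of "progressively smaller scales"; the schedule
is configurable. Real-data mode's lon/lat projection is a local
transverse-Mercator-style approximation adequate for a few hundred km, not
a geodesy library. The harbour-landings regression treats monthly counts
as Gaussian (OLS), as in the original workflow, rather than as counts.
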