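# Methods

This note documents the models, the numerical choices, and the limits
of what the synthetic tests demonstrate.

## Movement-state model

Steps are the straight segments between consecutive fixes on a nominal
2-h grid; each carries a length (m) and a signed turning angle in
(−π, π] (bearing change from the previous step; undefined at sequence
starts, after gaps, and after zero-length steps, where the bearing
itself is undefined). The N-state hidden Markov model emits step
lengths from a gamma distribution parametrized by mean μᵢ and SD sᵢ
(shape (μᵢ/sᵢ)², scale sᵢ²/μᵢ) and turning angles from a wrapped
Cauchy with location mᵢ and concentration ρᵢ ∈ [0, 1). Missing angles
contribute only the length term. Models are stored with states sorted
by ascending μᵢ, which also fixes the encamped/foraging/traveling
reading; the likelihood is invariant to relabeling.

**Left-censoring at 1 m.** Observed lengths at or below 1 m — below
GPS noise — enter the likelihood as the interval probability
P(X ≤ 1 m) rather than a point density. Two reasons: the gamma density
is degenerate at x = 0 (infinite for shape < 1, zero for shape > 1),
and mapping all sub-resolution lengths onto any single evaluation
point creates a spurious point mass there. That point mass is not
innocuous: on synthetic data whose encamped state is near-exponential
(mean ≈ SD ≈ 7 m, so ~13% of encamped steps fall below 1 m), a floored
likelihood rewards an artificial extra state that chases the spike,
and the AIC stage of model selection then prefers 4 states on 3-state
truth. Censoring removes the artifact while keeping the likelihood
proper.

**Fitting.** The forward-algorithm log-likelihood (scaled recursion,
numba-compiled) is maximized by L-BFGS-B on working parameters: log μ,
log s, m, logit ρ per state, multinomial-logit transition rows
(reference column fixed), and a multinomial-logit initial
distribution. The gradient is analytic via Fisher's identity — the
expected complete-data score under the forward–backward smoothing
distribution — except for the censored-length terms, whose
working-scale derivatives are central finite differences of
log P(X ≤ 1 m) (no closed form in the shape parameter); the whole
gradient is verified against finite differences in the test suite to
~1e-8. Parameter counting for AIC: 4N emission + N(N−1) transition +
(N−1) initial parameters.

**Multistart.** Starting values cross ordered subsets of the mean pool
{5, 50, 200, 500, 1500} m (SDs initialized equal to means, turn
locations 0) with ρ ∈ {0.2, 0.7}, spanning the study's state scales.
Every start runs 20 quasi-Newton iterations; the two best by
likelihood are run to convergence and the winner is kept, ties broken
by grid order. On 5000-step simulations this recovers state means
within a few percent and is ~3× faster than refining every start, with
identical winners in spot checks.

**Selection.** Sequential criteria: (1) plausibility — every
consecutive pair of state means separated by at least a factor of 3
(configurable); (2) predictive power — mean maximum smoothing
probability > 0.85; (3) minimum AIC among survivors. No silent
fallback: if nothing survives, the full per-candidate report is raised
with the error.

## CTCRW imputation

The velocity of each coordinate follows an Ornstein–Uhlenbeck process
dv = −βv dt + σ dW integrated into position; x and y are independent
with shared (β, σ, τ). Exact discrete transition over a slot Δ:
with a = e^{−βΔ},

    Φ = [[1, (1−a)/β], [0, a]]
    Q_vv = σ²(1−a²)/(2β),  Q_xv = σ²(1−a)²/(2β²)
    Q_xx = σ²/β² (Δ − 2(1−a)/β + (1−a²)/(2β))

Observations add Gaussian noise with SD τ, floored at 1 m (GPS noise
is never zero; the floor regularizes the likelihood). The state prior
conditions on the first observed fix (mean (z₀, 0), covariance
diag(τ², σ²/2β) — stationary velocity), and the likelihood accumulates
over the remaining observations; the test suite checks it against the
explicitly unrolled joint Gaussian of the observed positions to 1e-8.
Fitting is L-BFGS-B on (log β, log σ, log τ) from a few starts, with β
bounded in [10⁻³, 50] h⁻¹; a fit pinned at the upper bound (no
velocity persistence, e.g. pure white noise) is flagged rather than
hidden. Each missing slot is filled with one draw from its marginal
RTS-smoothing distribution per axis — single imputation, matching the
downstream rule that imputed steps keep the HMM series contiguous but
are removed from selection and budget analyses. Fitting is per burst;
pooling across bursts of an animal is a caller-side choice.

## Preprocessing rules

- **Speed filter:** fixes implying > 50 km/h to a neighbor are removed
  iteratively (fixes violating on both sides first; for a lone
  violating segment, the endpoint whose removal leaves the slower
  bridge). Segments in (10, 50] km/h are flagged for review but kept —
  a reproducible proxy for manual outlier inspection, with the flags
  preserved for audit.
- **Rarefaction:** greedy forward selection from the first fix keeps
  the earliest fix whose gap rounds (15-min grain) to exactly the
  target interval; when none exists — a missed fix on a regular
  schedule — the earliest fix whose rounded gap is a whole multiple of
  the target is kept instead, preserving slot alignment for burst
  extraction. Deterministic and idempotent. Note that a strict 2/6-h
  mixed schedule can never produce 7-h gaps (all sums are even), so
  7-h rarefaction of such data necessarily passes through the
  multiple-of-target rule.
- **Bursts:** maximal runs of 2-h slots with ≤ 4 consecutive missing
  slots, trimmed to start and end on observed fixes, discarded below
  8 days.
- Longitude/latitude inputs are projected to UTM (zone from the data
  centroid) on read; all analysis is metric.

## Temporal context

Snow season: Dec 10–Apr 15 below 300 m, Nov 20–May 1 at or above
300 m, windows inclusive and year-wrapping, elevation taken from the
DEM at each fix. Light condition uses sunrise/sunset at the standard
−0.833° solar altitude from the NOAA solar-position equations
(independent hour-angle formulation used as the test oracle, agreement
within 2 min). Crepuscular is the closed ±2-h windows around both
events (boundary instants are crepuscular); day and night fill the
remainder. Near-solstice overlap of the windows (not reachable at the
study latitude) is clamped with a warning so the three classes always
partition 24 h. Mean daily light-period durations per season, used for
the hours-per-day column of the time budget, are averaged over dates
sampled across the monitored span.

## Landscape covariates

Focal statistics use cell-center-in-circle membership (inclusive
boundary) and, at raster edges, the available cells only. Forest–open
edge density counts shared boundaries of 4-adjacent forest/open cell
pairs whose two cell centers both lie in the 50-m circle, as meters of
boundary per m² of circle; it is reported unstandardized. Simpson
diversity renormalizes forest/open/wetland proportions (anthropogenic
excluded) and returns 1 − Σpᵢ². Corridor density is the clipped length
(km) of corridor lines inside the 100-m or 500-m circle — length per
neighborhood, matching the km/100 m and km/500 m units, not per unit
area. Slope is Horn's 3×3 gradient in radians; elevation is reported
per 100 m. The bulk sampler evaluates raster-aligned statistics at the
containing cell center using FFT-convolution focal rasters (exact
pair-membership kernels for edges) and exact per-point chord lengths
for corridors; tests pin it to the per-point primitives at cell
centers. Covariates are sampled at step endpoints. The 100-m and
250-m vegetation scales are deliberately not computed (redundant with
the 10-m and 500-m scales).

## Home ranges

a-LoCoH: per root point, neighbors are added in ascending distance
while the cumulative distance sum stays within the sphere of influence
a (default: maximum pairwise distance); hulls are unioned in
ascending-area order (ties: fewer vertices, then construction order)
until the isopleth percentage of all points — duplicates counted,
boundary covered — is reached. Duplicates are removed before hull
construction so zero-area hulls cannot game the ordering. Note a
geometric consequence of the cumulative rule: even at the 100%
isopleth with a equal to the data diameter, the hull union is a proper
subset of the global convex hull for any non-degenerate point set,
because no root can afford both diameter endpoints
(d(r,u) + d(r,v) ≥ d_max). MCP trims the (100−isopleth)% of points
farthest from the mean location and takes the convex hull. Seasonal
ranges skip partitions under 30 locations (logged); both estimators
report km².

## iSSA

Availability is empirical: 10 random steps per used step, resampling
(length, angle) pairs from the pooled observed distributions of all
individuals, sharing the stratum's start and previous bearing;
candidates falling off the landscape are redrawn (bounded attempts).
Strata whose used step lacks a defined turning angle are dropped, as
are steps touching imputed fixes. Each of the 18 season × light ×
behavior datasets is fitted independently (no pooling, no
multiple-testing correction, matching the stratified-tables design),
with a configurable floor of 20 strata. The Newton–Raphson iteration
uses the analytic gradient and observed information of the softmax
partial likelihood with a 1e-8 ridge and step halving (monotone
ascent); the null partial log-likelihood is exactly n·ln(1/11).
Runaway coefficients (|β| > 15) are flagged as separation with an
infinite-SE marker. SEs come from the inverse observed information,
significance from the strict rule 2·SE < |β|, and VIFs from OLS of
each covariate on the rest over all candidate rows.

## Synthetic data

The generator defines the test conditions. Land cover thresholds a
smoothed Gaussian random field at the cumulative class proportions
(forest 0.55, open 0.25, wetland 0.15, anthropogenic 0.05 by default),
giving contiguous patches with near-exact frequencies; the DEM is a
low-frequency field blended with a sigmoid plateau along one axis and
rescaled to [0, 500 m], so both elevation regimes of the season rule
occur; corridors are random straight chords. Tracks follow a sticky
3-state Markov chain (diagonal 0.8) with per-state gamma lengths
(means 7/198/1426 m; SDs 7/150/800 m — chosen so the encamped range
stays within a few tens of meters and the traveling tail reaches the
multi-km scale) and wrapped-Cauchy turns (encamped centered at π with
ρ = 0.3 — frequent reversals; foraging near-uniform, ρ = 0.2;
traveling persistent, ρ = 0.8 at 0), a 2-h schedule, and 8.5% missing
fixes with at most 4 in a row by default. Selection bias draws 50
candidate endpoints per step from the movement kernel and picks one by
softmax of β·z — the standard importance-sampling construction whose
stationary selection is recoverable by conditional logistic
regression. Tracks reflect at the landscape boundary (documented,
never an error).

What the generator does not emulate: GPS measurement noise on
positions, autocorrelated or state-dependent missingness, landscape
change over time, multi-animal interactions, and true behavioral
semantics beyond the three kinematic states. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to field-data pathologies.

## Problem sizes and determinism

Everything is seeded; every generator and fit is a pure function of
(spec, seed), and the pipeline fans a single global seed out to stages
by stable name hashing. The heavier checks run at deliberately chosen
sizes: movement-state recovery and three-criterion selection on
5000-step tracks over 20 seeds; selection-coefficient recovery on 20
replicates of 600-step biased tracks over a shared 1024² landscape;
CTCRW recovery on 20 replicates of 2000-slot tracks; enumeration
oracles at N ≤ 3, T ≤ 8. These sizes give stable pass/fail behavior
for the stated tolerances (e.g. median state-mean error well under
10%) on a single CPU.

## Known limitations

- Transition probabilities are homogeneous — no covariate-dependent
  switching and no random effects across individuals.
- CTCRW imputation draws marginal (per-slot) smoothing draws; joint
  trajectory draws would preserve within-gap autocorrelation for
  multi-slot gaps.
- The conditional-logistic model fits each dataset separately; small
  datasets are skipped rather than partially pooled.
- Wetland/freshwater is the land-cover outgroup and anthropogenic
  cover is not a covariate (too rare by design in the generator).
- Snow is represented only through the calendar/elevation rule; there
  is no snow-depth covariate layer.

A note on validating selection recovery: the recovery experiments use a
single foraging-like movement kernel rather than the full 3-state
mixture. An unstratified fit to mixed-kernel tracks confounds per-step
selection with accumulated occupancy — a short encamped step's used
endpoint sits in the patch the animal already occupies while its
random steps, drawn from the pooled (mostly much longer) length
distribution, sample the marginal landscape. Behavior stratification
exists precisely to remove this, so the estimator is validated on the
homogeneous datasets it is designed to receive.
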