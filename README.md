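# carnmove

Behavior-aware analysis of GPS telemetry for a wide-ranging carnivore:
from raw collar relocations to movement-behavior states, behavioral
time budgets, home ranges, and behavior-, season-, and
light-stratified habitat selection. The package was built around the
kind of study design used for coyotes (*Canis latrans*) in a rugged
temperate park — 2-h collar schedules with missing fixes, a snowy
highland/lowland landscape, and selection that depends on what the
animal is doing and when — and ships a synthetic landscape/track
generator with known ground truth so every stage is testable without
any field data.

## What it computes

**Movement states.** Steps between consecutive 2-h fixes form a
bivariate series of step lengths and turning angles. A hidden Markov
model with gamma step lengths (mean μᵢ, SD sᵢ) and wrapped-Cauchy
turning angles (location mᵢ, concentration ρᵢ ∈ [0,1)) is fitted for
N = 2, 3, 4 states by maximizing the forward-algorithm likelihood with
bounded quasi-Newton on working-scale parameters over a grid of
starting values. States are decoded by the Viterbi algorithm and by
forward–backward smoothing probabilities. Model choice is sequential:
(1) biological plausibility (ordered, well-separated state means),
(2) predictive power (mean maximum posterior > 0.85), (3) AIC among
survivors. Three states are read, in ascending step length, as
*encamped*, *foraging*, and *traveling*.

**Gap imputation.** Missing slots inside a burst (≥ 8 days of 2-h
fixes, never more than 4 consecutive misses) are filled by single
draws from the smoothing distribution of a continuous-time correlated
random walk — an integrated Ornstein–Uhlenbeck velocity model
(dv = −βv dt + σ dW, Gaussian measurement noise τ ≥ 1 m) fitted
exactly by Kalman filtering. Imputed steps keep the state series
contiguous for fitting and are excluded from all downstream selection
analyses.

**Home ranges.** 95% adaptive local convex hulls (a-LoCoH, sphere of
influence a = maximum pairwise distance) and 95% minimum convex
polygons, from 7-h rarefied locations, overall and per snow season.

**Time budgets.** Counts of decoded steps per season × light period ×
behavior, as proportions and hours per day.

**Habitat selection (iSSA).** Each used step is matched with 10 random
steps resampled from the pooled empirical step-length and turn-angle
distributions. Candidates carry nine landscape covariates (local and
500-m forest/open cover, 50-m forest–open edge density, 500-m Simpson
diversity, corridor density at 100 m and 500 m, elevation/100,
slope) plus ln(step length) and cos(turning angle). A conditional
logistic regression is fitted per season × light × behavior dataset by
Newton–Raphson on the stratified partial likelihood; coefficients with
2·SE < |β| are flagged significant, and VIFs diagnose collinearity.

**Temporal context.** Snow season by an elevation-dependent calendar
rule (Dec 10–Apr 15 below 300 m, Nov 20–May 1 at or above); light
condition (diurnal / crepuscular / nocturnal) from NOAA solar-position
equations with 4-h crepuscular windows centered on sunrise and sunset.

## Worked example

```python
import numpy as np
from carnmove import hmm
from carnmove.preprocess import Burst, steps_from_burst
from carnmove.synth import TrackSpec, simulate_track

spec = TrackSpec(duration_days=5000 * 2 / 24, missingness=0.0, seed=3)
fixes, states = simulate_track(spec, None)
burst = Burst("sim", fixes[["timestamp", "x", "y", "source", "missing"]])
steps = steps_from_burst(burst)
model = hmm.multistart_fit(steps, 3)
print(np.round(model.mu, 1))          # [   6.9  201.0 1418.4]
dec = hmm.state_posteriors(model, steps)
print(round((dec.path == states[1:]).mean(), 3))      # 0.976
print(round(hmm.predictive_power(dec), 3))            # 0.977
```

The simulated truth uses per-state mean step lengths of 7, 198, and
1426 m (encamped / foraging / traveling). The fitted state means land
within a few percent of the truth, the Viterbi path recovers 97.6% of
the simulated states, and the predictive-power index (mean maximum
posterior) is 0.977 — comfortably above the 0.85 bar the selection
rule uses.

The full pipeline runs from a config:

```bash
carnmove run --seed 7 --out demo_run        # synthetic defaults
carnmove synth --seed 1 --out synth_out     # landscape + one track
```

`demo_run/` then contains the landscape (ASCII grids + GeoJSON), raw
and decoded tracks, the fitted movement model (JSON), the time-budget
and home-range tables, and the long-format selection results.

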