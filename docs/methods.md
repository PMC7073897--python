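# Methods

## Tank geometry and the along-channel metric

The arena is an annulus: inner (island) radius 12.5 cm, outer (chamber)
radius 32.5 cm, water depth 16 cm (informational — the analysis is planar).
Water circulates with a configurable sense (`flow_sense = +1` means
counterclockwise). All positions are reduced to polar coordinates about the
tank center; the input tracks are assumed already calibrated to cm.

Along-channel displacement between consecutive frames is the signed arc
length `±|Δθ| · r̄`, with `Δθ` wrapped to (−π, π] (a fish is not assumed to
lap the tank between frames at 1.5 frames/s) and `r̄` the mean of the two
endpoint radii — second-order accurate for the sub-band radial excursions
seen at this frame rate, unlike a fixed mid-channel radius. The sign is
positive when the angular motion opposes the circulation. The measure-zero
`|Δθ| = π` tie resolves to upstream; it is excluded from the antisymmetry
property test for that reason.

The ring is partitioned into four concentric flow zones scored 0–3 with
nominal speeds 4.2, 6.9, 8.8 and 17.1 cm/s. Neither the radial band edges
nor which wall carries the fast flow are physically constrained by the
apparatus description, so both are configuration: the default is four
equal-width bands with speed increasing outward (the diffusers inject along
the outer wall). Bands are half-open `[low, high)` with the outermost band
closed at the outer wall, so both walls score validly. Radii up to 0.5 cm
outside the annulus (tracking jitter) are clamped onto the walls with a
warning; beyond that the offending frame is a hard error.

## Per-trial metrics

Fish position is the midpoint of the tracked anterior and posterior ends
(configurable to anterior-only; which point the manual-tracking workflow
used is not recoverable). A trial of 300 s at 1.5 frames/s is exactly 450
frames; displacement sums run over the 449 inter-frame steps, so a
passively advected object in the fast zone measures −17.1 × 449/1.5 =
−5118.6 cm against the −5130 cm closed form — a 0.2% discretization
difference inherent to frame-wise tracking. Mean flow regime and upstream
orientation average over all 450 frames. The orientation window is
inclusive at exactly ±45°; a uniformly oriented fish therefore scores 90/360
= 0.25, which the calibration tests verify by Monte Carlo. Missing frames
are a hard error; tracks are validated as gap-free on read.

## The trajectory simulator

The simulator is a biased correlated random walk in the annulus, built to
have the statistical structure the analysis assumes rather than to be
hydrodynamically faithful:

- **Heading**: drawn each frame from a von Mises distribution centered on
  the local upstream tangent with concentration κ. κ = 0 is the
  uniform-heading limit (orientation score 0.25); κ → ∞ locks the fish
  upstream (score exactly 1). κ is the single knob linking simulation to
  the orientation metric.
- **Along-channel dynamics**: upstream thrust `swim_speed · cos(dev)` minus
  advection at the occupied zone's nominal speed, integrated as an angular
  step at the current radius. Advection is purely tangential — the zone
  abstraction has no radial flow component.
- **Radial dynamics**: the heading's radial thrust component, plus
  relaxation toward the mid-band radius of a piecewise-constant target-zone
  schedule, plus Gaussian jitter. The relaxation uses the exact exponential
  discretization `1 − exp(−k·Δt)`, stable for any rate (a naive Euler step
  oscillates unstably once `k·Δt > 1`). Walls reflect; fish cannot leave
  the annulus.
- **Markers**: anterior/posterior points sit ±1 cm (half a 2 cm body
  length, guppy-sized) along the heading through the midpoint.

Two built-in strategies emulate the two observed behavioral solutions:
constant-intermediate (hold zone score 1.5 throughout) and low-then-high
(slowest zone until 120 s, fastest thereafter). The 120 s switch is an
emulation choice — the observed switch is only loosely localized at "about
two minutes" — and is configurable.

Defaults, chosen once as field-plausible values: swim speed 8 cm/s
(sustained swimming for a ~3 cm poeciliid), κ = 2 (≈73% of a von Mises
distribution lies within ±45°, matching the ~70% upstream-alignment levels
these assays report), radial relaxation 0.5 s⁻¹, radial noise 0.5 cm per
step. Under these the default study produces mean net displacements around
−1000 cm against a −4000…−5000 cm passive baseline: strong positive
rheotaxis with realistic between-fish spread.

The study generator reproduces the factorial sampling design (61 females:
two rivers × three pool types × two generations, unbalanced as sampled),
masses per generation (F0 0.34 ± 0.08 g, F1 0.15 ± 0.07 g, truncated at
0.02 g), and trial temperatures (23 ± 1 °C). Per-trial RNG streams are
spawned deterministically from one seed; identical seeds give bitwise
identical studies. An optional outlier spec re-simulates a chosen number of
trials with multiplied swim speed to exercise the exclusion rule.

What the simulator does **not** emulate: burst-and-glide kinematics, wall
interactions beyond reflection, social or memory effects, tracking dropout,
and any coupling between mass/temperature and behavior (covariate effects
are null by construction). Passing tests therefore demonstrate that the
pipeline measures and tests what it claims on data with known structure —
not that real fish behave like the walk.

## Synthetic video and detection

The renderer draws each frame as the two tank walls plus two Gaussian
marker blobs (anterior brighter than posterior) at calibrated pixel
positions (default 0.35 cm/px, 200 px frames, blob σ = 1 px). The detector
subtracts the known walls-only background, thresholds, labels the residual
blobs (exactly two per frame, else a frame-indexed error), takes
intensity-weighted centroids, and assigns anterior/posterior by blob
brightness. Noise-free round trips recover coordinates to well under half a
pixel, and the four metrics of a full 450-frame round trip agree with the
truth track to better than 1%.

## Statistical pipeline

**Outlier rule.** The source criterion is descriptive ("values 4× or 15×
the mean"); it is codified as: iteratively remove the trial whose absolute
net displacement is ≥ k (default 4) times the mean absolute response of
the remaining trials, until none qualifies. The report lists removed trials
and their ratios.

**Model selection.** For each response the full model is
`y ~ mass + generation + temperature + pool + river + pool:river` (log
transform for cumulative upstream movement and mean flow regime, whose
positive skew calls for it). Candidates are tested for removal in the fixed
order mass, generation, temperature; a covariate is dropped iff removal
does not increase AIC (ties drop, favoring parsimony). The factors are
never candidates. Note the operating characteristics of this rule: a null
1-df covariate is dropped with probability P(χ²₁ ≤ 2) ≈ 0.84, so all three
null covariates survive pruning simultaneously in roughly half of
replicates — the rule is deliberately permissive, as information-criterion
backward selection is.

**Term tests.** The ANOVA flavor is a config switch: `sequential` (type-I,
model order) or `marginal` (type-II — each factor adjusted for the others,
the interaction entered last; the default, since it does not depend on term
order under imbalance).

**Planned contrasts.** Contrast 1 uses weights (+1, −½, −½) over (Above,
Between, Below) so its estimate reads directly as "Above minus the mean of
the downstream pools" in response units; contrast 2 is (0, +1, −1). Both
are computed from raw pool-level means of the (transformed) response with
`SE = sqrt(σ̂² Σ w²/n)` using the fitted model's residual variance and
degrees of freedom; the two weight vectors are orthogonal under equal cell
sizes. No multiple-testing correction is applied across the four responses;
the report says so.

**Temporal smooths.** The frame-wise group means (per river) of zone score
and alignment are fitted with `y = α + γ_river + f_river(frame) + ε`:
cubic B-splines with a second-order difference penalty per river smooth,
smoothing parameter by REML in the mixed-model representation (penalty null
space — the per-river linear trend — as fixed effects, the penalized part
as random effects). Each smooth carries a sum-to-zero constraint so the
river offsets stay identifiable. The river test is a Wald F on the offsets
with denominator df `n − edf` (edf = hat-matrix trace).

Residual autocorrelation is modeled as AR(1). The coefficient is estimated
by *profiled REML*: for each candidate ρ the data and design are
prewhitened within groups, the whitening Jacobian `(G/2)·log(1 − ρ²)` added
to the criterion, the smoothing parameter re-selected, and ρ chosen by a
bounded scalar search. The more common moment update (re-estimate ρ from
lag-1 residual autocorrelation and iterate) is biased in both directions
here — upward when the basis underfits a sharp trend (misfit reads as
autocorrelation), downward when the smoother absorbs low-frequency noise —
and calibration simulations with AR(1) ρ = 0.5 noise show the profiled
criterion recovering ρ within ±0.01 on average and holding the river test
at its nominal 5% level, where the moment update drifts to 0.6%–8%
depending on basis size.

**Numerical choices.** Basis dimension defaults to 15 per smooth for
450-frame series: knot spacing then resolves the fastest feature the
simulator produces (the ~10 s strategy-switch ramp), while the standard
too-small-basis diagnostic (edf saturating near the basis size together
with an inflated AR coefficient) flags 10 as insufficient. The smoothing
parameter is searched on `log θ ∈ [−20, 20]`; `penalty=0` reproduces the
unpenalized spline least-squares fit and `penalty=∞` collapses each smooth
to its ordinary least-squares line, both used as test oracles. Degenerate
inputs (constant response, non-positive values under log, rank-deficient
designs, missing pool levels) raise typed errors naming the offence.

## Known limitations

- The simulator's behavioral realism is limited to what the analysis needs;
  effect sizes injected in tests are nominal, not fish-derived.
- The passive baseline is the single-zone closed form; a drifting object
  that wanders across zones has no closed form here.
- The per-individual mixed temporal model (random fish effects with
  count/binomial families) is deliberately out of scope; only the
  GAM-on-group-means path is implemented.
- The river test of the temporal smooth compares group offsets; it does not
  decompose *where* in the trial the curves differ (the plotted pointwise
  bands serve that purpose informally).
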