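# Methods

This note documents the models, rules and numerical choices behind
`migtrack`, the points where the underlying analysis design left decisions
open, and what the synthetic-data tests do and do not demonstrate.

## Preprocessing and migration onset

Fixes with measured HDOP strictly above 5 are dropped; fixes with no HDOP
report are kept. Resampling to the 30-min target anchors slots at the first
fix and keeps, per slot, the nearest fix within a 5-min tolerance, with an
explicit guard that consecutive retained fixes are at least
(interval − tolerance) apart; gaps are never interpolated. All distances are
haversine on a sphere of radius 6371.0088 km — at these scales the ~8 m
device error dwarfs spheroid corrections.

Migration onset is the start of the first *movement bout* that displaces
≥ 50 km from the pre-bout position with a net northward latitude change.
"Bout" needs operationalizing: ours is a maximal run of steps each gaining
≥ 0.25 km of displacement from the bout start, tolerating at most two
consecutive non-progress steps provided the bout has already reached 5 km
and remains within 2 km of its running displacement maximum. The progress
floor (0.25 km, ≈ 30× the GPS noise scale per step) prevents stationary
jitter from chaining into a bout; the slack lets genuine flights survive
brief circling. These three constants are configuration fields
(`QCConfig.bout_*`) and the onset rule is deliberately flagged for
sensitivity analysis. The analysis window is [onset − 7 d, 1 Aug 23:59].
Tracks with no qualifying bout return a sentinel rather than raising, so
incomplete migrations can be dropped.

## Hidden Markov segmentation

States emit gamma step lengths (parameterized by mean m and sd s; shape
m²/s², scale s²/m) and von Mises turning angles (mean μ, concentration κ).
Zero-length steps are handled by a per-state zero-mass parameter, activated
only when zeros occur. The first turning angle of a series, and angles
adjacent to zero steps, are undefined and contribute nothing to the
likelihood. Transitions are multinomial-logit with the diagonal as
reference; device speed (+0.1 km/h against zero inflation, with step-speed
fallback when the device reports nothing) can enter the off-diagonal logits.
The initial distribution is the stationary distribution of the transition
matrix at the covariate mean, computed by power iteration (robust to the
near-singular matrices visited during optimization).

Fitting is direct numerical maximization — L-BFGS-B on unconstrained
working parameters (log means/sds/concentrations, logit zero-mass, raw
logits) over a numba-compiled forward recursion with per-step scaling — not
EM; this keeps covariate-dependent transitions trivial. Restarts (default
10; pipeline default 5) start from quantile-spread step-mean
initializations, jittered in log space after the first; fits are
deterministic given the seed. Per-individual refits can start from the
pooled fit's parameters. The modified-Bessel normalizer inside the compiled
objective uses the standard Abramowitz–Stegun rational approximations
(relative error ~1e-7, far below optimization noise); the pure-numpy
objective retained alongside serves as a cross-check.

The number of states is a user decision (the pipeline default is 4:
roost, forage, local flight, migratory flight); AIC per state count and
step-length pseudo-residual Kolmogorov–Smirnov diagnostics are reported but
never auto-select. The migratory state is the one with the largest mean step
length; if the top two means are within 10%, the harder concentration at a
zero-mean angle wins. Candidate flights are maximal runs of migratory-state
steps; a run with cumulative length below twice the fitted migratory step
mean is reclassified stopover (a per-step variant exists behind a flag).
Stopovers are counted *between* flights: the leading pre-onset residence and
the final pre-nesting settlement are excluded. Reverse migratory movements
are flight segments with net latitude decrease. Migration distance sums all
steps from onset through the final flight end (flight-only summation behind
a flag); duration is onset → final flight end; arrival is the ordinal date
of the final flight end.

## Dynamic Brownian bridge utilization distributions

The motion variance σ²m (km²/h) is estimated by the sliding-window
change-point method: within each 25-fix window, every single breakpoint at
least 9 fixes from either edge is compared against a no-break model by BIC,
with σ²m for each piece the maximum-likelihood value under leave-one-out
bridge interpolation of odd-indexed fixes (isotropic 2-d Gaussian with
variance Tα(1−α)σ²m + ((1−α)² + α² + 1)δ², δ = 8 m). The 1-d likelihood
maximization runs on a two-stage log-spaced grid (66 points over 13 decades,
then 41 points over ±1 decade; ~2% resolution, well under the estimator's
sampling noise) and is clamped to zero when the zero-variance likelihood is
higher. Each inter-fix interval inherits the mean of the window estimates
covering it; tracks shorter than one window fall back to a single global
estimate with a warning.

The UD accumulates, per interval and weighted by the interval's share of
total track time, the bridge position density integrated with 24 midpoint
quadrature nodes in time; each node's isotropic Gaussian is deposited as
exact per-cell mass via the separable normal CDF, truncated at 5 standard
deviations. Doubling the node count changes no cell by more than 1e-4 on the
test tracks. The grid is an Albers equal-area conic (standard parallels
20°/60°, origin 40° N 96° W, spherical formulas) with √10 × √10 km cells
(10 km² each) and origin snapped to cell-size multiples for run-to-run
stability; equal-area is forced by the area accounting downstream.

Day weighting multiplies each pixel by its number of distinct UTC fix-days;
pixels holding bridge mass but no fix receive the nominal fix interval
expressed in days (the residence one transit represents) so transit
corridors are down- but not zero-weighted; the surface is then renormalized.
Weighting operates on the normalized per-individual UD, and the composite
(cell-wise sum, renormalized) is built from the weighted surfaces; the
alternative weight-then-normalize order would change composites and is the
reason the order is fixed here. Isopleths take cells in descending value
order until the level's mass is reached, ties broken deterministically by
cell index, making each mask minimal and the set nested. Region accounting
assigns cells by centroid point-in-polygon, drops centroids at or above
60° N (pre-nesting local movement would otherwise read as migration space),
prices each cell at 10 km², and reports percent of the respective category
total with dense ranks over listed regions; area outside every region
accumulates in an explicit "unassigned" row, so percents are relative to the
full mask including unassigned. "Moderate use" is the 80% mask minus the
50% mask, so high + moderate = the 80% mask; an 80-minus-60 variant is a
flag.

## Breeding classification

Daily totals are sums of step lengths charged to the UTC day of the step's
starting fix, over 15 May – 30 July; days with no fixes are flagged missing,
not zero. A candidate nesting run is a maximal sequence of non-missing days
with total ≤ 2 km, tolerating one consecutive missing day when flanked by
quiet days; run length is the calendar span from first to last qualifying
day, so a tolerated gap neither extends nor breaks the run. In place of the
visual nest-plot confirmation a human analyst would perform, runs must also
pass an explicit site-fidelity check: ≥ 90% of the run's fixes within 250 m
(~30× the device error; configurable) of the run's median coordinate — this
is what separates true incubation from multi-day loafing at shifting sites.
Among qualifying runs the longest wins (first-run mode behind a flag),
guarding against short pre-laying quiet spells. An attempt requires ≥ 6
days; apparent success requires ≥ 23 days, the minimum published incubation
period for the species. Failures during egg laying, before incubation
starts, are undetectable from movement by design and are not claimed.

Pre-nesting duration is incubation start minus arrival (ordinal dates);
under 10 days it marks a capital-leaning strategy, as rapid follicle
development over fewer than ~10 days must draw on stored reserves.
Non-attempters receive the year cohort's median incubation start (lower
median on even counts) as their trajectory endpoint. The pipeline detects
attempts *before* summarizing migration, truncates each track at its
endpoint, and re-segments, so a deferring bird's molt movements or an
attempter's post-nesting movements never masquerade as its final migratory
flight. Calendar days are UTC; a configurable hour offset allows local-solar
sensitivity checks.

## Statistics

Continuous predictors are centered and scaled to unit SD; winter region is
dummy-coded against the MAV reference. Logistic fits go through IRLS
(statsmodels GLM); complete separation (all fitted probabilities pinned at
0/1, or exploding coefficients) yields a flagged sentinel fit that subset
enumeration skips. AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting the
intercept. All-subsets enumeration (refused above 12 predictors) retains
models within 6 ΔAICc of the best; Akaike weights are renormalized over the
retained set; averaging is conditional (each coefficient averaged over the
models containing it, weights renormalized over those) with 95% CIs from
the unconditional variance estimator
\[Σᵢ wᵢ √(var(β̂ᵢ) + (β̂ᵢ − β̄)²)\]². Mann–Whitney U uses midrank ties and
an exact two-sided p when n₁·n₂ ≤ 400 with no ties, otherwise the normal
approximation with tie and continuity corrections. A fixed year covariate is
the offered substitute for a random year intercept, which is poorly
identified at these sample sizes and is out of scope.

## Synthetic tracks

The generator emits an explicit itinerary rather than sampling an HMM:
winter residence; flight legs along the great circle to the destination
(each ≥ 80 km), separated by stopovers; optional reverse flights
(80–150 km southward, their own segments, each followed by a short pause);
pre-nesting settlement; then incubation, failure, or deferral with a molt
flight. Steps draw from state-specific gamma distributions (defaults:
roost 0.012, forage 0.12, local flight 1.4, migratory 32.3 km per 30-min
step) with waypoint navigation under von Mises heading noise; positions
advance by local dead reckoning re-projected to lon/lat (valid at step
scales ≪ Earth radius); isotropic 8 m GPS noise is added last. Fix times
sit on a 30-min grid anchored at midnight so day boundaries fall on fixes,
and incubation starts at a midnight fix, making planted incubation starts
and run lengths exact. Incubating birds sit at the nest with an 8%
per-fix chance of a ≤ 40 m recess; pre- and post-nesting movement is
forage-dominated (~6 km/day) so no spurious quiet day abuts a planted run.
The scenario mix defaults to the study conditions (55.4% attempt, 71%
success among attempters); failed runs draw 8–21 days, successful runs
23–30, pre-nesting 13–28 days (western destinations) or 4–18 (eastern),
floored so incubation never starts before 16 May, inside the
classification window.

The default (`SimConfig`) preset targets field-scale magnitudes (~5500 km,
~90 days, ~16 stopovers); the `compact` preset keeps the identical phase
structure at roughly quarter scale (~1500–3000 km, ~10 days of migration,
~4 stopovers, onset in early May) and is what the test suite and the
acceptance script run, sized so the whole battery fits comfortably on one
CPU. Because the generator is itinerary-driven, its truth ledger (onset
time, stopover and reverse counts, arrival date, nest start/duration,
outcome, strategy) is exact by construction — which is precisely why HMM
*parameter* recovery is tested against the step-level sampler
(`hmm.simulate_steps`), which draws from the fitted family itself.

## What passing tests show — and what they do not

The synthetic tracks have clean phase boundaries, gamma/von Mises motion,
stationary 30-min duty cycles, no habitat structure, no weather forcing,
and GPS noise that is honest but isotropic. Exact recovery of planted
breeding outcomes and ±1 recovery of itinerary counts therefore demonstrate
the *internal consistency* of the rule chain and its robustness to 8 m
noise — not performance on real telemetry, where duty-cycle drift, habitat-
driven movement and partial transmitter failure blur every boundary the
generator draws sharply. The statistical calibration checks (ANOVA type-I
error, exact Mann–Whitney p-values, logistic-oracle agreement) are
implementation checks, independent of the generator.

## Known limitations

- Mixed-effects (random year intercept) models are out of scope; a fixed
  year covariate is the offered approximation.
- Molt-migration detection, brood-rearing survival and renesting are not
  classified; analyses end at incubation or the median-initiation endpoint.
- Egg-laying-period failures are undetectable from movement and counted as
  deferrals.
- The onset bout rule and the day-weighting fallback constant are package
  operationalizations of verbally specified procedures; both are
  configurable and flagged for sensitivity analysis.
- Viterbi ties resolve to the lower state index; state order is canonical
  (ascending step mean) after fitting.
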