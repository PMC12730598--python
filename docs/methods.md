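# Methods

This note documents the models, defaults and design choices behind
`enoseopt`: what the synthetic data generator emulates, how the
feature-correlation objective and the three selection optimizers are
specified, and the numerical conventions used throughout. It records
decisions, not results; every empirical number quoted in the README is
printed by the code itself.

## The synthetic e-nose experiment

The simulator emulates a cold-chain spoilage study: shellfish stored in a
sealed chamber at one of four temperatures (4, 12, 20, 28 °C) releases
volatile compounds; a ten-sensor array samples the headspace at 1 Hz for
5 minutes per measurement cycle (300 samples).

**Sensor panel.** The bundled panel mirrors a TGS/MQ array. Each profile
lists the compound classes the sensor responds to, its detection range,
per-class gains, rise kinetics and a baseline noise level. Three
structural facts matter downstream:

* S5 responds to amines only; S2 and S6 carry the amine/ammonia wave,
  S1 the sulfide wave — together these are the complementary
  spoilage-marker sensors.
* S3/S7/S8 (same TGS261x family) share the ethanol/hydrogen/alkanes
  class set with nearly identical kinetics — the planted redundant trio.
* S9/S10 share ethanol/CO/alkanes, dominated by a common CO/solvent
  background — the planted redundant pair.

**Response model.** A trace is
`x(t) = a·f(c·t − b) + d + e·Noise(t)` with `f(u) = 1 − exp(−u)` for
u ≥ 0 and 0 otherwise: the canonical metal-oxide rise-to-plateau
morphology. The time scale `c` and onset delay `b/c` come from the
sensor profile (family-specific kinetics); `d` is the baseline, taken as
the bottom of the detection range; `e` is the noise amplitude as a
fraction of the range span (default 1 %). Noise is i.i.d. Gaussian; an
AR(1) drift mode is available behind a flag. The amplitude `a`
aggregates affinity × concentration over compound classes and is mapped
into the detection span through a saturating law
`span·(1 − exp(−A/c50))`, so steady-state responses always stay inside
`[range_low, range_high]`. Sensors whose inputs exceed their scope
saturate and lose resolution (S2's narrow 1–10 ppm scope saturates
during mid-spoilage) — a deliberate, realistic effect.

**Spoilage trajectories and classes.** Freshness classes are
storage-time bins: early / middle / advanced spoilage (three by
default). Spoilage rates double per 10 °C (Q10 = 2), so all times are
kept on a temperature-compressed *effective* axis: stage boundaries are
placed uniformly on that axis (24 and 48 effective hours over a
72-effective-hour horizon) and divided by the Q10 factor to give clock
times — stages occur proportionally earlier when warm, which is what
"accelerated spoilage" at 28 °C means here, while keeping the stages
themselves comparable across temperatures.

Marker concentrations rise in two logistic waves aligned with the stage
boundaries: amines and ammonia switch on around the early→middle
boundary, sulfides and H2S around middle→advanced — matching the
sequence in which amine and sulfur volatiles dominate shellfish
spoilage. Storage times are sampled uniformly inside each stage bin with
a 15 % guard band at each boundary (stage labels are assigned away from
transitions). Background volatiles (ethanol, hydrogen, alkanes, CO,
organic solvents) are constant in time; their cycle-to-cycle variation
is a shared lognormal factor per compound group (log-sd 0.35), which is
what makes the redundant groups mutually correlated: members of a group
see the same gas, differing only by a small per-sensor gain jitter whose
log-sd is `0.5·(1 − redundancy)` (default redundancy 0.95, so ≈2.5 %).
Marker compounds get small independent 5 % factors so the class signal
stays clean.

**What the generator does not emulate.** No adsorption/desorption
kinetics, humidity or drift compensation, sensor aging, or real VOC
chemistry; classes are exact functions of storage time, and replicates
share the true gas state. Passing tests therefore demonstrate that the
pipeline recovers structure it is designed to detect under controlled
conditions — not field performance on real measurements.

## Preprocessing

Fixed order: replicate averaging → Savitzky–Golay (window 11, order 3,
`mode="interp"`, i.e. the edge polynomial is fitted to the first/last 11
points so cubic reproduction holds at the edges) → per-temperature
Z-score → 3σ screening. The same per-temperature (μ, σ) parameters drive
both the Z-score and the outlier rule; a point is abnormal when
|z| > 3, and a cycle is rejected when the abnormal fraction pooled over
all 10 × 300 points strictly exceeds 5 %. Degenerate (zero-variance)
channels are rejected at parameter fitting with an explicit error.

## Curve features

Per curve: P_max, P_min (extrema of the smoothed, normalized trace);
*area* (trapezoidal integral over the window); T_eq, the earliest time
after which the trace stays within 2 % of its final value (a
conventional settling criterion); and t₁/t₂/t₃, the times to reach
10/50/90 % of (P_max − x(0)) above the initial value. An all-constant
trace is degenerate: rise times are set to the trace duration and
flagged. Features are invariant to appending a constant plateau except
for *area*, which grows by exactly plateau × tail duration.

## Feature-correlation objective

`C = Σ wᵢ·Similarity(Fᵢ, F_target)` with weights normalized to sum to
one (uniform by default) and similarities mapped into [0, 1]: Pearson
and cosine via (s+1)/2, Euclidean via 1/(1+RMSE) — RMSE rather than the
raw norm so the score does not depend on grid length. Pearson is the
default metric (scale-invariance suits Z-scored traces); Euclidean turns
the fit into a curve-recovery problem and is used wherever (a, d) must
be identified, since correlation-based similarity is invariant to affine
transformations of the curve. The comparison target is generated
noise-free; the noise amplitude `e` remains part of the search vector
but influences C only in an explicit noisy-target mode — maximizing
similarity to a random target is otherwise ill-posed. In per-sensor fits
used for clustering, `e` is pinned at zero: it is unidentifiable against
a noise-free target and would otherwise drift arbitrarily within its
bounds and contaminate the embedding.

Optimization of (a, b, c, d, e) runs the same GA-QPSO engine as subset
selection over a box (defaults: a ∈ [0.1, 5], b ∈ [0, 5],
c ∈ [10⁻³, 0.2] s⁻¹, d ∈ [−3, 3], e ∈ [0, 0.5], sized for Z-scored
traces), followed by a Nelder–Mead polish of the best point
(xatol 10⁻⁸). The polish is what pins the smooth noise-free optimum to
high precision; the swarm provides the global search. A user-supplied
initial guess is never degraded: its score is a floor on the result.

## Selection optimizers

**Fitness.** 5×2 cross-validated accuracy (percent) of the wrapper
classifier on the masked features, minus a parsimony penalty of 0.5
accuracy points per retained sensor — a sensor is kept only if it buys
at least half a point. The wrapper is a KNN (k = 5) on standardized
features (a bagged-forest wrapper is selectable); KNN is deterministic
given the folds, and the folds are drawn once per evaluator from the
seed and shared across all masks, so comparisons are paired and fitness
is memoized (there are only 2¹⁰ − 1 masks).

**RFA.** Random forest (200 trees, bootstrap, OOB score); a sensor's
importance is the summed impurity-decrease importance of its seven
features, normalized to sum to one; ties in the top-k cut are broken
toward the lower sensor index. Default k = 6.

**SA.** One single-bit-flip proposal per temperature step (re-drawn if
it would empty the mask), Metropolis acceptance exp(Δ/T) for worse
moves, geometric cooling T ← αT with defaults T₀ = 1, α = 0.95. At
T₀ = 0 the rule degenerates to hill climbing.

**GA-QPSO.** Particles hold continuous positions in [0, 1]¹⁰,
thresholded at 0.5 (an all-below-threshold position keeps its largest
coordinate). Quantum update: per-particle attractor = random convex
combination of personal and global best; new position = attractor ±
β·|mean-best − x|·ln(1/u) with the contraction–expansion coefficient β
decreasing linearly 1.0 → 0.5 over the iteration budget. Genetic layer:
arithmetic crossover and uniform resampling mutation with
rank-adaptive probabilities (pc ∈ [0.6, 0.9], pm ∈ [0.01, 0.1]; better
individuals are disrupted less). A fully collapsed population triggers a
logged reseeding mutation that preserves the best member.

**Stopping.** All optimizers stop after 20 consecutive iterations with
best-fitness improvement below 10⁻⁴, or at the iteration cap
(default 200). The geometric SA schedule must match the budget: on the
small exhaustive-search benchmark problems the suite uses a slower
schedule (α ≈ 0.995, larger T₀ and cap), since a fast-cooling chain
becomes a hill climber long before the cap and can stall in local
optima. These are optimizer settings, not data settings; fitness caching
makes the extra iterations nearly free.

**Chains.** Tri-level: RFA top-k mask → SA from that mask → GA-QPSO
with a population seeded on the SA solution and its one-bit
perturbations; the returned subset is the best fitness seen in any
stage. Dual chains compose the named pair in the same way; the
single-RFA model is the top-k subset itself. All seven chains share one
evaluator (identical folds, features and stopping rule) and per-chain
RNG streams derived from the seed, so an ablation rerun is bitwise
identical.

## Clustering validation

Per temperature, each sensor's mean preprocessed curve is fitted
(Euclidean metric, e pinned at 0) to give one (a, b, c, d, e) vector per
sensor. Vectors are standardized across sensors and projected onto their
top-2 principal directions (sign convention: the largest-magnitude
loading of each component is positive; rank-deficient input zero-pads
the second axis and is flagged). K-means (k-means++ seeding, 10
restarts) clusters the plane; a leave-one-out 3-nearest-neighbour
majority vote reports label consistency.

Equivalence groups are clusters whose mean distance to their centroid is
below a cohesion threshold; everything else stays a singleton, and the
groups always partition the sensor set. Defaults: **k = 5** and
**threshold 0.3**. The panel has five natural kinds (amine-wave
markers, the sulfide specialist S1, hydrogen-only S4, the S3/S7/S8
trio, the S9/S10 pair); with k = 3 the forced coarse merges have
dispersions larger than any sensible threshold and the planted groups
are not isolated, so the coarser default was rejected. Threshold 0.3 on
the standardized plane separates genuinely redundant clusters (observed
dispersions ≲ 0.15) from merely similar complementary sensors
(dispersions ≳ 0.45). Group recovery is read as containment: a planted
group is recovered when all its members share one equivalence group at
one or more temperatures. The validation path only annotates the
selection — each multi-sensor group is labelled with the compound
classes all members share — and never changes it.

## Evaluation protocol

Macro-accuracy is the arithmetic mean of the four per-temperature
accuracies; redundancy reduction is 100·(1 − kept/10). The 5×2 protocol
is five repetitions of stratified two-fold cross-validation (ten fold
accuracies; mean ± sd). Leave-one-temperature-out trains on three
temperatures and tests on the fourth, repeated over a seed list
(default 5 seeds) for stochastic estimators. Paired comparisons use the
paired t-test (or Wilcoxon) on fold accuracies with Cohen's
d = mean(a−b)/sd(a−b); the sign convention is a − b. Zero-variance
differences are degenerate: identical series give (p = 1, d = 0), a
constant nonzero shift gives p = NaN with an infinite-d sentinel and a
warning.

The ablation table reports, per chain, the per-temperature accuracies,
macro-accuracy, sensors retained, redundancy reduction, and the relative
gain — each chain's macro-accuracy minus the single-RFA baseline's.
Internal consistency (macro = mean of the accuracy columns; redundancy =
formula) is asserted programmatically on every emitted table. Display
rounding is one decimal, half-up, applied only at emission.

## Problem sizes and numerical conventions

The bundled default experiment is four temperatures × three classes ×
twelve cycles per class (144 cycles of 10 × 300 samples); the clustering
and benchmark studies use six cycles per class, and the
exhaustive-search benchmarks restrict the panel to its first six or
eight sensors so the optimum is enumerable. All randomness flows through
`numpy.random.default_rng` seeds (spawned per stage via `SeedSequence`);
sklearn estimators get explicit `random_state` and `n_jobs=1`. Every
dataset, fit and selection is a pure function of (configuration, seed).

## Known limitations

* The simulator's class structure is idealized (guard bands, exact
  storage-time labels); real spoilage stages blur at boundaries, and
  accuracies on real data would be lower.
* The parsimony penalty is linear in subset size; with strongly
  separable data the optimum can be a very small subset. The penalty
  weight is the lever to trade accuracy against array size.
* Per-temperature accuracies are computed on each temperature's cycles
  alone (36 by default), so their training folds are small and the
  values sit well below the pooled accuracy; they are comparative, not
  absolute, measures.
* The feature-correlation fit is identifiable only under the Euclidean
  metric; under Pearson, (a, d) are gauge freedoms and only (b, c) carry
  information.
* Equivalence grouping depends on k and the cohesion threshold; both are
  reported in the groups output and should be revisited for panels with
  a different redundancy structure.
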