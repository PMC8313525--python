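# Methods

This note documents the models and procedures implemented in `mobipred`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic benchmarks do and do not establish.

## Stay-point detection

A trajectory is a strictly time-ordered list of planar points (x, y, t) in
metres. The detector scans once: starting from the first unassigned point,
consecutive points are accumulated while their Euclidean distance to the
*first point of the run* stays below δ; at the first violation the run is
emitted as a stay-point iff its elapsed time exceeds τ (strictly), otherwise
discarded, and the scan restarts at the violating point. The trailing run at
end-of-data is tested the same way so a final overnight dwell is kept. The
stay-point's coordinates are the arithmetic mean of its members; its
interval is [first, last] member timestamp.

Defaults δ = 300 m, τ = 10 min are the values commonly used for
smartphone-GNSS data: δ absorbs positioning error and building footprints,
τ separates intentional stops from traffic halts. The distance test is
against the run's first point, not the running centroid — a deliberate,
documented reading of the classical algorithm; the two variants differ only
for runs that drift slowly.

Lon/lat input is projected with a local equirectangular projection
(`mobipred.io.lonlat_to_metres`), adequate at the city scales where these
thresholds are meaningful.

## Stay-region aggregation

Two aggregation families produce the symbol alphabet:

* **Grid** — axis-aligned cells of spacing G, anchored at the minimum
  corner of the stay-point bounding box (an explicit origin can be given).
  Membership is half-open, [x₀+kG, x₀+(k+1)G), so boundary ties are
  deterministic. Region centre = cell centre.
* **DBSCAN, minimum cluster size 1** — with that minimum size, DBSCAN's
  clusters are exactly the connected components of the graph linking
  stay-points at distance < ε (strict inequality). It is implemented that
  way (k-d tree pair search + connected components), which makes it
  oracle-checkable against a brute-force union-find; there is no noise
  label.

Per-region geometry reports the convex-hull area of member stay-points
(degenerate hulls — one point, collinear points — have area 0) and a
single-point flag. Hull area is one possible definition of "region size";
cell area G² would be another for the grid method. The hull was chosen
because it applies uniformly to both methods and measures the data, not the
tessellation.

The canonical parameter sweep is 30 values log-uniform on [10¹, 10⁴·⁸] m,
covering building scale up to roughly half a metropolitan extent.

## Sequences

From a region-labelled visit history:

* **Next time-bin** — one symbol per interval Δt: the region with the
  largest dwell overlap in the bin; ties broken by total visit count over
  the whole history, then by smallest region id; empty bins are null. Bins
  are anchored at the first visit's start floored to a whole multiple of Δt
  from midnight UTC, so hourly bins align with the hour-based missingness
  statistic q = (null bins)/(all bins). The bin count is ⌈span/Δt⌉ from
  that origin to the last visit's end.
* **Next place** — region ids in visit order with consecutive repeats
  collapsed; no clock, no nulls, no self-transitions by construction. A
  history spent in one region collapses to length 1 and is treated as
  completely predictable.

Sequence statistics count non-null records, distinct regions L, and
self-transitions (adjacent equal non-null symbols; a null breaks adjacency,
since a gap is no evidence the user stayed). The temporal sweep uses
Δt ∈ {5, 10, 15, 30, 45, 60 min, 6, 12, 24, 48, 72, 144 h}.

User filtering retains trajectories with hour-level q ≤ 0.15 spanning at
least 28 consecutive days, the strictness needed for entropy estimates to
be treated as reference values.

## Entropy and predictability

All logarithms are base 2; entropies are in bits. S_rand = log₂L and
S_unc = −Σ pₖ log₂ pₖ are exact. The actual entropy rate is estimated with
the Lempel-Ziv match-length estimator: Λⱼ is the length of the shortest
substring starting at position j that does not occur as a contiguous block
fully inside the first j−1 positions; when every substring starting at j
already occurs there, Λⱼ = n−j+2. Λ₁ = 1 by convention (the empty prefix
contains nothing); the convention is isolated in one function and verified
exhaustively against a brute-force double-loop oracle for all binary
sequences up to length 12. S_est = (mean Λ)⁻¹ log₂ n. Nulls are dropped
(the sequence concatenated) before estimation — treating null as a symbol
would inject spurious structure; the missing-data estimators, not the
estimator itself, own the bias correction.

The estimator converges as n → ∞; on seeded chains with n = 10⁵ it is
within 5% of the exact Markov entropy rate for rates ≥ 0.3 bits, and
estimates on short sequences (for example next place sequences at coarse
aggregation) must be read as noisy — which is also why Π_unc can exceed
Π_max there.

Fano's inequality is inverted by bisection on [1/L, 1] (F is strictly
decreasing, F(1/L) = log₂L, F(1) = 0) to |F(Π)−E| < 1e−10; bisection was
preferred to Newton because it is unconditionally convergent. L = 1 returns
Π = 1; E > log₂L (possible from estimator noise) clamps to 1/L with a
warning. E = log₂L returns 1/L exactly — substituting Π = 1/L satisfies
the Fano relation identically.

`markov_entropy_rate` gives the closed form H = −Σᵢ πᵢ Σⱼ Pᵢⱼ log₂ Pᵢⱼ used
as the oracle in estimator-validation tests. It requires an irreducible
chain (unique stationary π); a 1×1 chain trivially returns 0.

## Missing-data entropy estimators

Degradation nulls a seeded random subset of non-null bins; the removal
order for one seed is a fixed permutation, so null sets at increasing
targets are nested ("gradually removing records" holds exactly) and the
achieved q matches the target to within one bin. The q′ grid runs from the
sequence's own q in steps of 0.05 up to 0.90.

* **Ĥ_shuff** — at each q′, σ(q′) = log₂(S_est(q′)/S_shuff(q′)), where
  S_shuff is the LZ estimate on a seeded uniform shuffle of the degraded
  sequence (one shuffle by default; a repeat-and-average count is
  available). σ(q′) is fitted with both a linear and an offset-exponential
  (a·e^{bq}+c) model, the better R² wins, and the fit is extrapolated to
  q′ = 0; then Ĥ = 2^{σ(0)}·S_shuff(q).
* **Ĥ_unc** — identical, but the scaling feature is the analytic
  uncorrelated entropy of the degraded sequence's frequencies, and the
  final rescaling uses the analytic S_unc(q).
* **Ĥ_Δe** — from reference sequences with q < 0.15 (treated as presenting
  true entropy), the mean relative error Δe(q′) = (Ĥ(q′)−Ĥ(q))/Ĥ(q) of the
  raw LZ estimate is tabulated per q′ level and fitted with an offset
  exponential for interpolation; a degraded sequence is then corrected as
  Ĥ = S_est/(1+Δe(q)). Reference and evaluation sets are disjoint by
  construction — overlap would optimistically bias the measured error.

The benchmark protocol (`evaluate_estimators`) takes complete sequences,
uses their intact LZ entropy as the reference H, degrades each to every
plan level, applies all three estimators, and reports the mean of
|Ĥ−H|/H·100 with a 95% CI (1.96·SD/√N; NA for a single sample) per
(Δt, estimator). The error is reported as a relative absolute percentage —
the unsigned form of the ratio Ĥ/H that the estimators are judged by.

On the synthetic benchmark (20 four-state Markov chains, n = 2×10⁴,
entropy rates 0.3–1.5 bits, degraded to q = 0.6, with 8 disjoint reference
chains for the Δe curve, fixed seeds) the error-curve correction Ĥ_Δe is
on average substantially more accurate than the order-parameter methods;
the suite asserts the ordering mean|Ĥ_Δe−H|/H < mean|Ĥ_unc−H|/H, not any
specific percentage, because the absolute numbers depend on the generating
process.

## Synthetic mobility model

Each user is a Markov chain over a small set of anchor locations: a dwell
at the current anchor with shifted-exponential duration (floor 15 min, so
every visit is long enough to be detectable at τ = 10 min), then a
constant-speed straight-line travel leg to the next anchor drawn from the
transition matrix. Points are emitted on a fixed 60 s clock; isotropic
Gaussian noise (σ = 10 m by default) models GNSS error. Missingness empties
whole hour-long windows, chosen uniformly at random, until the hour-level
missing fraction matches the target within one window — matching how q is
defined. Everything is driven by one seed; identical configurations give
byte-identical output.

The default study population is 50 users over 28 days, each with 5–8
anchors scattered over an 8 km extent at least 800 m apart, one "home"
anchor with 8 h mean dwells and 3× transition bias, the others with 1–4 h
dwells, and a 0.04 hour-level missingness target. These are one realistic
urban configuration, chosen once; per-user seeds derive from the global
seed and user index so population results are order-independent.

What the generator does *not* emulate: road networks (travel is
straight-line), exploration of new places over time
(preferential-return/exploration dynamics), weekday/weekend structure,
correlated or burst missingness, and heavy-tailed displacement statistics.
Tests passing on this generator therefore establish correctness of the
pipeline's mechanics and the internal orderings it measures — not that any
particular predictability value will be observed on real data, where all
of the above matter.

## Problem sizes and numerical choices

The test suite exercises the LZ estimator up to n = 10⁵ and the estimator
benchmark at n = 2×10⁴ per sequence; sweeps run on the 50-user default
population. Quantiles everywhere are linear-interpolation quantiles
(median/IQR), stated because IQR values depend on the convention. R² of a
constant fit to constant data is defined as 1. Curve fits that fail to
converge fall back to the alternative form (σ fits) or to linear
interpolation (Δe curve). Degenerate inputs: empty trajectories yield empty
stay-point sequences; a single-symbol sequence has all predictabilities 1;
the LZ estimator refuses n < 2; degradation refuses targets below the
current q.

## Known limitations

* The stay-point scan tests distance against the run's first point; slowly
  drifting dwells can fragment.
* DBSCAN with minimum cluster size 1 never discards noise points, so
  single-visit locations always enter the alphabet (their prevalence is
  itself one of the reported metrics).
* The hull-area definition of region size understates grid-cell extent for
  sparse regions.
* LZ estimates on short sequences are biased; the suite only trusts them
  quantitatively at n ≥ 2×10⁴.
* The Δe correction requires low-missingness reference trajectories from a
  comparable generating process; with none available, only the
  order-parameter estimators apply.
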