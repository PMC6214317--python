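# Methods

## Model and assumptions

The input is a field `X(t)`: one stationary time series of length `T` per
cell of a spatial grid, modelled as a planar graph (4- or 8-connected
lattice, optional longitude wrap, optional invalid-cell mask).  All
statistics use the population (`1/T`) normalisation: the zero-lag Pearson
correlation `r_ij`, the biased sample autocorrelations entering Bartlett's
formula, and signal standard deviations.  Correlations are clamped to
[−1, 1] after floating-point evaluation.

A *domain* is a maximal connected cell set `A` containing a core cell, with
mean pairwise correlation `r̂(A) > δ`.  The method presumes that whatever
mechanism couples the cells of a domain expresses itself as zero-lag
correlation; lagged coupling is modelled only *between* domains (stage 2).
Nonstationary dynamics, spatially varying δ, and causal (effective)
connectivity are out of scope.

## Stage 1 choices

- **K-neighborhoods** are grown best-first over the adjacency structure in
  order of distance from the center (Euclidean on row/col indices,
  haversine on lat/lon, or graph hops), so they are contiguous by
  construction and never jump across masked gaps.  Ties break by ascending
  cell id; every tie-break in the package is id-based so runs are exactly
  reproducible.
- **δ estimation** samples 10,000 random unmasked pairs (size configurable),
  z-scores each correlation with Bartlett's variance truncated at
  `|τ| ≤ T−2` (the extreme lags are inherently damped by the biased
  autocorrelation estimator), applies a one-sided test at `α` (default
  10⁻²) keeping the positive tail, and averages the survivors.  Variances
  are floored at 10⁻¹² before division.  Spatially adjacent pairs are not
  excluded from the sample; with thousands of pairs on realistic grids
  their contribution to the mean is marginal.
- **Singleton domains**: `r̂(A)` is undefined for `|A| = 1`, so a fresh
  seed's homogeneity is taken to be its local homogeneity `r̂_K(seed)` until
  a second cell joins.  Domains still of size 1 at termination are
  discarded and reported separately.
- **Expansion acceptance** (the one genuinely open design point): the
  frontier cell maximizing the union homogeneity is added only if the union
  homogeneity exceeds δ *and* the cell's mean correlation to the current
  members exceeds δ (`expansion_rule="cell"`, the default).  The first
  condition alone (`expansion_rule="domain"`, also available) cannot stop a
  grown domain: one cell shifts an `m`-cell average by `O(1/m)`, so a
  domain that has exhausted its true support keeps absorbing uncorrelated
  frontier cells until its homogeneity decays to ≈δ, ending with inflated
  extents and homogeneity pinned at the threshold.  The per-cell condition
  stops growth where cells cease to co-vary with the domain, leaving
  domains as subsets of the true signal support with homogeneity well above
  δ — the behaviour the benchmark is scored against.
- **Merging** joins the touching pair (shared cell or edge-adjacent, which
  makes the union connected) with maximal union homogeneity, if above δ, to
  exhaustion — initially on the seed set and again after every single-cell
  expansion.  Union homogeneities are memoized keyed on domain versions.
  A domain may engulf another's seed without merging when the union
  homogeneity stays below δ; both domains then persist and may overlap
  arbitrarily (expansion never removes cells from other domains).

## Stage 2 choices

- Domain signals: `average` (mean of member-cell series) or `cumulative`
  (relative-area-weighted sum; cos-latitude weights on geographic grids).
  Correlation-based quantities are identical under equal weights; the
  covariance weights `w = σ̃_A σ̃_B r*` are not scale-free, which is the
  point of the cumulative mode for climate data.
- The cross-correlogram uses the `1/T` normalisation at every lag (as the
  method defines it) while the lagged Bartlett variance scales by
  `1/(T−|τ|)`; the asymmetry is deliberate fidelity to the method's
  definitions.  `τ_max` is validated against `T/4`.
- p-values are **two-sided** (edges are signed; negative teleconnections are
  first-class results), in contrast to the one-sided test used for δ.
- BH-FDR pools all `N(N−1)/2 · (2τ_max+1)` per-lag tests and applies the
  strict step-up rule `p_(m) < q·m/M`.
- The "one standard deviation" of the lag-range rule is `√Var[r(τ*)]`, the
  Bartlett standard deviation at the maximizing lag.  The qualifying lag
  set is retained verbatim and the lag range reported as its closed
  `[min, max]` integer interval; direction is derived from the interval.
  Ties at `|r*|` break toward smaller `|τ|`, then smaller `τ`.
- Edge weight defaults to `r*` at `τ*`; averaging the correlations over the
  lag range is available (`weight_from="mean_range"`), default off.
- Structural balance is decided by BFS two-coloring of the signed graph
  (positive edges keep the color, negative flip it); on conflict the
  violating cycle (tree paths plus the conflicting edge) is reported.
  Triangle lag-consistency searches the Cartesian product of the three
  qualifying lag sets for oriented offsets summing to zero.

## The synthetic benchmark

The generator reproduces a fully specified ground-truth experiment: five
circular domains on a 50×70 4-connected grid, T = 1200, with core radius,
peripheral radius, variance `s_i` and mixing recipe per domain as listed in
the module docstring of `deltamaps.synthetic`; amplitude decays as
`√f(d)`, `f(d) = (r_p−d)/(r_p−r_c)` between the radii; overlap cells sum
the contributing signals; unit white Gaussian noise covers the grid.  The
circle centers are not uniquely determined by the published layout; the
defaults reproduce its topology (1 and 3 each overlapping 2, 4 and 5
overlapping slightly) and are configurable.

**Mother series.**  The original experiment used real fMRI time series with
pairwise `|cross-correlation| < 0.05` at all lags `|τ| ≤ 20`.  Two
properties of those series matter and are enforced here:

1. *Mutual uncorrelatedness.*  Independent draws cannot deliver it: a single
   sample cross-correlation at T = 1200 has standard deviation ≥ 0.029, and
   the maximum over 10 pairs × 41 lags essentially never stays below 0.05.
   Each AR(1) surrogate is therefore orthogonalised against the zero-padded
   lagged copies (`|τ| ≤ 20`) of all earlier series, which makes the
   truncated-sum cross-correlations at those lags exactly zero; the < 0.05
   verification (with bounded re-draws) is kept as a safety net.
2. *Strong autocorrelation.*  Band-passed (0.01–0.08 Hz) BOLD series at
   TR = 0.72 s are slow; the AR(1) coefficient defaults to 0.8 to match.
   This is not cosmetic: the mixing recipes share mother 3 between domains
   1 and 5, implying an unintended cross-correlation of `−1/√85 ≈ −0.108`
   at lag 15.  With strongly autocorrelated mothers the Bartlett standard
   deviation of a domain-pair correlation is ≈ 0.06, so `|r| ≈ 0.11` is not
   significant and exactly the three constructed edges survive — while the
   weakest planted edge (`1/√17 ≈ 0.24`) remains at z ≈ 4.  A weakly
   autocorrelated surrogate (e.g. AR coefficient 0.3, Bartlett sd ≈ 0.03)
   would instead promote the (1,5) pair into a fourth edge.  Planted lags
   use circular shifts (lags ≤ 15 against T = 1200).

What the benchmark does *not* emulate: real BOLD marginals (heavier tails),
spatially correlated noise, irregular domain shapes, and the α→δ mapping of
real data (the benchmark fixes δ = 0.55 directly, as the mapping depends on
the autocorrelation structure of the underlying series).  Passing it shows
the machinery recovers planted low-dimensional structure under white noise;
it does not certify performance on fields whose noise is itself spatially
structured.

## Problem sizes and defaults

Benchmark pipeline hyperparameters default to K = 4, δ = 0.55, q = 0.10,
τ_max = 20, `average` signals.  A full 50×70×1200 run takes ~2 s on one CPU
(the running-sum representation makes one expansion step one matrix–vector
product).  The acceptance script runs three seeds and reports medians;
Monte-Carlo tests in the suite use T = 256–1200 and a few hundred to a
thousand replicates, sized so the whole suite stays in the tens of seconds.

## Known limitations

- The greedy loop gives no approximation guarantee (the underlying problem
  is NP-hard); seeds on noisy plateaus can fragment before merging heals
  them.
- Bartlett's formula assumes jointly stationary signals with normal errors;
  heavy-tailed or nonstationary data will miscalibrate both δ estimation
  and edge significance.
- The anomaly preprocessing deseasonalizes before detrending; a strong
  trend leaves a small within-cycle staircase residual (negligible at
  climate-scale trend slopes).
- `estimate_delta` needs at least one significant pair; on signal-free
  fields it refuses and asks for an explicit δ.
- Theil–Sen detrending is `O(T²)` per cell; for long records on large grids
  the anomaly step dominates runtime.
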