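# deltamaps

Overlapping spatial domain identification and lagged functional network
inference for gridded spatio-temporal fields (δ-MAPS).

Climate fields and resting-state fMRI recordings share a structure: the grid
they are sampled on is much finer than the true dimensionality of the system.
A relatively small number of *functional domains* — spatially contiguous,
possibly overlapping regions whose cells show highly correlated activity —
interact with each other, often at a time lag (ENSO leading the Indian-Ocean
SSTs; one cortical region leading another by a fraction of a second).  This
package identifies those domains and infers the weighted, signed, lagged
network between them.  It is aimed at climate scientists and neuroimaging
researchers who want an alternative to PCA/EOF, ICA or clustering that does
not require the number of components in advance, keeps components spatially
contiguous, lets them overlap, and attaches statistically controlled lagged
edges to them.

## The method

**Stage 1 — domains.**  Cells `i, j` are compared with the zero-lag Pearson
cross-correlation `r_ij`.  The *local homogeneity* at cell `i` is the mean
pairwise correlation over the K-neighborhood `Γ_K(i)`; the homogeneity of a
cell set `A` is

    r̂(A) = Σ_{m≠n∈A} r_mn / (|A|(|A|−1)).

A domain rooted at a core cell `c` is a maximal set `A` with `c ∈ A`,
`I_G(A) = 1` (connected in the grid graph) and `r̂(A) > δ`.  Exact
maximisation is NP-hard, so the method is greedy: *seeds* are local maxima of
the local-homogeneity field above δ; each seed starts a candidate domain;
domains expand one best frontier cell at a time (in rounds, ordered by
decreasing homogeneity) and touching domains merge whenever their union
stays above δ.  The threshold δ can be given directly or estimated as the
mean of the significantly positive correlations in a random sample of cell
pairs, where significance is a one-sided z-test using Bartlett's variance
formula `Var[r_ij] = (1/T) Σ_τ ρ_i(τ) ρ_j(τ)`.

**Stage 2 — the network.**  Each domain gets a signal `X_A(t)` (area-weighted
cumulative anomaly for climate grids, plain average for fMRI).  For every
domain pair the cross-correlogram `r_AB(τ)`, `|τ| ≤ τ_max`, is z-scored per
lag with the lagged Bartlett variance, and the pooled
`N(N−1)/2 · (2τ_max+1)` p-values go through Benjamini–Hochberg selection at
FDR `q`.  A pair with at least one surviving lag becomes an edge annotated
with `r*` (correlation at the maximizing lag `τ*`), the *lag range* `R_τ`
(surviving lags within one standard deviation of `|r*|`), a direction
(undirected iff `0 ∈ R_τ`, otherwise from the temporally leading domain),
and the covariance weight `w(A,B) = σ̃_A σ̃_B r*`.  Node strength is the sum
of incident `|w|`.  Helpers check structural balance of the signed network
and lag-consistency of its triangles.

## Worked example

The package ships a fully specified synthetic benchmark: five circular
domains on a 50×70 grid (T = 1200), mixed from five mutually uncorrelated
mother series so that exactly three domain-level edges exist — (1,3)
negative at lag 15, (4,5) positive, (3,5) positive — under unit white noise.

```python
from deltamaps import run_benchmark

grid, field, truth, domains, network, report = run_benchmark(seed=1)
print(len(domains.domains))
for e in network.edges:
    print(e.a, e.b, round(e.r_star, 3), e.tau_star,
          (e.lag_min, e.lag_max), e.direction)
print({k: round(v, 3) for k, v in report.fraction_overall.items()})
```

prints

```
5
1 2 -0.443 15 (15, 15) a->b
2 3 0.239 0 (-1, 1) undirected
3 4 0.334 0 (0, 0) undirected
{1: 0.924, 2: 0.868, 3: 0.924, 4: 0.852, 5: 0.805}
```

Five domains are recovered; the three inferred edges (in the relabelled
domain ids) map exactly onto the three planted ones with the right signs,
the planted lag 15 inside the inferred lag range, and `|r*|` ordered
(1,3) > (4,5) > (3,5); every domain recovers ≥ 80% of its ground-truth
cells.  The same pipeline runs on real data from the command line:

```sh
delta-maps network sst.nc --alpha 0.01 --lat-bounds -60 60 \
    --anomaly-period 12 --tau-max 12 --fdr-q 0.03 --out sst-network/
delta-maps benchmark --seed 1          # the synthetic experiment above
```

Scikit-learn users can compose the two stages as estimators:

```python
from sklearn.pipeline import Pipeline
from deltamaps import DomainIdentifier, FunctionalNetworkInference

pipe = Pipeline([
    ("domains", DomainIdentifier(grid=grid, delta=0.55, k=4)),
    ("network", FunctionalNetworkInference(tau_max=20, q=0.10)),
]).fit(field.series)
```

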