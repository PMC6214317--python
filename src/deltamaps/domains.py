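"""Stage 1: identification of spatially contiguous, overlapping domains.

A domain rooted at a core cell c is a maximal cell set A with c in A,
I_G(A) = 1 (spatial contiguity) and homogeneity r_hat(A) > delta.  Finding
the largest such set is NP-hard, so the method is a greedy two-phase
heuristic: (1) seed selection at local maxima of the local-homogeneity field;
(2) iterated expansion (one best frontier cell at a time, per domain, in
rounds ordered by decreasing homogeneity) interleaved with merging of
touching domains whose union stays above delta.

Expansion acceptance supports two rules (``expansion_rule``):

``"cell"`` (default)
    the argmax frontier cell is added iff the union homogeneity exceeds
    delta AND the cell's mean correlation to the current members exceeds
    delta.  The second condition is what stops a large domain from slowly
    absorbing uncorrelated cells (a single cell moves an m-cell average by
    O(1/m)), and is required to leave domains as subsets of the true signal
    support with homogeneity well above delta.
``"domain"``
    only the union-homogeneity condition, the literal reading of the
    constraint; large domains then dilute toward r_hat(A) ~ delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .grid import GridGraph, is_contiguous, k_neighborhood
from .field import Field, pairwise_correlation_sum, local_homogeneity

__all__ = [
    "Domain",
    "DomainSet",
    "compute_local_homogeneity_field",
    "select_seeds",
    "try_merge",
    "expand_domain_step",
    "identify_domains",
    "DomainIdentifier",
]


class Domain:
    """A contiguous cell set grown from one or more seed cells.

    Keeps an incremental representation: ``svec`` is the sum of the unit-norm
    rows of ``Field.U`` over member cells, and ``pair_sum`` the sum of all
    pairwise correlations, so that adding cell i costs one dot product
    (pair_sum += svec . u_i).
    """

    __slots__ = ("id", "cells", "seeds", "svec", "pair_sum", "frontier",
                 "singleton_homogeneity", "version")

    def __init__(self, did: int, seed: int, f: Field, g: GridGraph, seed_hom: float):
        self.id = did
        self.cells = {seed}
        self.seeds = {seed}
        self.svec = f.U[seed].copy()
        self.pair_sum = 0.0
        self.frontier = {j for j in g.adjacency[seed] if not g.mask[j]}
        self.singleton_homogeneity = seed_hom
        self.version = 0

    @property
    def size(self) -> int:
        return len(self.cells)

    @property
    def homogeneity(self) -> float:
        """r_hat(A); for a singleton, the seed's local homogeneity."""
        m = len(self.cells)
        if m < 2:
            return self.singleton_homogeneity
        return self.pair_sum / (m * (m - 1) / 2.0)

    def add_cell(self, i: int, f: Field, g: GridGraph) -> None:
        self.pair_sum += float(self.svec @ f.U[i])
        self.svec = self.svec + f.U[i]
        self.cells.add(i)
        self.frontier.discard(i)
        self.frontier |= {
            j for j in g.adjacency[i] if not g.mask[j] and j not in self.cells
        }
        self.version += 1

    def touches(self, other: "Domain") -> bool:
        """True iff the union of the two cell sets is connected."""
        a, b = (self, other) if len(self.cells) <= len(other.cells) else (other, self)
        return any(c in b.cells or c in b.frontier for c in a.cells)


@dataclass
class DomainSet:
    """The output of domain identification."""

    domains: list
    delta: float
    n_cells: int
    discarded: list = dfield(default_factory=list)  # sub-minimum-size domains

    def __len__(self):
        return len(self.domains)

    @property
    def cell_membership(self) -> dict:
        """Map cell id -> sorted tuple of domain ids (overlaps allowed)."""
        mem = {}
        for d in self.domains:
            for c in d.cells:
                mem.setdefault(c, []).append(d.id)
        return {c: tuple(sorted(v)) for c, v in mem.items()}

    def audit(self, f: Field, g: GridGraph) -> None:
        """Re-verify every domain constraint from scratch.

        Each domain must be contiguous, contain at least one seed, and have
        recomputed homogeneity above delta.
        """
        for d in self.domains:
            if not is_contiguous(g, d.cells):
                raise AssertionError(f"domain {d.id} is not contiguous")
            if not (d.seeds & d.cells):
                raise AssertionError(f"domain {d.id} lost its seeds")
            if d.size >= 2:
                m = d.size
                hom = pairwise_correlation_sum(f, d.cells) / (m * (m - 1) / 2.0)
                if not hom > self.delta:
                    raise AssertionError(
                        f"domain {d.id} homogeneity {hom:.4f} <= delta {self.delta}"
                    )
                if abs(hom - d.homogeneity) > 1e-8:
                    raise AssertionError(
                        f"domain {d.id} cached homogeneity drifted "
                        f"({d.homogeneity:.10f} vs {hom:.10f})"
                    )


def compute_local_homogeneity_field(
    f: Field, g: GridGraph, K: int, metric: str = "euclidean"
):
    """Local homogeneity r_hat_K at every unmasked cell (NaN elsewhere)."""
    hom = np.full(g.n_cells, np.nan)
    neighborhoods = {}
    for i in map(int, g.unmasked):
        nb = k_neighborhood(g, i, K, metric=metric)
        neighborhoods[i] = nb
        if len(nb.members) >= 2:
            hom[i] = local_homogeneity(f, nb)
    return hom, neighborhoods


def select_seeds(
    f: Field,
    g: GridGraph,
    K: int,
    delta: float,
    metric: str = "euclidean",
    hom_field=None,
):
    """Cells whose local homogeneity exceeds delta and is a local maximum.

    Cell i is a seed if r_hat_K(i) > delta and r_hat_K(i) >= r_hat_K(j) for
    every j in its K-neighborhood (ties admitted, so plateaus can yield
    several adjacent seeds).
    """
    if hom_field is None:
        hom, neighborhoods = compute_local_homogeneity_field(f, g, K, metric)
    else:
        hom, neighborhoods = hom_field
    seeds = []
    for i, nb in neighborhoods.items():
        if not np.isfinite(hom[i]) or hom[i] <= delta:
            continue
        others = [hom[j] for j in nb.members if j != i and np.isfinite(hom[j])]
        if all(hom[i] >= h for h in others):
            seeds.append(i)
    return sorted(seeds), hom, neighborhoods


class _UnionHomogeneityMemo:
    """Memoized union homogeneity of domain pairs, keyed by domain versions."""

    def __init__(self, f: Field):
        self.f = f
        self._memo = {}

    def __call__(self, a: Domain, b: Domain) -> float:
        key = (a.id, a.version, b.id, b.version)
        if key not in self._memo:
            cells = a.cells | b.cells
            m = len(cells)
            self._memo[key] = (
                pairwise_correlation_sum(self.f, cells) / (m * (m - 1) / 2.0)
            )
        return self._memo[key]


def _merge_pair(a: Domain, b: Domain, f: Field, g: GridGraph) -> Domain:
    # merge b into a (a keeps its id); recompute sums on the union set
    idx = np.fromiter(a.cells | b.cells, dtype=int)
    a.cells = set(map(int, idx))
    a.seeds |= b.seeds
    a.svec = f.U[idx].sum(axis=0)
    a.pair_sum = float((a.svec @ a.svec - idx.size) / 2.0)
    a.frontier = (a.frontier | b.frontier) - a.cells
    a.version += 1
    return a


def try_merge(domains: list, f: Field, g: GridGraph, delta: float, memo=None) -> bool:
    """Repeatedly merge the touching pair with maximum union homogeneity.

    A pair qualifies if the union of their cell sets is connected (both are
    connected, so it suffices that they share a cell or are edge-adjacent)
    and the union homogeneity exceeds delta.  Returns whether any merge
    happened; ``domains`` is modified in place.
    """
    if memo is None:
        memo = _UnionHomogeneityMemo(f)
    merged_any = False
    while True:
        best = None
        for ia in range(len(domains)):
            for ib in range(ia + 1, len(domains)):
                a, b = domains[ia], domains[ib]
                if not a.touches(b):
                    continue
                hom = memo(a, b)
                if hom > delta and (best is None or hom > best[0]):
                    best = (hom, ia, ib)
        if best is None:
            return merged_any
        _, ia, ib = best
        _merge_pair(domains[ia], domains[ib], f, g)
        del domains[ib]
        merged_any = True


def expand_domain_step(
    d: Domain,
    f: Field,
    g: GridGraph,
    delta: float,
    rule: str = "cell",
) -> bool:
    """Attempt to add the single best frontier cell to ``d``.

    Evaluates every unmasked cell adjacent to the domain (cells belonging to
    other domains included -- overlap is permitted), picks the one maximizing
    the union homogeneity (ties broken by lowest cell id), and adds it if it
    passes the acceptance rule.  Returns whether a cell was added.
    """
    if not d.frontier:
        return False
    cands = np.fromiter(sorted(d.frontier), dtype=int)
    cross = f.U[cands] @ d.svec  # sum of correlations of each candidate to members
    m = d.size
    n_pairs_new = (m + 1) * m / 2.0
    union_hom = (d.pair_sum + cross) / n_pairs_new
    k = int(np.argmax(union_hom))  # first occurrence -> lowest cell id on ties
    if union_hom[k] <= delta:
        return False
    if rule == "cell" and cross[k] / m <= delta:
        return False
    elif rule not in ("cell", "domain"):
        raise ValueError(f"unknown expansion rule {rule!r}")
    d.add_cell(int(cands[k]), f, g)
    return True


def identify_domains(
    f: Field,
    g: GridGraph,
    K: int,
    delta: float,
    metric: str = "euclidean",
    expansion_rule: str = "cell",
    min_size: int = 2,
    max_rounds: int = 100_000,
) -> DomainSet:
    """Run the full greedy domain-identification loop.

    One candidate domain is created per seed; the seed set is merged to
    exhaustion; then expansion proceeds in rounds.  At the start of each
    round domains are sorted in decreasing order of homogeneity (the order is
    frozen within the round); each domain attempts one single-cell expansion
    in that order, and after every expansion merges are attempted to
    exhaustion.  The loop terminates when a full round produces no expansion
    and no merge.  Domains smaller than ``min_size`` are discarded (reported
    via :attr:`DomainSet.discarded`).
    """
    seeds, hom, _ = select_seeds(f, g, K, delta, metric=metric)
    memo = _UnionHomogeneityMemo(f)
    domains = [Domain(i, s, f, g, float(hom[s])) for i, s in enumerate(seeds)]
    try_merge(domains, f, g, delta, memo)
    for _ in range(max_rounds):
        order = sorted(domains, key=lambda d: (-d.homogeneity, d.id))
        changed = False
        for d in order:
            if d not in domains:  # merged away earlier in this round
                continue
            if expand_domain_step(d, f, g, delta, rule=expansion_rule):
                changed = True
                if try_merge(domains, f, g, delta, memo):
                    changed = True
        if not changed:
            break
    else:
        raise RuntimeError("domain identification did not terminate")
    kept = [d for d in domains if d.size >= min_size]
    discarded = [d for d in domains if d.size < min_size]
    # relabel 0..N-1 in order of decreasing size then homogeneity
    kept.sort(key=lambda d: (-d.size, -d.homogeneity, min(d.cells)))
    for new_id, d in enumerate(kept):
        d.id = new_id
    ds = DomainSet(domains=kept, delta=delta, n_cells=g.n_cells, discarded=discarded)
    ds.audit(f, g)
    return ds


class DomainIdentifier(TransformerMixin, BaseEstimator):
    """Scikit-learn style estimator for domain identification.

    ``fit(X)`` takes the field as a ``(T, n_cells)`` matrix; the spatial
    structure is supplied through the ``grid`` parameter.  ``transform(X)``
    reduces the field to the ``(T, n_domains)`` matrix of domain signals.

    Parameters
    ----------
    grid : GridGraph
        Spatial adjacency/coordinates of the n_cells columns of X.
    k : int, default 4
        Neighborhood size for the local homogeneity field.
    delta : float or None
        Homogeneity threshold; mutually exclusive with ``alpha``.
    alpha : float or None
        One-sided significance level from which delta is estimated.
    metric : {"euclidean", "geodesic", "graph-hops"}
    expansion_rule : {"cell", "domain"}
    signal_mode : {"average", "cumulative"}
        How ``transform`` builds domain signals.
    random_state : int or None
        Seed for the delta-estimation pair sample.

    Attributes
    ----------
    delta_ : float            threshold actually used
    seeds_ : list of int      selected seed cells
    domain_set_ : DomainSet
    n_domains_ : int
    membership_ : dict        cell id -> tuple of domain ids
    """

    def __init__(
        self,
        grid=None,
        k=4,
        delta=None,
        alpha=None,
        metric="euclidean",
        expansion_rule="cell",
        signal_mode="average",
        min_domain_size=2,
        n_delta_pairs=10_000,
        random_state=None,
    ):
        self.grid = grid
        self.k = k
        self.delta = delta
        self.alpha = alpha
        self.metric = metric
        self.expansion_rule = expansion_rule
        self.signal_mode = signal_mode
        self.min_domain_size = min_domain_size
        self.n_delta_pairs = n_delta_pairs
        self.random_state = random_state

    def _to_field(self, X) -> Field:
        if isinstance(X, Field):
            return X
        mask = self.grid.mask if self.grid is not None else None
        return Field(np.asarray(X, dtype=float), mask=mask)

    def fit(self, X, y=None):
        from .field import estimate_delta

        if self.grid is None:
            raise ValueError("a GridGraph must be supplied via the grid parameter")
        if (self.delta is None) == (self.alpha is None):
            raise ValueError("exactly one of delta / alpha must be set")
        f = self._to_field(X)
        if f.n_cells != self.grid.n_cells:
            raise ValueError("field and grid disagree on the number of cells")
        if self.delta is not None:
            self.delta_ = float(self.delta)
        else:
            self.delta_ = estimate_delta(
                f,
                self.grid,
                alpha=self.alpha,
                n_pairs=self.n_delta_pairs,
                rng_seed=self.random_state,
            )
        self.field_ = f
        self.domain_set_ = identify_domains(
            f,
            self.grid,
            K=self.k,
            delta=self.delta_,
            metric=self.metric,
            expansion_rule=self.expansion_rule,
            min_size=self.min_domain_size,
        )
        self.seeds_ = sorted(s for d in self.domain_set_.domains for s in d.seeds)
        self.n_domains_ = len(self.domain_set_)
        self.membership_ = self.domain_set_.cell_membership
        return self

    def transform(self, X):
        """Reduce a (T, n_cells) field to the (T, n_domains) domain signals."""
        from .network import domain_signal

        f = self._to_field(X)
        sigs = [
            domain_signal(f, d, mode=self.signal_mode, cell_weight=self.grid.cell_weight)
            for d in self.domain_set_.domains
        ]
        return np.column_stack([s.series for s in sigs]) if sigs else np.empty((f.T, 0))
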