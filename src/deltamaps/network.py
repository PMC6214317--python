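"""Stage 2: the lagged, signed, weighted network between domains.

Each domain gets a representative signal X_A(t) (weighted cumulative sum for
area-weighted climate grids, plain average for fMRI-style data).  For every
domain pair the sample cross-correlogram over lags -tau_max..tau_max is
computed with the method's normalisation

    r_AB(tau) = sum_{t=1}^{T-tau} (X_A(t)-mu_A)(X_B(t+tau)-mu_B) / (T s_A s_B)

(negative lags by swapping roles).  Each per-lag correlation is z-scored
with its Bartlett variance

    Var[r_AB(tau)] = (1/(T-|tau|)) sum_k rho_A(k) rho_B(k),

two-sided normal p-values are pooled over all N(N-1)/2 x (2 tau_max + 1)
tests, and Benjamini-Hochberg step-up at rate q selects the significant
(pair, lag) tests.  A pair with at least one surviving lag becomes an edge,
annotated with the maximizing lag tau*, the lag range R_tau (surviving lags
within one Bartlett standard deviation of |r*|), a direction (undirected iff
R_tau spans 0), and the covariance weight w = s_A s_B r*.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field as dfield

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .field import VARIANCE_FLOOR, Field, sample_autocorrelation

__all__ = [
    "DomainSignal",
    "Correlogram",
    "Edge",
    "FunctionalNetwork",
    "domain_signal",
    "lagged_crosscorrelation",
    "bartlett_variance_lagged",
    "edge_significance",
    "fdr_select",
    "infer_lag_range",
    "edge_weight",
    "infer_network",
    "FunctionalNetworkInference",
    "structural_balance",
    "lag_consistent_triangles",
]


@dataclass
class DomainSignal:
    """Representative time series of one domain."""

    domain_id: int
    series: np.ndarray
    mode: str

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        self.mean = float(self.series.mean())
        self.sd = float(self.series.std())  # population convention
        if self.sd <= 0:
            raise ValueError(f"domain {self.domain_id} signal has zero variance")

    @property
    def T(self) -> int:
        return self.series.size


def domain_signal(f: Field, d, mode: str = "average", cell_weight=None) -> DomainSignal:
    """Build the domain-level signal from the member cells.

    ``mode="cumulative"``: sum of cell series weighted by relative cell area
    (cos-latitude on geographic grids); ``mode="average"``: unweighted mean
    (the BOLD convention).  With equal weights the two differ only by scale,
    so correlations are identical.
    """
    cells = np.fromiter(sorted(d.cells), dtype=int) if hasattr(d, "cells") else np.asarray(d, dtype=int)
    if cells.size < 1:
        raise ValueError("empty domain")
    X = f.series[:, cells]
    if mode == "average":
        series = X.mean(axis=1)
    elif mode == "cumulative":
        w = np.ones(cells.size) if cell_weight is None else np.asarray(cell_weight, dtype=float)[cells]
        series = X @ (w / w.sum())
    else:
        raise ValueError(f"unknown signal mode {mode!r}")
    did = getattr(d, "id", -1)
    return DomainSignal(domain_id=did, series=series, mode=mode)


@dataclass
class Correlogram:
    """Cross-correlations, Bartlett variances, z-scores and p-values per lag."""

    pair: tuple
    lags: np.ndarray
    r: np.ndarray
    var: np.ndarray = None
    z: np.ndarray = None
    p: np.ndarray = None

    def lag_index(self, tau: int) -> int:
        return int(tau - self.lags[0])


def lagged_crosscorrelation(sa: DomainSignal, sb: DomainSignal, tau_max: int) -> Correlogram:
    """Sample cross-correlogram of two domain signals over +-tau_max lags.

    Positive tau pairs X_A(t) with X_B(t+tau): a maximum at tau > 0 means
    A's signal precedes B's.  The printed normalisation by T (not T-tau) is
    used; values are clamped to [-1, 1].
    """
    T = sa.T
    if sb.T != T:
        raise ValueError("signals differ in length")
    if not 0 < tau_max <= T // 4:
        raise ValueError("tau_max must satisfy 0 < tau_max <= T/4")
    a = sa.series - sa.mean
    b = sb.series - sb.mean
    denom = T * sa.sd * sb.sd
    lags = np.arange(-tau_max, tau_max + 1)
    r = np.empty(lags.size)
    for k, tau in enumerate(lags):
        if tau >= 0:
            num = float(a[: T - tau] @ b[tau:])
        else:
            num = float(b[: T + tau] @ a[-tau:])
        r[k] = num / denom
    return Correlogram(pair=(sa.domain_id, sb.domain_id), lags=lags, r=np.clip(r, -1.0, 1.0))


def bartlett_variance_lagged(sa: DomainSignal, sb: DomainSignal, tau: int,
                             acf_a=None, acf_b=None) -> float:
    """Bartlett variance of r_AB(tau) under the uncoupled null."""
    T = sa.T
    if abs(tau) >= T - 1:
        raise ValueError("lag too large")
    if acf_a is None:
        acf_a = sample_autocorrelation(sa.series)
    if acf_b is None:
        acf_b = sample_autocorrelation(sb.series)
    s = 1.0 + 2.0 * float(acf_a[1 : T - 1] @ acf_b[1 : T - 1])
    return max(s / (T - abs(tau)), VARIANCE_FLOOR)


def edge_significance(c: Correlogram) -> np.ndarray:
    """Two-sided normal p-value per lag (edges can be negative)."""
    if c.var is None:
        raise ValueError("correlogram variances not computed")
    c.z = c.r / np.sqrt(c.var)
    c.p = 2.0 * stats.norm.sf(np.abs(c.z))
    return c.p


def fdr_select(pvalues, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up over a pooled vector of p-values.

    Keeps the m smallest p-values where p_(m) is the largest p-value with
    p_(m) < q * m / M (strict inequality).  Returns the kept indices into
    the input vector.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    M = p.size
    below = ranked < q * np.arange(1, M + 1) / M
    if not below.any():
        return np.array([], dtype=int)
    m = int(np.max(np.nonzero(below)[0])) + 1
    return np.sort(order[:m])


@dataclass
class Edge:
    """A significant domain pair with lag range, direction and weight."""

    a: int
    b: int
    r_star: float
    tau_star: int
    lag_min: int
    lag_max: int
    lag_set: tuple       # lags qualifying for the range (within one sd of |r*|)
    significant_lags: tuple  # all FDR-surviving lags for this pair
    direction: str       # "undirected", "a->b" or "b->a"
    weight: float

    def mirrored(self) -> "Edge":
        """The same edge seen from (b, a): lags negate, direction flips."""
        dirmap = {"undirected": "undirected", "a->b": "b->a", "b->a": "a->b"}
        return Edge(
            a=self.b, b=self.a, r_star=self.r_star, tau_star=-self.tau_star,
            lag_min=-self.lag_max, lag_max=-self.lag_min,
            lag_set=tuple(sorted(-t for t in self.lag_set)),
            significant_lags=tuple(sorted(-t for t in self.significant_lags)),
            direction=dirmap[self.direction], weight=self.weight,
        )


def infer_lag_range(c: Correlogram, kept_lags) -> dict:
    """Lag statistics of one edge from its FDR-surviving lags.

    tau* is the surviving lag maximizing |r| (ties: smaller |tau|, then
    smaller tau); the qualifying set holds every surviving lag with |r(tau)|
    within one Bartlett standard deviation (at tau*) of |r*|; R_tau is its
    closed [min, max] interval; the edge is undirected iff that interval
    contains 0, directed a->b if all its lags are positive, b->a otherwise.
    """
    kept = sorted(kept_lags)
    if not kept:
        raise ValueError("no surviving lags for this pair")
    idx = [c.lag_index(t) for t in kept]
    absr = np.abs(c.r[idx])
    best = max(range(len(kept)), key=lambda k: (absr[k], -abs(kept[k]), -kept[k]))
    tau_star = kept[best]
    r_star = float(c.r[c.lag_index(tau_star)])
    sd = float(np.sqrt(c.var[c.lag_index(tau_star)]))
    qual = tuple(t for k, t in enumerate(kept) if absr[k] >= abs(r_star) - sd)
    lag_min, lag_max = min(qual), max(qual)
    if lag_min <= 0 <= lag_max:
        direction = "undirected"
    elif lag_min > 0:
        direction = "a->b"
    else:
        direction = "b->a"
    return {
        "tau_star": int(tau_star),
        "r_star": r_star,
        "lag_min": int(lag_min),
        "lag_max": int(lag_max),
        "lag_set": qual,
        "direction": direction,
    }


def edge_weight(sa: DomainSignal, sb: DomainSignal, r_star: float) -> float:
    """Covariance-scale edge weight w(A,B) = sigma_A sigma_B r*."""
    return sa.sd * sb.sd * r_star


@dataclass
class FunctionalNetwork:
    """Weighted, lagged, signed network between domains."""

    n_domains: int
    edges: list
    strength: dict
    q: float
    tau_max: int
    n_tests: int
    signals: list = dfield(default_factory=list)
    correlograms: dict = dfield(default_factory=dict)
    domain_ids: list = dfield(default_factory=list)

    def edge_between(self, a: int, b: int):
        """The edge joining domains a and b, oriented as (a, b), or None."""
        for e in self.edges:
            if (e.a, e.b) == (a, b):
                return e
            if (e.a, e.b) == (b, a):
                return e.mirrored()
        return None

    def to_graph(self) -> nx.Graph:
        gr = nx.Graph()
        gr.add_nodes_from(self.domain_ids)
        for e in self.edges:
            gr.add_edge(e.a, e.b, weight=e.weight, sign=1 if e.weight >= 0 else -1,
                        edge=e)
        return gr

    def to_json(self) -> str:
        nodes = [
            {"id": int(i), "strength": float(self.strength.get(i, 0.0))}
            for i in self.domain_ids
        ]
        edges = [
            {
                "a": int(e.a), "b": int(e.b), "r_star": e.r_star,
                "tau_star": e.tau_star, "lag_min": e.lag_min, "lag_max": e.lag_max,
                "direction": e.direction, "weight": e.weight,
                "n_significant_lags": len(e.significant_lags),
            }
            for e in self.edges
        ]
        return json.dumps(
            {"q": self.q, "tau_max": self.tau_max, "n_tests": self.n_tests,
             "nodes": nodes, "edges": edges},
            indent=2,
        )


def _signals_from_matrix(S: np.ndarray, ids=None) -> list:
    S = np.asarray(S, dtype=float)
    ids = list(range(S.shape[1])) if ids is None else list(ids)
    return [DomainSignal(domain_id=i, series=S[:, k], mode="given")
            for k, i in enumerate(ids)]


def infer_network_from_signals(
    signals: list,
    tau_max: int = 20,
    q: float = 0.10,
    weight_from: str = "r_star",
) -> FunctionalNetwork:
    """Edge inference given the per-domain signals (see module docstring)."""
    N = len(signals)
    ids = [s.domain_id for s in signals]
    pairs = list(itertools.combinations(range(N), 2))
    n_lags = 2 * tau_max + 1
    n_tests = len(pairs) * n_lags
    if N < 2:
        return FunctionalNetwork(N, [], {i: 0.0 for i in ids}, q, tau_max, 0,
                                 signals=signals, domain_ids=ids)
    acfs = [sample_autocorrelation(s.series) for s in signals]
    T = signals[0].T
    correlograms = {}
    pooled_p = np.empty(n_tests)
    for k, (ia, ib) in enumerate(pairs):
        c = lagged_crosscorrelation(signals[ia], signals[ib], tau_max)
        base = 1.0 + 2.0 * float(acfs[ia][1 : T - 1] @ acfs[ib][1 : T - 1])
        c.var = np.maximum(base / (T - np.abs(c.lags)), VARIANCE_FLOOR)
        edge_significance(c)
        correlograms[(ids[ia], ids[ib])] = c
        pooled_p[k * n_lags : (k + 1) * n_lags] = c.p
    kept = fdr_select(pooled_p, q)
    kept_by_pair = {}
    for t in kept:
        k, li = divmod(int(t), n_lags)
        kept_by_pair.setdefault(k, []).append(int(li - tau_max))
    edges = []
    for k, lags in sorted(kept_by_pair.items()):
        ia, ib = pairs[k]
        c = correlograms[(ids[ia], ids[ib])]
        info = infer_lag_range(c, lags)
        if weight_from == "r_star":
            r_for_weight = info["r_star"]
        elif weight_from == "mean_range":
            r_for_weight = float(np.mean([c.r[c.lag_index(t)] for t in info["lag_set"]]))
        else:
            raise ValueError(f"unknown weight_from {weight_from!r}")
        w = edge_weight(signals[ia], signals[ib], r_for_weight)
        edges.append(
            Edge(
                a=ids[ia], b=ids[ib], r_star=info["r_star"],
                tau_star=info["tau_star"], lag_min=info["lag_min"],
                lag_max=info["lag_max"], lag_set=info["lag_set"],
                significant_lags=tuple(sorted(lags)),
                direction=info["direction"], weight=w,
            )
        )
    strength = {i: 0.0 for i in ids}
    for e in edges:
        strength[e.a] += abs(e.weight)
        strength[e.b] += abs(e.weight)
    return FunctionalNetwork(
        n_domains=N, edges=edges, strength=strength, q=q, tau_max=tau_max,
        n_tests=n_tests, signals=signals, correlograms=correlograms,
        domain_ids=ids,
    )


def infer_network(
    f: Field,
    ds,
    tau_max: int = 20,
    q: float = 0.10,
    mode: str = "average",
    cell_weight=None,
    weight_from: str = "r_star",
) -> FunctionalNetwork:
    """Full stage-2 inference from a field and an identified DomainSet."""
    signals = [domain_signal(f, d, mode=mode, cell_weight=cell_weight)
               for d in ds.domains]
    return infer_network_from_signals(signals, tau_max=tau_max, q=q,
                                      weight_from=weight_from)


class FunctionalNetworkInference(BaseEstimator):
    """Scikit-learn style estimator for stage-2 edge inference.

    ``fit(X)`` takes the ``(T, n_domains)`` matrix of domain signals (e.g.
    the output of :meth:`DomainIdentifier.transform`) and infers the lagged
    signed network between the columns.

    Attributes
    ----------
    network_ : FunctionalNetwork
    edges_ : list of Edge
    strength_ : dict domain id -> node strength
    """

    def __init__(self, tau_max=20, q=0.10, weight_from="r_star"):
        self.tau_max = tau_max
        self.q = q
        self.weight_from = weight_from

    def fit(self, X, y=None):
        signals = _signals_from_matrix(X)
        self.network_ = infer_network_from_signals(
            signals, tau_max=self.tau_max, q=self.q, weight_from=self.weight_from
        )
        self.edges_ = self.network_.edges
        self.strength_ = self.network_.strength
        return self


# ---------------------------------------------------------------------------
# Signed-graph analyses


@dataclass
class BalanceResult:
    balanced: bool
    poles: tuple | None       # (set, set) two-coloring when balanced
    violating_cycle: list | None  # node cycle with odd negative-edge count


def structural_balance(net) -> BalanceResult:
    """Check structural balance of the signed undirected network.

    A signed graph is balanced iff it has no cycle with an odd number of
    negative edges, equivalently iff nodes can be two-colored so positive
    edges stay within a pole and negative edges cross poles.  BFS two-coloring
    per connected component; on conflict the violating cycle (tree paths plus
    the conflicting edge) is returned.
    """
    gr = net.to_graph() if hasattr(net, "to_graph") else net
    color = {}
    parent = {}
    for root in sorted(gr.nodes):
        if root in color:
            continue
        color[root] = 0
        parent[root] = None
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v in sorted(gr.neighbors(u)):
                want = color[u] ^ (0 if gr[u][v]["sign"] >= 0 else 1)
                if v not in color:
                    color[v] = want
                    parent[v] = u
                    queue.append(v)
                elif color[v] != want:
                    return BalanceResult(False, None, _tree_cycle(parent, u, v))
    pole0 = {n for n, c in color.items() if c == 0}
    pole1 = {n for n, c in color.items() if c == 1}
    return BalanceResult(True, (pole0, pole1), None)


def _tree_cycle(parent, u, v):
    def path_to_root(x):
        out = [x]
        while parent[x] is not None:
            x = parent[x]
            out.append(x)
        return out
    pu, pv = path_to_root(u), path_to_root(v)
    su = set(pu)
    lca = next(x for x in pv if x in su)
    cyc = pu[: pu.index(lca) + 1] + list(reversed(pv[: pv.index(lca)]))
    return cyc


@dataclass
class TriangleReport:
    nodes: tuple
    consistent: bool
    witness: tuple | None  # oriented lags (a->b, b->c, c->a) summing to zero


def lag_consistent_triangles(net) -> list:
    """Lag consistency of every triangle of the network.

    A triangle (a, b, c) is lag-consistent if one lag can be chosen from each
    edge's qualifying set such that the oriented temporal offsets around the
    cycle sum to zero (an edge stored as (x, y) with lag tau contributes +tau
    when traversed x->y and -tau when traversed y->x).
    """
    gr = net.to_graph() if hasattr(net, "to_graph") else net
    reports = []
    for a, b, c in _triangles(gr):
        eab = _oriented_lags(gr, a, b)
        ebc = _oriented_lags(gr, b, c)
        eca = _oriented_lags(gr, c, a)
        witness = None
        for la, lb, lc in itertools.product(eab, ebc, eca):
            if la + lb + lc == 0:
                witness = (la, lb, lc)
                break
        reports.append(TriangleReport(nodes=(a, b, c), consistent=witness is not None,
                                      witness=witness))
    return reports


def _triangles(gr):
    nodes = sorted(gr.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if not gr.has_edge(a, b):
                continue
            for c in nodes[nodes.index(b) + 1:]:
                if gr.has_edge(a, c) and gr.has_edge(b, c):
                    yield (a, b, c)


def _oriented_lags(gr, x, y):
    e = gr[x][y]["edge"]
    lags = e.lag_set
    return lags if (e.a, e.b) == (x, y) else tuple(-t for t in lags)
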