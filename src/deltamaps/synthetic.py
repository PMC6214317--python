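"""Ground-truth benchmark: five circular domains on a 50 x 70 grid.

Five "mother" series y_i(t), mutually uncorrelated at every lag |tau| <= 20
(max absolute cross-correlation < 0.05), are mixed into per-domain signals

    x_1 = 2/3 y_1 - 1/3 y_3(t+15)      (s_1 = 16, r_c = 2,   r_p = 10)
    x_2 = y_2                          (s_2 = 11, r_c = 4,   r_p = 14)
    x_3 = y_3                          (s_3 = 16, r_c = 2,   r_p = 10)
    x_4 = 3/4 y_4 + 1/4 y_5            (s_4 = 9,  r_c = 0.5, r_p = 5)
    x_5 = 4/5 y_5 + 1/5 y_3            (s_5 = 6,  r_c = 1,   r_p = 7)

each restandardised and scaled by sqrt(s_i).  Every cell within r_c of a
domain center carries the full signal; between r_c and r_p the amplitude is
attenuated by sqrt(f(d)) with f(d) = (r_p - d)/(r_p - r_c); unit-variance
white Gaussian noise is added everywhere.  The construction plants exactly
three domain-level edges: (1,3) negative at lag 15, (4,5) positive at lag 0,
(3,5) positive at lag 0, ordered (1,3) > (4,5) > (3,5) in |correlation|.

The mothers are AR(1) surrogates standing in for strongly autocorrelated
band-passed BOLD series; see docs/methods.md for the construction that makes
them exactly uncorrelated over the tested lag window.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .grid import GridGraph, build_regular_grid
from .field import Field
from .network import DomainSignal, lagged_crosscorrelation

__all__ = [
    "DomainSpec",
    "SyntheticGroundTruth",
    "RecoveryReport",
    "DEFAULT_SPECS",
    "PLANTED_EDGES",
    "generate_mother_series",
    "mix_signals",
    "render_field",
    "generate_benchmark",
    "evaluate_recovery",
    "run_benchmark",
]


@dataclass
class DomainSpec:
    """Geometry, power and mixing recipe of one synthetic domain."""

    id: int
    center: tuple        # (row, col)
    r_core: float
    r_peripheral: float
    variance: float      # s_i
    recipe: tuple        # ((mother index 1-based, coefficient, lag), ...)

    def __post_init__(self):
        if not 0 <= self.r_core < self.r_peripheral:
            raise ValueError("need 0 <= r_core < r_peripheral")
        if self.variance <= 0:
            raise ValueError("variance must be positive")


# Mixing recipes, radii and variances follow the benchmark's generation
# table; the circle centers are chosen to reproduce its topology (domains 1
# and 3 each overlap domain 2; domains 4 and 5 overlap slightly; no other
# pair of circles intersects on the 50 x 70 grid).
DEFAULT_SPECS = (
    DomainSpec(1, (25, 15), 2.0, 10.0, 16.0, ((1, 2 / 3, 0), (3, -1 / 3, 15))),
    DomainSpec(2, (25, 35), 4.0, 14.0, 11.0, ((2, 1.0, 0),)),
    DomainSpec(3, (25, 55), 2.0, 10.0, 16.0, ((3, 1.0, 0),)),
    DomainSpec(4, (40, 12), 0.5, 5.0, 9.0, ((4, 3 / 4, 0), (5, 1 / 4, 0))),
    DomainSpec(5, (42, 22), 1.0, 7.0, 6.0, ((5, 4 / 5, 0), (3, 1 / 5, 0))),
)

# (domain a, domain b, sign, planted lag): positive lag = a's signal precedes b's
PLANTED_EDGES = ((1, 3, -1, 15), (4, 5, +1, 0), (3, 5, +1, 0))

GRID_ROWS, GRID_COLS = 50, 70


@dataclass
class SyntheticGroundTruth:
    specs: tuple
    membership: dict          # domain id -> set of cell ids (d <= r_p)
    cores: dict               # domain id -> set of cell ids (d <= r_c)
    center_cells: dict        # domain id -> cell id of the circle center
    planted_edges: tuple
    mothers: np.ndarray       # (n_mothers, T)
    mixed: dict               # domain id -> scaled series (T,)
    seed: int | None = None

    @property
    def overlap_cells(self) -> set:
        counts = {}
        for cells in self.membership.values():
            for c in cells:
                counts[c] = counts.get(c, 0) + 1
        return {c for c, k in counts.items() if k >= 2}


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    return x / x.std()


def _ar1(T: int, phi: float, rng, burn: int = 200) -> np.ndarray:
    e = rng.standard_normal(T + burn)
    x = np.empty(T + burn)
    x[0] = e[0] / np.sqrt(1 - phi**2)
    for t in range(1, T + burn):
        x[t] = phi * x[t - 1] + e[t]
    return x[burn:]


def _shift_matrix(y: np.ndarray, max_lag: int) -> np.ndarray:
    """Zero-padded shifted copies of centered y, lags -max_lag..max_lag."""
    T = y.size
    yc = y - y.mean()
    cols = []
    for tau in range(-max_lag, max_lag + 1):
        col = np.zeros(T)
        if tau >= 0:
            col[tau:] = yc[: T - tau]
        else:
            col[: T + tau] = yc[-tau:]
        cols.append(col)
    return np.column_stack(cols)


def max_abs_crosscorr(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Max |truncated-sum cross-correlation| of two series over +-max_lag."""
    sa = DomainSignal(-1, a, "raw")
    sb = DomainSignal(-2, b, "raw")
    return float(np.abs(lagged_crosscorrelation(sa, sb, max_lag).r).max())


def generate_mother_series(
    n: int = 5,
    T: int = 1200,
    rng_seed=None,
    max_abs_cc: float = 0.05,
    max_lag: int = 20,
    ar_coef: float = 0.8,
    max_tries: int = 20,
) -> np.ndarray:
    """Generate n standardized mother series, uncorrelated at |tau| <= max_lag.

    Each series starts as an AR(1) draw and is then orthogonalised against
    the zero-padded lagged copies (|tau| <= max_lag) of all earlier series,
    which makes the truncated-sum cross-correlations at those lags exactly
    zero; the max |cross-correlation| constraint is then verified, drawing a
    fresh sub-seed on the (numerically improbable) event of failure.
    """
    if T < 200:
        raise ValueError("T must be >= 200")
    if isinstance(rng_seed, np.random.SeedSequence):
        base = rng_seed
    else:
        base = np.random.SeedSequence(rng_seed)
    for sub in base.spawn(max_tries):
        rng = np.random.default_rng(sub)
        ys = []
        ok = True
        for i in range(n):
            y = _ar1(T, ar_coef, rng)
            if ys:
                X = np.column_stack([_shift_matrix(prev, max_lag) for prev in ys])
                X = np.column_stack([np.ones(T), X])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                y = y - X @ beta
            if y.std() <= 0:
                ok = False
                break
            ys.append(_standardize(y))
        if not ok:
            continue
        mothers = np.asarray(ys)
        worst = max(
            max_abs_crosscorr(mothers[i], mothers[j], max_lag)
            for i in range(n)
            for j in range(i + 1, n)
        )
        if worst < max_abs_cc:
            return mothers
    raise RuntimeError(
        f"could not satisfy the cross-correlation constraint in {max_tries} tries"
    )


def mix_signals(mothers: np.ndarray, specs=DEFAULT_SPECS) -> dict:
    """Per-domain series: linear mother combinations, restandardised, scaled.

    A recipe entry (m, coef, lag) contributes coef * y_m(t + lag); the shift
    is circular (lags are tiny relative to T).  The mixed series is
    standardized to zero mean and unit variance, then scaled by sqrt(s_i),
    so its sample variance is exactly s_i.
    """
    T = mothers.shape[1]
    out = {}
    for spec in specs:
        x = np.zeros(T)
        for m, coef, lag in spec.recipe:
            if not 1 <= m <= mothers.shape[0]:
                raise ValueError(f"unknown mother index {m}")
            if abs(lag) >= T / 10:
                raise ValueError("planted lag too large relative to T")
            x = x + coef * np.roll(mothers[m - 1], -lag)
        out[spec.id] = _standardize(x) * np.sqrt(spec.variance)
    return out


def attenuation(d, r_core: float, r_peripheral: float):
    """Linear amplitude-squared falloff f(d) between core and periphery."""
    d = np.asarray(d, dtype=float)
    f = (r_peripheral - d) / (r_peripheral - r_core)
    f = np.where(d <= r_core, 1.0, f)
    f = np.where(d > r_peripheral, 0.0, f)
    return np.clip(f, 0.0, 1.0)


def render_field(
    g: GridGraph,
    specs,
    mixed: dict,
    noise_seed=None,
    mothers: np.ndarray | None = None,
) -> tuple:
    """Paint the domain signals onto the grid and add unit white noise.

    Overlap cells carry the sum of the contributing attenuated signals.
    Returns ``(Field, SyntheticGroundTruth)``.
    """
    T = next(iter(mixed.values())).size
    rng = np.random.default_rng(noise_seed)
    series = rng.standard_normal((T, g.n_cells))
    membership, cores, center_cells = {}, {}, {}
    coords = g.coords
    for spec in specs:
        center = np.asarray(spec.center, dtype=float)
        d = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
        inside = d <= spec.r_peripheral
        membership[spec.id] = set(map(int, np.flatnonzero(inside)))
        cores[spec.id] = set(map(int, np.flatnonzero(d <= spec.r_core)))
        center_cells[spec.id] = int(np.argmin(d))
        amp = np.sqrt(attenuation(d[inside], spec.r_core, spec.r_peripheral))
        series[:, inside] += np.outer(mixed[spec.id], amp)
    gt = SyntheticGroundTruth(
        specs=tuple(specs),
        membership=membership,
        cores=cores,
        center_cells=center_cells,
        planted_edges=PLANTED_EDGES,
        mothers=mothers if mothers is not None else np.empty((0, T)),
        mixed=mixed,
        seed=noise_seed,
    )
    return Field(series), gt


def generate_benchmark(seed=None, T: int = 1200, specs=DEFAULT_SPECS,
                       ar_coef: float = 0.8):
    """Mother generation + mixing + rendering with a single seed."""
    ss = np.random.SeedSequence(seed)
    s_mothers, s_noise = ss.spawn(2)
    mothers = generate_mother_series(n=5, T=T, rng_seed=s_mothers, ar_coef=ar_coef)
    mixed = mix_signals(mothers, specs)
    grid = build_regular_grid(GRID_ROWS, GRID_COLS, connectivity=4)
    field, gt = render_field(grid, specs, mixed, noise_seed=s_noise, mothers=mothers)
    gt.seed = seed
    return grid, field, gt


@dataclass
class RecoveryReport:
    """Scoring of a pipeline run against the planted ground truth."""

    n_true: int
    n_inferred: int
    matched: dict                 # gt id -> inferred domain id
    unmatched_inferred: list
    fraction_overall: dict        # gt id -> |inferred & truth| / |truth|
    fraction_nonoverlap: dict
    fraction_overlap: dict        # NaN when the gt domain has no overlap cells
    inferred_homogeneity: dict
    matched_edges: list           # (gt pair, sign_correct, lag_in_range, edge)
    missing_edges: list
    extra_edges: list
    magnitude_order_ok: bool | None

    def to_dict(self) -> dict:
        return {
            "n_true": self.n_true,
            "n_inferred": self.n_inferred,
            "matched": {int(k): int(v) for k, v in self.matched.items()},
            "unmatched_inferred": list(map(int, self.unmatched_inferred)),
            "fraction_overall": {int(k): float(v) for k, v in self.fraction_overall.items()},
            "fraction_nonoverlap": {int(k): float(v) for k, v in self.fraction_nonoverlap.items()},
            "fraction_overlap": {int(k): float(v) for k, v in self.fraction_overlap.items()},
            "inferred_homogeneity": {int(k): float(v) for k, v in self.inferred_homogeneity.items()},
            "matched_edges": [
                {"pair": list(map(int, p)), "sign_correct": bool(s), "lag_in_range": bool(l)}
                for p, s, l, _ in self.matched_edges
            ],
            "missing_edges": [list(map(int, p)) for p in self.missing_edges],
            "extra_edges": [list(map(int, p)) for p in self.extra_edges],
            "magnitude_order_ok": self.magnitude_order_ok,
        }


def evaluate_recovery(gt: SyntheticGroundTruth, ds, net=None) -> RecoveryReport:
    """Match inferred domains to ground truth and score the recovery.

    Each inferred domain is matched to the ground-truth domain whose circle
    center cell it contains; when several inferred domains contain the same
    center, the one with the largest intersection with the truth wins and the
    others are reported as unmatched.
    """
    overlap = gt.overlap_cells
    matched, claimed = {}, set()
    for gid in sorted(gt.membership):
        center = gt.center_cells[gid]
        cands = [
            d for d in ds.domains
            if center in d.cells and d.id not in claimed
        ]
        if not cands:
            continue
        best = max(cands, key=lambda d: (len(d.cells & gt.membership[gid]), -d.id))
        matched[gid] = best.id
        claimed.add(best.id)
    unmatched = [d.id for d in ds.domains if d.id not in claimed]
    by_id = {d.id: d for d in ds.domains}

    frac_all, frac_non, frac_ov, homs = {}, {}, {}, {}
    for gid, cells in gt.membership.items():
        inferred = by_id[matched[gid]].cells if gid in matched else set()
        non = cells - overlap
        ov = cells & overlap
        frac_all[gid] = len(inferred & cells) / len(cells)
        frac_non[gid] = len(inferred & non) / len(non) if non else float("nan")
        frac_ov[gid] = len(inferred & ov) / len(ov) if ov else float("nan")
        homs[gid] = by_id[matched[gid]].homogeneity if gid in matched else float("nan")

    matched_edges, missing, extra = [], [], []
    order_ok = None
    if net is not None:
        inv = {v: k for k, v in matched.items()}
        seen_pairs = set()
        planted = {}
        for a, b, sign, lag in gt.planted_edges:
            planted[(min(a, b), max(a, b))] = (sign, lag) if a < b else (sign, -lag)
        for e in net.edges:
            ga, gb = inv.get(e.a), inv.get(e.b)
            if ga is None or gb is None:
                extra.append((e.a, e.b))
                continue
            key = (min(ga, gb), max(ga, gb))
            ee = e if ga < gb else e.mirrored()
            if key in planted:
                sign, lag = planted[key]
                sign_ok = np.sign(ee.r_star) == sign
                lag_ok = ee.lag_min <= lag <= ee.lag_max
                matched_edges.append((key, bool(sign_ok), bool(lag_ok), ee))
                seen_pairs.add(key)
            else:
                extra.append((ga, gb))
        missing = [p for p in planted if p not in seen_pairs]
        if not missing:
            mag = {p: abs(e.r_star) for p, _, _, e in matched_edges}
            order_ok = mag[(1, 3)] > mag[(4, 5)] > mag[(3, 5)]

    return RecoveryReport(
        n_true=len(gt.membership),
        n_inferred=len(ds.domains),
        matched=matched,
        unmatched_inferred=unmatched,
        fraction_overall=frac_all,
        fraction_nonoverlap=frac_non,
        fraction_overlap=frac_ov,
        inferred_homogeneity=homs,
        matched_edges=matched_edges,
        missing_edges=missing,
        extra_edges=extra,
        magnitude_order_ok=order_ok,
    )


def run_benchmark(
    seed=None,
    T: int = 1200,
    K: int = 4,
    delta: float = 0.55,
    q: float = 0.10,
    tau_max: int = 20,
    signal_mode: str = "average",
    expansion_rule: str = "cell",
    ar_coef: float = 0.8,
):
    """Generate the benchmark and run the full two-stage pipeline on it.

    Returns ``(grid, field, ground_truth, domain_set, network, report)``.
    Defaults are the benchmark's study conditions: K=4, delta=0.55, q=0.10,
    tau_max=20 on a 50 x 70 grid with T=1200.
    """
    from .domains import identify_domains
    from .network import infer_network

    grid, field, gt = generate_benchmark(seed=seed, T=T, ar_coef=ar_coef)
    ds = identify_domains(field, grid, K=K, delta=delta,
                          expansion_rule=expansion_rule)
    net = infer_network(field, ds, tau_max=tau_max, q=q, mode=signal_mode,
                        cell_weight=grid.cell_weight)
    report = evaluate_recovery(gt, ds, net)
    return grid, field, gt, ds, net, report
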