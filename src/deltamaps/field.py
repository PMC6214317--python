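"""Per-cell time-series statistics.

The similarity between two cells is the Pearson cross-correlation at zero
lag, computed with population (1/T) normalisation:

    r_ij = sum_t (x_i(t) - mu_i)(x_j(t) - mu_j) / (T sigma_i sigma_j)

Homogeneity of a cell set is the mean pairwise correlation over all distinct
pairs.  Significance of a single correlation under the no-coupling null uses
Bartlett's variance estimate, Var[r_ij] = (1/T) sum_tau rho_i(tau) rho_j(tau),
with the sample autocorrelations rho taken from the biased (1/T) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import GridGraph, Neighborhood

__all__ = [
    "Field",
    "CorrelationCache",
    "zero_lag_correlation",
    "local_homogeneity",
    "set_homogeneity",
    "pairwise_correlation_sum",
    "bartlett_variance_zero_lag",
    "estimate_delta",
]

VARIANCE_FLOOR = 1e-12


class Field:
    """A T x n matrix of per-cell time series.

    Parameters
    ----------
    series : array (T, n)
        One column per grid cell, one row per time sample.
    mask : bool array (n,), optional
        Cells flagged invalid.  Zero-variance cells must be masked; with
        ``auto_mask=True`` they are masked automatically.
    """

    def __init__(self, series, mask=None, auto_mask=False):
        series = np.asarray(series, dtype=float)
        if series.ndim != 2:
            raise ValueError("series must be a 2-D (T, n) array")
        self.series = series
        self.T, self.n_cells = series.shape
        if mask is None:
            mask = np.zeros(self.n_cells, dtype=bool)
        self.mask = np.asarray(mask, dtype=bool).copy()
        if np.any(~np.isfinite(series[:, ~self.mask])):
            raise ValueError("unmasked cells contain missing samples")
        self.mean = series.mean(axis=0)
        self.std = series.std(axis=0)  # population (1/T) convention
        degenerate = (self.std <= 0) & ~self.mask
        if degenerate.any():
            if auto_mask:
                self.mask |= degenerate
            else:
                raise ValueError(
                    f"{degenerate.sum()} unmasked cells have zero variance; "
                    "mask them or pass auto_mask=True"
                )
        self._U = None
        self._acf = None

    @property
    def U(self) -> np.ndarray:
        """(n, T) matrix with rows u_i = (x_i - mu_i) / (sigma_i sqrt(T)).

        Zero-lag correlations are then plain dot products, r_ij = u_i . u_j,
        which is what makes incremental homogeneity updates cheap.
        """
        if self._U is None:
            std = np.where(self.std > 0, self.std, 1.0)
            U = (self.series - self.mean).T / (std[:, None] * np.sqrt(self.T))
            self._U = np.ascontiguousarray(U)
        return self._U

    def autocorrelation(self, i: int) -> np.ndarray:
        """Biased sample autocorrelation of cell ``i`` at lags 0..T-1."""
        if self._acf is None:
            self._acf = {}
        if i not in self._acf:
            self._acf[i] = sample_autocorrelation(self.series[:, i])
        return self._acf[i]


def sample_autocorrelation(x: np.ndarray) -> np.ndarray:
    """Biased (1/T normalised) sample autocorrelation, lags 0..T-1, via FFT."""
    x = np.asarray(x, dtype=float)
    T = x.size
    xc = x - x.mean()
    nfft = 1 << (2 * T - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:T] / T
    if acov[0] <= 0:
        raise ValueError("zero-variance series")
    return acov / acov[0]


class CorrelationCache:
    """Lazy, memoized pairwise zero-lag correlations of a field."""

    def __init__(self, field: Field):
        self.field = field
        self._memo = {}

    def corr(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        key = (i, j) if i < j else (j, i)
        if key not in self._memo:
            U = self.field.U
            self._memo[key] = float(np.clip(U[key[0]] @ U[key[1]], -1.0, 1.0))
        return self._memo[key]

    def __len__(self):
        return len(self._memo)


def zero_lag_correlation(f: Field, i: int, j: int) -> float:
    """Pearson correlation at zero lag between cells ``i`` and ``j``."""
    for c in (i, j):
        if f.mask[c]:
            raise ValueError(f"cell {c} is masked")
        if f.std[c] <= 0:
            raise ValueError(f"cell {c} has zero variance")
    if i == j:
        return 1.0
    return float(np.clip(f.U[i] @ f.U[j], -1.0, 1.0))


def pairwise_correlation_sum(f: Field, cells) -> float:
    """Sum of zero-lag correlations over all unordered distinct pairs.

    Uses the identity sum_{i<j} u_i.u_j = (||sum u_i||^2 - m) / 2 for
    unit-norm rows of :attr:`Field.U`.
    """
    idx = np.fromiter(cells, dtype=int)
    s = f.U[idx].sum(axis=0)
    return float((s @ s - idx.size) / 2.0)


def set_homogeneity(f: Field, A) -> float:
    """Mean pairwise zero-lag correlation over all distinct cells of ``A``."""
    A = list(A)
    m = len(A)
    if m < 2:
        raise ValueError("set homogeneity requires at least two cells")
    return pairwise_correlation_sum(f, A) / (m * (m - 1) / 2.0)


def local_homogeneity(f: Field, nb: Neighborhood) -> float:
    """Mean pairwise correlation among the K+1 cells of a neighborhood."""
    if len(nb.members) < 2:
        raise ValueError("neighborhood must have at least two members")
    return set_homogeneity(f, nb.members)


def bartlett_variance_zero_lag(f: Field, i: int, j: int) -> float:
    """Bartlett estimate of Var[r_ij] under the no-coupling null.

    (1/T) * sum over lags |tau| <= T-2 of rho_i(tau) rho_j(tau), with biased
    sample autocorrelations; floored at a small positive constant.
    """
    T = f.T
    if T < 8:
        raise ValueError("series too short for Bartlett variance")
    ai = f.autocorrelation(i)
    aj = f.autocorrelation(j)
    s = 1.0 + 2.0 * float(ai[1 : T - 1] @ aj[1 : T - 1])
    return max(s / T, VARIANCE_FLOOR)


def estimate_delta(
    f: Field,
    g: GridGraph,
    alpha: float = 1e-2,
    n_pairs: int = 10_000,
    rng_seed=None,
) -> float:
    """Estimate the homogeneity threshold from significant sampled correlations.

    Samples ``n_pairs`` random unmasked cell pairs, z-scores each correlation
    with its Bartlett variance, keeps the pairs passing a one-sided z-test at
    level ``alpha`` (positive tail), and returns the mean of the surviving
    correlations.

    Raises
    ------
    ValueError
        If no pair is significant (signal-free field); supply delta directly.
    """
    if n_pairs < 100:
        raise ValueError("n_pairs must be >= 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    valid = g.unmasked if g is not None else np.flatnonzero(~f.mask)
    if valid.size < 2:
        raise ValueError("need at least two unmasked cells")
    ii = rng.choice(valid, size=n_pairs)
    jj = rng.choice(valid, size=n_pairs)
    bad = ii == jj
    while bad.any():  # resample self-pairs
        jj[bad] = rng.choice(valid, size=int(bad.sum()))
        bad = ii == jj
    U = f.U
    r = np.clip(np.einsum("ij,ij->i", U[ii], U[jj]), -1.0, 1.0)
    var = np.array([bartlett_variance_zero_lag(f, int(a), int(b)) for a, b in zip(ii, jj)])
    z = r / np.sqrt(var)
    z_crit = stats.norm.ppf(1 - alpha)
    keep = z > z_crit
    if not keep.any():
        raise ValueError(
            "no sampled correlation is significant; the field looks signal-free "
            "-- supply delta explicitly"
        )
    return float(r[keep].mean())
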