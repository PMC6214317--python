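"""Readers/writers for gridded inputs, anomaly preprocessing, pipeline glue.

NetCDF input follows CF conventions (time/lat/lon dimensions); cells with any
missing sample are masked (e.g. land in an SST field), longitude wraps, and
cell weights are cos(latitude).  Climate-style anomaly preprocessing removes
the seasonal cycle (per-phase means), the long-term trend (Theil-Sen line per
cell) and re-centers each series.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridGraph, build_latlon_grid, build_regular_grid
from .field import Field

logger = logging.getLogger("deltamaps")

__all__ = [
    "RunConfig",
    "read_gridded_netcdf",
    "write_field_netcdf",
    "read_field_matrix",
    "compute_anomalies",
    "write_domain_map_csv",
    "write_edge_list_csv",
    "write_network_json",
    "run_pipeline",
]

_LAT_NAMES = ("lat", "latitude", "y")
_LON_NAMES = ("lon", "longitude", "x")
_TIME_NAMES = ("time", "t")


def _find_dim(ds, names):
    for n in names:
        if n in ds.dims:
            return n
    raise ValueError(f"none of the dimensions {names} present in the file")


def read_gridded_netcdf(path, variable=None, lat_bounds=None):
    """Read a CF-style lat-lon NetCDF cube into ``(GridGraph, Field)``.

    Rows are serialized north to south, cells row-major and 0-based.  Cells
    with any missing sample are masked and removed from all neighborhoods.
    ``lat_bounds=(lo, hi)`` clips the latitude band before building the grid.
    """
    import xarray as xr

    ds = xr.open_dataset(path)
    tdim = _find_dim(ds, _TIME_NAMES)
    latdim = _find_dim(ds, _LAT_NAMES)
    londim = _find_dim(ds, _LON_NAMES)
    if variable is None:
        cands = [v for v in ds.data_vars if set(ds[v].dims) >= {tdim, latdim, londim}]
        if len(cands) != 1:
            raise ValueError(f"cannot pick a variable automatically from {list(ds.data_vars)}")
        variable = cands[0]
    da = ds[variable].transpose(tdim, latdim, londim)
    if lat_bounds is not None:
        lo, hi = sorted(lat_bounds)
        da = da.sel({latdim: (da[latdim] >= lo) & (da[latdim] <= hi)})
    # north-to-south serialization
    if float(da[latdim][0]) < float(da[latdim][-1]):
        da = da.isel({latdim: slice(None, None, -1)})
    lats = np.asarray(da[latdim], dtype=float)
    lons = np.asarray(da[londim], dtype=float)
    values = np.asarray(da, dtype=float).reshape(da.shape[0], -1)
    mask = ~np.isfinite(values).all(axis=0)
    if mask.all():
        raise ValueError("every cell is masked")
    values = values.copy()
    values[:, mask] = 0.0  # placeholder; masked cells are never used
    grid = build_latlon_grid(lats, lons, mask=mask)
    field = Field(values, mask=mask, auto_mask=True)
    return grid, field


def write_field_netcdf(path, field: Field, lats, lons, variable="field"):
    """Write a (T, n) field back to a CF-style NetCDF3 file."""
    import xarray as xr

    T = field.T
    data = field.series.reshape(T, len(lats), len(lons)).copy()
    data[:, field.mask.reshape(len(lats), len(lons))] = np.nan
    ds = xr.Dataset(
        {variable: (("time", "lat", "lon"), data)},
        coords={"time": np.arange(T), "lat": np.asarray(lats), "lon": np.asarray(lons)},
    )
    ds.to_netcdf(path, format="NETCDF3_CLASSIC")


def read_field_matrix(path, rows=None, cols=None, connectivity=4, wrap_columns=False):
    """Read a plain T x n matrix (.npy, .csv or .tsv) plus a lattice shape."""
    path = Path(path)
    if path.suffix == ".npy":
        series = np.load(path)
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        series = pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float)
    n = series.shape[1]
    if rows is None or cols is None:
        raise ValueError("lattice shape (rows, cols) is required for matrix input")
    if rows * cols != n:
        raise ValueError(f"matrix has {n} columns but rows*cols = {rows * cols}")
    grid = build_regular_grid(rows, cols, connectivity=connectivity,
                              wrap_columns=wrap_columns)
    return grid, Field(series, auto_mask=True)


def compute_anomalies(f: Field, period: int) -> Field:
    """Seasonal-cycle removal, Theil-Sen detrending and centering per cell.

    The per-phase mean (phase = t mod period) is removed first, then the
    Theil-Sen line (median of pairwise slopes; robust to outliers), then the
    series is re-centered.  Masked cells pass through untouched.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if f.T < 2 * period:
        raise ValueError("need at least two full cycles")
    X = f.series.copy()
    t = np.arange(f.T, dtype=float)
    phases = (np.arange(f.T) % period)
    for i in range(f.n_cells):
        if f.mask[i]:
            continue
        x = X[:, i]
        for ph in range(period):
            sel = phases == ph
            x[sel] -= x[sel].mean()
        slope, intercept, *_ = stats.theilslopes(x, t)
        x -= slope * t + intercept
        x -= x.mean()
    return Field(X, mask=f.mask, auto_mask=True)


def write_domain_map_csv(ds, path):
    """Per-cell domain labels: cell_id, semicolon-joined domain ids."""
    mem = ds.cell_membership
    rows = [
        {"cell_id": c, "domain_ids": ";".join(map(str, mem[c]))}
        for c in sorted(mem)
    ]
    pd.DataFrame(rows, columns=["cell_id", "domain_ids"]).to_csv(path, index=False)


def write_edge_list_csv(net, path):
    cols = ["domainA", "domainB", "r_star", "tau_star", "lag_lo", "lag_hi",
            "weight", "direction", "n_significant_lags"]
    rows = [
        {
            "domainA": e.a, "domainB": e.b,
            "r_star": round(e.r_star, 10), "tau_star": e.tau_star,
            "lag_lo": e.lag_min, "lag_hi": e.lag_max,
            "weight": round(e.weight, 10), "direction": e.direction,
            "n_significant_lags": len(e.significant_lags),
        }
        for e in net.edges
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_network_json(net, path):
    Path(path).write_text(net.to_json())


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one of delta/alpha is set."""

    input_path: str | None = None
    input_format: str = "netcdf"      # netcdf | matrix
    variable: str | None = None
    lat_bounds: tuple | None = None
    rows: int | None = None
    cols: int | None = None
    k: int = 4
    delta: float | None = None
    alpha: float | None = None
    tau_max: int = 12
    q: float = 0.05
    signal_mode: str = "cumulative"
    metric: str = "euclidean"
    anomaly_period: int | None = None
    output_dir: str = "deltamaps-output"
    rng_seed: int | None = None

    def validate(self):
        if (self.delta is None) == (self.alpha is None):
            raise ValueError("exactly one of delta / alpha must be set")
        if self.tau_max < 1:
            raise ValueError("tau_max must be >= 1")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        return self


def run_pipeline(cfg: RunConfig):
    """read -> (anomalies) -> delta -> domains -> network -> files on disk.

    Writes domain_map.csv, edges.csv, network.json and run_info.json into
    ``cfg.output_dir`` and returns ``(DomainSet, FunctionalNetwork)``.
    """
    from .field import estimate_delta
    from .domains import identify_domains
    from .network import infer_network

    cfg.validate()
    if cfg.input_format == "netcdf":
        grid, field = read_gridded_netcdf(cfg.input_path, cfg.variable, cfg.lat_bounds)
        metric = "geodesic" if cfg.metric == "euclidean" and grid.geographic else cfg.metric
    else:
        grid, field = read_field_matrix(cfg.input_path, cfg.rows, cfg.cols)
        metric = cfg.metric
    if cfg.anomaly_period:
        field = compute_anomalies(field, cfg.anomaly_period)
    if cfg.delta is not None:
        delta = cfg.delta
    else:
        delta = estimate_delta(field, grid, alpha=cfg.alpha, rng_seed=cfg.rng_seed)
    logger.info("delta = %.4f", delta)
    ds = identify_domains(field, grid, K=cfg.k, delta=delta, metric=metric)
    logger.info("%d domains identified", len(ds))
    net = infer_network(field, ds, tau_max=cfg.tau_max, q=cfg.q,
                        mode=cfg.signal_mode, cell_weight=grid.cell_weight)
    logger.info("%d edges inferred", len(net.edges))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_domain_map_csv(ds, out / "domain_map.csv")
    write_edge_list_csv(net, out / "edges.csv")
    write_network_json(net, out / "network.json")
    info = dataclasses.asdict(cfg)
    info.update({"delta_used": delta, "n_domains": len(ds),
                 "n_edges": len(net.edges),
                 "n_seeds": len({s for d in ds.domains for s in d.seeds})})
    (out / "run_info.json").write_text(json.dumps(info, default=str, indent=2))
    return ds, net
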