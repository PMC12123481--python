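"""From annual trap-catch points to per-transect spread rates.

Annual point catches are thresholded into occupancy indicators,
interpolated to a 1-km probability surface by ordinary indicator
kriging (exponential variogram, WLS fit, no nugget) or inverse-distance
weighting, intersected with a fan of fixed-origin radial transects at
the P = 0.5 level to locate the range edge, and differenced across
years into radial spread rates.  Climate values are extracted as means
over circular buffers sized by each region's mean annual displacement.

All geometry is planar, in km; bearings are degrees clockwise from
north.  Latitude/longitude inputs should be projected beforehand (see
:func:`project_lonlat`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .fields import SpatioTemporalField

__all__ = [
    "TRAP_COLUMNS",
    "DensitySurface",
    "ClimateRaster",
    "TransectFan",
    "VariogramModel",
    "IndicatorModel",
    "validate_traps",
    "project_lonlat",
    "mask_treatments",
    "fit_indicator_model",
    "fit_indicator_surface",
    "transect_crossings",
    "spread_rates",
    "buffer_mean",
    "region_buffer_diameter",
]

log = logging.getLogger(__name__)

TRAP_COLUMNS = ["year", "x_km", "y_km", "catch", "treated"]

EARTH_RADIUS_KM = 6371.0088


def project_lonlat(lon, lat, origin_lon: float, origin_lat: float):
    """Local equirectangular projection about a fan origin, in km."""
    lat0 = np.deg2rad(origin_lat)
    x = np.deg2rad(np.asarray(lon) - origin_lon) * EARTH_RADIUS_KM * np.cos(lat0)
    y = np.deg2rad(np.asarray(lat) - origin_lat) * EARTH_RADIUS_KM
    return x, y


def validate_traps(traps: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAP_COLUMNS if c not in traps.columns]
    if missing:
        raise ValueError(f"trap table missing columns {missing}")
    if not np.isfinite(traps["catch"]).all() or (traps["catch"] < 0).any():
        raise ValueError("catches must be finite and non-negative")
    dup = traps.duplicated(subset=["year", "x_km", "y_km"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (x, y) trap records within a year")
    return traps


@dataclass
class DensitySurface:
    """Occupancy-probability grid P(catch >= threshold) at 1-km cells.

    ``x0, y0`` are the coordinates of the first cell's center; masked
    cells are NaN.
    """

    p: np.ndarray  # (ny, nx)
    x0: float
    y0: float
    cell_km: float
    year: int
    threshold_catch: float

    @property
    def x_coords(self) -> np.ndarray:
        return self.x0 + np.arange(self.p.shape[1]) * self.cell_km

    @property
    def y_coords(self) -> np.ndarray:
        return self.y0 + np.arange(self.p.shape[0]) * self.cell_km


@dataclass
class ClimateRaster:
    values: np.ndarray  # (ny, nx)
    x0: float
    y0: float
    cell_km: float

    @property
    def x_coords(self) -> np.ndarray:
        return self.x0 + np.arange(self.values.shape[1]) * self.cell_km

    @property
    def y_coords(self) -> np.ndarray:
        return self.y0 + np.arange(self.values.shape[0]) * self.cell_km


@dataclass
class TransectFan:
    """Radial transects at a fixed angular step from a common origin."""

    origin: tuple[float, float]
    bearings: np.ndarray  # degrees clockwise from north, strictly increasing
    regions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bearings = np.asarray(self.bearings, dtype=float)
        steps = np.diff(self.bearings)
        if len(self.bearings) > 1:
            if not (steps > 0).all():
                raise ValueError("bearings must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ValueError("bearing step must be constant")
        if self.regions is not None:
            self.regions = np.asarray(self.regions)
            if len(self.regions) != len(self.bearings):
                raise ValueError("regions must align with bearings")

    def directions(self) -> np.ndarray:
        """Unit vectors (dx, dy) per bearing (clockwise from north)."""
        rad = np.deg2rad(self.bearings)
        return np.column_stack([np.sin(rad), np.cos(rad)])


def mask_treatments(
    traps: pd.DataFrame, treatment_sites: np.ndarray, radius: float = 1.5
) -> pd.DataFrame:
    """Drop trap records within ``radius`` km (closed ball) of any
    suppression-treatment site."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    sites = np.atleast_2d(np.asarray(treatment_sites, dtype=float))
    if sites.size == 0:
        return traps
    tree = cKDTree(sites)
    pts = traps[["x_km", "y_km"]].to_numpy(dtype=float)
    d, _ = tree.query(pts, k=1)
    keep = d > radius
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("mask_treatments: removed %d of %d traps", n_removed, len(traps))
    out = traps.loc[keep]
    if out.empty:
        raise ValueError("all traps fall within treatment buffers; year unusable")
    return out


@dataclass
class VariogramModel:
    """Exponential variogram gamma(h) = sill * (1 - exp(-h / range))."""

    sill: float
    range_km: float

    def gamma(self, h: np.ndarray) -> np.ndarray:
        return self.sill * (1.0 - np.exp(-np.asarray(h) / self.range_km))

    def cov(self, h: np.ndarray) -> np.ndarray:
        return self.sill * np.exp(-np.asarray(h) / self.range_km)


def _fit_variogram(xy: np.ndarray, z: np.ndarray, n_bins: int = 12, max_pairs: int = 2000):
    """Empirical variogram + WLS exponential fit (no nugget)."""
    n = len(xy)
    if n > max_pairs:
        idx = np.linspace(0, n - 1, max_pairs).astype(int)
        xy, z = xy[idx], z[idx]
    d = pdist(xy)
    dz = 0.5 * pdist(z[:, None], metric="sqeuclidean")
    dmax = d.max() / 2.0
    edges = np.linspace(0, dmax, n_bins + 1)
    h_mid, gam, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d > lo) & (d <= hi)
        if sel.sum() > 0:
            h_mid.append(d[sel].mean())
            gam.append(dz[sel].mean())
            counts.append(sel.sum())
    h_mid, gam, counts = map(np.asarray, (h_mid, gam, counts))
    sill0 = max(float(np.var(z)), 1e-3)
    range0 = max(float(np.median(d)), 1e-3)
    w = np.sqrt(counts / np.maximum(h_mid, 1e-6) ** 2)

    def resid(p):
        return w * (gam - VariogramModel(p[0], p[1]).gamma(h_mid))

    res = optimize.least_squares(
        resid,
        x0=[sill0, range0],
        bounds=([1e-6, 1e-3], [10.0, 10.0 * max(range0, dmax)]),
    )
    return VariogramModel(float(res.x[0]), float(res.x[1]))


@dataclass
class IndicatorModel:
    """Fitted interpolator for threshold-exceedance probabilities."""

    xy: np.ndarray
    indicator: np.ndarray
    threshold_catch: float
    method: str
    variogram: VariogramModel | None = None
    n_neighbors: int = 16
    _tree: cKDTree = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._tree = cKDTree(self.xy)

    def predict(self, points: np.ndarray) -> np.ndarray:
        """P(catch >= threshold) at arbitrary planar points, in [0, 1]."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(self.n_neighbors, len(self.xy))
        dist, idx = self._tree.query(pts, k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        if self.method == "idw":
            w = 1.0 / np.maximum(dist, 1e-12) ** 2
            exact = dist[:, 0] < 1e-9
            p = (w * self.indicator[idx]).sum(axis=1) / w.sum(axis=1)
            p[exact] = self.indicator[idx[exact, 0]]
        else:
            p = self._krige(pts, dist, idx)
        return np.clip(p, 0.0, 1.0)

    def _krige(self, pts, dist, idx):
        vg = self.variogram
        m, k = idx.shape
        nb_xy = self.xy[idx]  # (m, k, 2)
        diff = nb_xy[:, :, None, :] - nb_xy[:, None, :, :]
        h = np.sqrt((diff**2).sum(axis=-1))  # (m, k, k)
        A = np.empty((m, k + 1, k + 1))
        A[:, :k, :k] = vg.cov(h)
        # tiny jitter keeps nearly-coincident neighbourhoods solvable
        A[:, :k, :k] += 1e-10 * vg.sill * np.eye(k)
        A[:, :k, k] = 1.0
        A[:, k, :k] = 1.0
        A[:, k, k] = 0.0
        b = np.empty((m, k + 1))
        b[:, :k] = vg.cov(dist)
        b[:, k] = 1.0
        lam = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        return (lam[:, :k] * self.indicator[idx]).sum(axis=1)


def fit_indicator_model(
    traps: pd.DataFrame,
    threshold_catch: float = 10.0,
    method: str = "kriging",
    n_neighbors: int = 16,
) -> IndicatorModel:
    """Threshold the catches and fit the spatial interpolator.

    Requires at least 10 usable traps and both indicator classes: an
    all-occupied or all-unoccupied year has no estimable range edge and
    is a degenerate-surface error.
    """
    validate_traps(traps)
    if len(traps) < 10:
        raise ValueError(f"need >= 10 usable traps, got {len(traps)}")
    if method not in ("kriging", "idw"):
        raise ValueError(f"unknown interpolation method {method!r}")
    xy = traps[["x_km", "y_km"]].to_numpy(dtype=float)
    ind = (traps["catch"].to_numpy(dtype=float) >= threshold_catch).astype(float)
    if ind.min() == ind.max():
        state = "occupied" if ind[0] == 1 else "unoccupied"
        raise ValueError(
            f"degenerate surface: all traps {state} at threshold {threshold_catch}; "
            "treat the region as fully occupied/unoccupied instead of interpolating"
        )
    vg = _fit_variogram(xy, ind) if method == "kriging" else None
    return IndicatorModel(
        xy=xy,
        indicator=ind,
        threshold_catch=threshold_catch,
        method=method,
        variogram=vg,
        n_neighbors=n_neighbors,
    )


def fit_indicator_surface(
    traps: pd.DataFrame,
    threshold_catch: float = 10.0,
    cell_km: float = 1.0,
    method: str = "kriging",
    bbox: tuple[float, float, float, float] | None = None,
    max_trap_dist: float | None = None,
    n_neighbors: int = 16,
) -> DensitySurface:
    """Interpolate the occupancy indicator to a regular grid.

    ``bbox`` is (xmin, ymin, xmax, ymax); defaults to the trap extent
    padded by two cells.  Cells farther than ``max_trap_dist`` from any
    trap are masked (NaN).
    """
    model = fit_indicator_model(
        traps, threshold_catch=threshold_catch, method=method, n_neighbors=n_neighbors
    )
    xy = model.xy
    if bbox is None:
        pad = 2 * cell_km
        bbox = (
            xy[:, 0].min() - pad,
            xy[:, 1].min() - pad,
            xy[:, 0].max() + pad,
            xy[:, 1].max() + pad,
        )
    xmin, ymin, xmax, ymax = bbox
    xs = np.arange(xmin, xmax + cell_km / 2, cell_km)
    ys = np.arange(ymin, ymax + cell_km / 2, cell_km)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    p = model.predict(pts)
    if max_trap_dist is not None:
        d, _ = model._tree.query(pts, k=1)
        p[d > max_trap_dist] = np.nan
    year = int(traps["year"].iloc[0]) if len(traps) else 0
    return DensitySurface(
        p=p.reshape(len(ys), len(xs)),
        x0=float(xs[0]),
        y0=float(ys[0]),
        cell_km=cell_km,
        year=year,
        threshold_catch=threshold_catch,
    )


def transect_crossings(
    surface: DensitySurface,
    fan: TransectFan,
    level: float = 0.5,
    step_km: float = 0.25,
) -> pd.DataFrame:
    """Locate, per bearing, the outermost down-crossing of ``level``.

    The surface is sampled bilinearly along each ray at ``step_km``;
    the crossing is the outermost transition from P >= level to
    P < level, refined by linear interpolation between the bracketing
    samples.  A bearing is flagged missing when no transition exists or
    the ray leaves the surface while still at P >= level.
    """
    interp = RegularGridInterpolator(
        (surface.y_coords, surface.x_coords),
        surface.p,
        bounds_error=False,
        fill_value=np.nan,
    )
    ox, oy = fan.origin
    corners = [
        (surface.x_coords[j] - ox, surface.y_coords[i] - oy)
        for i in (0, -1)
        for j in (0, -1)
    ]
    r_max = max(np.hypot(cx, cy) for cx, cy in corners)
    r = np.arange(step_km, r_max + step_km, step_km)
    rows = []
    for bearing, (dx, dy) in zip(fan.bearings, fan.directions()):
        pts = np.column_stack([oy + r * dy, ox + r * dx])
        v = interp(pts)
        finite = np.isfinite(v)
        dist, is_missing = np.nan, True
        if finite.any():
            last = np.flatnonzero(finite)[-1]
            down = finite[:-1] & finite[1:] & (v[:-1] >= level) & (v[1:] < level)
            trans = np.flatnonzero(down)
            if len(trans) and not v[last] >= level:
                if len(trans) > 1:
                    log.info(
                        "bearing %.2f: %d level transitions; using outermost",
                        bearing,
                        len(trans),
                    )
                i = trans[-1]
                frac = (v[i] - level) / (v[i] - v[i + 1])
                dist = float(r[i] + frac * step_km)
                is_missing = False
        rows.append(
            {
                "bearing": float(bearing),
                "year": surface.year,
                "distance_km": dist,
                "missing": is_missing,
            }
        )
    return pd.DataFrame(rows)


def spread_rates(crossings: pd.DataFrame, regions=None) -> SpatioTemporalField:
    """Difference consecutive-year crossings into km/yr spread rates.

    Column t holds d(t+1) - d(t); negative values are contractions and
    entries with either crossing missing are NaN.
    """
    df = crossings.copy()
    df.loc[df["missing"].astype(bool), "distance_km"] = np.nan
    mat = df.pivot_table(
        index="bearing", columns="year", values="distance_km", dropna=False
    ).sort_index(axis=1)
    if mat.shape[1] < 2:
        raise ValueError("need crossings for at least 2 years")
    vals = mat.to_numpy(dtype=float)
    rates = vals[:, 1:] - vals[:, :-1]
    return SpatioTemporalField(
        values=rates,
        locations=mat.index.to_numpy(),
        years=mat.columns.to_numpy()[:-1],
        regions=None if regions is None else np.asarray(regions),
        name="spread",
    )


def buffer_mean(
    raster: ClimateRaster, center: tuple[float, float], diameter: float
) -> tuple[float, int]:
    """Mean of raster cells whose centers fall in the closed disc of the
    given diameter; returns (mean, number of contributing cells)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    cx, cy = center
    gx, gy = np.meshgrid(raster.x_coords, raster.y_coords)
    inside = np.hypot(gx - cx, gy - cy) <= diameter / 2.0
    vals = raster.values[inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("buffer contains no raster cells")
    return float(vals.mean()), int(vals.size)


def region_buffer_diameter(
    displacement: SpatioTemporalField, region=None, mode: str = "signed"
) -> float:
    """Buffer diameter for a region: mean over its transects and years
    of annual displacement (signed by default; 'absolute' optional)."""
    f = displacement if region is None else displacement.for_region(region)
    vals = f.values
    if mode == "absolute":
        vals = np.abs(vals)
    elif mode != "signed":
        raise ValueError(f"unknown mode {mode!r}")
    if not np.isfinite(vals).any():
        raise ValueError("region has no displacement data")
    return float(np.nanmean(vals))
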