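"""Series normalisation: rectangularise, Box-Cox, detrend, standardise.

Every series entering a wavelet computation is first made strictly
positive by an additive shift, power-transformed with a per-series
profile-likelihood Box-Cox lambda, linearly detrended against the year
index, demeaned and scaled to unit variance.  Rectangularisation removes
short series and sparse years instead of imputing gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .fields import SpatioTemporalField

__all__ = [
    "CleanParams",
    "RectangularizeReport",
    "rectangularize",
    "boxcox_transform",
    "clean_series",
    "clean_field",
]

log = logging.getLogger(__name__)

_LAMBDA_RANGE = (-5.0, 5.0)
_GRID_STEP = 0.01


@dataclass
class CleanParams:
    """Per-series normalisation parameters, sufficient to replay the
    transform exactly.  Standardisation uses the unbiased (n-1) variance
    estimator."""

    lmbda: float
    shift: float
    slope: float
    intercept: float
    scale: float


@dataclass
class RectangularizeReport:
    dropped_short_locations: list
    dropped_sparse_years: list
    dropped_incomplete_locations: list


def rectangularize(
    field: SpatioTemporalField,
    min_years: int = 20,
    min_locations: int = 10,
) -> tuple[SpatioTemporalField, RectangularizeReport]:
    """Reduce to a complete locations x years matrix.

    In order: (1) drop locations observed in fewer than ``min_years``
    years; (2) drop years observed at fewer than ``min_locations`` of
    the remaining locations; (3) drop locations still missing any
    retained year.  Raises if any rule empties the field.
    """
    if field.values.size == 0:
        raise ValueError("empty field")
    present = np.isfinite(field.values)

    keep_loc = present.sum(axis=1) >= min_years
    dropped_short = list(field.locations[~keep_loc])
    if not keep_loc.any():
        raise ValueError(
            f"no location has >= {min_years} years of data (rule 1 emptied the field)"
        )
    f1 = field.subset_locations(keep_loc)
    present = present[keep_loc]

    keep_year = present.sum(axis=0) >= min_locations
    dropped_years = list(f1.years[~keep_year])
    if not keep_year.any():
        raise ValueError(
            f"no year has >= {min_locations} locations (rule 2 emptied the field)"
        )
    f2 = f1.subset_years(keep_year)
    present = present[:, keep_year]

    complete = present.all(axis=1)
    dropped_incomplete = list(f2.locations[~complete])
    if not complete.any():
        raise ValueError(
            "no location is complete over the retained years (rule 3 emptied the field)"
        )
    out = f2.subset_locations(complete)
    assert out.is_complete()
    report = RectangularizeReport(dropped_short, dropped_years, dropped_incomplete)
    if dropped_short or dropped_years or dropped_incomplete:
        log.info(
            "rectangularize: dropped %d short locations, %d sparse years, "
            "%d incomplete locations",
            len(dropped_short),
            len(dropped_years),
            len(dropped_incomplete),
        )
    return out, report


def _boxcox(x: np.ndarray, lmbda: float) -> np.ndarray:
    if lmbda == 0.0:
        return np.log(x)
    return (x**lmbda - 1.0) / lmbda


def _boxcox_llf_grid(lmbdas: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of the Box-Cox parameter, vectorised over
    a lambda grid: (lmbda - 1) sum(ln x) - n/2 ln(var(y(lmbda)))."""
    lx = np.log(x)
    n = len(x)
    lam = np.asarray(lmbdas, dtype=float)[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        y = np.where(lam == 0.0, lx[None, :], (np.exp(lam * lx[None, :]) - 1.0) / np.where(lam == 0.0, 1.0, lam))
        var = y.var(axis=1)
        ll = np.where(var > 0, (lam[:, 0] - 1.0) * lx.sum() - 0.5 * n * np.log(var), -np.inf)
    ll[~np.isfinite(ll)] = -np.inf
    return ll


def boxcox_transform(
    series: np.ndarray, lmbda: float | None = None
) -> tuple[np.ndarray, CleanParams]:
    """Shift to strict positivity, then Box-Cox with profile-ML lambda.

    Shift c = 1 - min(series) when min <= 0 (shifted minimum exactly 1),
    else 0.  Lambda maximises the Box-Cox log-likelihood over [-5, 5]
    via a 0.01 grid followed by local refinement, unless given.
    """
    x = np.asarray(series, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("series contains missing values; rectangularize first")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no variance to normalize")
    mn = x.min()
    shift = 1.0 - mn if mn <= 0 else 0.0
    xs = x + shift
    if lmbda is None:
        lo, hi = _LAMBDA_RANGE
        grid = np.arange(lo, hi + _GRID_STEP, _GRID_STEP)
        ll = _boxcox_llf_grid(grid, xs)
        best = grid[int(np.argmax(ll))]
        res = optimize.minimize_scalar(
            lambda l: -_boxcox_llf_grid(np.array([l]), xs)[0],
            bounds=(max(lo, best - _GRID_STEP), min(hi, best + _GRID_STEP)),
            method="bounded",
        )
        lmbda = float(res.x)
    y = _boxcox(xs, lmbda)
    params = CleanParams(lmbda=lmbda, shift=shift, slope=0.0, intercept=0.0, scale=1.0)
    return y, params


def clean_series(
    series: np.ndarray, lmbda: float | None = None, label=""
) -> tuple[np.ndarray, CleanParams]:
    """Box-Cox -> OLS linear detrend on year index -> demean -> unit
    variance, in that order."""
    x = np.asarray(series, dtype=float)
    t = np.arange(len(x), dtype=float)
    # a series that is exactly linear in time carries nothing but trend
    if len(x) >= 2:
        res_lin = x - np.polyval(np.polyfit(t, x, 1), t)
        if np.ptp(x) > 0 and float(res_lin @ res_lin) <= 1e-12 * float(np.var(x)) * len(x):
            raise ValueError(f"series {label!r} is a pure linear ramp; detrending removes everything")
    y, params = boxcox_transform(x, lmbda=lmbda)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    resid -= resid.mean()
    scale = resid.std(ddof=1)
    if scale <= 1e-12:
        raise ValueError(f"series {label!r} has no variance after detrending")
    out = resid / scale
    return out, replace(
        params, slope=float(slope), intercept=float(intercept), scale=float(scale)
    )


def clean_field(
    field: SpatioTemporalField, lmbda: float | None = None
) -> tuple[SpatioTemporalField, list[CleanParams]]:
    """Apply :func:`clean_series` to each location of a complete field."""
    if not field.is_complete():
        raise ValueError("field has missing entries; rectangularize first")
    out = np.empty_like(field.values)
    params: list[CleanParams] = []
    for i, loc in enumerate(field.locations):
        out[i], p = clean_series(field.values[i], lmbda=lmbda, label=loc)
        params.append(p)
    return replace(field, values=out), params
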