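"""Synthetic invasion-front worlds with known ground truth.

Two modes.  The direct-series mode emits per-transect spread-rate and
climate matrices built from a shared oscillatory driver (sinusoids plus
AR(1) noise) with configurable coupling, lag and idiosyncratic noise.
The spatial mode additionally pushes a logistic density front outward
along a fan of transects and draws negative-binomial trap catches on a
regular grid covering a transition-zone band around the front, plus
per-year climate rasters, so the whole geometry stage can be exercised
against known truth.

No observation model for trap catches is published for the study
system; the negative-binomial choice here is a configurable stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clean import clean_field
from .coherence import LONG_BAND, SHORT_BAND, Band
from .fields import SpatioTemporalField
from .geometry import ClimateRaster, TransectFan
from .moran import moran_decompose

__all__ = [
    "DriverSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_driver",
    "simulate_series_bundle",
    "simulate_trap_world",
]


@dataclass(frozen=True)
class DriverSpec:
    """Shared oscillatory driver: sum of sinusoids plus AR(1) noise.

    components: (period_years, amplitude, phase_radians) triples.
    Periods below 2 years are not resolvable at annual sampling.
    """

    components: tuple = ((5.0, 1.0, 0.0),)
    ar1_phi: float = 0.0
    ar1_sigma: float = 0.0

    def __post_init__(self) -> None:
        for period, amp, _ in self.components:
            if period < 2.0:
                raise ValueError(
                    f"driver period {period} yr is below the 2-yr Nyquist limit "
                    "for annual sampling"
                )
            if amp < 0:
                raise ValueError("amplitudes must be non-negative")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        if self.ar1_sigma < 0:
            raise ValueError("ar1_sigma must be non-negative")

    def deterministic(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for period, amp, phase in self.components:
            out += amp * np.sin(2.0 * np.pi * t / period + phase)
        return out


@dataclass
class SimulationConfig:
    n_years: int = 31
    n_transects: int = 36
    bearing_start: float = 0.0
    bearing_step: float = 0.5
    base_spread_mu: float = 5.0
    coupling_b: float = 1.0
    climate_lag: float = 0.0
    idio_sigma_spread: float = 0.5
    idio_sigma_climate: float = 0.5
    trap_spacing: float = 2.0
    front_width_w: float = 3.0
    carrying_K: float = 300.0
    nb_dispersion: float = 1.0
    transition_zone_width: float = 170.0
    front_start_km: float = 120.0
    domain_max_km: float = 500.0
    climate_cell_km: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 20:
            raise ValueError(
                "n_years must be >= 20 (shorter series are rejected by the "
                "length filter downstream)"
            )
        if self.trap_spacing <= 0:
            raise ValueError("trap_spacing must be positive")
        for name in ("idio_sigma_spread", "idio_sigma_climate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    @property
    def bearings(self) -> np.ndarray:
        return self.bearing_start + self.bearing_step * np.arange(self.n_transects)


@dataclass
class TruthRecord:
    """Ground truth for recovery tests.

    ``true_front_distance`` has one more column than ``true_spread``:
    spread[i, t] = front[i, t + 1] - front[i, t] exactly.
    ``true_pct_explained`` holds, per band label, the percent synchrony
    explained computed by the Moran decomposition applied to the
    noise-free construction (a documented reference value, not an
    external truth).
    """

    driver_series: np.ndarray
    true_front_distance: np.ndarray  # (n_transects, T+1)
    true_spread: np.ndarray  # (n_transects, T)
    true_pct_explained: dict | None = None


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) draw of length n."""
    x = np.empty(n)
    if sigma == 0:
        x[:] = 0.0
        return x
    x[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - phi**2))
    eps = rng.normal(0.0, sigma, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def simulate_driver(spec: DriverSpec, n_years: int, seed: int | None = None) -> np.ndarray:
    """Driver series: sum of sinusoids plus stationary AR(1) noise."""
    if n_years < 4:
        raise ValueError("n_years must be >= 4")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years)
    return spec.deterministic(t) + _ar1(rng, n_years, spec.ar1_phi, spec.ar1_sigma)


def _lagged_driver(
    spec: DriverSpec, n_years: int, lag: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Driver at t and at t - lag (fractional lags allowed).

    Sinusoidal components are evaluated exactly at the shifted times;
    the AR(1) part is linearly interpolated on an extended sample.
    """
    t = np.arange(n_years, dtype=float)
    back = int(np.ceil(max(lag, 0.0)))
    fwd = int(np.ceil(max(-lag, 0.0)))
    ar_t = np.arange(-back, n_years + fwd, dtype=float)
    ar = _ar1(rng, len(ar_t), spec.ar1_phi, spec.ar1_sigma)
    driver = spec.deterministic(t) + np.interp(t, ar_t, ar)
    lagged = spec.deterministic(t - lag) + np.interp(t - lag, ar_t, ar)
    return driver, lagged


def _noise_free_pct(
    spec: DriverSpec,
    config: SimulationConfig,
    driver: np.ndarray,
    lagged: np.ndarray,
    bands: Sequence[Band] = (SHORT_BAND, LONG_BAND),
) -> dict | None:
    """Moran percent-explained on the noise-free construction."""
    if config.coupling_b == 0:
        return None
    spread0 = config.base_spread_mu + config.coupling_b * driver
    n = 2  # rows are identical, so percentages do not depend on n
    years = np.arange(config.n_years)
    sp = SpatioTemporalField(np.tile(spread0, (n, 1)), np.arange(n), years)
    cl = SpatioTemporalField(np.tile(lagged, (n, 1)), np.arange(n), years)
    try:
        sp_c, _ = clean_field(sp)
        cl_c, _ = clean_field(cl)
        return {
            band.label: moran_decompose(sp_c, cl_c, band).pct_explained
            for band in bands
        }
    except ValueError:
        return None


def simulate_series_bundle(
    config: SimulationConfig, spec: DriverSpec
) -> tuple[SpatioTemporalField, SpatioTemporalField, TruthRecord]:
    """Direct-series mode: per-transect spread and climate matrices.

    spread[i, t] = mu + b * driver(t) + eta_i(t); climate[i, t] =
    driver(t - lag) + xi_i(t), all noise iid Normal.
    """
    root = np.random.SeedSequence(config.seed)
    rng_driver, rng_spread, rng_climate = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    driver, lagged = _lagged_driver(spec, config.n_years, config.climate_lag, rng_driver)
    n, T = config.n_transects, config.n_years
    spread = (
        config.base_spread_mu
        + config.coupling_b * driver[None, :]
        + rng_spread.normal(0.0, config.idio_sigma_spread, size=(n, T))
    )
    climate = lagged[None, :] + rng_climate.normal(
        0.0, config.idio_sigma_climate, size=(n, T)
    )
    years = np.arange(T)
    bearings = config.bearings
    spread_f = SpatioTemporalField(spread, bearings, years, name="spread")
    climate_f = SpatioTemporalField(climate, bearings, years, name="climate")
    front = config.front_start_km + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(spread, axis=1)], axis=1
    )
    truth = TruthRecord(
        driver_series=driver,
        true_front_distance=front,
        true_spread=spread.copy(),
        true_pct_explained=_noise_free_pct(spec, config, driver, lagged),
    )
    return spread_f, climate_f, truth


def _front_profile(d: np.ndarray, f: float, w: float, K: float) -> np.ndarray:
    """Expected density at distance d for front position f (logistic in
    distance; w = 0 degenerates to a step)."""
    if w <= 0:
        return np.where(d < f, K, 0.0)
    z = np.clip((d - f) / w, -500, 500)
    return K / (1.0 + np.exp(z))


def _draw_catches(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.maximum(mean, 0.0)
    if not np.isfinite(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + np.maximum(mean, 1e-300))
    out = rng.negative_binomial(dispersion, p)
    out[mean == 0] = 0
    return out


def simulate_trap_world(
    config: SimulationConfig, spec: DriverSpec
) -> tuple[list[pd.DataFrame], list[ClimateRaster], TruthRecord, TransectFan]:
    """Spatial mode: yearly trap tables and climate rasters.

    The true front along bearing theta integrates the same spread-rate
    process as the series mode; expected trap density is logistic in
    distance from the origin, sampled on a trap grid restricted to a
    transition-zone band around the front.
    """
    root = np.random.SeedSequence(config.seed)
    rng_driver, rng_spread, rng_catch, rng_climate = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    driver, lagged = _lagged_driver(spec, config.n_years, config.climate_lag, rng_driver)
    n, T = config.n_transects, config.n_years
    rates = (
        config.base_spread_mu
        + config.coupling_b * driver[None, : T - 1]
        + rng_spread.normal(0.0, config.idio_sigma_spread, size=(n, T - 1))
    )
    front = config.front_start_km + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(rates, axis=1)], axis=1
    )  # (n, T)
    half = config.transition_zone_width / 2.0
    for t in range(T):
        if front[:, t].max() + half > config.domain_max_km:
            raise ValueError(
                f"front exits the simulated domain (max {config.domain_max_km} km) "
                f"in year {t}"
            )
        if front[:, t].min() - half < 2.0 * config.trap_spacing:
            raise ValueError(f"front too close to the fan origin in year {t}")

    bearings = config.bearings
    fan = TransectFan(origin=(0.0, 0.0), bearings=bearings)

    # one global trap grid; each year keeps the band around that year's front
    margin = np.rad2deg(config.trap_spacing / max(config.front_start_km, 1.0))
    b_lo = bearings[0] - config.bearing_step / 2 - margin
    b_hi = bearings[-1] + config.bearing_step / 2 + margin
    d_lo = front.min() - half
    d_hi = front.max() + half
    rad = np.deg2rad(np.array([b_lo, b_hi]))
    xs_all = np.sort(np.concatenate([d_hi * np.sin(rad), d_lo * np.sin(rad), [0.0]]))
    ys_all = np.sort(np.concatenate([d_hi * np.cos(rad), d_lo * np.cos(rad)]))
    gx = np.arange(xs_all[0] - 1, xs_all[-1] + 1 + config.trap_spacing, config.trap_spacing)
    gy = np.arange(ys_all[0] - 1, ys_all[-1] + 1 + config.trap_spacing, config.trap_spacing)
    GX, GY = np.meshgrid(gx, gy)
    px, py = GX.ravel(), GY.ravel()
    pd_dist = np.hypot(px, py)
    pb = np.rad2deg(np.arctan2(px, py))
    in_fan = (pb >= b_lo) & (pb <= b_hi) & (pd_dist > 0)
    px, py, pd_dist, pb = px[in_fan], py[in_fan], pd_dist[in_fan], pb[in_fan]

    traps: list[pd.DataFrame] = []
    rasters: list[ClimateRaster] = []
    cell = config.climate_cell_km
    cx = np.arange(gx[0], gx[-1] + cell, cell)
    cy = np.arange(gy[0], gy[-1] + cell, cell)
    for t in range(T):
        f_at = np.interp(pb, bearings, front[:, t])
        in_band = np.abs(pd_dist - f_at) <= half
        d, f = pd_dist[in_band], f_at[in_band]
        mean = _front_profile(d, f, config.front_width_w, config.carrying_K)
        catch = _draw_catches(rng_catch, mean, config.nb_dispersion)
        traps.append(
            pd.DataFrame(
                {
                    "year": t,
                    "x_km": px[in_band],
                    "y_km": py[in_band],
                    "catch": catch.astype(float),
                    "treated": 0,
                }
            )
        )
        vals = lagged[t] + rng_climate.normal(
            0.0, config.idio_sigma_climate, size=(len(cy), len(cx))
        )
        rasters.append(
            ClimateRaster(values=vals, x0=float(cx[0]), y0=float(cy[0]), cell_km=cell)
        )

    truth = TruthRecord(
        driver_series=driver,
        true_front_distance=front,
        true_spread=rates,
        true_pct_explained=_noise_free_pct(spec, config, driver, lagged),
    )
    return traps, rasters, truth, fan
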