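"""Morlet continuous wavelet transforms and synchrony mean fields.

The transform is computed by direct summation of the sampled mother
wavelet (annual series are short, so there is no need for FFT-based
convolution), on a geometric grid of timescales.  Two cross-location
summaries are provided: the wavelet mean field (WMF), which averages
power-normalised transforms and responds to both phase alignment and
correlated magnitudes, and the wavelet phasor mean field (WPMF), which
averages unit phasors and measures pure phase synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "ScaleGrid",
    "WaveletField",
    "MeanField",
    "morlet_cwt",
    "cwt_many",
    "normalize_power",
    "wmf",
    "wpmf",
    "wpmf_threshold",
]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class ScaleGrid:
    """Geometric grid of Morlet timescales (annual sampling).

    ``s_min`` must be at least 2 years: shorter periods are not
    resolvable at an annual sampling step (Nyquist).
    """

    s_min: float = 2.0
    s_max: float = 16.0
    step: float = 1.05
    omega0: float = 6.0

    def __post_init__(self) -> None:
        if self.s_min < 2.0:
            raise ValueError(
                "s_min < 2 years violates the Nyquist limit for annual sampling"
            )
        if self.s_max < self.s_min:
            raise ValueError("s_max must be >= s_min")
        if self.step <= 1.0:
            raise ValueError("step must exceed 1 (geometric spacing)")

    @classmethod
    def for_length(cls, n_years: int, **kw) -> "ScaleGrid":
        """Default grid for a series of ``n_years``: scales 2 .. T/2."""
        return cls(s_max=max(2.0, n_years / 2.0), **kw)

    @property
    def scales(self) -> np.ndarray:
        n = int(np.floor(np.log(self.s_max / self.s_min) / np.log(self.step))) + 1
        s = self.s_min * self.step ** np.arange(n)
        return s

    @property
    def fourier_factor(self) -> float:
        """Period / scale ratio for the Morlet wavelet."""
        w0 = self.omega0
        return 4.0 * np.pi / (w0 + np.sqrt(2.0 + w0 * w0))

    @property
    def periods(self) -> np.ndarray:
        return self.scales * self.fourier_factor


@dataclass
class WaveletField:
    """Complex wavelet coefficients, locations x times x timescales.

    ``coi`` is True where a (time, timescale) cell lies inside the cone
    of influence (boundary-affected); such cells are excluded from all
    averages downstream.
    """

    coeffs: np.ndarray  # (n_loc, T, S) complex
    coi: np.ndarray  # (T, S) bool, True = masked
    grid: ScaleGrid
    years: np.ndarray | None = None
    locations: np.ndarray | None = None

    @property
    def n_locations(self) -> int:
        return self.coeffs.shape[0]

    @property
    def scales(self) -> np.ndarray:
        return self.grid.scales

    @property
    def periods(self) -> np.ndarray:
        return self.grid.periods


@dataclass
class MeanField:
    """Times x timescales complex mean field (kind: "wmf" or "wpmf")."""

    values: np.ndarray  # (T, S) complex
    coi: np.ndarray  # (T, S) bool
    grid: ScaleGrid
    kind: str
    n_locations: int
    years: np.ndarray | None = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def timescale_average(self) -> np.ndarray:
        """Time-averaged magnitude per timescale over unmasked cells
        (NaN at timescales lying entirely inside the cone of influence)."""
        mag = np.where(self.coi, 0.0, np.abs(self.values))
        count = (~self.coi).sum(axis=0)
        out = np.full(self.values.shape[1], np.nan)
        nz = count > 0
        out[nz] = mag.sum(axis=0)[nz] / count[nz]
        return out


@lru_cache(maxsize=16)
def _kernel(n_years: int, grid: ScaleGrid) -> np.ndarray:
    """Direct-summation kernel K[u, t, s] with W[t,s] = sum_u x[u] K[u,t,s]."""
    t = np.arange(n_years)
    eta = (t[:, None, None] - t[None, :, None]) / grid.scales[None, None, :]
    psi = np.pi ** -0.25 * np.exp(1j * grid.omega0 * eta) * np.exp(-0.5 * eta**2)
    # W(t,s) = s^{-1/2} sum_u x(u) psi*((u - t)/s)
    return np.conj(psi) / np.sqrt(grid.scales)[None, None, :]


def coi_mask(n_years: int, grid: ScaleGrid) -> np.ndarray:
    """Cone-of-influence mask: True within sqrt(2)*s of either boundary."""
    t = np.arange(n_years)
    edge = np.minimum(t, n_years - 1 - t)
    return edge[:, None] < _SQRT2 * grid.scales[None, :]


def cwt_many(
    x: np.ndarray,
    grid: ScaleGrid,
    years: np.ndarray | None = None,
    locations: np.ndarray | None = None,
) -> WaveletField:
    """Morlet CWT of one or many series (rows of ``x``), vectorised."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    T = x.shape[1]
    if grid.s_max > T:
        grid = replace(grid, s_max=float(T))
    K = _kernel(T, grid)  # (T_u, T_t, S)
    W = np.tensordot(x, K, axes=([1], [0]))  # (n_loc, T, S)
    return WaveletField(
        coeffs=W, coi=coi_mask(T, grid), grid=grid, years=years, locations=locations
    )


def morlet_cwt(series: np.ndarray, grid: ScaleGrid | None = None) -> WaveletField:
    """Morlet CWT of a single cleaned annual series."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D; use cwt_many for a field")
    if grid is None:
        grid = ScaleGrid.for_length(len(series))
    return cwt_many(series[None, :], grid)


def normalize_power(wf: WaveletField, mode: str = "per_timescale") -> WaveletField:
    """Normalise transform magnitudes so mean fields land on a 0..1 scale.

    per_timescale: each (location, timescale) is scaled to unit time-mean
    squared magnitude over non-COI times (used for mean fields).
    global: one scale factor per location, from the mean squared
    magnitude over all non-COI cells (used for coherence/regression so
    relative power across timescales is retained).
    """
    valid = ~wf.coi  # (T, S)
    power = np.abs(wf.coeffs) ** 2
    if mode == "per_timescale":
        n_valid = valid.sum(axis=0)  # (S,)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.where(
                n_valid > 0,
                (power * valid[None, :, :]).sum(axis=1) / n_valid[None, :],
                np.nan,
            )  # (n_loc, S)
        if np.any((denom == 0) & (n_valid > 0)):
            loc, s = np.argwhere((denom == 0) & (n_valid > 0))[0]
            raise ValueError(
                f"zero wavelet power at location index {loc}, timescale index {s}"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            out = wf.coeffs / np.sqrt(denom)[:, None, :]
    elif mode == "global":
        n_valid = valid.sum()
        denom = (power * valid[None, :, :]).sum(axis=(1, 2)) / n_valid  # (n_loc,)
        if np.any(denom == 0):
            loc = int(np.argwhere(denom == 0)[0])
            raise ValueError(f"zero wavelet power at location index {loc}")
        out = wf.coeffs / np.sqrt(denom)[:, None, None]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(wf, coeffs=out)


def wmf(wf: WaveletField) -> MeanField:
    """Wavelet mean field: location-average of per-timescale-normalised
    transforms.  Per-timescale time-averaged magnitude is bounded by 1."""
    if wf.n_locations < 2:
        raise ValueError("mean field requires at least 2 locations")
    norm = normalize_power(wf, mode="per_timescale")
    vals = norm.coeffs.mean(axis=0)
    coi = wf.coi | ~np.isfinite(vals)
    return MeanField(
        values=vals,
        coi=coi,
        grid=wf.grid,
        kind="wmf",
        n_locations=wf.n_locations,
        years=wf.years,
    )


def wpmf(wf: WaveletField) -> MeanField:
    """Wavelet phasor mean field: location-average of unit phasors.

    Cells where any location has an exactly zero coefficient are masked
    rather than errored.
    """
    if wf.n_locations < 2:
        raise ValueError("mean field requires at least 2 locations")
    mod = np.abs(wf.coeffs)
    zero = (mod == 0).any(axis=0)  # (T, S)
    with np.errstate(invalid="ignore", divide="ignore"):
        phasors = np.where(mod > 0, wf.coeffs / np.where(mod > 0, mod, 1.0), 0.0)
    vals = phasors.mean(axis=0)
    return MeanField(
        values=vals,
        coi=wf.coi | zero,
        grid=wf.grid,
        kind="wpmf",
        n_locations=wf.n_locations,
        years=wf.years,
    )


def wpmf_threshold(
    n: int, p: float = 0.001, n_draws: int = 10000, seed: int | None = None
) -> float:
    """Monte-Carlo (1-p) quantile of |mean of n iid uniform unit phasors|.

    Used as the significance contour level for WPMF magnitude plots.
    Asymptotically sqrt(-ln(p)/n); the finite-n quantile is slightly
    below that.  Draws are chunked so large ``n_draws`` stay in memory.
    """
    if n < 2:
        raise ValueError("need at least 2 locations")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    chunk = max(1, min(n_draws, 4_000_000 // n))
    mags = np.empty(n_draws)
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(m, n))
        mags[done : done + m] = np.abs(np.exp(1j * theta).mean(axis=1))
        done += m
    return float(np.quantile(mags, 1.0 - p))
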