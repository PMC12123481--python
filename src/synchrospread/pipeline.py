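"""End-to-end orchestration: geometry -> clean -> synchrony -> coherence
-> Moran, emitting tidy result tables.

Regions are analysed independently.  For each (response, predictor,
band) combination a surrogate coherence test is run; combinations
passing the coherence threshold get a Moran decomposition, and the
predictors entering those rows are further tested for band coherence
with teleconnection index series.  Every random draw derives
deterministically from the configured seed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clean import clean_field, rectangularize
from .coherence import LONG_BAND, SHORT_BAND, Band, band_test, index_band_coherence
from .fields import SpatioTemporalField
from .geometry import (
    TransectFan,
    buffer_mean,
    fit_indicator_surface,
    mask_treatments,
    region_buffer_diameter,
    spread_rates,
    transect_crossings,
)
from .moran import moran_decompose
from .wavelet import ScaleGrid, cwt_many, wmf, wpmf, wpmf_threshold

__all__ = [
    "RegionSpec",
    "AnalysisConfig",
    "AnalysisInputs",
    "AnalysisResult",
    "seasonal_index_means",
    "align_fields",
    "traps_to_spread",
    "extract_climate_series",
    "run_analysis",
]

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "region",
    "band",
    "response",
    "predictor",
    "p",
    "mean_phase",
    "pct_synchrony_explained",
    "cross_term",
    "significant",
]


@dataclass(frozen=True)
class RegionSpec:
    label: str
    bearing_lo: float
    bearing_hi: float  # inclusive


@dataclass
class AnalysisConfig:
    regions: list[RegionSpec] | None = None
    bands: list[Band] = dfield(default_factory=lambda: [SHORT_BAND, LONG_BAND])
    threshold_catch: float = 10.0
    n_surrog: int = 2000
    alpha_coherence: float = 0.1
    alpha_wpmf: float = 0.001
    min_years: int = 20
    min_locations: int = 10
    bh_correction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_coherence", "alpha_wpmf"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        regions = None
        if "regions" in raw:
            regions = [
                RegionSpec(r["label"], float(r["bearing_lo"]), float(r["bearing_hi"]))
                for r in raw.pop("regions")
            ]
        bands = None
        if "bands" in raw:
            bands = [
                Band(b["label"], float(b["lower"]), float(b.get("upper", np.inf)))
                for b in raw.pop("bands")
            ]
        cfg = cls(regions=regions, **raw)
        if bands is not None:
            cfg.bands = bands
        return cfg


@dataclass
class AnalysisInputs:
    spread: SpatioTemporalField
    climate: dict[str, SpatioTemporalField]
    indices: dict[str, pd.DataFrame] = dfield(default_factory=dict)
    index_window: str = "winter"
    larval_windows: pd.DataFrame | None = None


@dataclass
class AnalysisResult:
    table: pd.DataFrame  # coherence + Moran rows (Table-1-shaped)
    index_table: pd.DataFrame  # climate vs teleconnection rows (Table-2-shaped)
    mean_fields: dict  # region -> {"wmf", "wpmf", "wpmf_threshold"}


def _derived_seed(seed: int, *parts) -> int:
    tag = "|".join(str(p) for p in parts)
    return (seed * 1_000_003 + zlib.crc32(tag.encode())) % 2**31


def seasonal_index_means(
    index: pd.DataFrame,
    years: np.ndarray,
    window: str = "winter",
    larval_windows: pd.DataFrame | None = None,
    region: str | None = None,
) -> np.ndarray:
    """Annual seasonal means of a monthly index series.

    winter: the value for analysis year t averages Dec(t-1), Jan(t),
    Feb(t) — the winter preceding that year's trapping season.
    larval: averages the months overlapping the supplied per-region,
    per-year larval date range (month granularity).
    """
    lut = {(int(y), int(m)): v for y, m, v in zip(index["year"], index["month"], index["value"])}
    out = np.empty(len(years))
    for i, y in enumerate(np.asarray(years, dtype=int)):
        if window == "winter":
            keys = [(y - 1, 12), (y, 1), (y, 2)]
        elif window == "larval":
            if larval_windows is None:
                raise ValueError("larval window requires larval_windows input")
            sel = larval_windows[larval_windows["year"] == y]
            if region is not None and "region" in sel.columns:
                sel = sel[sel["region"] == region]
            if sel.empty:
                raise ValueError(f"no larval window for year {y} (region {region!r})")
            start = pd.Timestamp(sel["start_date"].iloc[0])
            end = pd.Timestamp(sel["end_date"].iloc[0])
            months = pd.period_range(start, end, freq="M")
            keys = [(p.year, p.month) for p in months]
        else:
            raise ValueError(f"unknown window {window!r}")
        missing = [k for k in keys if k not in lut]
        if missing:
            raise ValueError(f"index series missing months {missing}")
        out[i] = np.mean([lut[k] for k in keys])
    return out


def align_fields(
    a: SpatioTemporalField, b: SpatioTemporalField
) -> tuple[SpatioTemporalField, SpatioTemporalField]:
    """Restrict two fields to their shared locations and years."""
    locs = [l for l in a.locations if l in set(b.locations)]
    yrs = [y for y in a.years if y in set(b.years)]
    am = np.isin(a.locations, locs)
    bm = np.isin(b.locations, locs)
    a2 = a.subset_locations(am).subset_years(np.isin(a.years, yrs))
    b2 = b.subset_locations(bm).subset_years(np.isin(b.years, yrs))
    # ensure identical ordering
    order_a = np.argsort(a2.locations)
    order_b = np.argsort(b2.locations)
    a2 = a2.subset_locations(order_a)
    b2 = b2.subset_locations(order_b)
    if list(a2.locations) != list(b2.locations) or list(a2.years) != list(b2.years):
        raise ValueError("fields could not be aligned")
    return a2, b2


def traps_to_spread(
    trap_tables: list[pd.DataFrame],
    fan: TransectFan,
    threshold_catch: float = 10.0,
    treatment_sites: np.ndarray | None = None,
    treatment_radius: float = 1.5,
    method: str = "kriging",
    cell_km: float = 1.0,
    max_trap_dist: float | None = 8.0,
    regions: np.ndarray | None = None,
) -> tuple[pd.DataFrame, SpatioTemporalField]:
    """Geometry stage: trap tables -> crossings -> spread-rate field."""
    crossings = []
    for traps in trap_tables:
        if treatment_sites is not None and len(treatment_sites):
            traps = mask_treatments(traps, treatment_sites, radius=treatment_radius)
        surface = fit_indicator_surface(
            traps,
            threshold_catch=threshold_catch,
            cell_km=cell_km,
            method=method,
            max_trap_dist=max_trap_dist,
        )
        crossings.append(transect_crossings(surface, fan))
    crossings = pd.concat(crossings, ignore_index=True)
    field = spread_rates(crossings, regions=regions)
    return crossings, field


def extract_climate_series(
    rasters: list,
    crossings: pd.DataFrame,
    diameter: float,
    name: str = "climate",
    regions: np.ndarray | None = None,
) -> SpatioTemporalField:
    """Buffer-average yearly rasters at each year's crossing points.

    The buffer for year t (used with the t -> t+1 displacement) is
    centered on the year-t crossing of each transect.
    """
    years = sorted(crossings["year"].unique())[:-1]
    bearings = np.sort(crossings["bearing"].unique())
    vals = np.full((len(bearings), len(years)), np.nan)
    by_key = crossings.set_index(["bearing", "year"])
    for j, yr in enumerate(years):
        raster = rasters[j]
        for i, b in enumerate(bearings):
            row = by_key.loc[(b, yr)]
            if bool(row["missing"]):
                continue
            d = float(row["distance_km"])
            rad = np.deg2rad(b)
            center = (d * np.sin(rad), d * np.cos(rad))
            try:
                vals[i, j], _ = buffer_mean(raster, center, diameter)
            except ValueError:
                pass
    return SpatioTemporalField(
        vals, bearings, np.asarray(years), regions=regions, name=name
    )


def _region_fields(field: SpatioTemporalField, config: AnalysisConfig):
    """Split a field into labelled per-region subfields."""
    if config.regions:
        for spec in config.regions:
            bearings = field.locations.astype(float)
            mask = (bearings >= spec.bearing_lo) & (bearings <= spec.bearing_hi)
            if mask.any():
                yield spec.label, field.subset_locations(mask)
    elif field.regions is not None:
        for label in pd.unique(field.regions):
            yield label, field.for_region(label)
    else:
        yield "all", field


def run_analysis(config: AnalysisConfig, inputs: AnalysisInputs) -> AnalysisResult:
    """Run the full analysis; deterministic given config and inputs."""
    rows, index_rows, mean_fields = [], [], {}
    for label, spread_region in _region_fields(inputs.spread, config):
        try:
            spread_rect, _ = rectangularize(
                spread_region, config.min_years, config.min_locations
            )
        except ValueError as err:
            log.warning("region %s skipped: %s", label, err)
            continue
        spread_clean, _ = clean_field(spread_rect)
        grid = ScaleGrid.for_length(spread_clean.n_years)
        wf = cwt_many(
            spread_clean.values, grid, years=spread_clean.years,
            locations=spread_clean.locations,
        )
        thresh = wpmf_threshold(
            spread_clean.n_locations,
            p=config.alpha_wpmf,
            seed=_derived_seed(config.seed, label, "wpmf"),
        )
        mean_fields[label] = {
            "wmf": wmf(wf),
            "wpmf": wpmf(wf),
            "wpmf_threshold": thresh,
        }

        significant_predictors = set()
        for var, clim in inputs.climate.items():
            try:
                clim_region = clim.for_region(label) if clim.regions is not None else clim
                clim_rect, _ = rectangularize(
                    clim_region, config.min_years, config.min_locations
                )
                sp_al, cl_al = align_fields(spread_rect, clim_rect)
                sp_c, _ = clean_field(sp_al)
                cl_c, _ = clean_field(cl_al)
            except ValueError as err:
                log.warning("region %s predictor %s skipped: %s", label, var, err)
                continue
            for band in config.bands:
                seed = _derived_seed(config.seed, label, var, band.label)
                res = band_test(sp_c, cl_c, band, n_surrog=config.n_surrog, seed=seed)
                sig = res.p_value is not None and res.p_value < config.alpha_coherence
                pct_exp = pct_cross = np.nan
                if sig:
                    dec = moran_decompose(sp_c, cl_c, band)
                    pct_exp, pct_cross = dec.pct_explained, dec.pct_cross
                    significant_predictors.add((var, band.label))
                rows.append(
                    {
                        "region": label,
                        "band": band.label,
                        "response": "spread",
                        "predictor": var,
                        "p": res.p_value,
                        "mean_phase": res.theta_bar,
                        "pct_synchrony_explained": pct_exp,
                        "cross_term": pct_cross,
                        "significant": sig,
                    }
                )
            # teleconnection tests for predictors with a significant band
            for var_band in [vb for vb in significant_predictors if vb[0] == var]:
                _, band_label = var_band
                band = next(b for b in config.bands if b.label == band_label)
                for idx_name, idx_df in inputs.indices.items():
                    try:
                        series = seasonal_index_means(
                            idx_df,
                            cl_c.years,
                            window=inputs.index_window,
                            larval_windows=inputs.larval_windows,
                            region=label,
                        )
                    except ValueError as err:
                        log.warning("index %s skipped: %s", idx_name, err)
                        continue
                    seed = _derived_seed(config.seed, label, var, band.label, idx_name)
                    ires = index_band_coherence(
                        cl_c, series, band, n_surrog=config.n_surrog, seed=seed
                    )
                    isig = ires.p_value is not None and ires.p_value < config.alpha_coherence
                    index_rows.append(
                        {
                            "region": label,
                            "predictor": idx_name,
                            "response": var,
                            "band": band.label,
                            "p": ires.p_value,
                            "mean_phase": ires.theta_bar if isig else np.nan,
                            "significant": isig,
                        }
                    )

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if config.bh_correction and len(table):
        table = _apply_bh(table, config.alpha_coherence)
    index_table = pd.DataFrame(
        index_rows,
        columns=["region", "predictor", "response", "band", "p", "mean_phase", "significant"],
    )
    return AnalysisResult(table=table, index_table=index_table, mean_fields=mean_fields)


def _apply_bh(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Optional Benjamini-Hochberg adjustment of the significance flags."""
    p = table["p"].to_numpy(dtype=float)
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    sig = np.zeros(m, dtype=bool)
    sig[order[:k]] = True
    out = table.copy()
    out["significant"] = sig
    return out
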