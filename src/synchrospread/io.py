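"""Plain-text readers/writers for the pipeline's file formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TRAP_COLUMNS, ClimateRaster, validate_traps
from .wavelet import MeanField, ScaleGrid

__all__ = [
    "read_traps",
    "write_traps",
    "read_raster",
    "write_raster",
    "read_index_series",
    "write_mean_field",
    "read_mean_field",
]


def read_traps(path) -> pd.DataFrame:
    """Trap CSV with columns year, x_km, y_km, catch, treated(0/1)."""
    df = pd.read_csv(path)
    return validate_traps(df)


def write_traps(df: pd.DataFrame, path) -> None:
    validate_traps(df)[TRAP_COLUMNS].to_csv(path, index=False)


def write_raster(raster: ClimateRaster, path) -> None:
    """Text grid: one header line 'nx ny cell_km x0 y0', then ny rows."""
    ny, nx = raster.values.shape
    with open(path, "w") as fh:
        fh.write(f"{nx} {ny} {raster.cell_km} {raster.x0} {raster.y0}\n")
        np.savetxt(fh, raster.values, fmt="%.6g")


def read_raster(path) -> ClimateRaster:
    with open(path) as fh:
        nx, ny, cell, x0, y0 = fh.readline().split()
        vals = np.loadtxt(fh)
    vals = vals.reshape(int(ny), int(nx))
    return ClimateRaster(values=vals, x0=float(x0), y0=float(y0), cell_km=float(cell))


def read_index_series(path) -> pd.DataFrame:
    """Monthly teleconnection index CSV: year, month, value."""
    df = pd.read_csv(path)
    for col in ("year", "month", "value"):
        if col not in df.columns:
            raise ValueError(f"index series missing column {col!r}")
    return df


def write_mean_field(mf: MeanField, path) -> None:
    """Self-describing array file (.npz + JSON attributes)."""
    attrs = {
        "kind": mf.kind,
        "n_locations": mf.n_locations,
        "s_min": mf.grid.s_min,
        "s_max": mf.grid.s_max,
        "step": mf.grid.step,
        "omega0": mf.grid.omega0,
    }
    np.savez(
        path,
        values=mf.values,
        coi=mf.coi,
        years=mf.years if mf.years is not None else np.arange(mf.values.shape[0]),
        attrs=np.array(json.dumps(attrs)),
    )


def read_mean_field(path) -> MeanField:
    with np.load(path, allow_pickle=False) as z:
        attrs = json.loads(str(z["attrs"]))
        grid = ScaleGrid(
            s_min=attrs["s_min"],
            s_max=attrs["s_max"],
            step=attrs["step"],
            omega0=attrs["omega0"],
        )
        return MeanField(
            values=z["values"],
            coi=z["coi"],
            grid=grid,
            kind=attrs["kind"],
            n_locations=attrs["n_locations"],
            years=z["years"],
        )
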