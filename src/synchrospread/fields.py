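"""Location x year data matrices shared by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SpatioTemporalField"]


@dataclass
class SpatioTemporalField:
    """A locations x years real matrix with location/year metadata.

    Missing entries are NaN.  ``locations`` are arbitrary hashable ids
    (bearings in degrees for spread-rate fields); ``regions`` optionally
    labels each location with an ecoregion.
    """

    values: np.ndarray
    locations: np.ndarray
    years: np.ndarray
    regions: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.locations = np.asarray(self.locations)
        self.years = np.asarray(self.years)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D locations x years matrix")
        if self.values.shape != (len(self.locations), len(self.years)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.locations)} locations x {len(self.years)} years"
            )
        if self.regions is not None:
            self.regions = np.asarray(self.regions)
            if len(self.regions) != len(self.locations):
                raise ValueError("regions must align with locations")

    @property
    def n_locations(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def subset_locations(self, mask: np.ndarray) -> "SpatioTemporalField":
        mask = np.asarray(mask)
        return replace(
            self,
            values=self.values[mask],
            locations=self.locations[mask],
            regions=None if self.regions is None else self.regions[mask],
        )

    def subset_years(self, mask: np.ndarray) -> "SpatioTemporalField":
        mask = np.asarray(mask)
        return replace(self, values=self.values[:, mask], years=self.years[mask])

    def for_region(self, label) -> "SpatioTemporalField":
        if self.regions is None:
            raise ValueError("field carries no region labels")
        return self.subset_locations(self.regions == label)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.locations, columns=self.years)
        df.index.name = "location"
        df.columns.name = "year"
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        regions: Sequence | None = None,
        name: str = "",
    ) -> "SpatioTemporalField":
        return cls(
            values=df.to_numpy(dtype=float),
            locations=df.index.to_numpy(),
            years=df.columns.to_numpy(),
            regions=None if regions is None else np.asarray(regions),
            name=name,
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        if self.regions is not None:
            df.insert(0, "region", self.regions)
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, name: str = "") -> "SpatioTemporalField":
        df = pd.read_csv(path, index_col=0)
        regions = None
        if "region" in df.columns:
            regions = df.pop("region").to_numpy()
        df.columns = df.columns.astype(float).astype(int)
        return cls.from_frame(df, regions=regions, name=name)
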