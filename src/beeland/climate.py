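"""Monthly climate series on a coarse grid, with period conventions.

``tmin``/``tmax`` hold monthly minimum/maximum temperature (°C) per coarse
cell, year and calendar month, spanning 1901-2015 by default.  Two named
periods follow the thermal-niche workflow: a *baseline* (1901-1975, before the
onset of rapid warming) and a *recent* period (2000-2014).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ClimateSeries", "BASELINE_PERIOD", "RECENT_PERIOD", "ClimateError"]

BASELINE_PERIOD = (1901, 1975)
RECENT_PERIOD = (2000, 2014)


class ClimateError(ValueError):
    pass


@dataclass(frozen=True)
class ClimateSeries:
    """Per-cell monthly min/max temperature series.

    Arrays are shaped ``(n_cells, n_years, 12)``; ``cell_x``/``cell_y`` are
    cell-centre coordinates (km) shared with the land-use history grid.
    """

    years: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    cell_x: np.ndarray
    cell_y: np.ndarray

    def __post_init__(self) -> None:
        if self.tmin.shape != self.tmax.shape or self.tmin.ndim != 3:
            raise ClimateError("tmin/tmax must share a (cells, years, 12) shape")
        if self.tmin.shape[2] != 12:
            raise ClimateError("expected 12 monthly values per year")
        if self.tmin.shape[1] != len(self.years):
            raise ClimateError("year axis mismatch")
        if np.any(self.tmax < self.tmin):
            raise ClimateError("monthly maximum below monthly minimum")

    @property
    def n_cells(self) -> int:
        return self.tmin.shape[0]

    def nearest_cell(self, x, y) -> np.ndarray:
        """Index of the nearest cell centre for each point."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        d2 = (x[:, None] - self.cell_x[None, :]) ** 2 + (y[:, None] - self.cell_y[None, :]) ** 2
        return np.argmin(d2, axis=1)

    def year_mask(self, period: tuple[int, int]) -> np.ndarray:
        lo, hi = period
        if lo > hi:
            raise ClimateError(f"empty climate period {period}")
        mask = (self.years >= lo) & (self.years <= hi)
        if not mask.any():
            raise ClimateError(f"climate series does not cover period {period}")
        return mask

    def to_frame(self) -> pd.DataFrame:
        cells, years, months = np.meshgrid(
            np.arange(self.n_cells), self.years, np.arange(1, 13), indexing="ij"
        )
        return pd.DataFrame(
            {
                "cell_id": cells.ravel(),
                "year": years.ravel(),
                "month": months.ravel(),
                "tmin": self.tmin.ravel(),
                "tmax": self.tmax.ravel(),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
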