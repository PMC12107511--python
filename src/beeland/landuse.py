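"""Land-use history reconstructions and the landscape-modification-duration metric.

A history is, per coarse (0.5°-analogue) cell, an ordered series of
(year, fraction) pairs giving the fraction of the cell under human-modified
land uses (croplands + pastures + urban).  The covariate derived from it is
the number of years, at a reference year, since the human fraction first
reached a threshold; a cell that never reaches the threshold has a
substantial-modification duration of zero years.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LandUseHistory", "modification_duration", "HistoryError"]


class HistoryError(ValueError):
    pass


@dataclass(frozen=True)
class LandUseHistory:
    """Human-modified land-use fraction through time for a set of coarse cells.

    ``human_fraction[c, t]`` is the fraction of cell ``c`` under croplands,
    pastures or urban areas in ``years[t]``; series are piecewise-constant
    between time steps (step reconstructions, not interpolated).
    """

    years: np.ndarray              # (T,), strictly increasing
    human_fraction: np.ndarray     # (n_cells, T) in [0, 1]
    cell_x: np.ndarray             # (n_cells,) cell-centre km coordinates
    cell_y: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years)
        if years.size == 0:
            raise HistoryError("empty land-use history")
        if np.any(np.diff(years) <= 0):
            raise HistoryError("history years must be strictly increasing")
        frac = np.asarray(self.human_fraction, dtype=float)
        if frac.ndim != 2 or frac.shape[1] != years.size:
            raise HistoryError("human_fraction must be (n_cells, n_years)")
        if np.nanmin(frac) < -1e-9 or np.nanmax(frac) > 1 + 1e-9:
            raise HistoryError("human fractions must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.human_fraction.shape[0]

    def cell_containing(self, x, y, cell_size_km: float) -> np.ndarray:
        """Index of the coarse cell whose (half-open) square contains each point."""
        cx = np.asarray(self.cell_x)
        cy = np.asarray(self.cell_y)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        half = cell_size_km / 2.0
        idx = np.empty(x.shape, dtype=int)
        for i, (xi, yi) in enumerate(zip(x, y)):
            inside = (
                (xi >= cx - half) & (xi < cx + half)
                & (yi >= cy - half) & (yi < cy + half)
            )
            hits = np.nonzero(inside)[0]
            if hits.size == 0:
                raise HistoryError(f"point ({xi:.2f}, {yi:.2f}) outside the history grid")
            idx[i] = hits[0]
        return idx

    def to_frame(self) -> pd.DataFrame:
        cells, years = np.meshgrid(np.arange(self.n_cells), self.years, indexing="ij")
        return pd.DataFrame(
            {
                "cell_id": cells.ravel(),
                "year": years.ravel(),
                "human_fraction": self.human_fraction.ravel(),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, cell_x: np.ndarray, cell_y: np.ndarray
    ) -> "LandUseHistory":
        wide = frame.pivot(index="cell_id", columns="year", values="human_fraction")
        wide = wide.sort_index().sort_index(axis=1)
        return cls(wide.columns.to_numpy(float), wide.to_numpy(float),
                   np.asarray(cell_x), np.asarray(cell_y))


def modification_duration(
    years: np.ndarray,
    human_fraction: np.ndarray,
    threshold: float = 0.30,
    reference_year: float = 2005,
) -> float:
    """Years since the human-modified fraction first reached ``threshold``.

    Returns ``reference_year - first_crossing_year`` or 0.0 for series that
    never reach the threshold (such cells are treated as having no substantial
    modification history).
    """
    if not 0.0 < threshold < 1.0:
        raise HistoryError(f"threshold must lie in (0, 1), got {threshold}")
    years = np.asarray(years, dtype=float)
    frac = np.asarray(human_fraction, dtype=float)
    if years.size == 0:
        raise HistoryError("empty land-use history series")
    if reference_year < years[0]:
        raise HistoryError("reference year precedes the history span")
    crossed = np.nonzero(frac >= threshold)[0]
    if crossed.size == 0:
        return 0.0
    return float(reference_year - years[crossed[0]])


def modification_duration_cells(
    history: LandUseHistory, threshold: float = 0.30, reference_year: float = 2005
) -> np.ndarray:
    """Vectorised duration for every cell of a history."""
    return np.array(
        [
            modification_duration(history.years, history.human_fraction[c],
                                  threshold, reference_year)
            for c in range(history.n_cells)
        ]
    )
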