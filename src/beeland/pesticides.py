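"""Cumulative pesticide toxic load: application density scaled by honey-bee LD50.

Application densities (kg/ha) are modelled per crop group x active ingredient
on a coarse application grid (the ~10 km analogue of 5-arc-minute data).  The
toxic load of a cell is the sum over crop groups and ingredients of
density / contact-LD50; ingredients without a contact LD50 are excluded from
the sum (and counted, so the exclusion is visible to callers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PesticideTable", "toxic_load", "toxic_load_map", "PesticideError"]

log = logging.getLogger(__name__)


class PesticideError(ValueError):
    pass


@dataclass(frozen=True)
class PesticideTable:
    """Application-density arrays plus the LD50 lookup.

    ``density[c, i, iy, ix]`` is kg/ha applied of ingredient ``i`` on crop
    group ``c``; ``ld50`` (µg/bee, contact) is NaN where no estimate exists.
    ``estimate`` selects between the low and high modelled application
    surfaces ('low' is the headline choice, 'high' the robustness check).
    """

    crops: tuple[str, ...]
    ingredients: tuple[str, ...]
    density_low: np.ndarray    # (n_crops, n_ingredients, ny, nx), kg/ha
    density_high: np.ndarray
    ld50: np.ndarray           # (n_ingredients,), µg/bee; NaN = unavailable
    x0: float
    y0: float
    cell_km: float

    def __post_init__(self) -> None:
        for arr in (self.density_low, self.density_high):
            if np.nanmin(arr) < 0:
                raise PesticideError("application densities must be non-negative")
        finite = self.ld50[np.isfinite(self.ld50)]
        if np.any(finite <= 0):
            raise PesticideError("LD50 values must be positive where present")
        if len(self.crops) > 10:
            raise PesticideError("at most 10 crop groups supported")
        if len(self.ingredients) > 20:
            raise PesticideError("at most 20 active ingredients per crop group")

    def density(self, estimate: str = "low") -> np.ndarray:
        if estimate not in ("low", "high"):
            raise PesticideError(f"estimate must be 'low' or 'high', got {estimate!r}")
        return self.density_low if estimate == "low" else self.density_high

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.x0) / self.cell_km).astype(int)
        iy = np.floor((y - self.y0) / self.cell_km).astype(int)
        ny, nx = self.density_low.shape[2:]
        if np.any((ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)):
            raise PesticideError("site outside the pesticide application grid")
        return ix, iy

    def applications_frame(self, estimate: str = "low") -> pd.DataFrame:
        """Long-format non-zero application records (for CSV export)."""
        d = self.density(estimate)
        c, i, iy, ix = np.nonzero(d)
        return pd.DataFrame(
            {
                "crop": np.asarray(self.crops)[c],
                "ingredient": np.asarray(self.ingredients)[i],
                "cell_ix": ix,
                "cell_iy": iy,
                "kg_per_ha": d[c, i, iy, ix],
            }
        )

    def ld50_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ingredient": self.ingredients, "contact_ld50_ug_per_bee": self.ld50}
        )

    def write_csv(self, directory: str | Path, estimate: str = "low") -> None:
        directory = Path(directory)
        self.applications_frame(estimate).to_csv(
            directory / f"pesticide_applications_{estimate}.csv", index=False
        )
        self.ld50_frame().to_csv(directory / "pesticide_ld50.csv", index=False)


def toxic_load_map(table: PesticideTable, estimate: str = "low") -> np.ndarray:
    """Summed density/LD50 over crops and ingredients for every application cell."""
    d = table.density(estimate)
    have = np.isfinite(table.ld50)
    n_missing = int((~have).sum())
    if n_missing:
        log.info("toxic load: %d/%d ingredients lack a contact LD50 and are excluded",
                 n_missing, table.ld50.size)
    inv = np.where(have, 1.0 / np.where(have, table.ld50, 1.0), 0.0)
    return np.einsum("cixy,i->xy", d, inv)


def toxic_load(table: PesticideTable, x, y, estimate: str = "low") -> np.ndarray:
    """Toxic load of the application cell containing each site (unitless index)."""
    ix, iy = table.cell_index(x, y)
    return toxic_load_map(table, estimate)[iy, ix]
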