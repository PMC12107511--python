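"""Realised thermal niche limits and niche-position covariates.

A species' realised thermal niche is bounded empirically: the lower limit is
the mean of the five lowest monthly minimum temperatures, and the upper limit
the mean of the five highest monthly maximum temperatures, pooled over the
climate cells of its occurrence records across the baseline period.  A
population's *niche position* rescales local monthly maxima onto that range
(0 = lower limit, 1 = upper limit), averaging the 12 rescaled monthly values
within each year and then averaging across the period's years.  Positions may
legitimately fall outside [0, 1] where local temperatures exceed the realised
limits; they are never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .climate import BASELINE_PERIOD, RECENT_PERIOD, ClimateSeries

__all__ = [
    "ThermalNiche",
    "NichePosition",
    "NicheError",
    "niche_limits",
    "niche_position",
    "position_change",
    "delta_position",
]

log = logging.getLogger(__name__)


class NicheError(ValueError):
    pass


@dataclass(frozen=True)
class ThermalNiche:
    species: str
    niche_min: float  # °C
    niche_max: float  # °C

    def __post_init__(self) -> None:
        if not self.niche_max > self.niche_min:
            raise NicheError(
                f"degenerate niche for {self.species}: "
                f"max {self.niche_max} must exceed min {self.niche_min}"
            )

    @property
    def breadth(self) -> float:
        return self.niche_max - self.niche_min


def _tail_mean(values: np.ndarray, k: int, lowest: bool, species: str) -> float:
    values = np.sort(np.asarray(values, dtype=float).ravel())
    if values.size == 0:
        raise NicheError(f"no occurrence records to derive a niche for {species}")
    if values.size < k:
        log.warning(
            "species %s: only %d pooled monthly values (<%d); using the mean of all",
            species, values.size, k,
        )
        return float(values.mean())
    return float(values[:k].mean() if lowest else values[-k:].mean())


def niche_limits(
    species: str,
    record_x: np.ndarray,
    record_y: np.ndarray,
    climate: ClimateSeries,
    baseline: tuple[int, int] = BASELINE_PERIOD,
    n_extremes: int = 5,
) -> ThermalNiche:
    """Realised niche limits from a species' spatial records.

    Records are deduplicated to unique climate cells (so record density does
    not weight the extremes), monthly values over the baseline period are
    pooled across those cells, and the limits are means of the ``n_extremes``
    most extreme pooled values on each side.
    """
    record_x = np.atleast_1d(np.asarray(record_x, dtype=float))
    if record_x.size == 0:
        raise NicheError(f"no occurrence records for species {species}")
    cells = np.unique(climate.nearest_cell(record_x, record_y))
    ymask = climate.year_mask(baseline)
    pooled_min = climate.tmin[cells][:, ymask, :]
    pooled_max = climate.tmax[cells][:, ymask, :]
    lo = _tail_mean(pooled_min, n_extremes, lowest=True, species=species)
    hi = _tail_mean(pooled_max, n_extremes, lowest=False, species=species)
    if not hi > lo:
        # pathological (e.g., constant climate with inverted tails cannot occur,
        # but a flat series gives hi == lo); widen minimally to stay usable
        raise NicheError(f"degenerate realised niche for {species}: [{lo}, {hi}]")
    return ThermalNiche(species, lo, hi)


@dataclass(frozen=True)
class NichePosition:
    """A species-by-cell niche position for a named period tag."""

    species: str
    cell: int
    period: str  # 'baseline' | 'recent'
    position: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.position):
            raise NicheError(f"non-finite niche position for {self.species}@{self.cell}")


def position_change(baseline: NichePosition, recent: NichePosition) -> float:
    """recent - baseline for a matched species-by-cell pair."""
    if baseline.species != recent.species or baseline.cell != recent.cell:
        raise NicheError(
            f"mismatched niche positions: {baseline.species}@{baseline.cell} "
            f"vs {recent.species}@{recent.cell}"
        )
    return recent.position - baseline.position


def niche_position(
    cell: int,
    period: tuple[int, int],
    niche: ThermalNiche,
    climate: ClimateSeries,
) -> float:
    """Mean rescaled monthly-maximum position of one cell over a period.

    Per year: mean over the 12 months of ``(tmax - niche_min) / breadth``;
    then the mean of those yearly values across the period.
    """
    if niche.breadth <= 0:
        raise NicheError(f"degenerate niche for {niche.species}")
    ymask = climate.year_mask(period)
    monthly = (climate.tmax[cell, ymask, :] - niche.niche_min) / niche.breadth
    return float(monthly.mean(axis=1).mean())


def delta_position(
    cell: int,
    niche: ThermalNiche,
    climate: ClimateSeries,
    baseline: tuple[int, int] = BASELINE_PERIOD,
    recent: tuple[int, int] = RECENT_PERIOD,
) -> float:
    """Shift in niche position between the baseline and recent periods."""
    return niche_position(cell, recent, niche, climate) - niche_position(
        cell, baseline, niche, climate
    )
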