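"""Fixed-effect design matrix for the occurrence model.

Fifteen columns: intercept; a human-land-use indicator (natural is the
reference class); six continuous main effects (natural habitat, log toxic
load, modification duration, baseline niche position and its raw-coded
square, niche-position shift); log elevation; and the six products of the
land-use indicator with the pressure/niche columns.  The quadratic is coded
raw — (x, x²) on the centred variable — rather than as an orthogonal
polynomial: the fitted curve is identical and counterfactual editing stays a
simple column substitution, though individual linear/quadratic coefficients
are then not comparable one-to-one with an orthogonally-coded fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import FIXED_EFFECT_LABELS, LAND_USE_HUMAN, LAND_USE_NATURAL

__all__ = ["ModelSpec", "DesignError", "build_design_matrix"]

log = logging.getLogger(__name__)


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Sampler settings; defaults follow the 4-chain, 1000+1000 convention."""

    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    slope_sd: float = 5.0          # Normal(0, slope_sd) slab on standardised slopes
    intercept_scale: float = 2.5   # Student-t(3, 0, scale) intercept prior
    intercept_df: float = 3.0
    sd_scale: float = 2.5          # half-t(3, 0, scale) on random-effect SDs
    sd_df: float = 3.0
    rhat_threshold: float = 1.01

    @property
    def n_draws(self) -> int:
        return self.chains * self.samples


_MAIN = {
    "landuse_human": None,
    "natural_habitat": "z_natural_habitat",
    "log_toxic_load": "z_log_toxic_load",
    "modification_duration": "z_modification_duration",
    "baseline_position": "z_baseline_position",
    "delta_position": "z_delta_position",
    "log_elevation": "z_log_elevation",
}

_INTERACTING = (
    "natural_habitat",
    "log_toxic_load",
    "modification_duration",
    "baseline_position",
    "baseline_position_sq",
    "delta_position",
)


def build_design_matrix(
    rows: pd.DataFrame, *, check_rank: bool = True
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix + column labels for a model-ready table.

    ``check_rank=False`` skips the constant-column warning and the
    rank-deficiency error — required for counterfactual scenario matrices,
    where pressure columns are constant by construction.
    """
    n = len(rows)
    lu = rows["land_use_class"].to_numpy()
    valid = np.isin(lu, (LAND_USE_NATURAL, LAND_USE_HUMAN))
    if not valid.all():
        raise DesignError(f"unknown land-use class {lu[~valid][0]!r}")
    human = (lu == LAND_USE_HUMAN).astype(float)

    cols: dict[str, np.ndarray] = {"intercept": np.ones(n), "landuse_human": human}
    for label, source in _MAIN.items():
        if source is None:
            continue
        v = rows[source].to_numpy(float)
        if not np.all(np.isfinite(v)):
            raise DesignError(f"non-finite values in {source}")
        cols[label] = v
    cols["baseline_position_sq"] = cols["baseline_position"] ** 2
    for name in _INTERACTING:
        cols[f"landuse_human:{name}"] = human * cols[name]

    X = np.column_stack([cols[lab] for lab in FIXED_EFFECT_LABELS])
    if not check_rank:
        return X, FIXED_EFFECT_LABELS
    for j, lab in enumerate(FIXED_EFFECT_LABELS[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            log.warning("design column %s is constant", lab)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via QR pivoting on the correlation structure
        _, r = np.linalg.qr(X)
        dep = [FIXED_EFFECT_LABELS[j] for j in range(X.shape[1])
               if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise DesignError(f"rank-deficient design matrix (rank {rank} < {X.shape[1]}); "
                          f"suspect columns: {dep or 'unresolved'}")
    return X, FIXED_EFFECT_LABELS
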