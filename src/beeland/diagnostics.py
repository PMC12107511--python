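"""Model diagnostics: Bayesian R² and Moran's I residual autocorrelation tests.

Bayes R² follows the Gelman et al. (2019) residual-variance formulation for a
Bernoulli response: per posterior draw, with fitted probabilities mu,

    R^2 = Var(mu) / (Var(mu) + mean(mu * (1 - mu)))

where the *marginal* version builds mu from fixed effects only and the
*conditional* version adds the estimated random intercepts.

Moran's I uses row-standardised inverse-distance weights among unique sites
by default (k-nearest-neighbour weights are available), with a two-sided
permutation p-value (999 permutations, doubled one-sided rank).  The test is
run once across all site-level residuals and once per study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import PosteriorSamples, predict_probability

__all__ = [
    "MoranResult",
    "DiagnosticError",
    "bayes_r2",
    "bayes_r2_summary",
    "morans_i",
    "moran_statistic",
    "per_study_moran",
    "per_study_moran_summary",
    "site_residuals",
]


class DiagnosticError(ValueError):
    pass


def bayes_r2(
    posterior: PosteriorSamples, rows: pd.DataFrame, mode: str = "marginal"
) -> np.ndarray:
    """Draw-wise Bayesian R² (length = total posterior draws)."""
    if mode not in ("marginal", "conditional"):
        raise DiagnosticError(f"mode must be marginal|conditional, got {mode!r}")
    mu = predict_probability(posterior, rows, conditional=(mode == "conditional"))
    return r2_from_mu(mu)


def r2_from_mu(mu: np.ndarray) -> np.ndarray:
    """R² per draw from a (draws, rows) matrix of fitted probabilities."""
    var_fit = mu.var(axis=1, ddof=1)
    var_res = (mu * (1.0 - mu)).mean(axis=1)
    denom = var_fit + var_res
    if np.any(denom == 0):
        raise DiagnosticError("zero explained and residual variance")
    return var_fit / denom


def bayes_r2_summary(r2_draws: np.ndarray) -> dict[str, float]:
    qs = np.quantile(r2_draws, [0.025, 0.165, 0.5, 0.835, 0.975])
    return {
        "median": float(qs[2]),
        "lo95": float(qs[0]),
        "lo67": float(qs[1]),
        "hi67": float(qs[3]),
        "hi95": float(qs[4]),
    }


@dataclass(frozen=True)
class MoranResult:
    statistic: float
    p_value: float
    scope: str
    n: int
    expected: float  # null expectation -1/(n-1)


def _weights(coords: np.ndarray, scheme: str, k: int) -> np.ndarray:
    n = coords.shape[0]
    d = np.hypot(
        coords[:, None, 0] - coords[None, :, 0], coords[:, None, 1] - coords[None, :, 1]
    )
    if np.all(d[~np.eye(n, dtype=bool)] == 0):
        raise DiagnosticError("all pairwise distances are zero")
    if scheme == "idw":
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        w[~np.isfinite(w)] = 0.0
        np.fill_diagonal(w, 0.0)
    elif scheme == "knn":
        w = np.zeros((n, n))
        order = np.argsort(d + np.where(np.eye(n, dtype=bool), np.inf, 0.0), axis=1)
        for i in range(n):
            w[i, order[i, : min(k, n - 1)]] = 1.0
    else:
        raise DiagnosticError(f"unknown weight scheme {scheme!r}")
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return w / rs


def moran_statistic(residuals: np.ndarray, w: np.ndarray) -> float:
    """Plain double-sum Moran's I with precomputed weights."""
    z = residuals - residuals.mean()
    denom = float(z @ z)
    if denom == 0:
        raise DiagnosticError("zero residual variance")
    s0 = w.sum()
    return float(len(z) / s0 * (z @ w @ z) / denom)


def morans_i(
    residuals: np.ndarray,
    coords: np.ndarray,
    *,
    scheme: str = "idw",
    k: int = 8,
    n_permutations: int = 999,
    seed: int = 0,
    scope: str = "all",
) -> MoranResult:
    """Moran's I with a two-sided permutation test.

    Residuals are permuted over the fixed site locations; the two-sided
    p-value doubles the smaller one-sided permutation rank (with the +1
    inclusion of the observed statistic).
    """
    residuals = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = residuals.size
    if n < 3 or np.unique(coords, axis=0).shape[0] < 3:
        raise DiagnosticError("need >= 3 sites with distinct coordinates")
    z = residuals - residuals.mean()
    if float(z @ z) == 0:
        raise DiagnosticError("zero residual variance")
    w = _weights(coords, scheme, k)
    i_obs = moran_statistic(residuals, w)

    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, n))
    for b in range(n_permutations):
        perms[b] = z[rng.permutation(n)]
    s0 = w.sum()
    num = np.einsum("bi,ij,bj->b", perms, w, perms)
    den = np.einsum("bi,bi->b", perms, perms)
    i_perm = n / s0 * num / den

    ge = int(np.sum(i_perm >= i_obs))
    le = int(np.sum(i_perm <= i_obs))
    p_one = (1 + min(ge, le)) / (n_permutations + 1)
    p = min(1.0, 2.0 * p_one)
    return MoranResult(i_obs, p, scope, n, -1.0 / (n - 1))


def site_residuals(
    posterior: PosteriorSamples, rows: pd.DataFrame
) -> pd.DataFrame:
    """Site-level mean response residuals (observed minus posterior-mean fitted).

    Species-by-site residuals are averaged to one value per site, the spatial
    support on which the autocorrelation tests run.
    """
    mu = predict_probability(posterior, rows, conditional=True).mean(axis=0)
    resid = rows["outcome"].to_numpy(float) - mu
    out = rows[["study_id", "site_id", "x_km", "y_km"]].copy()
    out["residual"] = resid
    return (
        out.groupby(["study_id", "site_id"], as_index=False)
        .agg(x_km=("x_km", "first"), y_km=("y_km", "first"),
             residual=("residual", "mean"))
    )


def per_study_moran(
    site_resid: pd.DataFrame,
    *,
    scheme: str = "idw",
    n_permutations: int = 999,
    seed: int = 0,
) -> list[MoranResult]:
    """Moran's I per study on that study's sites only."""
    results = []
    rng = np.random.default_rng(seed)
    for study, grp in site_resid.groupby("study_id", sort=True):
        try:
            results.append(
                morans_i(
                    grp["residual"].to_numpy(),
                    grp[["x_km", "y_km"]].to_numpy(),
                    scheme=scheme,
                    n_permutations=n_permutations,
                    seed=int(rng.integers(2**31 - 1)),
                    scope=str(study),
                )
            )
        except DiagnosticError:
            continue
    return results


def per_study_moran_summary(
    results: list[MoranResult], alpha: float = 0.05
) -> dict[str, float]:
    """Fraction of studies with significant residual autocorrelation."""
    if not results:
        raise DiagnosticError("no per-study Moran results")
    sig = sum(r.p_value < alpha for r in results)
    return {
        "fraction_significant": sig / len(results),
        "n_studies": len(results),
        "expected_by_chance": alpha,
    }
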