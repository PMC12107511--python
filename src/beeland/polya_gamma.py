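"""Vectorised Pólya-Gamma PG(1, z) sampling for logistic data augmentation.

A PG(1, z) variate is an infinite weighted sum of exponentials,

    omega = (1 / (2 pi^2)) * sum_{k>=1} g_k / ((k - 1/2)^2 + z^2 / (4 pi^2)),
    g_k ~ Exp(1),

(Polson, Scott & Windle 2013).  We draw the first ``n_terms`` terms exactly
and replace the tail by its conditional mean, which has a closed form via

    sum_{k>=1} 1 / ((k - 1/2)^2 + c) = (pi / (2 sqrt(c))) * tanh(pi sqrt(c)).

With the default 64 terms the neglected tail *randomness* has a standard
deviation below 0.2% of the mean of the draw, far inside Monte-Carlo noise
for the Gibbs sweeps this feeds.

Reference moments used by tests:  E[PG(1,z)] = tanh(z/2) / (2 z)  and
Var[PG(1,z)] = sech^2(z/2) * (sinh(z) - z) / (4 z^3).
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_pg", "pg_mean", "pg_var"]

_TWO_PI_SQ = 2.0 * np.pi**2


def pg_mean(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 0.25)
    nz = np.abs(z) > 1e-8
    out[nz] = np.tanh(z[nz] / 2.0) / (2.0 * z[nz])
    return out


def pg_var(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 1.0 / 24.0)
    nz = np.abs(z) > 1e-4
    zz = z[nz]
    out[nz] = (np.sinh(zz) - zz) / (np.cosh(zz / 2.0) ** 2 * 4.0 * zz**3)
    return out


def sample_pg(
    z: np.ndarray, rng: np.random.Generator, n_terms: int = 64
) -> np.ndarray:
    """One PG(1, z_i) draw per element of ``z``."""
    z = np.asarray(z, dtype=float)
    c = (z / (2.0 * np.pi)) ** 2
    k = np.arange(1, n_terms + 1) - 0.5           # (K,)
    denom = k**2 + c[..., None]                   # (..., K)
    g = rng.standard_exponential(denom.shape)
    head = (g / denom).sum(axis=-1) / _TWO_PI_SQ

    # closed-form total mean minus the head's mean = tail mean
    root = np.sqrt(np.maximum(c, 1e-300))
    total = np.where(
        c < 1e-12, np.pi**2 / 2.0, (np.pi / (2.0 * root)) * np.tanh(np.pi * root)
    )
    tail_mean = (total - (1.0 / denom).sum(axis=-1)) / _TWO_PI_SQ
    return head + np.maximum(tail_mean, 0.0)
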