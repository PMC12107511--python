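"""Bayesian R² and Moran's I spatial autocorrelation diagnostics."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from beeland.diagnostics import (
    DiagnosticError,
    _weights,
    bayes_r2,
    bayes_r2_summary,
    moran_statistic,
    morans_i,
    per_study_moran,
    per_study_moran_summary,
    r2_from_mu,
    site_residuals,
)


# ------------------------------------------------------------------ Bayes R²
def test_r2_zero_for_constant_probabilities():
    mu = np.full((3, 50), 0.4)
    assert np.allclose(r2_from_mu(mu), 0.0)


def test_r2_matches_hand_computed_two_draw_example():
    mu = np.array([[0.2, 0.4, 0.6, 0.8], [0.5, 0.5, 0.9, 0.1]])
    got = r2_from_mu(mu)
    for d in range(2):
        var_fit = np.var(mu[d], ddof=1)
        var_res = np.mean(mu[d] * (1 - mu[d]))
        assert got[d] == pytest.approx(var_fit / (var_fit + var_res), abs=1e-14)


def test_r2_bounds_and_conditional_exceeds_marginal(small_study):
    m = small_study.r2_marginal
    c = small_study.r2_conditional
    assert np.all((m >= 0) & (m < 1)) and np.all((c >= 0) & (c < 1))
    assert np.median(c) >= np.median(m)
    s = bayes_r2_summary(c)
    assert s["lo95"] <= s["lo67"] <= s["median"] <= s["hi67"] <= s["hi95"]


def test_r2_mode_validation(small_study):
    with pytest.raises(DiagnosticError):
        bayes_r2(small_study.posterior, small_study.model_table, "weird")


# ------------------------------------------------------------------ Moran's I
def brute_force_moran(z, w):
    z = z - z.mean()
    n = len(z)
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
    return n / w.sum() * num / (z @ z)


def test_moran_permutation_mean_is_null_expectation():
    rng = np.random.default_rng(3)
    n = 30
    coords = rng.uniform(0, 10, (n, 2))
    resid = rng.standard_normal(n)
    w = _weights(coords, "idw", 8)
    perms = [moran_statistic(rng.permutation(resid), w) for _ in range(4000)]
    assert np.mean(perms) == pytest.approx(-1.0 / (n - 1), abs=0.01)


def test_checkerboard_residuals_give_negative_moran_matching_oracle():
    side = 6
    xx, yy = np.meshgrid(np.arange(side), np.arange(side))
    coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    resid = ((xx + yy) % 2).ravel().astype(float) - 0.5
    w = _weights(coords, "knn", 4)
    i_stat = moran_statistic(resid, w)
    assert i_stat < 0
    assert i_stat == pytest.approx(brute_force_moran(resid, w), abs=1e-12)
    res = morans_i(resid, coords, scheme="knn", k=4, seed=5)
    assert res.statistic == pytest.approx(i_stat, abs=1e-12)
    assert res.p_value <= 0.05


def test_idw_moran_matches_double_sum_oracle_on_random_data():
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = int(rng.integers(5, 40))
        coords = rng.uniform(0, 100, (n, 2))
        resid = rng.standard_normal(n)
        w = _weights(coords, "idw", 8)
        assert moran_statistic(resid, w) == pytest.approx(
            brute_force_moran(resid, w), abs=1e-12
        )


def test_smooth_gradient_detected_as_positive_autocorrelation():
    rng = np.random.default_rng(11)
    n = 100
    coords = rng.uniform(0, 100, (n, 2))
    resid = coords[:, 0] / 100.0 + 0.05 * rng.standard_normal(n)
    res = morans_i(resid, coords, seed=13)
    assert res.statistic > 0
    assert res.p_value <= 0.05
    assert -1 - 1e-9 <= res.statistic <= 1 + 1e-9


def test_moran_statistic_agrees_with_r_ape_oracle():
    """Cross-check the statistic against ape::Moran.I with identical weights."""
    rng = np.random.default_rng(17)
    n = 25
    coords = rng.uniform(0, 50, (n, 2))
    resid = rng.standard_normal(n)
    w = _weights(coords, "idw", 8)
    ours = moran_statistic(resid, w)
    with tempfile.TemporaryDirectory() as td:
        np.savetxt(Path(td) / "w.csv", w, delimiter=",")
        np.savetxt(Path(td) / "z.csv", resid, delimiter=",")
        script = (
            f"w <- as.matrix(read.csv('{td}/w.csv', header=FALSE));"
            f"z <- scan('{td}/z.csv');"
            "r <- ape::Moran.I(z, w, scaled=FALSE);"
            "cat(sprintf('%.12f', r$observed))"
        )
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=120, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.fail(f"R oracle unavailable: {exc}")
    assert ours == pytest.approx(float(out.stdout.strip()), abs=1e-8)


def test_moran_input_validation():
    coords = np.zeros((5, 2))
    with pytest.raises(DiagnosticError):
        morans_i(np.arange(5.0), coords)  # all distances zero
    with pytest.raises(DiagnosticError):
        morans_i(np.ones(5), np.random.default_rng(0).uniform(0, 1, (5, 2)))
    with pytest.raises(DiagnosticError):
        morans_i(np.arange(2.0), np.array([[0.0, 0], [1, 1]]))


# ----------------------------------------------------------- per-study scans
def test_per_study_fraction_simple_counts():
    from beeland.diagnostics import MoranResult

    results = [MoranResult(0.1, p, "s", 10, -1 / 9)
               for p in (0.2, 0.01, 0.5, 0.9, 0.3, 0.6, 0.7, 0.8)]
    s = per_study_moran_summary(results)
    assert s["fraction_significant"] == pytest.approx(1 / 8)
    assert s["expected_by_chance"] == 0.05
    none = [MoranResult(0.0, 0.5, "s", 10, -1 / 9)]
    assert per_study_moran_summary(none)["fraction_significant"] == 0.0


def test_injected_autocorrelation_is_detected_in_affected_studies():
    """Strong spatially correlated site noise inflates per-study rejections."""
    from beeland.synthetic import TrueParameters, simulate_occurrence
    from conftest import random_model_table

    rng = np.random.default_rng(23)
    frames = []
    k_affected = 0
    for s in range(8):
        rows = random_model_table(720, seed=100 + s, n_studies=1,
                                  sites_per_study=36, n_species=6)
        rows["study_id"] = f"study_{s}"
        rows["site_id"] = rows["study_id"] + "_" + rows["site_id"]
        # give each site one fixed coordinate
        sites = rows["site_id"].unique()
        coords = {sid: rng.uniform(0, 40, 2) for sid in sites}
        rows["x_km"] = [coords[sid][0] for sid in rows["site_id"]]
        rows["y_km"] = [coords[sid][1] for sid in rows["site_id"]]
        inject = s < 4
        k_affected += inject
        out = simulate_occurrence(
            rows, TrueParameters(beta={}, sigma_study=0, sigma_site=0, sigma_species=0),
            seed=200 + s,
            spatial_noise_sd=2.0 if inject else 0.0, spatial_range_km=8.0,
        )
        frames.append(out)
    table = pd.concat(frames, ignore_index=True)
    resid = table.groupby(["study_id", "site_id"], as_index=False).agg(
        x_km=("x_km", "first"), y_km=("y_km", "first"),
        residual=("outcome", lambda v: v.mean() - table["outcome"].mean()),
    )
    results = per_study_moran(resid, n_permutations=499, seed=31)
    s = per_study_moran_summary(results)
    # at these effect/power settings every affected study and no clean study rejects
    assert s["fraction_significant"] == pytest.approx(k_affected / 8)


def test_site_residuals_aggregate_to_unique_sites(small_study):
    resid = site_residuals(small_study.posterior, small_study.model_table)
    assert resid["site_id"].is_unique
    assert abs(resid["residual"].mean()) < 0.2
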