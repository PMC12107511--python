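"""Pressure-free reference scenario and posterior percentage differences."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from beeland.counterfactual import (
    CounterfactualError,
    REFERENCE_VALUES,
    make_reference,
    percent_difference,
    predict_occurrence,
)
from beeland.dataset import SCALED_COVARIATES, build_model_table
from beeland.design import ModelSpec
from beeland.gibbs import PosteriorSamples
from beeland.synthetic import FIXED_EFFECT_LABELS


def _raw_table(n=6, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "study_id": ["st1"] * n,
            "site_id": [f"s{i}" for i in range(n)],
            "species": ["sp1"] * n,
            "land_use_class": ["natural", "human_modified"] * (n // 2),
            "x_km": rng.uniform(0, 10, n),
            "y_km": rng.uniform(0, 10, n),
            "natural_habitat": rng.uniform(0.1, 0.9, n),
            "toxic_load": rng.uniform(0, 5, n),
            "modification_duration": rng.uniform(0, 300, n),
            "baseline_position": rng.uniform(0.1, 0.9, n),
            "delta_position": rng.uniform(0, 0.1, n),
            "elevation": rng.uniform(0, 900, n),
        }
    )
    return build_model_table(df)


def test_reference_sets_pressure_covariates_and_is_idempotent():
    table, scalers = _raw_table()
    ref = make_reference(table, scalers)
    assert (ref["natural_habitat"] == 1.0).all()
    assert (ref["modification_duration"] == 0.0).all()
    assert (ref["toxic_load"] == 0.0).all()
    assert (ref["log_toxic_load"] == 0.0).all()
    assert (ref["delta_position"] == 0.0).all()
    # untouched columns
    assert np.array_equal(ref["baseline_position"], table["baseline_position"])
    assert np.array_equal(ref["elevation"], table["elevation"])
    assert np.array_equal(ref["land_use_class"], table["land_use_class"])
    # scaled columns re-expressed with the same scalers
    m, s = scalers["natural_habitat"]
    assert np.allclose(ref["z_natural_habitat"], (1.0 - m) / s)
    ref2 = make_reference(ref, scalers)
    pd.testing.assert_frame_equal(ref, ref2)


def test_reference_requires_scalers():
    table, scalers = _raw_table()
    with pytest.raises(CounterfactualError):
        make_reference(table, {"natural_habitat": (0.0, 1.0)})


def test_reference_can_reset_local_landuse():
    table, scalers = _raw_table()
    ref = make_reference(table, scalers, reset_local_landuse=True)
    assert (ref["land_use_class"] == "natural").all()


def _hand_posterior(beta_by_label: dict, n_draws=4, levels=None, spec=None):
    """A tiny posterior with identical draws and zero random intercepts."""
    levels = levels or {"study": np.array(["st1"]), "site": np.array([f"s{i}" for i in range(6)]),
                        "species": np.array(["sp1"])}
    beta = np.array([[ [beta_by_label.get(l, 0.0) for l in FIXED_EFFECT_LABELS] ]
                     * n_draws])
    u = {f: np.zeros((1, n_draws, len(levels[f]))) for f in ("study", "site", "species")}
    sigma = np.zeros((1, n_draws, 3))
    rhat = pd.DataFrame({"parameter": list(FIXED_EFFECT_LABELS), "rhat": 1.0})
    return PosteriorSamples(beta, FIXED_EFFECT_LABELS, sigma, u, levels, rhat, True,
                            spec or ModelSpec(chains=1, samples=n_draws))


def test_zero_linear_predictor_gives_half():
    table, scalers = _raw_table()
    post = _hand_posterior({})
    p = predict_occurrence(post, table)
    assert np.allclose(p, 0.5)


def test_single_row_difference_matches_scalar_arithmetic():
    table, scalers = _raw_table()
    row = table.iloc[[0]].reset_index(drop=True)  # natural land use
    beta = {"intercept": 0.2, "natural_habitat": 0.8, "log_toxic_load": -0.6,
            "modification_duration": -0.3, "delta_position": -0.5}
    post = _hand_posterior(beta, levels={"study": np.array(["st1"]),
                                         "site": np.array(["s0"]),
                                         "species": np.array(["sp1"])})
    summary = percent_difference(post, row, scalers, n_draws=4, seed=0)

    def eta(r):
        z = lambda c: (r[c] - scalers[c][0]) / scalers[c][1]
        return (0.2 + 0.8 * z("natural_habitat") - 0.6 * z("log_toxic_load")
                - 0.3 * z("modification_duration") - 0.5 * z("delta_position"))

    raw = row.iloc[0].to_dict()
    p_act = expit(eta({**raw,
                       "log_toxic_load": np.log1p(raw["toxic_load"]),
                       }))
    ref = {**raw, "natural_habitat": 1.0, "log_toxic_load": 0.0,
           "modification_duration": 0.0, "delta_position": 0.0}
    p_ref = expit(eta(ref))
    expected = 100.0 * (p_ref - p_act) / p_ref
    assert summary.draws["natural"] == pytest.approx(expected, abs=1e-12)


def test_zero_pressure_coefficients_give_identically_zero_difference():
    table, scalers = _raw_table()
    post = _hand_posterior({"intercept": 0.4, "landuse_human": -0.7,
                            "baseline_position": 0.5, "baseline_position_sq": -0.3,
                            "log_elevation": -0.2,
                            "landuse_human:baseline_position": 0.1,
                            "landuse_human:baseline_position_sq": -0.1})
    summary = percent_difference(post, table, scalers, n_draws=4, seed=1)
    for cls, draws in summary.draws.items():
        assert np.allclose(draws, 0.0, atol=1e-12)


def test_actual_at_reference_values_gives_zero_difference():
    rng = np.random.default_rng(5)
    n = 4
    df = pd.DataFrame(
        {
            "study_id": ["st1"] * n, "site_id": [f"s{i}" for i in range(n)],
            "species": ["sp1"] * n,
            "land_use_class": ["natural", "human_modified"] * 2,
            "x_km": rng.uniform(0, 5, n), "y_km": rng.uniform(0, 5, n),
            "natural_habitat": 1.0, "toxic_load": 0.0,
            "modification_duration": 0.0,
            "baseline_position": rng.uniform(0.2, 0.8, n),
            "delta_position": 0.0, "elevation": rng.uniform(0, 200, n),
        }
    )
    # scalers from a variable table; the actual rows already sit at reference
    _, scalers = _raw_table()
    table, _ = build_model_table(df, scalers=scalers)
    post = _hand_posterior({"intercept": 0.3, "natural_habitat": 1.0,
                            "log_toxic_load": -1.0})
    summary = percent_difference(post, table, scalers, n_draws=4, seed=2)
    for draws in summary.draws.values():
        assert np.allclose(draws, 0.0, atol=1e-12)


def test_pooled_difference_lies_between_group_values():
    table, scalers = _raw_table(n=8, seed=9)
    post = _hand_posterior({"intercept": 0.1, "natural_habitat": 0.9,
                            "log_toxic_load": -0.7, "landuse_human": -0.4,
                            "landuse_human:log_toxic_load": 0.3},
                           levels={"study": np.array(["st1"]),
                                   "site": np.array([f"s{i}" for i in range(8)]),
                                   "species": np.array(["sp1"])})
    s = percent_difference(post, table, scalers, n_draws=4, seed=3)
    lo = np.minimum(s.draws["natural"], s.draws["human_modified"])
    hi = np.maximum(s.draws["natural"], s.draws["human_modified"])
    assert np.all(s.draws["all"] >= lo - 1e-12)
    assert np.all(s.draws["all"] <= hi + 1e-12)


def test_draw_subsampling_reproducible_and_bounded(small_study):
    post = small_study.posterior
    table = small_study.model_table
    s1 = percent_difference(post, table, small_study.scalers, n_draws=100, seed=42)
    s2 = percent_difference(post, table, small_study.scalers, n_draws=100, seed=42)
    for cls in s1.draws:
        assert np.array_equal(s1.draws[cls], s2.draws[cls])
    with pytest.raises(CounterfactualError):
        percent_difference(post, table, small_study.scalers,
                           n_draws=10**6, seed=0)
    tbl = s1.table
    assert (tbl["lo95"] <= tbl["lo67"]).all() and (tbl["hi67"] <= tbl["hi95"]).all()


def test_harmful_pressures_yield_positive_median_reduction(small_study):
    """End-to-end: generator's harmful pressure coefficients imply reduced occurrence."""
    cf = small_study.counterfactual
    assert cf.median("natural") > 0
    assert cf.median("human_modified") > 0
    assert len(cf.draws["natural"]) == 200
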