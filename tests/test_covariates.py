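"""Land-use history, pesticide toxic load and thermal-niche covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beeland.climate import ClimateSeries
from beeland.landuse import HistoryError, modification_duration
from beeland.niche import (
    NichePosition,
    NicheError,
    ThermalNiche,
    delta_position,
    niche_limits,
    niche_position,
    position_change,
)
from beeland.pesticides import PesticideError, PesticideTable, toxic_load_map


# ---------------------------------------------------------------- duration
def duration_oracle(years, frac, threshold, ref):
    """Linear scan for the first crossing of the threshold."""
    for y, f in zip(years, frac):
        if f >= threshold:
            return ref - y
    return 0.0


def test_duration_never_crossing_is_zero():
    years = np.arange(1500, 2006, 10)
    frac = np.full(years.size, 0.25)
    assert modification_duration(years, frac, 0.30, 2005) == 0.0


def test_duration_simple_subtraction():
    years = np.array([1800, 1900, 2000])
    frac = np.array([0.1, 0.5, 0.9])
    assert modification_duration(years, frac, 0.30, 2005) == 105.0


@pytest.mark.parametrize("threshold", [0.10, 0.30, 0.50])
def test_duration_matches_scan_oracle_on_random_steps(threshold):
    rng = np.random.default_rng(17)
    years = np.arange(1500, 2006, 5)
    for _ in range(50):
        frac = np.clip(np.cumsum(rng.uniform(-0.02, 0.03, years.size)), 0, 1)
        got = modification_duration(years, frac, threshold, 2005)
        assert got == duration_oracle(years, frac, threshold, 2005)


def test_duration_monotone_nonincreasing_in_threshold():
    rng = np.random.default_rng(23)
    years = np.arange(1500, 2006, 10)
    for _ in range(25):
        frac = np.clip(np.cumsum(rng.uniform(0, 0.04, years.size)), 0, 1)
        durations = [modification_duration(years, frac, t, 2005)
                     for t in (0.10, 0.30, 0.50)]
        assert durations[0] >= durations[1] >= durations[2]


def test_duration_input_validation():
    with pytest.raises(HistoryError):
        modification_duration(np.array([]), np.array([]), 0.3, 2005)
    with pytest.raises(HistoryError):
        modification_duration(np.array([1900.0]), np.array([0.5]), 1.5, 2005)


# --------------------------------------------------------------- toxic load
def _pesticide_table(rng, n_crops=10, n_ing=20, nx=6, missing_frac=0.1):
    dens = rng.random((n_crops, n_ing, nx, nx)) * (rng.random((n_crops, n_ing, nx, nx)) < 0.5)
    ld50 = np.exp(rng.normal(0, 2, n_ing))
    n_missing = int(round(missing_frac * n_ing))
    if n_missing:
        ld50[rng.choice(n_ing, n_missing, replace=False)] = np.nan
    return PesticideTable(
        tuple(f"c{i}" for i in range(n_crops)),
        tuple(f"a{i}" for i in range(n_ing)),
        dens, dens * 1.5, ld50, 0.0, 0.0, 10.0,
    )


def toxic_oracle(table, estimate="low"):
    d = table.density(estimate)
    out = np.zeros(d.shape[2:])
    for c in range(d.shape[0]):
        for i in range(d.shape[1]):
            if np.isfinite(table.ld50[i]):
                out += d[c, i] / table.ld50[i]
    return out


def test_toxic_load_zero_and_single_ratio():
    t = PesticideTable(("c",), ("a",), np.zeros((1, 1, 2, 2)), np.zeros((1, 1, 2, 2)),
                       np.array([0.1]), 0.0, 0.0, 10.0)
    assert np.all(toxic_load_map(t) == 0.0)
    d = np.zeros((1, 1, 2, 2))
    d[0, 0, 0, 0] = 0.5
    t2 = PesticideTable(("c",), ("a",), d, d, np.array([0.1]), 0.0, 0.0, 10.0)
    assert toxic_load_map(t2)[0, 0] == pytest.approx(5.0)


def test_toxic_load_matches_nested_loop_oracle_with_missing_ld50():
    rng = np.random.default_rng(31)
    for _ in range(20):
        t = _pesticide_table(rng)
        assert np.max(np.abs(toxic_load_map(t) - toxic_oracle(t))) < 1e-10
        assert np.max(np.abs(toxic_load_map(t, "high") - toxic_oracle(t, "high"))) < 1e-10


def test_toxic_load_additive_over_ingredient_partition():
    rng = np.random.default_rng(37)
    t = _pesticide_table(rng, missing_frac=0.0)
    half = 10
    t_a = PesticideTable(t.crops, t.ingredients[:half], t.density_low[:, :half],
                         t.density_high[:, :half], t.ld50[:half], 0.0, 0.0, 10.0)
    t_b = PesticideTable(t.crops, t.ingredients[half:], t.density_low[:, half:],
                         t.density_high[:, half:], t.ld50[half:], 0.0, 0.0, 10.0)
    assert np.allclose(toxic_load_map(t), toxic_load_map(t_a) + toxic_load_map(t_b))


def test_toxic_load_rejects_invalid_inputs():
    with pytest.raises(PesticideError):
        PesticideTable(("c",), ("a",), -np.ones((1, 1, 2, 2)), np.ones((1, 1, 2, 2)),
                       np.array([1.0]), 0.0, 0.0, 10.0)
    with pytest.raises(PesticideError):
        PesticideTable(("c",), ("a",), np.ones((1, 1, 2, 2)), np.ones((1, 1, 2, 2)),
                       np.array([-1.0]), 0.0, 0.0, 10.0)


# ------------------------------------------------------------ thermal niche
def _climate(rng, n_cells=4, years=np.arange(1901, 2016)):
    tmax = 20 + 8 * rng.standard_normal((n_cells, years.size, 12))
    gap = 5 + 2 * rng.random((n_cells, years.size, 12))
    xy = rng.uniform(0, 100, (n_cells, 2))
    return ClimateSeries(years, tmax - gap, tmax, xy[:, 0], xy[:, 1])


def test_niche_limits_constant_climate():
    years = np.arange(1901, 2016)
    tmin = np.full((3, years.size, 12), 4.0)
    tmax = np.full((3, years.size, 12), 19.0)
    clim = ClimateSeries(years, tmin, tmax, np.array([0., 10, 20]), np.array([0., 0, 0]))
    niche = niche_limits("sp", [1.0, 11.0], [0.0, 0.0], clim)
    assert niche.niche_min == pytest.approx(4.0)
    assert niche.niche_max == pytest.approx(19.0)


def test_niche_limits_match_sort_oracle():
    rng = np.random.default_rng(41)
    for _ in range(10):
        clim = _climate(rng)
        xs = rng.uniform(0, 100, 3)
        ys = rng.uniform(0, 100, 3)
        niche = niche_limits("sp", xs, ys, clim)
        cells = np.unique(clim.nearest_cell(xs, ys))
        ymask = (clim.years >= 1901) & (clim.years <= 1975)
        pooled_min = np.sort(clim.tmin[cells][:, ymask, :].ravel())
        pooled_max = np.sort(clim.tmax[cells][:, ymask, :].ravel())
        assert niche.niche_min == pytest.approx(pooled_min[:5].mean(), abs=1e-12)
        assert niche.niche_max == pytest.approx(pooled_max[-5:].mean(), abs=1e-12)


def test_niche_limits_record_cells_deduplicated():
    rng = np.random.default_rng(43)
    clim = _climate(rng)
    # many records in one cell must give the same limits as a single record
    x0, y0 = clim.cell_x[0], clim.cell_y[0]
    one = niche_limits("sp", [x0], [y0], clim)
    many = niche_limits("sp", [x0] * 10, [y0] * 10, clim)
    assert (one.niche_min, one.niche_max) == (many.niche_min, many.niche_max)


def test_niche_limits_requires_records():
    rng = np.random.default_rng(47)
    with pytest.raises(NicheError):
        niche_limits("sp", [], [], _climate(rng))


def test_niche_position_limits_map_to_zero_and_one():
    years = np.arange(1901, 1976)
    niche = ThermalNiche("sp", 2.0, 30.0)
    tmax_lo = np.full((1, years.size, 12), 2.0)
    clim_lo = ClimateSeries(years, tmax_lo - 5, tmax_lo, np.zeros(1), np.zeros(1))
    assert niche_position(0, (1901, 1975), niche, clim_lo) == pytest.approx(0.0)
    tmax_hi = np.full((1, years.size, 12), 30.0)
    clim_hi = ClimateSeries(years, tmax_hi - 5, tmax_hi, np.zeros(1), np.zeros(1))
    assert niche_position(0, (1901, 1975), niche, clim_hi) == pytest.approx(1.0)


def test_niche_position_matches_double_mean_oracle():
    rng = np.random.default_rng(53)
    for _ in range(10):
        clim = _climate(rng, n_cells=2)
        niche = ThermalNiche("sp", -5.0, 33.0)
        got = niche_position(1, (1950, 1960), niche, clim)
        ymask = (clim.years >= 1950) & (clim.years <= 1960)
        yearly = []
        for yr in np.nonzero(ymask)[0]:
            yearly.append(
                np.mean([(clim.tmax[1, yr, m] - (-5.0)) / 38.0 for m in range(12)])
            )
        assert got == pytest.approx(np.mean(yearly), abs=1e-12)


def test_position_affine_equivariance_and_uniform_shift_delta():
    """Adding k degC to every monthly maximum shifts the position by k/breadth."""
    rng = np.random.default_rng(59)
    clim = _climate(rng, n_cells=1)
    niche = ThermalNiche("sp", 0.0, 25.0)
    base = niche_position(0, (1910, 1930), niche, clim)
    k = 3.7
    shifted = ClimateSeries(clim.years, clim.tmin, clim.tmax + k,
                            clim.cell_x, clim.cell_y)
    assert niche_position(0, (1910, 1930), niche, shifted) == pytest.approx(
        base + k / 25.0, abs=1e-12
    )
    # delta under a uniform warming of the recent period only
    warmed = clim.tmax.copy()
    recent = (clim.years >= 2000) & (clim.years <= 2014)
    warmed[:, recent, :] = clim.tmax[:, recent, :]
    mixed = ClimateSeries(clim.years, clim.tmin, warmed, clim.cell_x, clim.cell_y)
    d0 = delta_position(0, niche, mixed)
    warmed2 = warmed.copy()
    warmed2[:, recent, :] += 2.0
    mixed2 = ClimateSeries(clim.years, clim.tmin, warmed2, clim.cell_x, clim.cell_y)
    assert delta_position(0, niche, mixed2) == pytest.approx(d0 + 2.0 / 25.0, abs=1e-12)


def test_position_change_requires_matched_pair():
    a = NichePosition("sp1", 0, "baseline", 0.4)
    b = NichePosition("sp1", 0, "recent", 0.55)
    assert position_change(a, b) == pytest.approx(0.15)
    with pytest.raises(NicheError):
        position_change(a, NichePosition("sp2", 0, "recent", 0.5))


def test_degenerate_niche_rejected():
    with pytest.raises(NicheError):
        ThermalNiche("sp", 10.0, 10.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(-20, 20), st.floats(1, 40))
def test_positions_may_exceed_unit_interval_without_clamping(nmin, breadth):
    years = np.arange(1901, 1976)
    tmax = np.full((1, years.size, 12), nmin + breadth + 5.0)  # beyond upper limit
    clim = ClimateSeries(years, tmax - 3, tmax, np.zeros(1), np.zeros(1))
    pos = niche_position(0, (1901, 1975), ThermalNiche("sp", nmin, nmin + breadth), clim)
    assert pos == pytest.approx(1.0 + 5.0 / breadth, rel=1e-9)
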