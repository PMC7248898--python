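"""Look-up-table construction, RRMSE cost and multi-solution averaging."""

import math

import numpy as np
import pytest

import gflai as g
from gflai.lut_inversion import LookUpTable, rrmse
from gflai.rtm_forward import PARAM_NAMES


def _make_lut(features, lais, strategy):
    """Assemble a LookUpTable with arbitrary features and LAI column."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    params = np.zeros((features.shape[0], len(PARAM_NAMES)))
    params[:, PARAM_NAMES.index("lai")] = lais
    return LookUpTable(features, params, strategy)


# ---------------------------------------------------------------------------
# cost function
# ---------------------------------------------------------------------------

def test_cost_zero_iff_equal():
    obs = np.array([0.2, 0.4, 0.1])
    assert rrmse(obs, obs[None, :])[0] == 0.0
    assert rrmse(obs, (obs * 1.01)[None, :])[0] > 0.0


def test_single_band_relative_error():
    assert rrmse(np.array([0.2]), np.array([[0.1]]))[0] == pytest.approx(0.5, abs=1e-15)


def test_two_band_root_mean_square():
    got = rrmse(np.array([0.2, 0.4]), np.array([[0.1, 0.4]]))[0]
    assert got == pytest.approx(math.sqrt((0.5**2 + 0.0) / 2), abs=1e-12)
    assert got == pytest.approx(0.3536, abs=5e-5)


def test_cost_nonnegative_on_random_pairs():
    rng = np.random.default_rng(0)
    obs = rng.uniform(0.05, 0.9, 4)
    cand = rng.uniform(0.05, 0.9, (500, 4))
    assert np.all(rrmse(obs, cand) >= 0.0)


def test_near_zero_observed_band_component_excluded():
    # first component below epsilon: cost falls back to the second band only
    obs = np.array([1e-9, 0.2])
    got = rrmse(obs, np.array([[0.5, 0.1]]))[0]
    assert got == pytest.approx(0.5, abs=1e-12)


def test_all_components_near_zero_is_undefined():
    costs = rrmse(np.array([1e-9]), np.array([[0.5], [0.2]]))
    assert np.all(np.isnan(costs))


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

def test_exact_row_with_k1_returns_that_lai(small_lut):
    q = 1.0 / small_lut.n_entries
    for i in (0, 57, 199):
        sol = g.invert_lut(small_lut.features[i], small_lut, q=q)
        assert sol.n_retained == 1
        assert sol.lai_estimate == small_lut.lai[i]
        assert sol.rrmse_min == 0.0


def test_engineered_five_entry_average():
    # single-band features chosen so costs against obs=1.0 are
    # (0.0, 0.1, 0.2, 0.9, 0.9); q=0.4 keeps ceil(2) entries -> mean(1,2)
    lut = _make_lut([[1.0], [0.9], [0.8], [0.1], [0.1]], [1, 2, 3, 4, 5],
                    g.Strategy(vi_name="NDVI"))
    sol = g.invert_lut(np.array([1.0]), lut, q=0.4)
    assert sol.n_retained == 2
    assert sol.lai_estimate == pytest.approx(1.5)


def test_equidistant_entries_with_full_threshold_average_everything():
    lut = _make_lut([[0.3], [0.5]], [2.0, 6.0], g.Strategy(vi_name="NDVI"))
    sol = g.invert_lut(np.array([0.4]), lut, q=1.0)
    assert sol.n_retained == 2 and sol.lai_estimate == pytest.approx(4.0)


def test_tie_costs_break_by_entry_index():
    lut = _make_lut([[0.5], [0.5], [0.5]], [1.0, 2.0, 3.0], g.Strategy(vi_name="NDVI"))
    sol = g.invert_lut(np.array([0.5]), lut, q=1 / 3)
    assert sol.retained_indices[0] == 0 and sol.lai_estimate == 1.0


def test_matches_brute_force_oracle_on_random_tables():
    rng = np.random.default_rng(17)
    for _ in range(20):
        n = int(rng.integers(5, 400))
        m = int(rng.integers(1, 5))
        feats = rng.uniform(0.05, 0.9, (n, m))
        lais = rng.uniform(0.0, 7.0, n)
        strat = g.Strategy(bands=("B1", "B2", "B3", "B4")[:m]) if m > 1 \
            else g.Strategy(vi_name="NDVI")
        lut = _make_lut(feats, lais, strat)
        obs = rng.uniform(0.05, 0.9, m)
        for q in (1.0 / n, 0.1, 0.5, 1.0):
            k = math.ceil(q * n)
            # independent oracle: plain python cost + stable sort on (cost, idx)
            costs = []
            for i, row in enumerate(feats):
                rel = [((o - c) / o) ** 2 for o, c in zip(obs, row)]
                cost = abs((obs[0] - row[0]) / obs[0]) if m == 1 \
                    else math.sqrt(sum(rel) / m)
                costs.append((cost, i))
            top = sorted(costs)[:k]
            want = sum(lais[i] for _, i in top) / k
            sol = g.invert_lut(obs, lut, q=q)
            assert sol.n_retained == k
            assert sol.lai_estimate == pytest.approx(want, abs=1e-12)


def test_undefined_observation_flags_invalid(small_lut):
    obs = np.zeros(4)
    sol = g.invert_lut(obs, small_lut)
    assert not sol.valid and math.isnan(sol.lai_estimate)


def test_invalid_threshold_rejected(small_lut):
    with pytest.raises(ValueError):
        g.invert_lut(small_lut.features[0], small_lut, q=0.0)
    with pytest.raises(ValueError):
        g.invert_lut(small_lut.features[0], small_lut, q=1.5)


def test_averaging_widens_the_solution_set(lai_spec):
    """On noise-free observations, nearest-neighbour (k=1) inversion is at
    least as accurate (median absolute error) as 10% averaging."""
    lut = g.build_lut(lai_spec, "B1B2B3B4", n_entries=1000, seed=5, noise_sigma=0.0)
    obs_lut = g.build_lut(lai_spec, "B1B2B3B4", n_entries=60, seed=77, noise_sigma=0.0)
    err1, err10 = [], []
    for row, truth in zip(obs_lut.features, obs_lut.lai):
        e1 = g.invert_lut(row, lut, q=1 / lut.n_entries).lai_estimate
        e10 = g.invert_lut(row, lut, q=0.10).lai_estimate
        err1.append(abs(e1 - truth))
        err10.append(abs(e10 - truth))
    assert np.median(err1) <= np.median(err10)


# ---------------------------------------------------------------------------
# construction and serialization
# ---------------------------------------------------------------------------

def test_build_lut_shape_and_range(lai_spec):
    lut = g.build_lut(lai_spec, "MSAVI", n_entries=10, seed=1)
    assert lut.features.shape == (10, 1)
    assert np.all(np.isfinite(lut.features))
    assert np.all((lut.lai >= 0) & (lut.lai <= 7))


def test_build_lut_deterministic(full_spec):
    a = g.build_lut(full_spec, "B2B4", n_entries=50, seed=4, noise_sigma=0.01)
    b = g.build_lut(full_spec, "B2B4", n_entries=50, seed=4, noise_sigma=0.01)
    np.testing.assert_array_equal(a.features, b.features)
    np.testing.assert_array_equal(a.params, b.params)


def test_build_lut_rejects_empty():
    with pytest.raises(ValueError):
        g.build_lut(n_entries=0)


def test_lut_save_load_round_trip(tmp_path, small_lut):
    path = tmp_path / "lut.npz"
    g.save_lut(small_lut, path)
    back = g.load_lut(path)
    np.testing.assert_array_equal(back.features, small_lut.features)
    np.testing.assert_array_equal(back.params, small_lut.params)
    assert back.strategy.name == small_lut.strategy.name
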