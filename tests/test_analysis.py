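"""Analysis statistics against literal brute-force implementations."""

import itertools
from math import comb, log2

import numpy as np
import pytest
from scipy.stats import norm

from chromanet.analysis import (
    cells_to_plateau,
    clustering_coefficient,
    dip_statistic,
    multiple_cell_info,
    select_on_off_cells,
    select_opponent_cells,
    single_cell_info,
    weight_bimodality,
)

# ---------------------------------------------------------------------------
# clustering coefficient
# ---------------------------------------------------------------------------

from _oracles import brute_force_clustering, brute_force_multi_info, brute_force_single_info


def test_clustering_matches_brute_force(make_rate_table):
    rng = np.random.default_rng(0)
    for _ in range(5):
        fr = rng.uniform(0, 20, size=(4, 1, 36))
        table = make_rate_table(fr, rows=6, cols=6)
        got = clustering_coefficient(table, layer="V1L5").C
        want = brute_force_clustering(fr[:, 0, :], 6, 6)
        assert got == pytest.approx(want, abs=1e-10)


def test_clustering_saturates_at_one(make_rate_table):
    # constant positive rates normalize to 1 everywhere -> C = 1
    fr = np.full((3, 1, 25), 7.0)
    with pytest.warns(UserWarning):
        res = clustering_coefficient(make_rate_table(fr, rows=5, cols=5))
    assert res.C == pytest.approx(1.0)


def test_clustering_zero_for_silent_layer(make_rate_table):
    fr = np.zeros((3, 1, 25))
    res = clustering_coefficient(make_rate_table(fr, rows=5, cols=5))
    assert res.C == 0.0


def test_clustering_neighborhood_is_nine(make_rate_table):
    fr = np.random.default_rng(1).uniform(0, 1, size=(2, 1, 36))
    res = clustering_coefficient(make_rate_table(fr, rows=6, cols=6))
    assert res.k == 9


def test_clustering_rewards_spatial_blobs(make_rate_table):
    # a contiguous active block scores higher than the same rates scattered
    rows = cols = 6
    blob = np.zeros(36)
    for r, c in itertools.product(range(3), range(3)):
        blob[r * cols + c] = 10.0
    rng = np.random.default_rng(2)
    scattered = rng.permutation(blob)
    c_blob = clustering_coefficient(make_rate_table(blob[None, None, :], rows=6, cols=6)).C
    c_scat = clustering_coefficient(make_rate_table(scattered[None, None, :], rows=6, cols=6)).C
    assert c_blob > c_scat


# ---------------------------------------------------------------------------
# single-cell information
# ---------------------------------------------------------------------------



def test_single_info_matches_brute_force(make_rate_table):
    rng = np.random.default_rng(3)
    resp = rng.uniform(0, 10, size=(8, 10, 9))
    table = make_rate_table(resp, rows=3, cols=3)
    got = single_cell_info(table, n_bins=8)
    want = brute_force_single_info(resp, 8)
    assert np.allclose(got.per_stimulus_bits, want, atol=1e-10)


def test_eight_stimuli_ceiling_is_three_bits(make_rate_table):
    resp = np.random.default_rng(4).uniform(0, 10, size=(8, 5, 4))
    res = single_cell_info(make_rate_table(resp, rows=2, cols=2))
    assert res.max_bits == pytest.approx(3.0)
    assert np.all(res.single_bits <= 3.0 + 1e-12)


def test_flat_cell_carries_zero_bits(make_rate_table):
    resp = np.full((8, 5, 1), 4.2)
    res = single_cell_info(make_rate_table(resp, rows=1, cols=1))
    assert res.single_bits[0] == 0.0


def test_unique_bin_responder_hits_three_bits(make_rate_table):
    # one cell responding in its own bin for exactly one of 8 equiprobable
    # stimuli: I(that s) = log2(8) = 3 bits
    resp = np.zeros((8, 4, 1))
    resp[5, :, 0] = 10.0
    res = single_cell_info(make_rate_table(resp, rows=1, cols=1))
    assert res.per_stimulus_bits[0, 5] == pytest.approx(3.0)
    assert res.single_bits[0] == pytest.approx(3.0)


def test_single_info_invariant_to_stimulus_relabeling(make_rate_table):
    rng = np.random.default_rng(5)
    resp = rng.uniform(0, 10, size=(8, 6, 5))
    perm = rng.permutation(8)
    a = single_cell_info(make_rate_table(resp, rows=1, cols=5))
    b = single_cell_info(make_rate_table(resp[perm], rows=1, cols=5))
    assert np.allclose(np.sort(a.per_stimulus_bits, axis=1), np.sort(b.per_stimulus_bits, axis=1))
    assert np.allclose(a.single_bits, b.single_bits)


# ---------------------------------------------------------------------------
# multiple-cell information
# ---------------------------------------------------------------------------



def test_multi_info_matches_brute_force(make_rate_table):
    rng = np.random.default_rng(6)
    resp = rng.uniform(0, 10, size=(4, 6, 6))
    table = make_rate_table(resp, rows=2, cols=3)
    res = multiple_cell_info(table, max_cells=4)
    for k in (1, 2, 4):
        want = brute_force_multi_info(resp, res.ranking[:k])
        assert res.multiple_bits[k - 1] == pytest.approx(want, abs=1e-10)


def test_perfect_code_reaches_three_bits(make_rate_table):
    # 8 stimuli, responses cleanly separated per stimulus -> 3 bits
    rng = np.random.default_rng(7)
    resp = np.empty((8, 10, 4))
    for s in range(8):
        resp[s] = 10.0 * s + rng.normal(0, 0.05, size=(10, 4))
    resp -= resp.min()
    res = multiple_cell_info(make_rate_table(resp, rows=2, cols=2), max_cells=4)
    assert res.multiple_bits[-1] == pytest.approx(3.0, abs=1e-6)


def test_uninformative_cells_give_near_zero_bits(make_rate_table):
    # identical response statistics for every stimulus -> decoding at chance
    rng = np.random.default_rng(8)
    resp = rng.normal(5.0, 1.0, size=(8, 40, 3)).clip(min=0)
    res = multiple_cell_info(make_rate_table(resp, rows=1, cols=3), max_cells=3)
    assert res.multiple_bits[-1] < 0.25  # estimator bias at this sample size


def test_multi_info_nondecreasing_with_informative_cells(make_rate_table):
    rng = np.random.default_rng(9)
    means = rng.uniform(0, 10, size=(6, 8))
    resp = means[:, None, :] + rng.normal(0, 0.8, size=(6, 12, 8))
    resp -= resp.min()
    res = multiple_cell_info(make_rate_table(resp, rows=2, cols=4), max_cells=8)
    diffs = np.diff(res.multiple_bits)
    assert np.all(diffs >= -1e-9)


def test_multi_info_bounded_by_ceiling(make_rate_table):
    rng = np.random.default_rng(10)
    resp = rng.uniform(0, 10, size=(8, 6, 5))
    res = multiple_cell_info(make_rate_table(resp, rows=1, cols=5), max_cells=5)
    assert np.all(res.multiple_bits <= 3.0 + 1e-9)
    assert np.all(res.multiple_bits >= 0.0)


def test_cells_to_plateau():
    curve = np.array([1.0, 2.0, 2.8, 2.95, 3.0, 3.0])
    assert cells_to_plateau(curve) == 4  # 2.95 is the first >= 0.95 * 3.0


# ---------------------------------------------------------------------------
# ON/OFF selection
# ---------------------------------------------------------------------------

def test_silent_raster_gives_zero_scores(grid_network, make_raster):
    net = grid_network(6, 6)
    raster = make_raster([], [], on_ms=240.0, off_ms=60.0)
    on_cells, on_counts, off_cells, off_counts = select_on_off_cells(
        raster, net, n_select=30
    )
    assert np.all(on_counts == 0) and np.all(off_counts == 0)
    assert len(on_cells) == 30


def test_known_early_bursters_head_on_ranking(grid_network, make_raster):
    net = grid_network(6, 6)
    offset = net.offset("V1L5")
    bursters = [3, 11, 17, 22, 30]
    cells, times = [], []
    for c in bursters:
        for k in range(6):
            cells.append(offset + c)
            times.append(5.0 + k * 8.0)  # dense burst in the first 60 ms
    for c in range(36):
        cells.append(offset + c)
        times.append(150.0)  # one mid-trial spike each
    raster = make_raster(cells, times, on_ms=240.0, off_ms=60.0)
    on_cells, _, _, _ = select_on_off_cells(raster, net, n_select=5)
    assert sorted(on_cells) == bursters


def test_off_ranking_uses_post_removal_window(grid_network, make_raster):
    net = grid_network(6, 6)
    offset = net.offset("V1L5")
    cells = [offset + 7] * 4 + [offset + 20] * 2
    times = [250.0, 255.0, 260.0, 290.0, 10.0, 20.0]
    raster = make_raster(cells, times, on_ms=240.0, off_ms=60.0)
    _, _, off_cells, off_counts = select_on_off_cells(raster, net, n_select=2)
    assert off_cells[0] == 7 and off_counts[0] == 4


def test_opponent_selection_and_short_flag(grid_network, make_raster):
    net = grid_network(6, 6)
    offset = net.offset("V1L5")
    # red: cells 0..9 burst at onset; green: cells 0..4 burst after removal
    red_cells = [offset + c for c in range(10) for _ in range(5)]
    red_times = [t for _ in range(10) for t in (2.0, 10.0, 20.0, 30.0, 50.0)]
    red = make_raster(red_cells, red_times, on_ms=240.0, off_ms=60.0)
    green_cells = [offset + c for c in range(5) for _ in range(3)]
    green_times = [t for _ in range(5) for t in (245.0, 250.0, 280.0)]
    green = make_raster(green_cells, green_times, on_ms=240.0, off_ms=60.0)
    sel = select_opponent_cells(
        {"red": red, "green": green}, net, "red", "green", n_pool=10, n_select=5
    )
    assert not sel.short
    assert sorted(sel.cells) == list(range(5))
    strict = select_opponent_cells(
        {"red": red, "green": green}, net, "red", "green", n_pool=10, n_select=8
    )
    assert strict.short and len(strict.cells) == 5


def test_degenerate_same_color_selection(grid_network, make_raster):
    net = grid_network(6, 6)
    offset = net.offset("V1L5")
    cells = [offset + 1] * 4
    times = [5.0, 30.0, 250.0, 270.0]  # early- and late-active cell
    raster = make_raster(cells, times, on_ms=240.0, off_ms=60.0)
    sel = select_opponent_cells({"red": raster}, net, "red", "red", n_pool=5, n_select=1)
    assert list(sel.cells) == [1]


# ---------------------------------------------------------------------------
# weight bimodality
# ---------------------------------------------------------------------------

def test_uniform_weights_near_bound_fraction():
    rng = np.random.default_rng(11)
    w = rng.uniform(0, 1, size=20000)
    res = weight_bimodality(w, 0.0, 1.0)
    assert res.near_bound_fraction == pytest.approx(0.2, abs=0.02)


def test_saturated_weights_fraction_one():
    w = np.concatenate([np.zeros(50), np.ones(50)])
    res = weight_bimodality(w, 0.0, 1.0)
    assert res.near_bound_fraction == 1.0


def test_dip_separates_bimodal_from_unimodal():
    rng = np.random.default_rng(12)
    unimodal = rng.normal(0.5, 0.1, size=3000)
    bimodal = np.concatenate(
        [rng.normal(0.1, 0.03, size=1500), rng.normal(0.9, 0.03, size=1500)]
    )
    assert dip_statistic(bimodal) > 3 * dip_statistic(unimodal)


def test_too_few_weights_rejected():
    with pytest.raises(ValueError):
        weight_bimodality(np.ones(5), 0.0, 1.0)
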