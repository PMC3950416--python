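"""Cone transform, input spike trains and the synthetic patch generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromanet.stimuli import (
    ColorPatch,
    color_transforms,
    corner_colors,
    generate_input_spikes,
    named_test_colors,
    regular_train,
    rgb_to_cone_rates,
    synth_patch_sampler,
    uniform_patch,
)


def cone_rates(rgb):
    d = rgb_to_cone_rates(uniform_patch(rgb, 1, 1))
    return d.l_hz[0, 0], d.m_hz[0, 0], d.s_hz[0, 0]


@pytest.mark.parametrize(
    "rgb, expected",
    [
        ((0, 0, 0), (0.0, 0.0, 0.0)),
        ((1, 1, 1), (40.0, 40.0, 40.0)),
        ((1, 0, 0), (40.0 / 1.95, 40.0 * 0.7 / 1.95, 0.0)),
        ((0, 1, 0), (40.0 * 0.7 / 1.95, 40.0 / 1.95, 0.0)),
        ((0, 0, 1), (40.0 * 0.25 / 1.95, 40.0 * 0.25 / 1.95, 40.0)),
    ],
)
def test_cone_transform_values(rgb, expected):
    l, m, s = cone_rates(rgb)
    assert (l, m, s) == pytest.approx(expected, abs=1e-9)


def test_cone_transform_monotone_in_each_channel():
    rng = np.random.default_rng(3)
    for _ in range(50):
        base = rng.uniform(0, 0.9, size=3)
        l0, m0, s0 = cone_rates(base)
        for ch in range(3):
            up = base.copy()
            up[ch] += 0.1
            l1, m1, s1 = cone_rates(up)
            assert l1 >= l0 and m1 >= m0 and s1 >= s0


def test_l_exceeds_m_iff_red_exceeds_green():
    rng = np.random.default_rng(4)
    for _ in range(100):
        rgb = rng.uniform(0, 1, size=3)
        l, m, _ = cone_rates(rgb)
        if rgb[0] > rgb[1]:
            assert l > m
        elif rgb[0] < rgb[1]:
            assert l < m
        else:
            assert l == pytest.approx(m)


@given(
    rgb=st.tuples(
        st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0)
    )
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_cone_rates_bounded_and_ordered(rgb):
    """For any color: rates lie in [0, 40] Hz and the L/M ordering
    follows the R/G ordering (symmetry of the transform)."""
    l, m, s = cone_rates(rgb)
    for x in (l, m, s):
        assert 0.0 <= x <= 40.0 + 1e-9
    if rgb[0] > rgb[1]:
        assert l > m
    elif rgb[0] < rgb[1]:
        assert l < m


def test_out_of_range_patch_rejected():
    with pytest.raises(ValueError):
        ColorPatch(np.full((2, 2, 3), 1.5))


def test_regular_train_at_40hz():
    spikes = regular_train(40.0, 300.0, phase=0.0)
    assert len(spikes) == 12
    assert np.allclose(spikes, np.arange(0, 300, 25.0))


def test_zero_rate_is_silent():
    assert len(regular_train(0.0, 300.0)) == 0
    trains = generate_input_spikes(np.zeros(5), 300.0, 0.1, np.random.default_rng(0))
    assert all(len(t) == 0 for t in trains)


@pytest.mark.parametrize("f", [7.0, 13.5, 40.0])
def test_noise_free_counts_match_rate(f):
    spikes = regular_train(f, 1000.0, phase=0.0)
    assert abs(len(spikes) - round(f)) <= 1


def test_onset_phases_span_one_interspike_interval():
    """Equal-rate cells with different phases end up to ~one ISI apart."""
    rates = np.full(200, 40.0)
    phases = np.random.default_rng(5).uniform(0, 1, size=200)
    trains = generate_input_spikes(rates, 240.0, 0.0, np.random.default_rng(0), phases)
    last = np.array([t[-1] for t in trains])
    spread = last.max() - last.min()
    assert 20.0 <= spread < 25.0  # up to 24 ms of final-spike offset


def test_rate_noise_bounds():
    rates = np.full(500, 40.0)
    trains = generate_input_spikes(rates, 1000.0, 0.1, np.random.default_rng(6))
    counts = np.array([len(t) for t in trains])
    assert counts.min() >= 35 and counts.max() <= 45  # 40 Hz +/- 10 %


def test_corner_palette_is_cube_corners():
    vals = sorted(corner_colors().values())
    assert len(vals) == 8
    assert all(set(v) <= {0.0, 1.0} for v in vals)
    assert len(set(vals)) == 8


def test_named_palette_has_eight_distinct_hues():
    pal = named_test_colors()
    assert len(pal) == 8
    assert (0, 0, 0) not in pal.values()


def test_color_transforms_shape_and_scale():
    rng = np.random.default_rng(7)
    variants = color_transforms((1.0, 0.5, 0.0), 10, 0.01, rng)
    assert variants.shape == (10, 3)
    assert np.allclose(variants[0], (1.0, 0.5, 0.0))
    assert np.all(variants[:, 2] == 0.0)  # zero channel stays zero
    assert np.all(np.abs(variants[1:, 1] - 0.5) <= 0.005 + 1e-12)


def test_uniform_color_corner_only_patches():
    rng = np.random.default_rng(8)
    for patch in synth_patch_sampler(20, (5, 5), rng, style="uniform_color", corner_only=True):
        assert set(np.unique(patch.pixels)) <= {0.0, 1.0}
        assert len(np.unique(patch.pixels.reshape(-1, 3), axis=0)) == 1


def test_smooth_field_channel_means_cover_midrange():
    rng = np.random.default_rng(9)
    means = np.array(
        [p.pixels.mean(axis=(0, 1)) for p in synth_patch_sampler(2000, (10, 10), rng)]
    )
    assert np.all(means.mean(axis=0) >= 0.3)
    assert np.all(means.mean(axis=0) <= 0.7)


def test_smooth_field_is_spatially_correlated():
    rng = np.random.default_rng(10)
    patch = next(synth_patch_sampler(1, (10, 10), rng))
    ch = patch.pixels[..., 0]
    neighbor_diff = np.abs(np.diff(ch, axis=0)).mean()
    shuffled = rng.permutation(ch.ravel()).reshape(ch.shape)
    shuffled_diff = np.abs(np.diff(shuffled, axis=0)).mean()
    assert neighbor_diff < shuffled_diff


def test_natural_mix_spans_soft_and_saturated_patches():
    rng = np.random.default_rng(12)
    patches = list(synth_patch_sampler(300, (5, 5), rng, style="natural_mix"))
    saturated = np.mean(
        [np.mean((p.pixels < 0.05) | (p.pixels > 0.95)) for p in patches]
    )
    assert 0.02 < saturated < 0.5  # mixture includes saturated hues
    means = np.array([p.pixels.mean() for p in patches])
    assert 0.3 < means.mean() < 0.7


def test_sampler_deterministic_under_seed():
    a = [p.pixels for p in synth_patch_sampler(5, (6, 6), np.random.default_rng(11), style="two_tone")]
    b = [p.pixels for p in synth_patch_sampler(5, (6, 6), np.random.default_rng(11), style="two_tone")]
    for x, y in zip(a, b):
        assert np.array_equal(x, y)
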