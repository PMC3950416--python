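"""Simulation engine: determinism, delays, plasticity integration."""

import numpy as np
import pytest

from chromanet.circuit import LayerSpec, NetworkModel, Projection, build_network
from chromanet.engine import Simulator
from chromanet.membrane import (
    AMPA,
    GABA,
    MembraneParams,
    advance_neuron,
    deliver_synaptic_event,
    resting_state,
)
from chromanet.stimuli import regular_train, uniform_patch
from chromanet.workbench import preset


@pytest.fixture(scope="module")
def mini_cfg():
    return preset(
        "desk_small",
        photoreceptor_dims=(3, 3),
        lgn_dims=(6, 6),
        v1_dims=(6, 6),
    )


@pytest.fixture(scope="module")
def mini_sim(mini_cfg):
    return Simulator(build_network(mini_cfg), mini_cfg)


def white(cfg):
    return uniform_patch((1, 1, 1), *cfg.photoreceptor_dims)


def test_black_patch_is_silent(mini_sim, mini_cfg):
    raster = mini_sim.run_trial(
        uniform_patch((0, 0, 0), 3, 3), rule="frozen", rng=np.random.default_rng(0)
    )
    assert raster.n_spikes == 0


def test_trials_bit_identical_under_seed(mini_cfg):
    def once():
        sim = Simulator(build_network(mini_cfg), mini_cfg)
        return sim.run_trial(white(mini_cfg), rule="frozen", rng=np.random.default_rng(7))

    a, b = once(), once()
    assert np.array_equal(a.cells, b.cells)
    assert np.array_equal(a.times, b.times)


def test_raster_sorted_and_in_range(mini_sim, mini_cfg):
    raster = mini_sim.run_trial(white(mini_cfg), rule="frozen", rng=np.random.default_rng(1))
    assert np.all(np.diff(raster.times) >= 0)
    assert raster.times.min() >= 0.0
    assert raster.times.max() <= raster.duration_ms
    assert raster.n_spikes > 0


def test_no_runaway_excitation(mini_sim, mini_cfg):
    # every cell stays below 200 Hz in a fully driven trial
    raster = mini_sim.run_trial(white(mini_cfg), rule="frozen", rng=np.random.default_rng(2))
    for nm in ("L", "C1", "C2", "V1L4", "V1L23", "V1L5"):
        assert raster.layer_rates(mini_sim.network, nm).max() < 200.0


def test_frozen_rule_keeps_weights(mini_cfg):
    net = build_network(mini_cfg)
    before = {p.name: p.weight.copy() for p in net.projections}
    sim = Simulator(net, mini_cfg)
    sim.run_trial(white(mini_cfg), rule="frozen", rng=np.random.default_rng(3))
    for p in net.projections:
        assert np.array_equal(p.weight, before[p.name])


def test_stdp_trial_updates_only_plastic_projections(mini_cfg):
    net = build_network(mini_cfg)
    before = {p.name: p.weight.copy() for p in net.projections}
    sim = Simulator(net, mini_cfg)
    sim.run_trial(white(mini_cfg), rule="stdp", rng=np.random.default_rng(4))
    changed = 0
    for p in net.projections:
        if p.plastic:
            changed += int(not np.array_equal(p.weight, before[p.name]))
            # normalization keeps the mean at mid-range
            assert p.weight.mean() == pytest.approx(
                0.5 * (p.w_min + p.w_max), abs=1e-6
            )
        else:
            assert np.array_equal(p.weight, before[p.name])
    assert changed >= 1


def test_zero_iterations_changes_nothing(mini_cfg):
    net = build_network(mini_cfg)
    before = {p.name: p.weight.copy() for p in net.projections}
    sim = Simulator(net, mini_cfg)
    trace = sim.train(n_iterations=0)
    assert len(trace) == 0
    for p in net.projections:
        assert np.array_equal(p.weight, before[p.name])


def test_color_transforms_identical_without_noise_or_frac(mini_cfg):
    cfg = mini_cfg.replace(noise_frac=0.0)
    sim = Simulator(build_network(cfg), cfg)
    table = sim.test_colors(
        colors={"red": (1, 0, 0)}, n_transforms=3, transform_frac=0.0, duration_ms=200.0
    )
    assert np.array_equal(table.rates_hz[0, 0], table.rates_hz[0, 1])
    assert np.array_equal(table.rates_hz[0, 0], table.rates_hz[0, 2])


def test_on_off_protocol_silences_input_after_removal(mini_sim, mini_cfg):
    rasters = mini_sim.on_off_protocol(colors={"white": (1, 1, 1)})
    raster = rasters["white"]
    on_ms = raster.metadata["on_ms"]
    assert on_ms == 240.0 and raster.metadata["off_ms"] == 60.0
    n_in = mini_sim.n_input
    input_times = raster.times[raster.cells < n_in]
    assert input_times.max() < on_ms


def test_protocol_defaults_match_run_configuration(mini_cfg):
    assert preset("paper_full").n_iterations == 2000
    assert preset("paper_full").iteration_ms == 300.0
    assert mini_cfg.on_ms == 240.0 and mini_cfg.off_ms == 60.0


# ---------------------------------------------------------------------------
# kernel vs scalar reference
# ---------------------------------------------------------------------------

def _single_synapse_network(weight, is_gaba, delay_ms):
    layers = [LayerSpec(nm, 1, 1) for nm in ("R", "G", "B")]
    layers.append(LayerSpec("L", 1, 1))
    proj = Projection(
        name="R->L",
        source="R",
        target="L",
        src=np.zeros(1, dtype=np.int64),
        tgt=np.zeros(1, dtype=np.int64),
        weight=np.full(1, weight),
        delay_ms=np.full(1, delay_ms),
        is_gaba=np.array([is_gaba]),
        plastic=False,
    )
    return NetworkModel(
        layers=layers,
        projections=[proj],
        membrane=MembraneParams(),
        ampa=AMPA,
        gaba=GABA,
        input_phases=np.zeros(3),
        seed=0,
    )


@pytest.mark.parametrize("is_gaba, delay", [(False, 1.0), (True, 4.0)])
def test_kernel_matches_scalar_path_with_delays(is_gaba, delay):
    """The jitted loop reproduces the scalar neuron driven by the same
    events shifted by exactly the synaptic delay."""
    from chromanet.config import RunConfig

    dt = 0.05
    weight = 0.03
    cfg = RunConfig(
        photoreceptor_dims=(1, 1),
        lgn_dims=(1, 1),
        v1_dims=(1, 1),
        dt_ms=dt,
        noise_frac=0.0,
        input_delays=False,
        plasticity_rule="frozen",
    )
    net = _single_synapse_network(weight, is_gaba, delay)
    sim = Simulator(net, cfg)
    raster = sim.run_trial(
        uniform_patch((1, 0, 0), 1, 1), rule="frozen", rng=np.random.default_rng(0),
        duration_ms=300.0,
    )
    _, kernel_spikes = raster.layer_events(net, "L")

    # scalar reference: the same input train, events delayed by `delay`
    in_rate = 40.0 / 1.95  # L-cone rate for pure red
    in_times = regular_train(in_rate, 300.0)
    ev_steps = {int(round(t / dt)) + int(round(delay / dt)) for t in in_times}
    state = resting_state(MembraneParams())
    ref_spikes = []
    for step in range(int(round(300.0 / dt))):
        if step in ev_steps:
            state = deliver_synaptic_event(state, "GABA" if is_gaba else "AMPA", weight)
        state, spiked = advance_neuron(state, MembraneParams(), dt)
        if spiked:
            ref_spikes.append(state.t_ms)
    assert np.allclose(kernel_spikes, ref_spikes, atol=1e-9)
    if not is_gaba:
        assert len(kernel_spikes) > 0
    else:
        assert len(kernel_spikes) == 0
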