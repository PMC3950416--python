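"""Single-neuron dynamics: fixed point, spiking, synapse arithmetic."""

import math

import numpy as np
import pytest

from chromanet.membrane import (
    AMPA,
    GABA,
    MembraneParams,
    NeuronState,
    advance_neuron,
    deliver_synaptic_event,
    resting_potential,
    resting_state,
)

PARAMS = MembraneParams()


def integrate(
    state,
    params,
    dt,
    t_total,
    injected=0.0,
    events=None,
):
    """Drive one neuron; returns (final state, spike times).

    ``events`` is a list of (time_ms, kind, weight) delivered at the
    step boundary nearest their time.
    """
    events = sorted(events or [], key=lambda e: e[0])
    n_steps = int(round(t_total / dt))
    spikes = []
    ei = 0
    for step in range(n_steps):
        t = step * dt
        while ei < len(events) and events[ei][0] <= t + 1e-12:
            _, kind, w = events[ei]
            state = deliver_synaptic_event(state, kind, w)
            ei += 1
        state, spiked = advance_neuron(state, params, dt, injected_nA=injected)
        if spiked:
            spikes.append(state.t_ms)
    return state, np.array(spikes)


def find_suprathreshold_current(params, dt=0.025):
    """Smallest scanned current giving sustained repetitive spiking.

    The f-I relation is non-monotone (depolarization block at strong
    drive), so this scans upward from zero and refines by bisection
    within the first repetitively firing interval.
    """
    coarse = None
    for i in np.arange(0.05, 1.0, 0.05):
        _, spikes = integrate(resting_state(params), params, dt, 300.0, injected=i)
        if len(spikes) >= 8:
            coarse = i
            break
    assert coarse is not None, "no repetitively spiking current found"
    lo, hi = coarse - 0.05, coarse
    for _ in range(8):
        mid = 0.5 * (lo + hi)
        _, spikes = integrate(resting_state(params), params, dt, 300.0, injected=mid)
        if len(spikes) >= 8:
            hi = mid
        else:
            lo = mid
    return hi


def test_resting_state_is_fixed_point():
    state = resting_state(PARAMS)
    v0 = state.v_mV
    for _ in range(100):
        state, spiked = advance_neuron(state, PARAMS, 0.025)
        assert not spiked
    assert abs(state.v_mV - v0) < 1e-9 * 100


def test_resting_potential_near_minus_65():
    # absolute-convention leak at -65 mV plus the standing K+ current
    v = resting_potential(PARAMS)
    assert -80.0 < v < -60.0


def test_constant_current_gives_regular_spiking():
    i_inj = find_suprathreshold_current(PARAMS)
    _, spikes = integrate(resting_state(PARAMS), PARAMS, 0.025, 300.0, injected=i_inj)
    assert len(spikes) >= 5
    isis = np.diff(spikes)[2:]  # after the third spike
    assert isis.std() / isis.mean() < 0.01


def test_spike_times_converge_with_dt():
    """Halving dt moves each spike of a 300 ms driven trial by < 0.5 ms,
    and the shift shrinks with further refinement."""
    i_inj = find_suprathreshold_current(PARAMS) * 1.3
    times = {}
    for dt in (0.025, 0.0125, 0.0025):
        _, spikes = integrate(resting_state(PARAMS), PARAMS, dt, 300.0, injected=i_inj)
        times[dt] = spikes
    counts = {dt: len(v) for dt, v in times.items()}
    assert min(counts.values()) >= 5
    assert counts[0.025] == counts[0.0025]
    n = min(counts.values())
    shift_halving = np.abs(times[0.025][:n] - times[0.0125][:n]).max()
    shift_fine = np.abs(times[0.0125][:n] - times[0.0025][:n]).max()
    assert shift_halving < 0.5
    assert shift_fine < shift_halving


def test_ampa_peak_depolarization_monotone_in_weight():
    peaks = []
    for w in [0.001, 0.002, 0.004, 0.008, 0.016]:
        state = resting_state(PARAMS)
        state = deliver_synaptic_event(state, "AMPA", w)
        v_peak = state.v_mV
        for _ in range(int(20.0 / 0.025)):
            state, _ = advance_neuron(state, PARAMS, 0.025)
            v_peak = max(v_peak, state.v_mV)
        peaks.append(v_peak)
    assert all(b > a for a, b in zip(peaks, peaks[1:]))


def test_zero_weight_event_is_identity():
    state = resting_state(PARAMS)
    out = deliver_synaptic_event(state, "AMPA", 0.0)
    assert out == state


def test_simultaneous_events_sum_linearly():
    state = resting_state(PARAMS)
    twice = deliver_synaptic_event(deliver_synaptic_event(state, "GABA", 0.003), "GABA", 0.003)
    once = deliver_synaptic_event(state, "GABA", 0.006)
    assert twice.g_gaba_uS == pytest.approx(once.g_gaba_uS)


def test_negative_weight_rejected():
    with pytest.raises(ValueError):
        deliver_synaptic_event(resting_state(PARAMS), "AMPA", -1e-3)


def test_gaba_current_smaller_near_reversal():
    # i_syn = g (v - e_rev): clamped near -80 mV the driving force vanishes
    g = 0.005
    i_near = abs(g * (-79.0 - GABA.e_rev_mV))
    i_far = abs(g * (-50.0 - GABA.e_rev_mV))
    assert i_near < i_far


def test_conductance_decay_exact_exponential():
    state = resting_state(PARAMS)
    state = deliver_synaptic_event(state, "AMPA", 0.01)
    state = deliver_synaptic_event(state, "GABA", 0.02)
    g_a0, g_g0 = state.g_ampa_uS, state.g_gaba_uS
    dt, n = 0.025, 400
    for _ in range(n):
        state, _ = advance_neuron(state, PARAMS, dt)
    assert state.g_ampa_uS == pytest.approx(g_a0 * math.exp(-n * dt / AMPA.tau_ms), rel=1e-12)
    assert state.g_gaba_uS == pytest.approx(g_g0 * math.exp(-n * dt / GABA.tau_ms), rel=1e-12)


def test_gating_variables_stay_in_unit_interval():
    state = resting_state(PARAMS)
    rng = np.random.default_rng(0)
    for step in range(int(1000.0 / 0.025)):
        if rng.random() < 0.002:
            state = deliver_synaptic_event(state, "AMPA", 0.02)
        state, _ = advance_neuron(state, PARAMS, 0.025)
        assert 0.0 <= state.m <= 1.0
        assert 0.0 <= state.h <= 1.0
        assert 0.0 <= state.n <= 1.0


def test_silence_without_input():
    _, spikes = integrate(resting_state(PARAMS), PARAMS, 0.025, 1000.0)
    assert len(spikes) == 0


def test_dt_out_of_range_rejected():
    with pytest.raises(ValueError):
        advance_neuron(resting_state(PARAMS), PARAMS, 0.2)


def test_divergence_reported():
    from chromanet.membrane import IntegrationDivergedError

    bad = NeuronState(v_mV=float("nan"), m=0.5, h=0.5, n=0.5)
    with pytest.raises(IntegrationDivergedError):
        advance_neuron(bad, PARAMS, 0.025)
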