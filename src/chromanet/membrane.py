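"""Single-compartment Hodgkin-Huxley neuron with conductance synapses.

The neuron is a cylindrical compartment (default 30 um diameter, 10 um
length) carrying classic squid-axon Na+/K+ channels, a passive leak and
two synaptic conductances (AMPA and GABA) that rise instantaneously on
each presynaptic event and decay exponentially with their own time
constant.  All voltages are absolute membrane potentials in mV (rest
near -65 mV), times are ms, conductances uS, currents nA and the total
capacitance nF, so that ``C dv/dt`` and ``g (v - e_rev)`` combine
without unit factors.

Integration is fixed-step: exponential Euler for the gating variables
and a forward update for the voltage.  A spike is an upward crossing of
0 mV outside a 2 ms refractory lockout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MembraneParams",
    "SynapseParams",
    "NeuronState",
    "IntegrationDivergedError",
    "AMPA",
    "GABA",
    "advance_neuron",
    "deliver_synaptic_event",
    "resting_potential",
    "resting_state",
]

# With the model's high capacitive density (10 uF/cm^2) action potentials
# are slow and, under sustained drive, peak well below 0 mV once Na+
# inactivation builds up; detection therefore sits at -20 mV, far above
# any passive EPSP yet below the reduced overshoot of repetitive spikes.
SPIKE_THRESHOLD_MV = -20.0
REFRACTORY_MS = 2.0


class IntegrationDivergedError(RuntimeError):
    """Raised when a state variable leaves the finite range during a step."""


@dataclass(frozen=True)
class MembraneParams:
    """Passive and active membrane properties of one compartment.

    Conductances are specified as densities over the compartment surface;
    totals in uS are exposed as properties.  ``axial_resistivity`` is kept
    for fidelity with the source compartment description but plays no role
    in a single compartment.

    The leak is parameterised as a density (S/cm^2) by default.  Setting
    ``leak_total_nS`` switches to an absolute leak conductance, the
    alternative reading of the published constant (see
    :meth:`literal_published`).
    """

    diameter_um: float = 30.0
    length_um: float = 10.0
    axial_resistivity_ohm_cm: float = 100.0
    cm_uF_per_cm2: float = 10.0
    leak_S_per_cm2: float = 1e-4
    leak_total_nS: float | None = None
    e_leak_mV: float = -65.0
    gna_mS_per_cm2: float = 120.0
    gk_mS_per_cm2: float = 36.0
    e_na_mV: float = 50.0
    e_k_mV: float = -77.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.length_um <= 0:
            raise ValueError("compartment dimensions must be positive")
        if self.cm_uF_per_cm2 <= 0:
            raise ValueError("capacitance density must be positive")
        for name in ("leak_S_per_cm2", "gna_mS_per_cm2", "gk_mS_per_cm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def area_cm2(self) -> float:
        # lateral surface of the cylinder; end caps ignored as usual
        return math.pi * self.diameter_um * 1e-4 * self.length_um * 1e-4

    @property
    def c_total_nF(self) -> float:
        return self.cm_uF_per_cm2 * self.area_cm2 * 1e3  # uF -> nF

    @property
    def g_leak_uS(self) -> float:
        if self.leak_total_nS is not None:
            return self.leak_total_nS * 1e-3
        return self.leak_S_per_cm2 * self.area_cm2 * 1e6  # S -> uS

    @property
    def g_na_uS(self) -> float:
        return self.gna_mS_per_cm2 * self.area_cm2 * 1e3  # mS -> uS

    @property
    def g_k_uS(self) -> float:
        return self.gk_mS_per_cm2 * self.area_cm2 * 1e3

    @classmethod
    def literal_published(cls) -> "MembraneParams":
        """The published constants read literally.

        An absolute leak of 0.001 nS over this compartment and a leak
        reversal of 0 mV.  With ~0.094 nF of capacitance this leak alone
        gives a ~100 s membrane time constant, which is why the default
        parameter set instead interprets the leak as a density and uses
        the absolute voltage convention (rest near -65 mV).  Both
        readings are preserved; neither is asserted as ground truth.
        """
        return cls(leak_total_nS=0.001, e_leak_mV=0.0)


@dataclass(frozen=True)
class SynapseParams:
    """Exponential-decay conductance synapse (kind, tau in ms, reversal in mV)."""

    kind: str
    tau_ms: float
    e_rev_mV: float

    def __post_init__(self) -> None:
        if self.kind not in ("AMPA", "GABA"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.tau_ms <= 0:
            raise ValueError("tau must be positive")


AMPA = SynapseParams("AMPA", tau_ms=5.0, e_rev_mV=0.0)
GABA = SynapseParams("GABA", tau_ms=10.0, e_rev_mV=-80.0)


@dataclass
class NeuronState:
    """Dynamical state of one neuron at time ``t_ms``."""

    v_mV: float
    m: float
    h: float
    n: float
    g_ampa_uS: float = 0.0
    g_gaba_uS: float = 0.0
    t_ms: float = 0.0
    last_spike_ms: float | None = None
    refractory_until_ms: float = -math.inf

    def copy(self) -> "NeuronState":
        return replace(self)


# ---------------------------------------------------------------------------
# Gating kinetics (absolute voltage convention; rest near -65 mV)
# ---------------------------------------------------------------------------

def alpha_m(v: float) -> float:
    x = v + 40.0
    if abs(x) < 1e-7:
        return 1.0
    return 0.1 * x / (1.0 - math.exp(-x / 10.0))


def beta_m(v: float) -> float:
    return 4.0 * math.exp(-(v + 65.0) / 18.0)


def alpha_h(v: float) -> float:
    return 0.07 * math.exp(-(v + 65.0) / 20.0)


def beta_h(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))


def alpha_n(v: float) -> float:
    x = v + 55.0
    if abs(x) < 1e-7:
        return 0.1
    return 0.01 * x / (1.0 - math.exp(-x / 10.0))


def beta_n(v: float) -> float:
    return 0.125 * math.exp(-(v + 65.0) / 80.0)


def _steady_state_current(v: float, p: MembraneParams) -> float:
    m = alpha_m(v) / (alpha_m(v) + beta_m(v))
    h = alpha_h(v) / (alpha_h(v) + beta_h(v))
    n = alpha_n(v) / (alpha_n(v) + beta_n(v))
    i_leak = p.g_leak_uS * (v - p.e_leak_mV)
    i_na = p.g_na_uS * m**3 * h * (v - p.e_na_mV)
    i_k = p.g_k_uS * n**4 * (v - p.e_k_mV)
    return i_leak + i_na + i_k


def resting_potential(params: MembraneParams) -> float:
    """Zero of the steady-state current in [-90, -40] mV."""
    return brentq(_steady_state_current, -90.0, -40.0, args=(params,), xtol=1e-12)


def resting_state(params: MembraneParams) -> NeuronState:
    """A fixed point of the dynamics: v at rest, gating at steady state."""
    v = resting_potential(params)
    return NeuronState(
        v_mV=v,
        m=alpha_m(v) / (alpha_m(v) + beta_m(v)),
        h=alpha_h(v) / (alpha_h(v) + beta_h(v)),
        n=alpha_n(v) / (alpha_n(v) + beta_n(v)),
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def deliver_synaptic_event(state: NeuronState, kind: str, weight_uS: float) -> NeuronState:
    """Instantaneous conductance increment of one synaptic event.

    Multiple simultaneous events sum linearly; all other state fields are
    untouched.
    """
    if weight_uS < 0:
        raise ValueError("synaptic weight must be non-negative")
    out = state.copy()
    if kind == "AMPA":
        out.g_ampa_uS += weight_uS
    elif kind == "GABA":
        out.g_gaba_uS += weight_uS
    else:
        raise ValueError(f"unknown synapse kind {kind!r}")
    return out


def advance_neuron(
    state: NeuronState,
    params: MembraneParams,
    dt_ms: float,
    ampa: SynapseParams = AMPA,
    gaba: SynapseParams = GABA,
    injected_nA: float = 0.0,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by ``dt_ms``; return the new state and spike flag.

    One step comprises, in order: exponential decay of both synaptic
    conductances, exponential-Euler update of the gating variables at the
    pre-step voltage, and a forward voltage update using the fresh gating
    values.  A spike is reported when the voltage crosses 0 mV upward and
    the refractory lockout (2 ms from the previous spike) has expired.
    """
    if not (0.0 < dt_ms <= 0.1):
        raise ValueError("dt must be in (0, 0.1] ms")
    v0 = state.v_mV
    out = state.copy()

    out.g_ampa_uS = state.g_ampa_uS * math.exp(-dt_ms / ampa.tau_ms)
    out.g_gaba_uS = state.g_gaba_uS * math.exp(-dt_ms / gaba.tau_ms)

    for var, a, b in (("m", alpha_m, beta_m), ("h", alpha_h, beta_h), ("n", alpha_n, beta_n)):
        av, bv = a(v0), b(v0)
        inf = av / (av + bv)
        tau = 1.0 / (av + bv)
        x = getattr(state, var)
        setattr(out, var, inf + (x - inf) * math.exp(-dt_ms / tau))

    i_leak = params.g_leak_uS * (v0 - params.e_leak_mV)
    i_na = params.g_na_uS * out.m**3 * out.h * (v0 - params.e_na_mV)
    i_k = params.g_k_uS * out.n**4 * (v0 - params.e_k_mV)
    i_syn = out.g_ampa_uS * (v0 - ampa.e_rev_mV) + out.g_gaba_uS * (v0 - gaba.e_rev_mV)
    out.v_mV = v0 + dt_ms * (injected_nA - i_leak - i_na - i_k - i_syn) / params.c_total_nF
    out.t_ms = state.t_ms + dt_ms

    for name in ("v_mV", "m", "h", "n", "g_ampa_uS", "g_gaba_uS"):
        if not np.isfinite(getattr(out, name)):
            raise IntegrationDivergedError(
                f"non-finite {name} after step of dt={dt_ms} ms at t={out.t_ms} ms"
            )

    spiked = False
    if v0 < SPIKE_THRESHOLD_MV <= out.v_mV and out.t_ms >= state.refractory_until_ms:
        spiked = True
        out.last_spike_ms = out.t_ms
        out.refractory_until_ms = out.t_ms + REFRACTORY_MS
    return out, spiked
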