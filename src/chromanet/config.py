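"""Run configuration: every model constant in one structured object.

The configuration collects the published constants (layer dimensions,
40 Hz input ceiling, 10 % rate noise, STDP windows 17/34 ms, synaptic
delays 1/4 ms, 2000 x 300 ms training, 240/60 ms ON/OFF testing)
together with the constants the source leaves open (feed-forward radius,
lateral radii and sparsity, conductance gains, learning rate), all of
which are exposed here and documented in ``SYMBOL_MAP``.

Configurations round-trip through YAML via :meth:`RunConfig.to_yaml` /
:meth:`RunConfig.from_yaml`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .membrane import MembraneParams, SynapseParams, AMPA, GABA
from .plasticity import STDPParams

__all__ = ["RunConfig", "SYMBOL_MAP"]

# mapping from configuration keys to the symbols / phrases used in the
# model description they encode
SYMBOL_MAP = {
    "photoreceptor_dims": "photoreceptor layer dimensions (10 x 10)",
    "lgn_dims": "LGN layer dimensions (30 x 30)",
    "v1_dims": "V1 layer dimensions (30 x 30)",
    "max_rate_hz": "maximum photoreceptor activation frequency (40 Hz)",
    "noise_frac": "input rate noise (10 %)",
    "delay_exc_ms": "excitatory synaptic delay (1 ms)",
    "delay_inh_ms": "inhibitory synaptic delay (4 ms)",
    "stdp.p_tau_ms": "p_tau, potentiation window (17 ms)",
    "stdp.d_tau_ms": "d_tau, depression window (34 ms)",
    "stdp.lr": "LR, learning rate (not published; default 1e-3 * w_max)",
    "n_iterations": "training iterations (2000)",
    "iteration_ms": "presentation length per iteration (300 ms)",
    "on_ms": "stimulus-ON window for ON/OFF testing (240 ms)",
    "off_ms": "no-input window for ON/OFF testing (60 ms)",
    "membrane.cm_uF_per_cm2": "Cm, capacitive density (10 uF/cm^2)",
    "membrane.leak_S_per_cm2": "g_pas read as a density (see membrane module)",
    "membrane.e_leak_mV": "e_leak in the absolute voltage convention",
    "ampa": "AMPA synapse (tau 5 ms, e_rev 0 mV)",
    "gaba": "GABA synapse (tau 10 ms, e_rev -80 mV)",
    "r_ff": "feed-forward convergence radius (not published)",
    "r_exc/r_inh/p_connect": "Mexican-hat radii and sparsity (not published)",
    "g_lgn_uS": "fixed photoreceptor->LGN weight per signed term (calibrated)",
    "w_min_uS/w_max_uS": "plastic weight range (calibrated)",
    "w_lat_exc_uS/w_lat_inh_uS": "lateral weights (calibrated)",
}


@dataclass(frozen=True)
class RunConfig:
    # architecture
    photoreceptor_dims: tuple[int, int] = (10, 10)
    lgn_dims: tuple[int, int] = (30, 30)
    v1_dims: tuple[int, int] = (30, 30)
    r_ff: int = 1
    r_exc: int = 1
    r_inh: int = 3
    p_connect: float = 0.5

    # synaptic conductances (uS) and delays (ms)
    g_lgn_uS: float = 0.008
    w_min_uS: float = 0.0
    w_max_uS: float = 0.0012
    w_lat_exc_uS: float = 0.004
    w_lat_inh_uS: float = 0.002
    delay_exc_ms: float = 1.0
    delay_inh_ms: float = 4.0

    # neuron and synapse models
    membrane: MembraneParams = field(default_factory=MembraneParams)
    ampa: SynapseParams = AMPA
    gaba: SynapseParams = GABA

    # plasticity
    plasticity_rule: str = "stdp"  # stdp | hebbian | frozen
    stdp: STDPParams | None = None  # filled in __post_init__ from w bounds
    hebbian_amplitude: float | None = None  # defaults to stdp.lr

    # protocol
    n_iterations: int = 2000
    iteration_ms: float = 300.0
    dt_ms: float = 0.025
    on_ms: float = 240.0
    off_ms: float = 60.0
    max_rate_hz: float = 40.0
    noise_frac: float = 0.1
    input_delays: bool = True
    input_mode: str = "regular"  # or "poisson"

    # analysis defaults
    n_transforms: int = 10
    transform_frac: float = 0.01
    n_bins: int = 8

    # seeds
    network_seed: int = 0
    input_seed: int = 1
    noise_seed: int = 2

    def __post_init__(self) -> None:
        if self.plasticity_rule not in ("stdp", "hebbian", "frozen"):
            raise ValueError(f"unknown plasticity rule {self.plasticity_rule!r}")
        if self.iteration_ms <= 0 or self.dt_ms <= 0 or self.on_ms <= 0 or self.off_ms <= 0:
            raise ValueError("all durations must be positive")
        if self.stdp is None:
            object.__setattr__(
                self,
                "stdp",
                STDPParams(lr=1e-3 * self.w_max_uS, w_min=self.w_min_uS, w_max=self.w_max_uS),
            )
        if self.hebbian_amplitude is None:
            object.__setattr__(self, "hebbian_amplitude", self.stdp.lr)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("photoreceptor_dims", "lgn_dims", "v1_dims"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if isinstance(d.get("membrane"), dict):
            d["membrane"] = MembraneParams(**d["membrane"])
        if isinstance(d.get("ampa"), dict):
            d["ampa"] = SynapseParams(**d["ampa"])
        if isinstance(d.get("gaba"), dict):
            d["gaba"] = SynapseParams(**d["gaba"])
        if isinstance(d.get("stdp"), dict):
            d["stdp"] = STDPParams(**d["stdp"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
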