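"""Hand-wired opponent ON/OFF microcircuits.

Two small circuits, built from the same Hodgkin-Huxley neurons and
synapses as the full network, demonstrate the proposed mechanism by
which input-timing delays create stimulus-OFF responses combined with
color opponency.  Inputs are small grids of R, G and B cells firing
clock-like trains at the cone-transformed rates with random per-cell
onset phases; "delayed" (starred) edges model the input phase offset of
up to one interspike interval as a 24 ms synaptic delay, so their drive
outlasts stimulus removal by up to 24 ms.

A property of these single-compartment neurons shapes both designs:
under a smooth summed conductance they fire once and then sit in
depolarization block, so a cell is either an onset detector (dense
subthreshold-per-event drive) or an event follower (sparse strong
events with recovery in between).  The tuned weights place each cell
deliberately in one of those regimes.

Red-ON/Green-OFF circuit
    C1 is the R-G opponent cell: its summed R drive sits just above the
    firing threshold for red's L-cone rate but below it for green's
    weaker crosstalk, with G-driven GABA adding margin, so C1 spikes
    under red and stays silent under green.  L1 is a luminance cell
    whose green input arrives through a sparse set of strong delayed
    edges: it event-follows green activity and keeps firing for ~24 ms
    after green is removed.  The target (Red-ON/Green-OFF cell) fires
    immediately on C1 spikes and sluggishly on single L1 spikes; the
    neighbor N, relaying the plain luminance cell L2, vetoes those slow
    L1-driven responses during the stimulus-onset window but is silent
    after stimulus removal, letting the delayed L1 tail through — the
    green-OFF response.  The red-ON/green-OFF window contrasts are
    population-level: they hold in aggregate over seeds (and in most
    individual seeds), not deterministically per trial, because each
    60 ms window contains only a couple of spikes.

Yellow-ON/Blue-OFF circuit
    Three blue/yellow opponent cells: C2_1 (no delays), C2_2 (delayed R
    and G), C2_3 (all inputs delayed, including the B inhibition).
    Yellow drives the target through C2_1; after yellow removal C2_3's
    delayed drive keeps N2 suppressing N1.  Blue silences all C2 cells
    (target quiet); at blue removal C2_2 receives the delayed weak R/G
    crosstalk with its B inhibition gone, while C2_3 stays under
    delayed B inhibition, so N1 fires and excites the target — the
    blue-OFF response.

The synaptic weights are hand-tuned constants shipped as the default
fixtures ``RG_PARAMS`` and ``YB_PARAMS``; the qualitative ON/OFF window
contrasts, not exact rates, are the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import LayerSpec, NetworkModel, Projection
from .config import RunConfig
from .engine import Simulator, SpikeRaster
from .membrane import AMPA, GABA, MembraneParams
from .stimuli import uniform_patch

__all__ = [
    "ToyParams",
    "ToyCircuit",
    "RG_PARAMS",
    "YB_PARAMS",
    "build_rg_circuit",
    "build_yb_circuit",
    "run_toy",
]

DELAYED_MS = 24.0  # starred edges: one interspike interval at the 40 Hz ceiling


@dataclass(frozen=True)
class ToyParams:
    """Toy circuit weights in uS (input edges sum over the input grid)."""

    w_in_exc: float = 0.0070      # undelayed input -> LGN, per input cell
    w_in_inh: float = 0.0140      # opponent (inhibitory) input -> LGN
    w_in_delayed: float = 0.0175  # starred input -> LGN
    w_l1_in: float = 0.0016       # undelayed input -> L1 (subthreshold crosstalk)
    w_l2_in: float = 0.0020      # input -> L2, the veto drive chain
    w_c1_exc: float = 0.0020      # input -> C1: below threshold for green,
                                  # above it for red's stronger L-cone rate
    w_c1_inh: float = 0.0030      # opponent GABA onto C1 (adds margin)
    w_lgn_tgt: float = 0.0300     # LGN cell -> output cell (single spikes relay)
    w_rg_tgt: float = 0.0120      # L1 -> RG target (slow, veto-abortable)
    w_c1_tgt: float = 0.0900      # C1 -> RG target (fires through the veto)
    w_inh_out: float = 0.0400     # inhibition between output cells
    n_delayed: int = 6            # input cells carrying the delayed edge onto L1
    input_grid: tuple[int, int] = (3, 3)
    delayed_ms: float = DELAYED_MS
    delays_enabled: bool = True
    dt_ms: float = 0.025

    def star(self, base_ms: float) -> float:
        return self.delayed_ms if self.delays_enabled else base_ms


RG_PARAMS = ToyParams(
    w_l1_in=0.0016,
    w_in_delayed=0.016,
    n_delayed=6,
    w_c1_exc=0.002,
    w_c1_inh=0.003,
    w_rg_tgt=0.012,
    w_c1_tgt=0.09,
    w_l2_in=0.002,
    w_lgn_tgt=0.03,
    w_inh_out=0.15,
    input_grid=(4, 4),
)

YB_PARAMS = ToyParams(
    w_in_exc=0.007,
    w_in_inh=0.014,
    w_in_delayed=0.0175,
    w_lgn_tgt=0.05,
    w_inh_out=0.15,
    input_grid=(3, 3),
)


@dataclass
class ToyCircuit:
    name: str
    network: NetworkModel
    config: RunConfig
    target: str = "TGT"

    def adjacency(self) -> list[tuple[str, str, str, float]]:
        """(source, target, kind, delay) per projection — the wiring summary."""
        out = []
        for p in self.network.projections:
            kind = "GABA" if p.is_gaba.all() else "AMPA"
            out.append((p.source, p.target, kind, float(p.delay_ms[0])))
        return out


def _edges_full(n_src: int, w: float, delay: float, gaba: bool, limit: int | None = None) -> dict:
    n = n_src if limit is None else min(limit, n_src)
    return dict(
        src=np.arange(n, dtype=np.int64),
        tgt=np.zeros(n, dtype=np.int64),
        weight=np.full(n, w),
        delay_ms=np.full(n, delay),
        is_gaba=np.full(n, gaba, dtype=bool),
        plastic=False,
    )


def _edge_single(w: float, delay: float, gaba: bool) -> dict:
    return dict(
        src=np.zeros(1, dtype=np.int64),
        tgt=np.zeros(1, dtype=np.int64),
        weight=np.full(1, w),
        delay_ms=np.full(1, delay),
        is_gaba=np.full(1, gaba, dtype=bool),
        plastic=False,
    )


def _assemble(
    name: str,
    hh_layers: list[str],
    projections: list[Projection],
    params: ToyParams,
    seed: int,
) -> ToyCircuit:
    rows, cols = params.input_grid
    layers = [LayerSpec(nm, rows, cols) for nm in ("R", "G", "B")]
    layers += [LayerSpec(nm, 1, 1) for nm in hh_layers]
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 1.0, size=3 * rows * cols)
    config = RunConfig(
        photoreceptor_dims=params.input_grid,
        lgn_dims=params.input_grid,
        v1_dims=params.input_grid,
        dt_ms=params.dt_ms,
        plasticity_rule="frozen",
        network_seed=seed,
        noise_seed=seed + 1,
    )
    net = NetworkModel(
        layers=layers,
        projections=projections,
        membrane=MembraneParams(),
        ampa=AMPA,
        gaba=GABA,
        input_phases=phases,
        seed=seed,
    )
    return ToyCircuit(name=name, network=net, config=config)


def build_rg_circuit(params: ToyParams | None = None, seed: int = 0) -> ToyCircuit:
    """The Red-ON/Green-OFF microcircuit (defaults: ``RG_PARAMS``)."""
    p = params or RG_PARAMS
    n_in = p.input_grid[0] * p.input_grid[1]
    projections = [
        # C1 = R - G opponent cell: summed drive sits below the firing
        # threshold for green's L-cone crosstalk but above it for red
        Projection("R->C1", "R", "C1", **_edges_full(n_in, p.w_c1_exc, 1.0, False)),
        Projection("G->C1", "G", "C1", **_edges_full(n_in, p.w_c1_inh, 4.0, True)),
        # L1 = luminance cell with the delayed green input (starred); the
        # delayed edges are sparse and strong so L1 event-follows them
        Projection("R->L1", "R", "L1", **_edges_full(n_in, p.w_l1_in, 1.0, False)),
        Projection("G->L1*", "G", "L1",
                   **_edges_full(n_in, p.w_in_delayed, p.star(1.0), False, limit=p.n_delayed)),
        # L2 = plain luminance cell driving the neighbor N
        Projection("R->L2", "R", "L2", **_edges_full(n_in, p.w_l2_in, 1.0, False)),
        Projection("G->L2", "G", "L2", **_edges_full(n_in, p.w_l2_in, 1.0, False)),
        # output wiring
        Projection("C1->TGT", "C1", "TGT", **_edge_single(p.w_c1_tgt, 1.0, False)),
        Projection("L1->TGT", "L1", "TGT", **_edge_single(p.w_rg_tgt, 1.0, False)),
        Projection("L2->N", "L2", "N", **_edge_single(p.w_lgn_tgt, 1.0, False)),
        Projection("N->TGT", "N", "TGT", **_edge_single(p.w_inh_out, 4.0, True)),
    ]
    return _assemble("RG", ["C1", "L1", "L2", "N", "TGT"], projections, p, seed)


def build_yb_circuit(params: ToyParams | None = None, seed: int = 0) -> ToyCircuit:
    """The Yellow-ON/Blue-OFF microcircuit (defaults: ``YB_PARAMS``)."""
    p = params or YB_PARAMS
    n_in = p.input_grid[0] * p.input_grid[1]
    projections = [
        # C2_1: undelayed (R + G) - B opponent cell
        Projection("R->C2_1", "R", "C2_1", **_edges_full(n_in, p.w_in_exc, 1.0, False)),
        Projection("G->C2_1", "G", "C2_1", **_edges_full(n_in, p.w_in_exc, 1.0, False)),
        Projection("B->C2_1", "B", "C2_1", **_edges_full(n_in, p.w_in_inh, 4.0, True)),
        # C2_2: delayed R and G, undelayed B inhibition
        Projection("R->C2_2*", "R", "C2_2", **_edges_full(n_in, p.w_in_delayed, p.star(1.0), False)),
        Projection("G->C2_2*", "G", "C2_2", **_edges_full(n_in, p.w_in_delayed, p.star(1.0), False)),
        Projection("B->C2_2", "B", "C2_2", **_edges_full(n_in, p.w_in_inh, 4.0, True)),
        # C2_3: everything delayed, including the B inhibition
        Projection("R->C2_3*", "R", "C2_3", **_edges_full(n_in, p.w_in_delayed, p.star(1.0), False)),
        Projection("G->C2_3*", "G", "C2_3", **_edges_full(n_in, p.w_in_delayed, p.star(1.0), False)),
        Projection("B->C2_3*", "B", "C2_3", **_edges_full(n_in, p.w_in_inh, p.star(4.0), True)),
        # output wiring
        Projection("C2_1->TGT", "C2_1", "TGT", **_edge_single(p.w_lgn_tgt, 1.0, False)),
        Projection("C2_2->N1", "C2_2", "N1", **_edge_single(p.w_lgn_tgt, 1.0, False)),
        Projection("C2_3->N2", "C2_3", "N2", **_edge_single(p.w_lgn_tgt, 1.0, False)),
        Projection("N2->N1", "N2", "N1", **_edge_single(p.w_inh_out, 4.0, True)),
        Projection("N1->TGT", "N1", "TGT", **_edge_single(p.w_lgn_tgt, 1.0, False)),
    ]
    return _assemble("YB", ["C2_1", "C2_2", "C2_3", "N1", "N2", "TGT"], projections, p, seed)


def run_toy(
    circuit: ToyCircuit,
    color: tuple[float, float, float],
    on_ms: float = 240.0,
    off_ms: float = 60.0,
    rng: np.random.Generator | None = None,
) -> SpikeRaster:
    """Present a full-field color for ``on_ms`` then silence for ``off_ms``;
    returns the raster of every named cell."""
    if any(not (0.0 <= c <= 1.0) for c in color):
        raise ValueError("color channels must lie in [0, 1]")
    rng = np.random.default_rng(circuit.config.noise_seed) if rng is None else rng
    sim = Simulator(circuit.network, circuit.config)
    patch = uniform_patch(color, *circuit.config.photoreceptor_dims)
    raster = sim.run_trial(
        patch, rule="frozen", rng=rng, duration_ms=on_ms + off_ms, stim_until_ms=on_ms
    )
    raster.metadata.update({"on_ms": on_ms, "off_ms": off_ms, "circuit": circuit.name})
    return raster
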