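"""Network construction: layers, opponent wiring and lateral connectivity.

The model is nine layers of cells on 2-D grids, organised in five areas:
photoreceptors (R, G, B), LGN (L, C1, C2) and three cortical layers
(V1 L4, L2/3, L5).  Photoreceptor cells are spike generators; every
other cell is a Hodgkin-Huxley neuron.

Signal routing follows the anatomy of the early color pathways:

* magnocellular luminance channel  L  = R + G        -> V1 L4
* parvocellular red/green channel  C1 = R - G        -> V1 L4
* koniocellular blue/yellow channel C2 = (R + G) - B -> V1 L2/3

Negative channel terms are carried by GABA synapses (a spiking cell
cannot transmit a negative rate); positive terms by AMPA.  The
photoreceptor->LGN weights are fixed; all later feed-forward projections
(including L4 -> L2/3 -> L5) are plastic and topographic.  Within each
cortical layer, cells make short-range excitatory and longer-range
inhibitory lateral connections (a Mexican-hat profile) with sparse
random pruning.  Excitatory synapses carry a 1 ms delay, inhibitory
4 ms.

Grids are 0-based row-major and neighborhoods use Chebyshev distance,
so radius 1 is a 3x3 block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .membrane import MembraneParams, SynapseParams, AMPA, GABA

__all__ = [
    "LayerSpec",
    "Projection",
    "NetworkModel",
    "LAYER_ORDER",
    "INPUT_LAYERS",
    "OPPONENT_WIRING",
    "build_network",
    "topographic_map",
    "mexican_hat_edges",
]

LAYER_ORDER = ("R", "G", "B", "L", "C1", "C2", "V1L4", "V1L23", "V1L5")
INPUT_LAYERS = ("R", "G", "B")

# signed photoreceptor contributions to each LGN channel
OPPONENT_WIRING: dict[str, tuple[tuple[str, int], ...]] = {
    "L": (("R", +1), ("G", +1)),
    "C1": (("R", +1), ("G", -1)),
    "C2": (("R", +1), ("G", +1), ("B", -1)),
}


@dataclass(frozen=True)
class LayerSpec:
    name: str
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("layer dimensions must be positive")

    @property
    def n(self) -> int:
        return self.rows * self.cols


@dataclass
class Projection:
    """A bundle of synapses between two layers (or within one).

    ``src``/``tgt`` are cell indices local to the source/target layer;
    weights are conductances in uS and always non-negative — the sign of
    the effect is carried by ``is_gaba``.
    """

    name: str
    source: str
    target: str
    src: np.ndarray
    tgt: np.ndarray
    weight: np.ndarray
    delay_ms: np.ndarray
    is_gaba: np.ndarray
    plastic: bool
    w_min: float = 0.0
    w_max: float = np.inf

    @property
    def n_edges(self) -> int:
        return len(self.src)


def topographic_map(
    source_dims: tuple[int, int],
    target_dims: tuple[int, int],
    target_cell: tuple[int, int],
    radius: int = 0,
) -> np.ndarray:
    """Source cells in a Chebyshev disc around the scaled target position.

    The target cell's grid coordinate is scaled proportionally onto the
    source grid (so for a 10x10 source under a 30x30 target, each 3x3
    block of targets shares one source position), then all source cells
    within ``radius`` are returned as flat row-major indices, clipped at
    the borders.
    """
    srows, scols = source_dims
    trows, tcols = target_dims
    r, c = target_cell
    cr = int((r + 0.5) * srows / trows)
    cc = int((c + 0.5) * scols / tcols)
    r0, r1 = max(0, cr - radius), min(srows - 1, cr + radius)
    c0, c1 = max(0, cc - radius), min(scols - 1, cc + radius)
    rr, cc_ = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    return (rr * scols + cc_).ravel()


def mexican_hat_edges(
    layer: LayerSpec,
    r_exc: int,
    r_inh: int,
    p_connect: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lateral edges with a Mexican-hat profile.

    Excitatory edges run to cells within Chebyshev distance ``r_exc``
    (excluding self), inhibitory edges to the annulus out to ``r_inh``;
    each candidate is kept independently with probability ``p_connect``.
    Returns (src, tgt, is_gaba) arrays of local indices.
    """
    if not (0 < r_exc < r_inh):
        raise ValueError("require 0 < r_exc < r_inh")
    if not (0.0 <= p_connect <= 1.0):
        raise ValueError("p_connect must be in [0, 1]")
    src_l, tgt_l, gaba_l = [], [], []
    for r in range(layer.rows):
        for c in range(layer.cols):
            i = r * layer.cols + c
            for dr in range(-r_inh, r_inh + 1):
                for dc in range(-r_inh, r_inh + 1):
                    d = max(abs(dr), abs(dc))
                    if d == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < layer.rows and 0 <= c2 < layer.cols):
                        continue
                    if rng.random() >= p_connect:
                        continue
                    src_l.append(i)
                    tgt_l.append(r2 * layer.cols + c2)
                    gaba_l.append(d > r_exc)
    return (
        np.asarray(src_l, dtype=np.int64),
        np.asarray(tgt_l, dtype=np.int64),
        np.asarray(gaba_l, dtype=bool),
    )


@dataclass
class NetworkModel:
    """Layers, projections and fixed per-cell input phases of one network."""

    layers: list[LayerSpec]
    projections: list[Projection]
    membrane: MembraneParams
    ampa: SynapseParams
    gaba: SynapseParams
    input_phases: np.ndarray  # one onset phase in [0,1) per photoreceptor cell
    seed: int

    def __post_init__(self) -> None:
        self._offsets: dict[str, int] = {}
        off = 0
        for spec in self.layers:
            self._offsets[spec.name] = off
            off += spec.n
        self.n_cells = off

    def layer(self, name: str) -> LayerSpec:
        for spec in self.layers:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def offset(self, name: str) -> int:
        return self._offsets[name]

    def cell_range(self, name: str) -> tuple[int, int]:
        off = self._offsets[name]
        return off, off + self.layer(name).n

    @property
    def n_input_cells(self) -> int:
        return sum(self.layer(nm).n for nm in INPUT_LAYERS)

    def projection(self, name: str) -> Projection:
        for p in self.projections:
            if p.name == name:
                return p
        raise KeyError(name)

    def plastic_projections(self) -> list[Projection]:
        return [p for p in self.projections if p.plastic]

    # -- diagnostics -------------------------------------------------------

    def receptive_field_sizes(self) -> dict[str, float]:
        """Mean per-cell count of photoreceptor positions reachable by
        at least one feed-forward path, per non-input layer."""
        n_pos = self.layer("R").n  # photoreceptor grid positions
        reach: dict[str, list[set[int]]] = {
            nm: [{i} for i in range(self.layer(nm).n)] for nm in INPUT_LAYERS
        }
        # walk layers in order; feed-forward projections only
        for spec in self.layers:
            if spec.name in INPUT_LAYERS:
                continue
            sets = [set() for _ in range(spec.n)]
            for p in self.projections:
                if p.target != spec.name or p.source == p.target:
                    continue
                if p.source not in reach:
                    continue
                for s, t in zip(p.src, p.tgt):
                    sets[t] |= reach[p.source][s]
            reach[spec.name] = sets
        out = {}
        for spec in self.layers:
            if spec.name in INPUT_LAYERS:
                continue
            sizes = [len(s & set(range(n_pos))) for s in reach[spec.name]]
            out[spec.name] = float(np.mean(sizes))
        return out


def build_network(config) -> NetworkModel:
    """Construct the full network for a :class:`~chromanet.config.RunConfig`.

    Deterministic given the configuration's network seed: wiring, random
    pruning, initial plastic weights and input onset phases all derive
    from one generator.
    """
    rng = np.random.default_rng(config.network_seed)
    pr, pc = config.photoreceptor_dims
    lr, lc = config.lgn_dims
    vr, vc = config.v1_dims
    if lr % pr or lc % pc:
        raise ValueError("LGN dims must be an integer multiple of the photoreceptor dims")

    layers = [LayerSpec(nm, pr, pc) for nm in INPUT_LAYERS]
    layers += [LayerSpec(nm, lr, lc) for nm in ("L", "C1", "C2")]
    layers += [LayerSpec(nm, vr, vc) for nm in ("V1L4", "V1L23", "V1L5")]
    by_name = {s.name: s for s in layers}

    projections: list[Projection] = []

    # fixed opponent wiring, one photoreceptor position per LGN cell
    for lgn_name, terms in OPPONENT_WIRING.items():
        lgn = by_name[lgn_name]
        for src_name, sign in terms:
            src_layer = by_name[src_name]
            src_idx, tgt_idx = [], []
            for r in range(lgn.rows):
                for c in range(lgn.cols):
                    srcs = topographic_map(
                        (src_layer.rows, src_layer.cols), (lgn.rows, lgn.cols), (r, c), radius=0
                    )
                    src_idx.extend(srcs)
                    tgt_idx.extend([r * lgn.cols + c] * len(srcs))
            n = len(src_idx)
            gaba = sign < 0
            delay = config.delay_inh_ms if gaba else config.delay_exc_ms
            projections.append(
                Projection(
                    name=f"{src_name}->{lgn_name}",
                    source=src_name,
                    target=lgn_name,
                    src=np.asarray(src_idx, dtype=np.int64),
                    tgt=np.asarray(tgt_idx, dtype=np.int64),
                    weight=np.full(n, config.g_lgn_uS),
                    delay_ms=np.full(n, delay),
                    is_gaba=np.full(n, gaba, dtype=bool),
                    plastic=False,
                )
            )

    # plastic topographic feed-forward projections
    ff_routes = [
        ("L", "V1L4"),
        ("C1", "V1L4"),
        ("C2", "V1L23"),  # the koniocellular pathway bypasses L4
        ("V1L4", "V1L23"),
        ("V1L23", "V1L5"),
    ]
    for src_name, tgt_name in ff_routes:
        s_layer, t_layer = by_name[src_name], by_name[tgt_name]
        src_idx, tgt_idx = [], []
        for r in range(t_layer.rows):
            for c in range(t_layer.cols):
                srcs = topographic_map(
                    (s_layer.rows, s_layer.cols),
                    (t_layer.rows, t_layer.cols),
                    (r, c),
                    radius=config.r_ff,
                )
                src_idx.extend(srcs)
                tgt_idx.extend([r * t_layer.cols + c] * len(srcs))
        n = len(src_idx)
        projections.append(
            Projection(
                name=f"{src_name}->{tgt_name}",
                source=src_name,
                target=tgt_name,
                src=np.asarray(src_idx, dtype=np.int64),
                tgt=np.asarray(tgt_idx, dtype=np.int64),
                weight=rng.uniform(config.w_min_uS, config.w_max_uS, size=n),
                delay_ms=np.full(n, config.delay_exc_ms),
                is_gaba=np.zeros(n, dtype=bool),
                plastic=True,
                w_min=config.w_min_uS,
                w_max=config.w_max_uS,
            )
        )

    # lateral Mexican-hat connectivity within each cortical layer
    for nm in ("V1L4", "V1L23", "V1L5"):
        layer = by_name[nm]
        src, tgt, gaba = mexican_hat_edges(layer, config.r_exc, config.r_inh, config.p_connect, rng)
        weight = np.where(gaba, config.w_lat_inh_uS, config.w_lat_exc_uS)
        delay = np.where(gaba, config.delay_inh_ms, config.delay_exc_ms)
        projections.append(
            Projection(
                name=f"{nm}<->{nm}",
                source=nm,
                target=nm,
                src=src,
                tgt=tgt,
                weight=weight.astype(float),
                delay_ms=delay.astype(float),
                is_gaba=gaba,
                plastic=False,
            )
        )

    n_input = 3 * pr * pc
    phases = rng.uniform(0.0, 1.0, size=n_input) if config.input_delays else np.zeros(n_input)

    return NetworkModel(
        layers=layers,
        projections=projections,
        membrane=config.membrane,
        ampa=config.ampa,
        gaba=config.gaba,
        input_phases=phases,
        seed=config.network_seed,
    )
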