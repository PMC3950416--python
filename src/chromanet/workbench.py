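"""Experiment presets and figure recipes.

``preset`` returns fully populated run configurations:

* ``paper_full`` — the published scale: 10x10 photoreceptor grids,
  30x30 LGN and V1 grids (5700 cells), 2000 x 300 ms training.
* ``desk_small`` — a desk-scale reduction (5x5 photoreceptors, 10x10
  LGN/V1, 675 cells, 200 iterations, dt 0.05 ms) used throughout the
  test suite.
* ``ablation_no_delays`` — desk_small with the random input onset
  phases disabled (the OFF-cell ablation).
* ``hebbian_control`` — desk_small trained with the order-blind
  Hebbian rule instead of STDP.

``figure_recipes`` maps result-figure identifiers to executable recipes
that rerun the corresponding experiment at desk scale and draw the
analogous matplotlib figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .config import RunConfig

__all__ = ["preset", "figure_recipes", "FigureRecipe", "PRESETS"]


def _desk_small(**over) -> RunConfig:
    base = dict(
        photoreceptor_dims=(5, 5),
        lgn_dims=(10, 10),
        v1_dims=(10, 10),
        n_iterations=200,
        dt_ms=0.05,
    )
    base.update(over)
    cfg = RunConfig(**base)
    if "stdp" not in over:
        # 10x fewer iterations than the full protocol: scale the learning
        # rate so total weight drift over a training run is comparable
        from .plasticity import STDPParams

        cfg = cfg.replace(
            stdp=STDPParams(lr=1e-2 * cfg.w_max_uS, w_min=cfg.w_min_uS, w_max=cfg.w_max_uS),
            hebbian_amplitude=None if "hebbian_amplitude" in over else 1e-2 * cfg.w_max_uS,
        )
    return cfg


PRESETS: dict[str, Callable[..., RunConfig]] = {
    "paper_full": lambda **over: RunConfig(**over),
    "desk_small": _desk_small,
    "ablation_no_delays": lambda **over: _desk_small(input_delays=False, **over),
    "hebbian_control": lambda **over: _desk_small(plasticity_rule="hebbian", **over),
}


def preset(name: str, **overrides) -> RunConfig:
    """A fully populated run configuration for a named experiment."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return factory(**overrides)


@dataclass(frozen=True)
class FigureRecipe:
    preset_name: str
    description: str
    run: Callable  # (seed, quick) -> matplotlib Figure


def _fig_weights(seed: int = 0, quick: bool = True):
    """Weight histograms before vs after STDP training."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .model import ColorVisionModel

    n_iter = 40 if quick else None
    model = ColorVisionModel.from_preset("desk_small", network_seed=seed)
    res = model.fit(n_iterations=n_iter)
    proj = res.network.projection("V1L23->V1L5")
    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    for ax, w, title in (
        (axes[0], res.weights_before["V1L23->V1L5"], "untrained"),
        (axes[1], proj.weight, "trained"),
    ):
        ax.hist(w * 1e3, bins=20, color="steelblue")
        ax.set_title(title)
        ax.set_xlabel("weight (nS)")
    axes[0].set_ylabel("synapse count")
    fig.tight_layout()
    return fig


def _fig_color_maps(seed: int = 0, quick: bool = True):
    """Per-color response maps of the output layer before/after training."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .model import ColorVisionModel

    n_iter = 40 if quick else None
    model = ColorVisionModel.from_preset("desk_small", network_seed=seed)
    res = model.fit(n_iterations=n_iter)
    table = res.rate_table()
    rates = table.layer("V1L5").mean(axis=1)
    rows, cols = table.grid_dims["V1L5"]
    fig, axes = plt.subplots(2, 4, figsize=(10, 5))
    for ax, s in zip(axes.ravel(), range(rates.shape[0])):
        ax.imshow(rates[s].reshape(rows, cols), cmap="viridis")
        ax.set_title(table.stimuli[s] if s < len(table.stimuli) else "")
        ax.axis("off")
    fig.suptitle("V1 L5 mean rate per test color (trained)")
    fig.tight_layout()
    return fig


def _fig_clustering(seed: int = 0, quick: bool = True):
    """Clustering-coefficient trajectories: STDP layers vs Hebbian control."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .model import ColorVisionModel

    n_iter = 40 if quick else None
    cadence = 10 if quick else 25
    fig, ax = plt.subplots(figsize=(6, 4))
    for preset_name, style in (("desk_small", "-"), ("hebbian_control", "--*")):
        model = ColorVisionModel.from_preset(preset_name, network_seed=seed)
        res = model.fit(n_iterations=n_iter, trace_cadence=cadence)
        tr = res.trace.dropna(subset=["clustering_V1L5"])
        label = "Hebbian L5" if preset_name == "hebbian_control" else "STDP L5"
        ax.plot(tr["iteration"], tr["clustering_V1L5"], style.rstrip("*"), label=label)
    ax.set_xlabel("training iteration")
    ax.set_ylabel("clustering coefficient C")
    ax.legend()
    fig.tight_layout()
    return fig


def _fig_information(seed: int = 0, quick: bool = True):
    """Single- and multiple-cell information, trained vs untrained."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .analysis import multiple_cell_info, single_cell_info
    from .model import ColorVisionModel

    n_iter = 40 if quick else None
    model = ColorVisionModel.from_preset("desk_small", network_seed=seed)
    res = model.fit(n_iterations=n_iter)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for label, table in (("untrained", res.rate_table_untrained()), ("trained", res.rate_table())):
        s = single_cell_info(table, layer="V1L5")
        axes[0].plot(sorted(s.single_bits, reverse=True), label=label)
        m = multiple_cell_info(table, layer="V1L5", max_cells=15)
        axes[1].plot(np.arange(1, 16), m.multiple_bits, label=label)
    axes[0].set_xlabel("cell rank")
    axes[0].set_ylabel("single-cell information (bits)")
    axes[1].set_xlabel("number of cells")
    axes[1].set_ylabel("multiple-cell information (bits)")
    axes[1].axhline(3.0, ls=":", c="gray")
    axes[1].legend()
    fig.tight_layout()
    return fig


def _fig_onoff(seed: int = 0, quick: bool = True):
    """ON/OFF raster of the most responsive output cells per color."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .analysis import select_on_off_cells
    from .model import ColorVisionModel

    n_iter = 40 if quick else None
    model = ColorVisionModel.from_preset("desk_small", network_seed=seed)
    res = model.fit(n_iterations=n_iter)
    rasters = res.on_off()
    colors = list(rasters)[:4]
    fig, axes = plt.subplots(len(colors), 1, figsize=(7, 2 * len(colors)), sharex=True)
    for ax, cname in zip(np.atleast_1d(axes), colors):
        raster = rasters[cname]
        on_cells, _, off_cells, _ = select_on_off_cells(raster, res.network, n_select=15)
        chosen = np.unique(np.concatenate([on_cells, off_cells]))
        cells, times = raster.layer_events(res.network, "V1L5")
        for row, cell in enumerate(chosen):
            tt = times[cells == cell]
            ax.plot(tt, np.full_like(tt, row), "|", ms=4, color="k")
        ax.axvspan(0, raster.metadata["on_ms"], color=cname if cname != "aqua" else "cyan", alpha=0.15)
        ax.set_ylabel(cname, rotation=0, ha="right")
    fig.tight_layout()
    return fig


def _fig_opponent(seed: int = 0, quick: bool = True):
    """Opponent-cell rasters with random input delays vs without."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .analysis import select_opponent_cells
    from .model import ColorVisionModel

    n_iter = 40 if quick else None
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, preset_name in zip(axes, ("desk_small", "ablation_no_delays")):
        model = ColorVisionModel.from_preset(preset_name, network_seed=seed)
        res = model.fit(n_iterations=n_iter)
        rasters = res.on_off()
        sel = select_opponent_cells(rasters, res.network, "red", "green", n_pool=30, n_select=10)
        raster = rasters["green"]
        cells, times = raster.layer_events(res.network, "V1L5")
        for row, cell in enumerate(sel.cells):
            tt = times[cells == cell]
            ax.plot(tt, np.full_like(tt, row), "|", ms=4, color="k")
        ax.axvline(raster.metadata["on_ms"], ls=":", c="gray")
        flag = " (short)" if sel.short else ""
        ax.set_title(f"{preset_name}{flag}")
    axes[0].set_ylabel("Red-ON/Green-OFF cell")
    fig.tight_layout()
    return fig


def _fig_toys(seed: int = 0, quick: bool = True):
    """ON/OFF window rates of both toy circuits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .toycircuits import build_rg_circuit, build_yb_circuit, run_toy

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    cases = (
        (build_rg_circuit(seed=seed), [("red", (1, 0, 0)), ("green", (0, 1, 0))], axes[0]),
        (build_yb_circuit(seed=seed), [("yellow", (1, 1, 0)), ("blue", (0, 0, 1))], axes[1]),
    )
    for circuit, colors, ax in cases:
        width = 0.35
        for k, (nm, rgb) in enumerate(colors):
            raster = run_toy(circuit, rgb)
            on = raster.window_counts(circuit.network, circuit.target, 0, 60)[0]
            off = raster.window_counts(circuit.network, circuit.target, 240, 300)[0]
            ax.bar([0 + k * width, 1 + k * width], [on, off], width, label=nm)
        ax.set_xticks([width / 2, 1 + width / 2])
        ax.set_xticklabels(["ON window", "OFF window"])
        ax.set_ylabel("target spikes")
        ax.set_title(f"{circuit.name} circuit")
        ax.legend()
    fig.tight_layout()
    return fig


def figure_recipes() -> dict[str, FigureRecipe]:
    """Executable recipes for the package's result figures."""
    return {
        "fig4": FigureRecipe("desk_small", "weight histograms before/after STDP", _fig_weights),
        "fig5": FigureRecipe("desk_small", "per-color response maps of V1 L5", _fig_color_maps),
        "fig6": FigureRecipe("desk_small", "clustering trajectories, STDP vs Hebbian", _fig_clustering),
        "fig7": FigureRecipe("desk_small", "single/multiple-cell information", _fig_information),
        "fig8": FigureRecipe("desk_small", "ON/OFF rasters per color", _fig_onoff),
        "fig9": FigureRecipe("desk_small", "opponent cells, delays vs no delays", _fig_opponent),
        "fig13": FigureRecipe("desk_small", "toy circuit ON/OFF contrasts", _fig_toys),
    }
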