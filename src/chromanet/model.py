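"""High-level modelling interface.

:class:`ColorVisionModel` bundles a run configuration with a freshly
built network; :meth:`~ColorVisionModel.fit` runs the training protocol
and returns a :class:`TrainingResults` carrying the trained network,
the training trace, pre-training weight snapshots and lazily computed
diagnostics (rate tables, clustering, information measures), with a
``summary()`` table in the spirit of statistical modelling packages.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import NetworkModel, build_network
from .config import RunConfig
from .engine import RateTable, Simulator, SpikeRaster
from .workbench import preset as _preset

__all__ = ["ColorVisionModel", "TrainingResults"]


class ColorVisionModel:
    """The early color-vision network as a fittable model.

    Parameters
    ----------
    config
        Full run configuration; see :class:`chromanet.config.RunConfig`.
    patch_source
        Optional iterable of training patches.  By default training
        draws synthetic smooth color fields from the configuration's
        input seed.
    """

    def __init__(self, config: RunConfig, patch_source=None):
        self.config = config
        self.patch_source = patch_source
        self.network: NetworkModel = build_network(config)

    @classmethod
    def from_preset(cls, name: str, patch_source=None, **overrides) -> "ColorVisionModel":
        return cls(_preset(name, **overrides), patch_source=patch_source)

    def fit(
        self,
        n_iterations: int | None = None,
        rule: str | None = None,
        trace_cadence: int = 0,
        progress: bool = False,
    ) -> "TrainingResults":
        """Train the plastic projections and return the results object."""
        config = self.config if rule is None else self.config.replace(plasticity_rule=rule)
        sim = Simulator(self.network, config)
        weights_before = {
            p.name: p.weight.copy() for p in self.network.plastic_projections()
        }
        untrained = copy.deepcopy(
            {p.name: p.weight.copy() for p in self.network.projections}
        )
        trace = sim.train(
            self.patch_source,
            n_iterations=n_iterations,
            trace_cadence=trace_cadence,
            progress=progress,
        )
        return TrainingResults(
            model=self,
            config=config,
            network=self.network,
            simulator=sim,
            trace=trace,
            weights_before=weights_before,
            _all_weights_before=untrained,
        )


@dataclass
class TrainingResults:
    """Outcome of one training run plus cached diagnostics."""

    model: ColorVisionModel
    config: RunConfig
    network: NetworkModel
    simulator: Simulator
    trace: pd.DataFrame
    weights_before: dict[str, np.ndarray]
    _all_weights_before: dict[str, np.ndarray]
    _table: RateTable | None = field(default=None, repr=False)
    _table_untrained: RateTable | None = field(default=None, repr=False)

    # -- diagnostics -------------------------------------------------------

    def rate_table(self, **kw) -> RateTable:
        """Color-test rate table of the trained network (cached for the
        default arguments)."""
        if kw:
            return self.simulator.test_colors(**kw)
        if self._table is None:
            self._table = self.simulator.test_colors()
        return self._table

    def rate_table_untrained(self, **kw) -> RateTable:
        """Same color test with the pre-training weights restored."""
        if self._table_untrained is None or kw:
            saved = {p.name: p.weight.copy() for p in self.network.projections}
            for p in self.network.projections:
                p.weight[:] = self._all_weights_before[p.name]
            try:
                table = self.simulator.test_colors(**kw)
            finally:
                for p in self.network.projections:
                    p.weight[:] = saved[p.name]
            if kw:
                return table
            self._table_untrained = table
        return self._table_untrained

    def on_off(self, **kw) -> dict[str, SpikeRaster]:
        return self.simulator.on_off_protocol(**kw)

    def clustering(self, layer: str = "V1L5"):
        from .analysis import clustering_coefficient

        return clustering_coefficient(self.rate_table(), layer=layer)

    def information(self, layer: str = "V1L5", max_cells: int = 15):
        from .analysis import multiple_cell_info, single_cell_info

        table = self.rate_table()
        return single_cell_info(table, layer=layer), multiple_cell_info(
            table, layer=layer, max_cells=max_cells
        )

    # -- summary -----------------------------------------------------------

    def summary(self) -> str:
        from .analysis import clustering_coefficient, weight_bimodality

        cfg = self.config
        lines = []
        add = lines.append
        add("Color-vision network training results")
        add("=" * 54)
        add(f"{'plasticity rule':28s} {cfg.plasticity_rule}")
        add(f"{'iterations':28s} {len(self.trace)} x {cfg.iteration_ms:.0f} ms")
        add(f"{'total cells':28s} {self.network.n_cells}")
        dims = " / ".join(
            f"{s.name} {s.rows}x{s.cols}" for s in self.network.layers
        )
        add(f"{'layers':28s} {dims}")
        add("-" * 54)
        first = self.trace.iloc[0]
        last = self.trace.iloc[-1]
        for nm in ("V1L4", "V1L23", "V1L5"):
            add(
                f"{'mean rate ' + nm + ' (Hz)':28s} "
                f"{first[f'rate_{nm}']:6.3f} -> {last[f'rate_{nm}']:6.3f}"
            )
        add("-" * 54)
        table = self.rate_table()
        for nm in ("V1L4", "V1L23", "V1L5"):
            C = clustering_coefficient(table, layer=nm).C
            add(f"{'clustering C ' + nm:28s} {C:6.4f}")
        add("-" * 54)
        for p in self.network.plastic_projections():
            before = weight_bimodality(
                self.weights_before[p.name], p.w_min, p.w_max
            ).near_bound_fraction
            after = weight_bimodality(p.weight, p.w_min, p.w_max).near_bound_fraction
            add(f"{'near-bound frac ' + p.name:28s} {before:5.3f} -> {after:5.3f}")
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_weight_hist(self, projection: str = "V1L23->V1L5", ax=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.network.projection(projection)
        ax.hist(self.weights_before[projection] * 1e3, bins=20, alpha=0.5, label="before")
        ax.hist(p.weight * 1e3, bins=20, alpha=0.5, label="after")
        ax.set_xlabel("weight (nS)")
        ax.set_ylabel("count")
        ax.legend()
        return ax

    def plot_trace(self, column: str = "rate_V1L5", ax=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace["iteration"], self.trace[column])
        ax.set_xlabel("iteration")
        ax.set_ylabel(column)
        return ax
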