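"""Simulation engine: delayed-event delivery, training and testing protocols.

The :class:`Simulator` owns a network plus a run configuration,
flattens all projections into a CSR edge table once, and runs
fixed-step trials through the jitted kernel.  Each trial starts from
the resting state (presentations are independent saccade-like
exposures), generates the input spike trains for one patch, integrates
the cortical cells with exact synaptic delays, and — unless plasticity
is frozen — applies the selected learning rule followed by per-
projection weight normalization.

Protocols:

* :meth:`Simulator.train` — iterate patch presentations (default
  2000 x 300 ms), recording a training trace.
* :meth:`Simulator.test_colors` — present each test color and its
  slightly perturbed transforms full-field with plasticity off; returns
  the mean-rate table that feeds all analyses.
* :meth:`Simulator.on_off_protocol` — 240 ms stimulus ON followed by
  60 ms OFF per color, with full spike recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from . import stimuli as stim
from ._kernel import simulate
from .circuit import INPUT_LAYERS, NetworkModel
from .config import RunConfig
from .membrane import (
    REFRACTORY_MS,
    SPIKE_THRESHOLD_MV,
    IntegrationDivergedError,
    resting_state,
)
from .plasticity import apply_stdp, hebbian_update, normalize_weights

__all__ = ["SpikeRaster", "RateTable", "Simulator", "run_trial", "train", "test_colors", "on_off_protocol"]


@dataclass
class SpikeRaster:
    """Spike events of one trial: (global cell id, time in ms), time-sorted."""

    cells: np.ndarray
    times: np.ndarray
    duration_ms: float
    n_cells: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = np.argsort(self.times, kind="stable")
        self.cells = np.asarray(self.cells, dtype=np.int64)[order]
        self.times = np.asarray(self.times, dtype=float)[order]

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def layer_events(self, network: NetworkModel, layer: str) -> tuple[np.ndarray, np.ndarray]:
        """(local cell indices, times) for one layer."""
        lo, hi = network.cell_range(layer)
        mask = (self.cells >= lo) & (self.cells < hi)
        return self.cells[mask] - lo, self.times[mask]

    def per_cell_spikes(self, network: NetworkModel, layer: str) -> list[np.ndarray]:
        cells, times = self.layer_events(network, layer)
        n = network.layer(layer).n
        out: list[list[float]] = [[] for _ in range(n)]
        for c, t in zip(cells, times):
            out[c].append(t)
        return [np.asarray(s) for s in out]

    def window_counts(
        self, network: NetworkModel, layer: str, t0: float, t1: float
    ) -> np.ndarray:
        """Spike count per cell of ``layer`` within [t0, t1)."""
        cells, times = self.layer_events(network, layer)
        mask = (times >= t0) & (times < t1)
        return np.bincount(cells[mask], minlength=network.layer(layer).n)

    def layer_rates(self, network: NetworkModel, layer: str) -> np.ndarray:
        return self.window_counts(network, layer, 0.0, self.duration_ms) * (
            1000.0 / self.duration_ms
        )


@dataclass
class RateTable:
    """Mean firing rate per (stimulus, transform, cell) — the analysis input."""

    rates_hz: np.ndarray  # (n_stims, n_transforms, n_hh_cells)
    stimuli: list[str]
    layer_slices: dict[str, slice]
    grid_dims: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if np.any(self.rates_hz < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_stims(self) -> int:
        return self.rates_hz.shape[0]

    @property
    def n_transforms(self) -> int:
        return self.rates_hz.shape[1]

    def layer(self, name: str) -> np.ndarray:
        return self.rates_hz[:, :, self.layer_slices[name]]


class Simulator:
    """Clock-driven simulator bound to one network and configuration."""

    def __init__(self, network: NetworkModel, config: RunConfig):
        self.network = network
        self.config = config
        self.n_input = network.n_input_cells
        self.n_hh = network.n_cells - self.n_input
        self._build_edge_table()
        rest = resting_state(network.membrane)
        self._rest = (rest.v_mV, rest.m, rest.h, rest.n)

    # -- construction ------------------------------------------------------

    def _build_edge_table(self) -> None:
        net, cfg = self.network, self.config
        src_parts, tgt_parts, delay_parts, gaba_parts = [], [], [], []
        self._proj_slices: list[tuple[int, int]] = []
        pos = 0
        for p in net.projections:
            src_parts.append(p.src + net.offset(p.source))
            tgt_parts.append(p.tgt + net.offset(p.target) - self.n_input)
            delay_parts.append(p.delay_ms)
            gaba_parts.append(p.is_gaba)
            self._proj_slices.append((pos, pos + p.n_edges))
            pos += p.n_edges
        src = np.concatenate(src_parts)
        self._tgt_unsorted = np.concatenate(tgt_parts).astype(np.int64)
        if self._tgt_unsorted.min() < 0:
            raise ValueError("projection targets photoreceptor cells")
        delay = np.concatenate(delay_parts)
        steps = np.maximum(np.rint(delay / cfg.dt_ms).astype(np.int64), 1)
        gaba = np.concatenate(gaba_parts)
        self._order = np.argsort(src, kind="stable")
        self._e_src = src[self._order]
        self._e_tgt = self._tgt_unsorted[self._order]
        self._e_delay_steps = steps[self._order]
        self._e_is_gaba = gaba[self._order]
        counts = np.bincount(src, minlength=net.n_cells)
        self._indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self._buf_len = int(self._e_delay_steps.max()) + 2
        self._n_edges = pos

    def _sorted_weights(self) -> np.ndarray:
        w = np.empty(self._n_edges)
        for p, (a, b) in zip(self.network.projections, self._proj_slices):
            w[a:b] = p.weight
        return w[self._order]

    # -- single trial ------------------------------------------------------

    def _input_rates(self, patch: stim.ColorPatch) -> np.ndarray:
        drive = stim.rgb_to_cone_rates(patch)
        # R grid carries L-cone rates, G the M-cone, B the S-cone
        return np.concatenate([drive.l_hz.ravel(), drive.m_hz.ravel(), drive.s_hz.ravel()])

    def run_trial(
        self,
        patch: stim.ColorPatch,
        rule: str | None = None,
        rng: np.random.Generator | None = None,
        duration_ms: float | None = None,
        stim_until_ms: float | None = None,
    ) -> SpikeRaster:
        """One presentation; applies plasticity unless ``rule`` is frozen."""
        net, cfg = self.network, self.config
        rule = cfg.plasticity_rule if rule is None else rule
        rng = np.random.default_rng(cfg.noise_seed) if rng is None else rng
        duration = cfg.iteration_ms if duration_ms is None else duration_ms
        stim_until = duration if stim_until_ms is None else stim_until_ms
        dt = cfg.dt_ms
        n_steps = int(round(duration / dt))

        rates = self._input_rates(patch)
        trains = stim.generate_input_spikes(
            rates, stim_until, cfg.noise_frac, rng, net.input_phases, cfg.input_mode
        )
        in_cell_l, in_time_l = [], []
        for ci, tt in enumerate(trains):
            if len(tt):
                in_cell_l.append(np.full(len(tt), ci, dtype=np.int64))
                in_time_l.append(tt)
        if in_cell_l:
            in_cells = np.concatenate(in_cell_l)
            in_times = np.concatenate(in_time_l)
        else:
            in_cells = np.empty(0, dtype=np.int64)
            in_times = np.empty(0)
        in_steps = np.rint(in_times / dt).astype(np.int64)
        keep = in_steps < n_steps
        in_cells, in_times, in_steps = in_cells[keep], in_times[keep], in_steps[keep]
        order = np.argsort(in_steps, kind="stable")
        in_cells_s, in_steps_s = in_cells[order], in_steps[order]

        v = np.full(self.n_hh, self._rest[0])
        m = np.full(self.n_hh, self._rest[1])
        h = np.full(self.n_hh, self._rest[2])
        n = np.full(self.n_hh, self._rest[3])
        g_a = np.zeros(self.n_hh)
        g_g = np.zeros(self.n_hh)
        refrac = np.full(self.n_hh, -np.inf)
        buf_a = np.zeros((self._buf_len, self.n_hh))
        buf_g = np.zeros((self._buf_len, self.n_hh))
        cap = int(self.n_hh * duration / 1000.0 * 400) + 1024
        rec_cell = np.empty(cap, dtype=np.int64)
        rec_step = np.empty(cap, dtype=np.int64)

        mb, syn_a, syn_g = net.membrane, net.ampa, net.gaba
        n_rec, err_cell, err_step = simulate(
            n_steps, dt,
            mb.c_total_nF, mb.g_leak_uS, mb.e_leak_mV,
            mb.g_na_uS, mb.e_na_mV, mb.g_k_uS, mb.e_k_mV,
            syn_a.tau_ms, syn_a.e_rev_mV, syn_g.tau_ms, syn_g.e_rev_mV,
            SPIKE_THRESHOLD_MV, REFRACTORY_MS,
            v, m, h, n, g_a, g_g, refrac,
            buf_a, buf_g,
            self._indptr, self._e_tgt, self._sorted_weights(),
            self._e_delay_steps, self._e_is_gaba,
            in_steps_s, in_cells_s, self.n_input,
            rec_cell, rec_step,
        )
        if err_cell >= 0:
            raise IntegrationDivergedError(
                f"voltage diverged for cortical cell {err_cell} at "
                f"t={err_step * dt:.3f} ms (dt={dt} ms)"
            )

        cells = np.concatenate([in_cells, rec_cell[:n_rec] + self.n_input])
        times = np.concatenate([in_times, rec_step[:n_rec] * dt])
        raster = SpikeRaster(cells, times, duration, net.n_cells)

        if rule != "frozen":
            self._apply_plasticity(raster, rule, duration)
        return raster

    def _apply_plasticity(self, raster: SpikeRaster, rule: str, duration: float) -> None:
        net, cfg = self.network, self.config
        needed = {p.source for p in net.plastic_projections()} | {
            p.target for p in net.plastic_projections()
        }
        by_layer = {nm: raster.per_cell_spikes(net, nm) for nm in needed}
        for p in net.plastic_projections():
            if rule == "stdp":
                apply_stdp(p, by_layer[p.source], by_layer[p.target], cfg.stdp)
            elif rule == "hebbian":
                hebbian_update(
                    p, by_layer[p.source], by_layer[p.target], cfg.hebbian_amplitude, duration
                )
            else:
                raise ValueError(f"unknown plasticity rule {rule!r}")
            normalize_weights(p)

    # -- protocols ---------------------------------------------------------

    def train(
        self,
        patch_source: Iterable[stim.ColorPatch] | None = None,
        n_iterations: int | None = None,
        trace_cadence: int = 0,
        clustering_layers: Sequence[str] = ("V1L4", "V1L23", "V1L5"),
        progress: bool = False,
    ) -> pd.DataFrame:
        """Iterate training presentations; returns the training trace.

        The trace records per-iteration mean V1 rates and near-bound
        weight fractions; if ``trace_cadence`` > 0, the clustering
        coefficient of each cortical layer is additionally measured
        every that many iterations (plus at the start and end) with a
        frozen-weight color test.
        """
        from .analysis import clustering_coefficient, weight_bimodality

        cfg = self.config
        n_iter = cfg.n_iterations if n_iterations is None else n_iterations
        if patch_source is None:
            patch_rng = np.random.default_rng(cfg.input_seed)
            patch_source = stim.synth_patch_sampler(
                n_iter, cfg.photoreceptor_dims, patch_rng, style="natural_mix"
            )
        noise_rng = np.random.default_rng(cfg.noise_seed)
        it_patches: Iterator[stim.ColorPatch] = iter(patch_source)
        rows = []
        for it in range(n_iter):
            patch = next(it_patches)
            raster = self.run_trial(patch, rng=noise_rng)
            row = {"iteration": it}
            for nm in ("V1L4", "V1L23", "V1L5"):
                row[f"rate_{nm}"] = float(raster.layer_rates(self.network, nm).mean())
            for p in self.network.plastic_projections():
                row[f"bound_frac_{p.name}"] = weight_bimodality(
                    p.weight, p.w_min, p.w_max
                ).near_bound_fraction
            if trace_cadence and (it % trace_cadence == 0 or it == n_iter - 1):
                table = self.test_colors(n_transforms=1, duration_ms=cfg.iteration_ms)
                for nm in clustering_layers:
                    row[f"clustering_{nm}"] = clustering_coefficient(table, layer=nm).C
            rows.append(row)
            if progress and it % 25 == 0:
                print(f"iteration {it}/{n_iter}  L5 rate {row['rate_V1L5']:.2f} Hz")
        return pd.DataFrame(rows)

    def test_colors(
        self,
        colors: dict[str, tuple[float, float, float]] | None = None,
        n_transforms: int | None = None,
        transform_frac: float | None = None,
        duration_ms: float | None = None,
        rng: np.random.Generator | None = None,
    ) -> RateTable:
        """Full-field presentation of each color and its transforms,
        plasticity off; returns mean rates per cell."""
        cfg = self.config
        colors = stim.named_test_colors() if colors is None else colors
        n_trans = cfg.n_transforms if n_transforms is None else n_transforms
        frac = cfg.transform_frac if transform_frac is None else transform_frac
        duration = cfg.iteration_ms if duration_ms is None else duration_ms
        rng = np.random.default_rng(cfg.noise_seed + 104729) if rng is None else rng
        rows, cols = cfg.photoreceptor_dims
        names = list(colors)
        rates = np.zeros((len(names), n_trans, self.n_hh))
        for si, nm in enumerate(names):
            variants = stim.color_transforms(colors[nm], n_trans, frac, rng)
            for ti in range(n_trans):
                patch = stim.uniform_patch(variants[ti], rows, cols)
                raster = self.run_trial(patch, rule="frozen", rng=rng, duration_ms=duration)
                counts = np.bincount(
                    raster.cells[raster.cells >= self.n_input] - self.n_input,
                    minlength=self.n_hh,
                )
                rates[si, ti] = counts * 1000.0 / duration
        slices, dims = {}, {}
        for spec in self.network.layers:
            if spec.name in INPUT_LAYERS:
                continue
            lo, hi = self.network.cell_range(spec.name)
            slices[spec.name] = slice(lo - self.n_input, hi - self.n_input)
            dims[spec.name] = (spec.rows, spec.cols)
        return RateTable(rates, names, slices, dims)

    def on_off_protocol(
        self,
        colors: dict[str, tuple[float, float, float]] | None = None,
        on_ms: float | None = None,
        off_ms: float | None = None,
        rng: np.random.Generator | None = None,
    ) -> dict[str, SpikeRaster]:
        """One ON+OFF trial per color with full spike recording."""
        cfg = self.config
        colors = stim.named_test_colors() if colors is None else colors
        on = cfg.on_ms if on_ms is None else on_ms
        off = cfg.off_ms if off_ms is None else off_ms
        rng = np.random.default_rng(cfg.noise_seed + 15485863) if rng is None else rng
        rows, cols = cfg.photoreceptor_dims
        out = {}
        for nm, rgb in colors.items():
            patch = stim.uniform_patch(rgb, rows, cols)
            raster = self.run_trial(
                patch, rule="frozen", rng=rng, duration_ms=on + off, stim_until_ms=on
            )
            raster.metadata.update({"stimulus": nm, "on_ms": on, "off_ms": off})
            out[nm] = raster
        return out


# -- thin functional wrappers ----------------------------------------------

def run_trial(network, patch, config, rule=None, rng=None, **kw):
    return Simulator(network, config).run_trial(patch, rule=rule, rng=rng, **kw)


def train(network, config, patch_source=None, **kw):
    sim = Simulator(network, config)
    trace = sim.train(patch_source, **kw)
    return network, trace


def test_colors(network, config, **kw):
    return Simulator(network, config).test_colors(**kw)


def on_off_protocol(network, config, **kw):
    return Simulator(network, config).on_off_protocol(**kw)
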