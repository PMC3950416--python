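import numpy as np
import pytest

from chromanet.circuit import LayerSpec, NetworkModel
from chromanet.engine import RateTable, SpikeRaster
from chromanet.membrane import AMPA, GABA, MembraneParams


@pytest.fixture
def make_rate_table():
    """Factory for single-layer rate tables on an rows x cols grid."""

    def factory(rates, layer="V1L5", rows=None, cols=None):
        rates = np.asarray(rates, dtype=float)
        n = rates.shape[2]
        if rows is None:
            rows = int(np.sqrt(n))
            cols = n // rows
        return RateTable(
            rates_hz=rates,
            stimuli=[f"s{i}" for i in range(rates.shape[0])],
            layer_slices={layer: slice(0, n)},
            grid_dims={layer: (rows, cols)},
        )

    return factory


@pytest.fixture
def grid_network():
    """Minimal network with 1x1 input layers and one rows x cols output
    layer, enough for raster-window analyses."""

    def factory(rows=6, cols=6, layer="V1L5"):
        layers = [LayerSpec(nm, 1, 1) for nm in ("R", "G", "B")]
        layers.append(LayerSpec(layer, rows, cols))
        return NetworkModel(
            layers=layers,
            projections=[],
            membrane=MembraneParams(),
            ampa=AMPA,
            gaba=GABA,
            input_phases=np.zeros(3),
            seed=0,
        )

    return factory


@pytest.fixture
def make_raster():
    def factory(cells, times, duration=300.0, n_cells=39, **meta):
        return SpikeRaster(
            np.asarray(cells, dtype=np.int64),
            np.asarray(times, dtype=float),
            duration,
            n_cells,
            metadata=dict(meta),
        )

    return factory
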