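"""On-disk formats: rasters as TSV + JSON sidecar, weights as HDF5."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .circuit import NetworkModel
from .engine import SpikeRaster

__all__ = ["save_raster", "load_raster", "save_weights", "load_weights"]


def save_raster(path, raster: SpikeRaster, network: NetworkModel) -> None:
    """Write ``layer  cell_row  cell_col  time_ms`` rows plus a ``.json``
    metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("layer\tcell_row\tcell_col\ttime_ms\n")
        for gid, t in zip(raster.cells, raster.times):
            for spec in network.layers:
                lo = network.offset(spec.name)
                if lo <= gid < lo + spec.n:
                    local = gid - lo
                    fh.write(
                        f"{spec.name}\t{local // spec.cols}\t{local % spec.cols}\t{t:.4f}\n"
                    )
                    break
    meta = {
        "duration_ms": raster.duration_ms,
        "n_cells": raster.n_cells,
        "n_spikes": raster.n_spikes,
        **raster.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_raster(path, network: NetworkModel) -> SpikeRaster:
    path = Path(path)
    cells, times = [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            layer, row, col, t = line.rstrip("\n").split("\t")
            spec = network.layer(layer)
            cells.append(network.offset(layer) + int(row) * spec.cols + int(col))
            times.append(float(t))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    duration = meta.pop("duration_ms")
    meta.pop("n_spikes", None)
    n_cells = meta.pop("n_cells")
    return SpikeRaster(
        np.asarray(cells), np.asarray(times), duration, n_cells, metadata=meta
    )


def save_weights(path, network: NetworkModel) -> None:
    """Snapshot every projection's edge table into an HDF5 group."""
    with h5py.File(path, "w") as fh:
        for p in network.projections:
            g = fh.create_group(p.name)
            for key in ("src", "tgt", "weight", "delay_ms", "is_gaba"):
                g.create_dataset(key, data=getattr(p, key))
            g.attrs.update(
                source=p.source, target=p.target, plastic=p.plastic,
                w_min=p.w_min, w_max=p.w_max,
            )


def load_weights(path, network: NetworkModel) -> None:
    """Restore projection weights saved by :func:`save_weights` in place."""
    with h5py.File(path, "r") as fh:
        for p in network.projections:
            if p.name not in fh:
                raise KeyError(f"projection {p.name!r} missing from {path}")
            w = np.asarray(fh[p.name]["weight"])
            if w.shape != p.weight.shape:
                raise ValueError(f"weight shape mismatch for {p.name!r}")
            p.weight[:] = w
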