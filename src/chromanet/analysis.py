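"""Rate-based statistics: spatial clustering, information measures and
ON/OFF cell selection.

All statistics consume a :class:`~chromanet.engine.RateTable` (mean rate
per stimulus, transform and cell) or a :class:`~chromanet.engine.SpikeRaster`.

Clustering coefficient
    The mean pairwise product of normalized rates over each cell's 3x3
    spatial neighborhood, averaged over cells and stimuli — a spatial
    co-activation statistic (not the graph-theoretic coefficient).
    Rates are min-max normalized to [0, 1] per stimulus across the
    layer so the coefficient itself lies in [0, 1].

Single-cell information
    For each cell, responses are discretized into equal-width bins over
    the cell's observed range and the stimulus-specific information
    I(s, R) = sum_r P(r|s) log2 [P(r|s) / P(r)] is computed, with the
    transforms of each stimulus providing the response distribution.
    The ceiling is log2(n_stims) bits — 3 bits for 8 stimuli.

Multiple-cell information
    Cells are ranked by single-cell information and added one at a
    time.  Each held presentation is decoded with a Bayesian decoder
    using independent per-cell Gaussian likelihoods (mean and SD over
    transforms, SD floored); the mutual information of the resulting
    soft (stimulus, decoded) confusion distribution is reported per
    subset size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb, log2

import numpy as np
from scipy.stats import norm

from .engine import RateTable, SpikeRaster
from .circuit import NetworkModel

__all__ = [
    "ClusteringResult",
    "InfoResult",
    "BimodalityResult",
    "OpponentSelection",
    "clustering_coefficient",
    "single_cell_info",
    "multiple_cell_info",
    "cells_to_plateau",
    "select_on_off_cells",
    "select_opponent_cells",
    "weight_bimodality",
    "dip_statistic",
]

SD_FLOOR_HZ = 1e-3


@dataclass
class ClusteringResult:
    C: float
    per_cell: np.ndarray  # (n_stims, n_cells)
    k: int
    layer: str


@dataclass
class InfoResult:
    layer: str
    max_bits: float
    single_bits: np.ndarray | None = None          # (n_cells,) max over stimuli
    per_stimulus_bits: np.ndarray | None = None    # (n_cells, n_stims)
    multiple_bits: np.ndarray | None = None        # (max_cells,)
    ranking: np.ndarray | None = None


@dataclass
class BimodalityResult:
    near_bound_fraction: float
    dip: float


@dataclass
class OpponentSelection:
    cells: np.ndarray
    off_counts: np.ndarray
    short: bool           # fewer qualifying cells than requested
    n_requested: int


def _stimulus_mean(table: RateTable, layer: str) -> np.ndarray:
    """(n_stims, n_cells) transform-averaged rates of one layer."""
    return table.layer(layer).mean(axis=1)


def clustering_coefficient(
    table: RateTable, layer: str = "V1L5", radius: int = 1
) -> ClusteringResult:
    """Spatial co-activation coefficient over square neighborhoods.

    ``radius`` 1 gives the default 3x3 (k = 9) neighborhood, which
    includes the center cell; border cells use their truncated
    neighborhood with the pair count adjusted accordingly.
    """
    rows, cols = table.grid_dims[layer]
    fr = _stimulus_mean(table, layer)  # (S, n)
    n_stims, n_cells = fr.shape
    norm_fr = np.empty_like(fr)
    for s in range(n_stims):
        lo, hi = fr[s].min(), fr[s].max()
        if hi > lo:
            norm_fr[s] = (fr[s] - lo) / (hi - lo)
        elif hi == 0.0:
            norm_fr[s] = 0.0
        else:
            warnings.warn(
                f"stimulus {s}: all rates equal ({hi:.3g} Hz); normalized value set to 1"
            )
            norm_fr[s] = 1.0
    per_cell = np.zeros((n_stims, n_cells))
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            r0, r1 = max(0, r - radius), min(rows - 1, r + radius)
            c0, c1 = max(0, c - radius), min(cols - 1, c + radius)
            idx = [rr * cols + cc for rr in range(r0, r1 + 1) for cc in range(c0, c1 + 1)]
            k_i = len(idx)
            if k_i < 2:
                continue
            x = norm_fr[:, idx]  # (S, k_i)
            pair_sum = 0.5 * (x.sum(axis=1) ** 2 - (x**2).sum(axis=1))
            per_cell[:, i] = pair_sum / comb(k_i, 2)
    C = float(per_cell.mean())
    return ClusteringResult(C=C, per_cell=per_cell, k=(2 * radius + 1) ** 2, layer=layer)


def single_cell_info(
    table: RateTable, layer: str = "V1L5", n_bins: int = 8
) -> InfoResult:
    """Stimulus-specific information of every cell in a layer."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    resp = table.layer(layer)  # (S, T, n)
    n_stims, n_trans, n_cells = resp.shape
    per_stim = np.zeros((n_cells, n_stims))
    for i in range(n_cells):
        r = resp[:, :, i]
        lo, hi = r.min(), r.max()
        if hi <= lo:
            continue  # zero response range: information 0 by convention
        bins = np.clip(((r - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
        p_r = np.bincount(bins.ravel(), minlength=n_bins) / (n_stims * n_trans)
        for s in range(n_stims):
            p_rs = np.bincount(bins[s], minlength=n_bins) / n_trans
            nz = p_rs > 0
            per_stim[i, s] = float(np.sum(p_rs[nz] * np.log2(p_rs[nz] / p_r[nz])))
    return InfoResult(
        layer=layer,
        max_bits=log2(n_stims),
        single_bits=per_stim.max(axis=1),
        per_stimulus_bits=per_stim,
    )


def multiple_cell_info(
    table: RateTable,
    layer: str = "V1L5",
    max_cells: int = 15,
    ranking: np.ndarray | None = None,
    sd_floor: float = SD_FLOOR_HZ,
) -> InfoResult:
    """Mutual information of Bayesian population decoding vs subset size.

    Cells are added in decreasing single-cell-information order (ties by
    cell index).  Every presentation (s, t) is decoded under a uniform
    stimulus prior with independent Gaussian per-cell likelihoods; the
    soft confusion distribution P(s, s') accumulates the posteriors and
    its mutual information is reported for each subset size.
    """
    resp = table.layer(layer)  # (S, T, n)
    n_stims, n_trans, n_cells = resp.shape
    max_cells = min(max_cells, n_cells)
    if ranking is None:
        single = single_cell_info(table, layer=layer).single_bits
        ranking = np.lexsort((np.arange(n_cells), -single))
    cells = np.asarray(ranking)[:max_cells]
    mean = resp.mean(axis=1)  # (S, n)
    sd = np.maximum(resp.std(axis=1, ddof=0), sd_floor)

    # log-likelihood of each presentation (s, t) under each candidate s',
    # per cell: shape (S, T, S', n_sel)
    r_obs = resp[:, :, cells]  # (S, T, n_sel)
    mu = mean[:, cells]  # (S', n_sel)
    sg = sd[:, cells]
    ll = norm.logpdf(
        r_obs[:, :, None, :], loc=mu[None, None, :, :], scale=sg[None, None, :, :]
    )  # (S, T, S', n_sel)

    info = np.zeros(max_cells)
    for k in range(1, max_cells + 1):
        tot = ll[:, :, :, :k].sum(axis=3)  # (S, T, S')
        tot -= tot.max(axis=2, keepdims=True)
        post = np.exp(tot)
        post /= post.sum(axis=2, keepdims=True)
        joint = post.sum(axis=1) / (n_stims * n_trans)  # (S, S')
        ps = joint.sum(axis=1)
        psp = joint.sum(axis=0)
        nz = joint > 0
        denom = np.outer(ps, psp)
        info[k - 1] = float(np.sum(joint[nz] * np.log2(joint[nz] / denom[nz])))
    return InfoResult(
        layer=layer, max_bits=log2(n_stims), multiple_bits=info, ranking=cells
    )


def cells_to_plateau(curve: np.ndarray, frac: float = 0.95) -> int:
    """Number of cells needed to reach ``frac`` of the curve's plateau."""
    curve = np.asarray(curve, dtype=float)
    target = frac * curve.max()
    return int(np.argmax(curve >= target)) + 1


# ---------------------------------------------------------------------------
# ON/OFF cell selection
# ---------------------------------------------------------------------------

def _window_scores(
    raster: SpikeRaster, network: NetworkModel, layer: str, window: tuple[float, float]
) -> np.ndarray:
    return raster.window_counts(network, layer, window[0], window[1])


def select_on_off_cells(
    raster: SpikeRaster,
    network: NetworkModel,
    layer: str = "V1L5",
    on_window: tuple[float, float] | None = None,
    off_window: tuple[float, float] | None = None,
    n_select: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Top responders just after stimulus onset and just after removal.

    Windows default to the first 60 ms of the stimulus and the 60 ms
    following its removal (taken from the raster's ON/OFF metadata).
    Returns (on_cells, on_counts, off_cells, off_counts) with cells in
    descending count order, ties broken by cell index.
    """
    on_ms = raster.metadata.get("on_ms", 240.0)
    off_ms = raster.metadata.get("off_ms", 60.0)
    if on_window is None:
        on_window = (0.0, min(60.0, on_ms))
    if off_window is None:
        off_window = (on_ms, on_ms + off_ms)
    on_counts = _window_scores(raster, network, layer, on_window)
    off_counts = _window_scores(raster, network, layer, off_window)

    def rank(counts):
        return np.lexsort((np.arange(len(counts)), -counts))[:n_select]

    on_cells = rank(on_counts)
    off_cells = rank(off_counts)
    return on_cells, on_counts[on_cells], off_cells, off_counts[off_cells]


def select_opponent_cells(
    rasters: dict[str, SpikeRaster],
    network: NetworkModel,
    primary_color: str,
    opponent_color: str,
    layer: str = "V1L5",
    n_pool: int = 100,
    n_select: int = 30,
    min_off_count: int = 1,
) -> OpponentSelection:
    """Cells that are ON for one color and OFF for its opponent.

    First the ``n_pool`` strongest ON responders to ``primary_color``
    are taken, then ranked by their OFF-window response to
    ``opponent_color``; cells with fewer than ``min_off_count`` OFF
    spikes do not qualify.  A selection shorter than ``n_select`` is
    flagged — the signature of the no-input-delay ablation, in which
    opponent OFF cells fail to appear.
    """
    prim = rasters[primary_color]
    opp = rasters[opponent_color]
    on_cells, _, _, _ = select_on_off_cells(
        prim, network, layer=layer, n_select=n_pool
    )
    on_ms = opp.metadata.get("on_ms", 240.0)
    off_ms = opp.metadata.get("off_ms", 60.0)
    off_counts = _window_scores(opp, network, layer, (on_ms, on_ms + off_ms))
    pool_scores = off_counts[on_cells]
    order = np.lexsort((on_cells, -pool_scores))
    ranked = on_cells[order]
    scores = pool_scores[order]
    qualified = ranked[scores >= min_off_count][:n_select]
    return OpponentSelection(
        cells=qualified,
        off_counts=off_counts[qualified],
        short=len(qualified) < n_select,
        n_requested=n_select,
    )


# ---------------------------------------------------------------------------
# Weight distribution shape
# ---------------------------------------------------------------------------

def dip_statistic(x: np.ndarray, max_points: int = 400, n_modes: int = 80) -> float:
    """Deviation of the empirical CDF from the nearest unimodal CDF.

    A CDF is unimodal with mode m when it is convex left of m and
    concave right of m.  For each candidate mode the sup-norm distance
    to the nearest such function is half the largest gap between the
    ECDF and its greatest convex minorant on the left part (resp. least
    concave majorant on the right part); the statistic minimizes this
    over candidate modes.  Large samples are reduced to ``max_points``
    quantiles and ``n_modes`` candidate mode locations.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 4 or x[-1] == x[0]:
        return 0.0
    if n > max_points:
        x = np.quantile(x, np.linspace(0.0, 1.0, max_points))
        n = max_points
    f = np.arange(1, n + 1) / n

    def max_convex_gap(xs, fs):
        """max of fs - GCM(fs) over these points (0 if convex)."""
        hull = [0]
        for i in range(1, len(xs)):
            while len(hull) >= 2:
                i1, i2 = hull[-2], hull[-1]
                if (xs[i2] - xs[i1]) * (fs[i] - fs[i1]) <= (fs[i2] - fs[i1]) * (xs[i] - xs[i1]):
                    hull.pop()
                else:
                    break
            hull.append(i)
        gap = 0.0
        hi = 0
        for i in range(len(xs)):
            while hi < len(hull) - 2 and xs[hull[hi + 1]] <= xs[i]:
                hi += 1
            j, k = hull[hi], hull[hi + 1]
            if xs[k] > xs[j]:
                g = fs[j] + (fs[k] - fs[j]) * (xs[i] - xs[j]) / (xs[k] - xs[j])
            else:
                g = fs[j]
            gap = max(gap, fs[i] - g)
        return gap

    modes = np.unique(np.linspace(0, n - 1, min(n_modes, n)).astype(int))
    best = np.inf
    for m in modes:
        left = max_convex_gap(x[: m + 1], f[: m + 1]) if m >= 2 else 0.0
        # concave right part: mirror to reuse the convex routine
        right = (
            max_convex_gap(-x[m:][::-1], -f[m:][::-1]) if m <= n - 3 else 0.0
        )
        best = min(best, max(left, right))
        if best == 0.0:
            break
    return float(best / 2.0)


def weight_bimodality(
    weights: np.ndarray, w_min: float, w_max: float
) -> BimodalityResult:
    """Fraction of weights within 10 % of either bound, plus a dip-type
    unimodality deviation; both are reported.  A uniform distribution
    gives a near-bound fraction of ~0.2 and a small dip."""
    w = np.asarray(weights, dtype=float)
    if len(w) < 10:
        raise ValueError("need at least 10 weights")
    band = 0.1 * (w_max - w_min)
    frac = float(np.mean((w <= w_min + band) | (w >= w_max - band)))
    return BimodalityResult(near_bound_fraction=frac, dip=dip_statistic(w))
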