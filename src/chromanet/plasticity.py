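"""Synaptic learning rules and weight normalization.

The spike-timing dependent rule potentiates a synapse when the
presynaptic spike precedes the postsynaptic spike and depresses it for
the opposite order, with exponential windows:

    dw = +LR * exp(-(t_post - t_pre) / p_tau)   if t_post > t_pre
    dw = -LR * exp( (t_post - t_pre) / d_tau)   if t_post < t_pre

with p_tau = 17 ms and d_tau = 34 ms by default; the wider depression
window makes uncorrelated firing net-depressing.  Coincident spikes
(dt exactly 0) produce no change by convention.

Spike pairing is nearest-neighbor by default: each postsynaptic spike
pairs with the closest preceding presynaptic spike, and each presynaptic
spike with the closest preceding postsynaptic spike.  All-to-all pairing
is available for comparison.

The order-blind Hebbian control potentiates a synapse by a fixed
amplitude once per presentation whenever both cells fired at least once
within the window, regardless of relative timing.

After every training iteration each plastic projection's weights are
rescaled multiplicatively so their mean sits at the middle of the
allowed range, then clipped — repeated until the mean converges.  This
keeps total drive constant and prevents runaway excitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit import Projection

__all__ = [
    "STDPParams",
    "stdp_delta",
    "pair_deltas",
    "apply_stdp",
    "hebbian_update",
    "normalize_weights",
]


@dataclass(frozen=True)
class STDPParams:
    lr: float
    p_tau_ms: float = 17.0
    d_tau_ms: float = 34.0
    w_min: float = 0.0
    w_max: float = 1.0
    pairing: str = "nearest"  # or "all"

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.p_tau_ms <= 0 or self.d_tau_ms <= 0:
            raise ValueError("lr and time constants must be positive")
        if not (0 <= self.w_min < self.w_max):
            raise ValueError("require 0 <= w_min < w_max")


def stdp_delta(t_pre: float, t_post: float, params: STDPParams) -> float:
    """Weight change for a single pre/post spike pair."""
    dt = t_post - t_pre
    if dt > 0:
        return params.lr * math.exp(-dt / params.p_tau_ms)
    if dt < 0:
        return -params.lr * math.exp(dt / params.d_tau_ms)
    return 0.0


def pair_deltas(
    pre: np.ndarray, post: np.ndarray, params: STDPParams
) -> float:
    """Summed weight change for one synapse over one trial.

    Nearest-neighbor pairing: every post spike contributes a potentiation
    term with the latest pre spike strictly before it; every pre spike
    contributes a depression term with the latest post spike strictly
    before it.  All-to-all pairing sums ``stdp_delta`` over the full
    cross product.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    if params.pairing == "all":
        dt = post[None, :] - pre[:, None]
        out = np.where(
            dt > 0,
            params.lr * np.exp(-dt / params.p_tau_ms),
            np.where(dt < 0, -params.lr * np.exp(dt / params.d_tau_ms), 0.0),
        )
        return float(out.sum())
    if params.pairing != "nearest":
        raise ValueError(f"unknown pairing scheme {params.pairing!r}")
    total = 0.0
    # potentiation: latest pre strictly before each post
    idx = np.searchsorted(pre, post, side="left") - 1
    ok = idx >= 0
    dt = post[ok] - pre[idx[ok]]
    dt = dt[dt > 0]
    total += params.lr * np.exp(-dt / params.p_tau_ms).sum()
    # depression: latest post strictly before each pre
    idx = np.searchsorted(post, pre, side="left") - 1
    ok = idx >= 0
    dt = post[idx[ok]] - pre[ok]  # negative
    dt = dt[dt < 0]
    total -= params.lr * np.exp(dt / params.d_tau_ms).sum()
    return float(total)


def _spike_lists(spikes: dict[int, np.ndarray] | list[np.ndarray], n: int):
    if isinstance(spikes, dict):
        return [np.asarray(spikes.get(i, ()), dtype=float) for i in range(n)]
    return [np.asarray(s, dtype=float) for s in spikes]


def apply_stdp(
    projection: Projection,
    pre_spikes,
    post_spikes,
    params: STDPParams,
) -> Projection:
    """Accumulate STDP over one trial's spikes, then clip to the bounds.

    ``pre_spikes``/``post_spikes`` give sorted spike times per local cell
    index of the source/target layer (list of arrays or dict).  Weights
    are updated in place and the projection returned.
    """
    if not projection.plastic:
        raise ValueError(f"projection {projection.name} is not plastic")
    n_pre = int(projection.src.max()) + 1 if projection.n_edges else 0
    n_post = int(projection.tgt.max()) + 1 if projection.n_edges else 0
    pre_l = _spike_lists(pre_spikes, n_pre)
    post_l = _spike_lists(post_spikes, n_post)
    pre_active = {i for i, s in enumerate(pre_l) if len(s)}
    post_active = {i for i, s in enumerate(post_l) if len(s)}
    for e in range(projection.n_edges):
        s, t = projection.src[e], projection.tgt[e]
        if s in pre_active and t in post_active:
            projection.weight[e] += pair_deltas(pre_l[s], post_l[t], params)
    np.clip(projection.weight, params.w_min, params.w_max, out=projection.weight)
    return projection


def hebbian_update(
    projection: Projection,
    pre_spikes,
    post_spikes,
    amplitude: float,
    window_ms: float = 300.0,
) -> Projection:
    """Order-blind control rule: potentiate once per presentation when
    both cells spiked within the window, regardless of lag."""
    if not projection.plastic:
        raise ValueError(f"projection {projection.name} is not plastic")
    n_pre = int(projection.src.max()) + 1 if projection.n_edges else 0
    n_post = int(projection.tgt.max()) + 1 if projection.n_edges else 0
    pre_l = _spike_lists(pre_spikes, n_pre)
    post_l = _spike_lists(post_spikes, n_post)

    def active(lists):
        return np.array(
            [bool(len(s)) and s.min() <= window_ms for s in lists], dtype=bool
        )

    pre_a, post_a = active(pre_l), active(post_l)
    if projection.n_edges:
        both = pre_a[projection.src] & post_a[projection.tgt]
        projection.weight[both] += amplitude
        np.clip(projection.weight, projection.w_min, projection.w_max, out=projection.weight)
    return projection


def normalize_weights(projection: Projection, target_mean: float | None = None) -> Projection:
    """Rescale a plastic projection's weights to the target mean.

    The mean is pulled to the middle of [w_min, w_max] (or an explicit
    target) by multiplicative rescaling followed by clipping, iterated
    until the mean is within 1e-6 of the target or 100 passes.  An
    all-zero weight vector is reset uniformly to the target (the
    degenerate case where no ratio information survives).
    """
    if projection.n_edges == 0:
        raise ValueError("projection has no edges")
    if target_mean is None:
        target_mean = 0.5 * (projection.w_min + projection.w_max)
    w = projection.weight
    if np.all(w == 0):
        w[:] = target_mean
        return projection
    for _ in range(100):
        mean = w.mean()
        if abs(mean - target_mean) <= 1e-6:
            break
        w *= target_mean / mean
        np.clip(w, projection.w_min, projection.w_max, out=w)
    return projection
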