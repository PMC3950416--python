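"""Independent brute-force implementations used as oracles.

Literal, loop-based renderings of each statistic's definition, kept
deliberately separate from the package's vectorized implementations.
"""

import math
from math import comb, log2

import numpy as np
from scipy.stats import norm


def brute_force_nearest_stdp(pre, post, params):
    """Nearest-neighbor pairing by explicit enumeration."""
    total = 0.0
    for tp in post:
        before = [t for t in pre if t < tp]
        if before:
            total += params.lr * math.exp(-(tp - max(before)) / params.p_tau_ms)
    for tq in pre:
        before = [t for t in post if t < tq]
        if before:
            total -= params.lr * math.exp((max(before) - tq) / params.d_tau_ms)
    return total


def brute_force_clustering(fr, rows, cols, radius=1):
    """Per cell and stimulus, mean pairwise product of min-max normalized
    rates over the (truncated) square neighborhood; double loop."""
    n_stims = fr.shape[0]
    total = 0.0
    for s in range(n_stims):
        lo, hi = fr[s].min(), fr[s].max()
        if hi > lo:
            nf = (fr[s] - lo) / (hi - lo)
        elif hi == 0:
            nf = np.zeros_like(fr[s])
        else:
            nf = np.ones_like(fr[s])
        for r in range(rows):
            for c in range(cols):
                idx = [
                    rr * cols + cc
                    for rr in range(max(0, r - radius), min(rows, r + radius + 1))
                    for cc in range(max(0, c - radius), min(cols, c + radius + 1))
                ]
                k = len(idx)
                acc = 0.0
                for a in range(k):
                    for b in range(a + 1, k):
                        acc += nf[idx[a]] * nf[idx[b]]
                total += acc / comb(k, 2)
    return total / (n_stims * rows * cols)


def brute_force_single_info(resp, n_bins):
    """Explicit probability tables per cell and stimulus."""
    n_stims, n_trans, n_cells = resp.shape
    out = np.zeros((n_cells, n_stims))
    for i in range(n_cells):
        r = resp[:, :, i]
        lo, hi = r.min(), r.max()
        if hi <= lo:
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        which = np.minimum(np.searchsorted(edges, r, side="right") - 1, n_bins - 1)
        for s in range(n_stims):
            for b in range(n_bins):
                p_rs = np.mean(which[s] == b)
                p_r = np.mean(which == b)
                if p_rs > 0:
                    out[i, s] += p_rs * log2(p_rs / p_r)
    return out


def brute_force_multi_info(resp, cells, sd_floor=1e-3):
    """Loop-based Bayesian decoder for one fixed cell set."""
    n_stims, n_trans, _ = resp.shape
    mean = resp.mean(axis=1)
    sd = np.maximum(resp.std(axis=1), sd_floor)
    joint = np.zeros((n_stims, n_stims))
    for s in range(n_stims):
        for t in range(n_trans):
            logpost = np.zeros(n_stims)
            for sp in range(n_stims):
                for c in cells:
                    logpost[sp] += norm.logpdf(resp[s, t, c], mean[sp, c], sd[sp, c])
            logpost -= logpost.max()
            post = np.exp(logpost)
            post /= post.sum()
            joint[s] += post
    joint /= n_stims * n_trans
    ps, psp = joint.sum(1), joint.sum(0)
    info = 0.0
    for s in range(n_stims):
        for sp in range(n_stims):
            if joint[s, sp] > 0 and ps[s] > 0 and psp[sp] > 0:
                info += joint[s, sp] * log2(joint[s, sp] / (ps[s] * psp[sp]))
    return info
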