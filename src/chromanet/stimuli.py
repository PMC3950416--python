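"""Color stimuli: RGB patches, cone rates and input spike trains.

A stimulus is a small RGB raster patch (channels in [0, 1]).  Each pixel
drives the three cone classes through a fixed linear transform whose
40 Hz ceiling is reached for full-field white:

    S = 40 * B
    M = 40 * (G + 0.7 R + 0.25 B) / 1.95
    L = 40 * (R + 0.7 G + 0.25 B) / 1.95

The cross-talk terms mirror the broad, overlapping spectral sensitivity
of M and L cones: a pure red stimulus still drives the M channel
substantially.  The photoreceptor grids are conventionally named R, G
and B after the driving channel, but carry L-, M- and S-cone rates
respectively.

Input cells fire clock-like regular trains at their cone rate (25 ms
interspike interval at the 40 Hz ceiling), with +/-10 % multiplicative
rate noise redrawn per presentation and a fixed per-cell onset phase
drawn once at network construction.  The phase spreads the final spikes
of equal-rate cells over up to one interspike interval, the ingredient
behind stimulus-OFF responses; an ablation flag zeroes all phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ColorPatch",
    "ConeDrive",
    "MAX_RATE_HZ",
    "rgb_to_cone_rates",
    "regular_train",
    "generate_input_spikes",
    "synth_patch_sampler",
    "corner_colors",
    "named_test_colors",
    "color_transforms",
    "uniform_patch",
]

MAX_RATE_HZ = 40.0
_M_WEIGHTS = (0.7, 1.0, 0.25)   # (R, G, B) numerator weights for the M cone
_L_WEIGHTS = (1.0, 0.7, 0.25)
_NORM = 1.0 + 0.7 + 0.25


@dataclass(frozen=True)
class ColorPatch:
    """An rows x cols RGB raster with channel values in [0, 1]."""

    pixels: np.ndarray  # shape (rows, cols, 3)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("patch must have shape (rows, cols, 3)")
        if not np.all(np.isfinite(px)) or px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("channel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ConeDrive:
    """Per-pixel cone firing rates in Hz (before presentation noise)."""

    l_hz: np.ndarray
    m_hz: np.ndarray
    s_hz: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.l_hz.shape


def uniform_patch(rgb: Sequence[float], rows: int, cols: int) -> ColorPatch:
    """Full-field patch of a single color."""
    px = np.broadcast_to(np.asarray(rgb, dtype=float), (rows, cols, 3)).copy()
    return ColorPatch(px)


def rgb_to_cone_rates(patch: ColorPatch) -> ConeDrive:
    """Apply the cone transform pixelwise.

    Monotone in every channel for every cone; white maps to 40 Hz on all
    three cones and black to silence.
    """
    r = patch.pixels[..., 0]
    g = patch.pixels[..., 1]
    b = patch.pixels[..., 2]
    s = MAX_RATE_HZ * b
    m = MAX_RATE_HZ * (_M_WEIGHTS[0] * r + _M_WEIGHTS[1] * g + _M_WEIGHTS[2] * b) / _NORM
    l = MAX_RATE_HZ * (_L_WEIGHTS[0] * r + _L_WEIGHTS[1] * g + _L_WEIGHTS[2] * b) / _NORM
    return ConeDrive(l_hz=l, m_hz=m, s_hz=s)


def regular_train(
    rate_hz: float, duration_ms: float, phase: float = 0.0
) -> np.ndarray:
    """Spike times of a clock-like train: onset + k * ISI within the window.

    ``phase`` in [0, 1) positions the onset within one interspike
    interval.  A zero rate yields an empty train.
    """
    if rate_hz <= 0.0:
        return np.empty(0)
    isi = 1000.0 / rate_hz
    onset = phase * isi
    if onset >= duration_ms:
        return np.empty(0)
    times = onset + isi * np.arange(int(np.ceil((duration_ms - onset) / isi)) + 1)
    return times[times < duration_ms]


def generate_input_spikes(
    rates_hz: np.ndarray,
    duration_ms: float,
    noise_frac: float,
    rng: np.random.Generator,
    phases: np.ndarray | None = None,
    mode: str = "regular",
) -> list[np.ndarray]:
    """Spike trains for a flat vector of input cells.

    Each cell's nominal rate is scaled by ``1 + eps`` with
    ``eps ~ U(-noise_frac, +noise_frac)`` redrawn per call (one draw per
    presentation per cell).  ``phases`` are the fixed per-cell onset
    phases in [0, 1); ``None`` means zero phase for every cell
    (the no-delay ablation).  ``mode='poisson'`` replaces the clock-like
    train with a homogeneous Poisson train at the same effective rate.
    """
    rates = np.asarray(rates_hz, dtype=float).ravel()
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    if phases is None:
        phases = np.zeros(rates.size)
    eps = rng.uniform(-noise_frac, noise_frac, size=rates.size) if noise_frac > 0 else np.zeros(rates.size)
    trains: list[np.ndarray] = []
    for f, e, u in zip(rates, eps, phases):
        eff = f * (1.0 + e)
        if eff <= 0.0:
            trains.append(np.empty(0))
        elif mode == "regular":
            trains.append(regular_train(eff, duration_ms, u))
        elif mode == "poisson":
            n = rng.poisson(eff * duration_ms / 1000.0)
            trains.append(np.sort(rng.uniform(0.0, duration_ms, size=n)))
        else:
            raise ValueError(f"unknown train mode {mode!r}")
    return trains


# ---------------------------------------------------------------------------
# Test palettes
# ---------------------------------------------------------------------------

def corner_colors() -> dict[str, tuple[float, float, float]]:
    """The eight corners of the RGB cube (all 0/1 combinations)."""
    names = ["black", "red", "green", "blue", "yellow", "magenta", "cyan", "white"]
    vals = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
            (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    return {n: tuple(float(x) for x in v) for n, v in zip(names, vals)}


def named_test_colors() -> dict[str, tuple[float, float, float]]:
    """Eight distinct hues used for selectivity testing.

    Unlike the cube corners this palette contains no black, so every
    stimulus actually drives the network.
    """
    return {
        "red": (1.0, 0.0, 0.0),
        "orange": (1.0, 0.5, 0.0),
        "yellow": (1.0, 1.0, 0.0),
        "green": (0.0, 1.0, 0.0),
        "aqua": (0.0, 1.0, 1.0),
        "blue": (0.0, 0.0, 1.0),
        "purple": (0.5, 0.0, 1.0),
        "pink": (1.0, 0.5, 0.75),
    }


def color_transforms(
    rgb: Sequence[float],
    n_transforms: int,
    frac: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Slightly varied copies of a color: each channel scaled by 1 +/- frac.

    The first transform is the unperturbed color; perturbations are
    multiplicative (a zero channel stays zero) and clipped to [0, 1].
    """
    base = np.asarray(rgb, dtype=float)
    out = np.empty((n_transforms, 3))
    out[0] = base
    for k in range(1, n_transforms):
        out[k] = np.clip(base * (1.0 + rng.uniform(-frac, frac, size=3)), 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Synthetic training patches
# ---------------------------------------------------------------------------

def synth_patch_sampler(
    n_patches: int,
    dims: tuple[int, int],
    rng: np.random.Generator,
    style: str = "smooth_field",
    corner_only: bool = False,
) -> Iterator[ColorPatch]:
    """Generate small RGB patches emulating crops of natural color scenes.

    Three styles are available:

    ``uniform_color``
        Constant patches; colors alternate between cube corners and
        uniformly random interior points (``corner_only`` restricts to
        corners).
    ``smooth_field``
        Per-channel low-pass filtered noise, rescaled to a random
        contrast band, giving spatially correlated pixels with broad hue
        coverage — the stand-in for patches cropped from photographs.
    ``two_tone``
        The patch split by a random straight edge between two random
        colors.
    ``natural_mix``
        A mixture emulating crops of natural scenes: mostly smooth
        fields, with occasional two-tone object boundaries and
        full-field saturated colors, so training covers both soft
        gradients and the saturated hues that dominate color testing.
    """
    if n_patches <= 0:
        raise ValueError("n_patches must be positive")
    rows, cols = dims
    corners = np.array(list(corner_colors().values()), dtype=float)
    for _ in range(n_patches):
        if style == "natural_mix":
            u = rng.random()
            style_now = "smooth_field" if u < 0.6 else ("two_tone" if u < 0.85 else "uniform_color")
        else:
            style_now = style
        if style_now == "uniform_color":
            if corner_only or rng.random() < 0.5:
                rgb = corners[rng.integers(len(corners))]
            else:
                rgb = rng.uniform(0.0, 1.0, size=3)
            yield uniform_patch(rgb, rows, cols)
        elif style_now == "smooth_field":
            px = np.empty((rows, cols, 3))
            for c in range(3):
                field = gaussian_filter(rng.uniform(0.0, 1.0, size=(rows, cols)), sigma=2.0, mode="reflect")
                lo_f, hi_f = field.min(), field.max()
                span = hi_f - lo_f
                unit = (field - lo_f) / span if span > 0 else np.full_like(field, 0.5)
                lo = rng.uniform(0.0, 0.3)
                hi = rng.uniform(0.7, 1.0)
                px[..., c] = lo + (hi - lo) * unit
            yield ColorPatch(px)
        elif style_now == "two_tone":
            c1 = rng.uniform(0.0, 1.0, size=3)
            c2 = rng.uniform(0.0, 1.0, size=3)
            theta = rng.uniform(0.0, np.pi)
            normal = np.array([np.cos(theta), np.sin(theta)])
            center = rng.uniform(0.0, 1.0, size=2) * [rows - 1, cols - 1]
            rr, cc = np.mgrid[0:rows, 0:cols]
            side = (rr - center[0]) * normal[0] + (cc - center[1]) * normal[1] > 0
            px = np.where(side[..., None], c1, c2)
            yield ColorPatch(px)
        else:
            raise ValueError(f"unknown patch style {style_now!r}")
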