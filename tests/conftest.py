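"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's vectorized code paths: explicit
Python loops, explicit kernel construction, explicit floor division.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from phasorviz import ColorMapConfig, DecayStack, PhasorPoint

OMEGA_80MHZ = 2.0 * math.pi * 80.0 / 1000.0  # rad/ns at 80 MHz


@pytest.fixture
def omega80() -> float:
    return OMEGA_80MHZ


@pytest.fixture
def triangle_cmap() -> ColorMapConfig:
    """Three principal points inside the semicircle, center defaulted."""
    return ColorMapConfig(
        principal_points=(
            PhasorPoint(0.8, 0.35),
            PhasorPoint(0.25, 0.4),
            PhasorPoint(0.5, 0.1),
        )
    )


@pytest.fixture
def random_stack() -> DecayStack:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 200, size=(8, 8, 16))
    counts[0, 0] = 0  # one empty pixel to exercise the invalid path
    return DecayStack.from_counts(counts, rep_rate_MHz=80.0)


# ---------------------------------------------------------------------------
# oracles

def phasor_brute_force(stack: DecayStack, harmonic: int = 1):
    """Per-pixel triple loop over the discrete Fourier sums."""
    rows, cols, k = stack.counts.shape
    g = np.full((rows, cols), np.nan)
    s = np.full((rows, cols), np.nan)
    inten = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            tot = sg = ss = 0.0
            for j in range(k):
                w = float(stack.counts[r, c, j])
                ang = harmonic * 2.0 * math.pi * stack.bin_centers_ns[j] / stack.period_ns
                sg += w * math.cos(ang)
                ss += w * math.sin(ang)
                tot += w
            inten[r, c] = tot
            if tot > 0:
                g[r, c] = sg / tot
                s[r, c] = ss / tot
    return g, s, inten


def gaussian_kernel_2d(sigma: float, truncate: float) -> np.ndarray:
    """Explicitly constructed normalized 2D Gaussian kernel."""
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=float)
    k1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k1 /= k1.sum()
    return np.outer(k1, k1)


def convolve_reflect_brute(a: np.ndarray, sigma: float, truncate: float):
    """Double-loop convolution with symmetric (reflect) padding."""
    k2 = gaussian_kernel_2d(sigma, truncate)
    r = k2.shape[0] // 2
    pad = np.pad(a, r, mode="symmetric")
    rows, cols = a.shape
    out = np.zeros_like(a, dtype=float)
    for i in range(rows):
        for j in range(cols):
            acc = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    acc += k2[di + r, dj + r] * pad[i + di + r, j + dj + r]
            out[i, j] = acc
    return out


def weighted_phasor_smooth_brute(field, sigma: float, truncate: float):
    """Intensity-weighted Gaussian average of G and S, by explicit loops."""
    w = np.where(field.valid, field.intensity, 0.0)
    num_g = convolve_reflect_brute(w * np.where(field.valid, field.G, 0.0),
                                   sigma, truncate)
    num_s = convolve_reflect_brute(w * np.where(field.valid, field.S, 0.0),
                                   sigma, truncate)
    den = convolve_reflect_brute(w, sigma, truncate)
    g = np.full_like(num_g, np.nan)
    s = np.full_like(num_s, np.nan)
    ok = field.valid & (den > 0)
    g[ok] = num_g[ok] / den[ok]
    s[ok] = num_s[ok] / den[ok]
    return g, s, ok


def bin_index_brute(value: float, bin_size: float) -> int:
    """Half-open [k*b, (k+1)*b) bin index by explicit floor division."""
    return int(math.floor(value / bin_size))


def fit_circle_kasa(x: np.ndarray, y: np.ndarray):
    """Algebraic least-squares circle fit: x^2+y^2 = 2ax + 2by + c."""
    a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b_vec = x**2 + y**2
    (cx, cy, c), *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    radius = math.sqrt(c + cx**2 + cy**2)
    return cx, cy, radius
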