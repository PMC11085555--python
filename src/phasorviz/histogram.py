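"""Intensity-weighted 2D phasor histograms and the colored phasor plot.

Each valid image pixel deposits its intensity into the 0.02 x 0.02 bin
(default) containing its (G, S), so bright structures dominate the plot
without any threshold.  The plot is rendered with the same hue/saturation
colormap as the image (colors taken at geometric bin centers) and a value
channel from the binned weights, normalized separately from the image.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from matplotlib.colors import hsv_to_rgb
from skimage.draw import line as _draw_line

from .core import PhasorField, SEMICIRCLE_CENTER, SEMICIRCLE_RADIUS
from .colormap import (
    ColorMapConfig,
    RenderConfig,
    intensity_transfer,
    phasor_colors,
    resolve_center,
)

__all__ = ["PhasorHistogram", "bin_phasors", "render_phasor_plot",
           "export_histogram", "import_histogram"]

DEFAULT_RANGE = (-0.05, 1.05)


@dataclasses.dataclass
class PhasorHistogram:
    """Weights on a fixed grid of half-open bins [k*b, (k+1)*b) aligned at 0.

    The requested g/s ranges are snapped outward to bin-edge multiples of
    the bin size.  ``weights[i, j]`` covers g-bin i, s-bin j.  Out-of-range
    phasors accumulate in ``overflow_weight``.
    """

    bin_size: float
    g_edges: np.ndarray
    s_edges: np.ndarray
    weights: np.ndarray
    overflow_weight: float = 0.0

    @property
    def g_centers(self) -> np.ndarray:
        return 0.5 * (self.g_edges[:-1] + self.g_edges[1:])

    @property
    def s_centers(self) -> np.ndarray:
        return 0.5 * (self.s_edges[:-1] + self.s_edges[1:])

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum() + self.overflow_weight)


def _snapped_edges(lo: float, hi: float, b: float) -> tuple[int, np.ndarray]:
    k0 = int(np.floor(lo / b + 1e-12))
    k1 = int(np.ceil(hi / b - 1e-12))
    return k0, np.arange(k0, k1 + 1) * b


def bin_phasors(
    field: PhasorField,
    bin_size: float = 0.02,
    g_range: tuple[float, float] = DEFAULT_RANGE,
    s_range: tuple[float, float] = DEFAULT_RANGE,
) -> PhasorHistogram:
    """Accumulate each valid pixel's intensity into its (G, S) bin."""
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    kg0, g_edges = _snapped_edges(*g_range, bin_size)
    ks0, s_edges = _snapped_edges(*s_range, bin_size)
    ng, ns = len(g_edges) - 1, len(s_edges) - 1
    weights = np.zeros((ng, ns), dtype=float)
    m = field.valid
    g = field.G[m]
    s = field.S[m]
    w = field.intensity[m]
    ig = np.floor(g / bin_size).astype(int) - kg0
    is_ = np.floor(s / bin_size).astype(int) - ks0
    inside = (ig >= 0) & (ig < ng) & (is_ >= 0) & (is_ < ns)
    np.add.at(weights, (ig[inside], is_[inside]), w[inside])
    overflow = float(w[~inside].sum())
    if overflow > 0:
        warnings.warn(
            f"{(~inside).sum()} phasors outside the histogram range "
            f"(weight {overflow:g}) counted in the overflow bucket",
            stacklevel=2,
        )
    return PhasorHistogram(bin_size, g_edges, s_edges, weights, overflow)


def _to_pixel(h: PhasorHistogram, upscale: int, g: float, s: float) -> tuple[int, int]:
    """Map phasor coordinates to (row, col) of the upscaled plot image."""
    ng = len(h.g_edges) - 1
    ns = len(h.s_edges) - 1
    col = (g - h.g_edges[0]) / h.bin_size * upscale
    row = (h.s_edges[-1] - s) / h.bin_size * upscale
    col = int(np.clip(round(col), 0, ng * upscale - 1))
    row = int(np.clip(round(row), 0, ns * upscale - 1))
    return row, col


def _draw_polyline(img: np.ndarray, pix: list[tuple[int, int]],
                   color: tuple[float, float, float], closed: bool) -> None:
    pairs = list(zip(pix, pix[1:] + ([pix[0]] if closed else [])))
    for (r0, c0), (r1, c1) in pairs:
        rr, cc = _draw_line(r0, c0, r1, c1)
        img[rr, cc] = color


def render_phasor_plot(
    h: PhasorHistogram,
    cmap: ColorMapConfig,
    rc: RenderConfig | None = None,
    show_polygon: bool = True,
    show_center: bool = True,
    show_semicircle: bool = True,
    upscale: int = 8,
) -> np.ndarray:
    """RGB phasor-plot image, S up and G right.

    Bin colors come from the colormap at geometric bin centers; the value
    channel is the transfer of each bin's weight over the maximum weight.
    Overlays: principal-point polygon (light gray), center marker (cyan x),
    universal semicircle (gray).
    """
    rc = rc or RenderConfig()
    if h.weights.sum() <= 0:
        warnings.warn("empty histogram; rendering overlays on blank plot",
                      stacklevel=2)
    gg, ss = np.meshgrid(h.g_centers, h.s_centers, indexing="ij")
    hue, sat = phasor_colors(gg, ss, cmap)
    wmax = h.weights.max()
    norm = h.weights / wmax if wmax > 0 else h.weights
    value = intensity_transfer(norm, rc)
    hsv = np.stack([hue, sat, value], axis=-1)
    rgb = hsv_to_rgb(hsv)
    rgb[h.weights == 0] = rc.background
    # orient: rows = S descending (S up), cols = G ascending
    img = np.transpose(rgb, (1, 0, 2))[::-1].copy()
    img = np.kron(img, np.ones((upscale, upscale, 1)))
    if show_semicircle:
        t = np.linspace(0.0, np.pi, 256)
        arc = [
            _to_pixel(h, upscale,
                      SEMICIRCLE_CENTER[0] + SEMICIRCLE_RADIUS * np.cos(a),
                      SEMICIRCLE_CENTER[1] + SEMICIRCLE_RADIUS * np.sin(a))
            for a in t
        ]
        _draw_polyline(img, arc + [_to_pixel(h, upscale, 0.0, 0.0),
                                   _to_pixel(h, upscale, 1.0, 0.0)],
                       (0.5, 0.5, 0.5), closed=False)
    if show_polygon:
        pix = [_to_pixel(h, upscale, p.g, p.s) for p in cmap.principal_points]
        _draw_polyline(img, pix, (0.8, 0.8, 0.8), closed=True)
    if show_center:
        c = resolve_center(cmap)
        r0, c0 = _to_pixel(h, upscale, c.g, c.s)
        arm = max(2, upscale // 2)
        for dr, dc in ((1, 1), (1, -1)):
            rr, cc = _draw_line(r0 - arm * dr, c0 - arm * dc,
                                r0 + arm * dr, c0 + arm * dc)
            keep = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
            img[rr[keep], cc[keep]] = (0.0, 1.0, 1.0)
    return img


def export_histogram(h: PhasorHistogram, path) -> None:
    """Write the weight matrix as text with a header naming the bin edges."""
    header = (
        f"phasor histogram; bin_size={float(h.bin_size)!r}; "
        f"g_edges={float(h.g_edges[0])!r}..{float(h.g_edges[-1])!r}; "
        f"s_edges={float(h.s_edges[0])!r}..{float(h.s_edges[-1])!r}; "
        f"overflow={float(h.overflow_weight)!r}; rows=g bins, cols=s bins"
    )
    np.savetxt(path, h.weights, header=header)


def import_histogram(path) -> PhasorHistogram:
    """Read a histogram written by :func:`export_histogram`."""
    with open(path) as fh:
        header = fh.readline()
    if "phasor histogram" not in header:
        raise ValueError("not a phasor histogram file")
    fields = dict(
        item.strip().split("=", 1)
        for item in header.lstrip("# ").split(";")
        if "=" in item
    )
    b = float(fields["bin_size"])
    g_lo, g_hi = (float(x) for x in fields["g_edges"].split(".."))
    s_lo, s_hi = (float(x) for x in fields["s_edges"].split(".."))
    weights = np.loadtxt(path)
    weights = np.atleast_2d(weights)
    g_edges = g_lo + np.arange(weights.shape[0] + 1) * b
    s_edges = s_lo + np.arange(weights.shape[1] + 1) * b
    return PhasorHistogram(b, g_edges, s_edges, weights,
                           float(fields["overflow"]))
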