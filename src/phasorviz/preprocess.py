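"""Spatial smoothing and intensity thresholding of phasor fields.

Intensity is smoothed with a plain normalized Gaussian; G and S are smoothed
with a Gaussian *weighted by the raw per-pixel intensities*, so that bright
pixels dominate the local phasor average and empty pixels contribute
nothing.  Thresholds are fractions of the maximum smoothed intensity:
pixels below the low threshold are invalidated, pixels above the high
threshold are clipped (kept, but their display intensity is capped).

Pipeline order contract: smooth -> threshold -> color / histogram.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .core import PhasorField

__all__ = [
    "SmoothConfig",
    "ThresholdConfig",
    "smooth_intensity",
    "smooth_phasor",
    "apply_thresholds",
    "preprocess_field",
]


@dataclasses.dataclass(frozen=True)
class SmoothConfig:
    """Gaussian smoothing parameters: sigma in pixels, kernel cut in sigmas."""

    sigma_px: float = 1.0
    kernel_truncate: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_px < 0:
            raise ValueError("sigma must be non-negative")
        if self.kernel_truncate <= 0:
            raise ValueError("kernel_truncate must be positive")


@dataclasses.dataclass(frozen=True)
class ThresholdConfig:
    """Low/high intensity cuts as fractions of the max smoothed intensity."""

    low_fraction: float | None = None
    high_fraction: float | None = None

    def __post_init__(self) -> None:
        for name, v in (("low", self.low_fraction), ("high", self.high_fraction)):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} fraction must lie in [0, 1]")
        if (
            self.low_fraction is not None
            and self.high_fraction is not None
            and self.low_fraction > self.high_fraction
        ):
            raise ValueError("low threshold exceeds high threshold")


def _gauss(a: np.ndarray, cfg: SmoothConfig) -> np.ndarray:
    # reflective boundary preserves mass near edges (no dark frame)
    return ndimage.gaussian_filter(
        a, sigma=cfg.sigma_px, mode="reflect", truncate=cfg.kernel_truncate
    )


def smooth_intensity(intensity: np.ndarray, cfg: SmoothConfig) -> np.ndarray:
    """Normalized Gaussian filter of a non-negative intensity grid."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    if cfg.sigma_px == 0:
        return intensity.copy()
    return _gauss(intensity, cfg)


def smooth_phasor(field: PhasorField, cfg: SmoothConfig) -> PhasorField:
    """Intensity-weighted Gaussian average of G and S.

    Per pixel: ``G' = sum_q w(q) I(q) G(q) / sum_q w(q) I(q)`` with ``w`` a
    Gaussian of the configured sigma; likewise for S.  Invalid pixels carry
    zero weight; a pixel whose weighted support vanishes stays invalid.
    The intensity channel itself is untouched here.
    """
    if cfg.sigma_px == 0:
        return field.copy()
    w = np.where(field.valid, field.intensity, 0.0)
    num_g = _gauss(w * np.where(field.valid, field.G, 0.0), cfg)
    num_s = _gauss(w * np.where(field.valid, field.S, 0.0), cfg)
    den = _gauss(w, cfg)
    valid = field.valid & (den > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(valid, num_g / den, np.nan)
        s = np.where(valid, num_s / den, np.nan)
    return PhasorField(g, s, field.intensity.copy(), valid, field.harmonic)


def apply_thresholds(field: PhasorField, cfg: ThresholdConfig) -> PhasorField:
    """Invalidate below low*max intensity; clip above high*max (keep valid)."""
    out = field.copy()
    if cfg.low_fraction is None and cfg.high_fraction is None:
        return out
    if not np.any(field.valid):
        return out
    imax = float(field.intensity[field.valid].max())
    if cfg.low_fraction is not None:
        cut = cfg.low_fraction * imax
        kill = out.valid & (out.intensity < cut)
        out.valid[kill] = False
        out.G[kill] = np.nan
        out.S[kill] = np.nan
    if cfg.high_fraction is not None:
        cap = cfg.high_fraction * imax
        out.intensity = np.minimum(out.intensity, cap)
    return out


def preprocess_field(
    field: PhasorField,
    smooth: SmoothConfig | None = None,
    thresholds: ThresholdConfig | None = None,
) -> PhasorField:
    """Standard pipeline: smooth G/S (raw-intensity weights), smooth the
    intensity channel, then apply thresholds on the smoothed intensity."""
    smooth = smooth or SmoothConfig()
    out = smooth_phasor(field, smooth)
    out.intensity = smooth_intensity(field.intensity, smooth)
    if thresholds is not None:
        out = apply_thresholds(out, thresholds)
    return out
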