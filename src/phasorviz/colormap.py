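"""Invertible phasor-position -> (hue, saturation) colormap.

The map is anchored on an ordered list of "principal" points in the phasor
plot (ideally the positions of pure fluorescent species) plus a "center"
point where saturation vanishes (by default, the mean of the principal
points).

Hue encodes the *direction* from the center: the principal points receive
equidistant hues k/N (with 0 and 1 both on the first point) and the hue of
any other direction is the linear angular interpolation between the two
bracketing principal directions, increasing clockwise or anticlockwise
according to the order of the given points.

Saturation encodes the *distance* r from the center via a continuous,
strictly increasing three-piece profile.  Along the half-line from the
center through the phasor, let d1 be the distance to the crossing of the
closed polygon through the principal points and d2 the distance to the
crossing of the universal-semicircle boundary (roles swapped if the
semicircle is hit first):

    r <= d1        : v1_eff * sin(pi/2 * r/d1)
    d1 < r <= d2   : linear from v1_eff to v2
    r > d2         : 1 - (1 - v2) * exp(-(r - d2)/lambda),  lambda = (d1+d2)/2

with v2 = 0.95 and an uncorrected first value v1 = 0.85 by default;
v1_eff = v2 - (v2 - v1) * (d2 - d1)/d2 approaches v2 as the two crossings
coincide.  If a crossing is undefined along a direction (nonstandard
center placements) the missing distance is set equal to the available one,
which collapses the linear piece and keeps the profile continuous and
monotone; with both undefined the semicircle radius 1/2 is used.

Because hue is cyclically monotone in the angle and saturation strictly
monotone in the radius, the map is bijective and :func:`invert_color`
recovers the phasor position from a color exactly.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .core import PhasorPoint, PhasorField, SEMICIRCLE_CENTER, SEMICIRCLE_RADIUS

__all__ = [
    "ColorMapConfig",
    "SaturationGeometry",
    "RenderConfig",
    "resolve_center",
    "principal_angles",
    "hue_of",
    "saturation_geometry_of",
    "saturation_of",
    "color_of",
    "invert_color",
    "intensity_transfer",
    "render_image",
    "render_legend",
    "phasor_colors",
]

TWO_PI = 2.0 * np.pi
_T_MIN = 1e-12  # smallest ray parameter counted as a forward crossing


@dataclasses.dataclass(frozen=True)
class ColorMapConfig:
    """Principal points, optional center, and saturation constants."""

    principal_points: tuple[PhasorPoint, ...]
    center: PhasorPoint | None = None
    v1_uncorrected: float = 0.85
    v2: float = 0.95
    orientation: str = "auto"  # clockwise | anticlockwise | auto

    def __post_init__(self) -> None:
        pts = tuple(
            p if isinstance(p, PhasorPoint) else PhasorPoint(*p)
            for p in self.principal_points
        )
        object.__setattr__(self, "principal_points", pts)
        if self.center is not None and not isinstance(self.center, PhasorPoint):
            object.__setattr__(self, "center", PhasorPoint(*self.center))
        if len(pts) < 2:
            raise ValueError("need at least two principal points")
        arr = np.array([p.as_array() for p in pts])
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if arr[i, 0] == arr[j, 0] and arr[i, 1] == arr[j, 1]:
                    raise ValueError("principal points must be pairwise distinct")
        if not 0.0 < self.v1_uncorrected <= self.v2 < 1.0:
            raise ValueError("require 0 < v1 <= v2 < 1")
        if self.orientation not in ("clockwise", "anticlockwise", "auto"):
            raise ValueError("orientation must be clockwise|anticlockwise|auto")
        c = resolve_center(self)
        if any(np.hypot(p.g - c.g, p.s - c.s) < 1e-12 for p in pts):
            raise ValueError("a principal point coincides with the center")

    @classmethod
    def from_dict(cls, d: dict) -> "ColorMapConfig":
        known = {"principal_points", "center", "v1", "v2", "orientation"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown colormap config keys: {sorted(unknown)}")
        return cls(
            principal_points=tuple(PhasorPoint(*p) for p in d["principal_points"]),
            center=PhasorPoint(*d["center"]) if d.get("center") is not None else None,
            v1_uncorrected=float(d.get("v1", 0.85)),
            v2=float(d.get("v2", 0.95)),
            orientation=d.get("orientation", "auto"),
        )

    def to_dict(self) -> dict:
        return {
            "principal_points": [[p.g, p.s] for p in self.principal_points],
            "center": [self.center.g, self.center.s] if self.center else None,
            "v1": self.v1_uncorrected,
            "v2": self.v2,
            "orientation": self.orientation,
        }


@dataclasses.dataclass(frozen=True)
class SaturationGeometry:
    """Radial geometry along one direction from the center.

    d1: distance to the polygon-boundary crossing; d2: distance to the
    universal-semicircle boundary crossing (after role normalization
    d1 <= d2); lam: exponential tail constant (d1+d2)/2; v1_effective:
    gap-corrected saturation value reached at d1.
    """

    d1: float
    d2: float
    lam: float
    v1_effective: float


@dataclasses.dataclass(frozen=True)
class RenderConfig:
    """Value-channel transfer: linear, or linear-then-log above x% of max."""

    scale: str = "linear"
    log_crossover_percent: float = 1.0
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        if not 0.0 < self.log_crossover_percent < 100.0:
            raise ValueError("log crossover must be in (0, 100) percent")


def resolve_center(cfg: ColorMapConfig) -> PhasorPoint:
    """Explicit center if given, else the mean of the principal points."""
    if cfg.center is not None:
        return cfg.center
    arr = np.array([p.as_array() for p in cfg.principal_points])
    g, s = arr.mean(axis=0)
    return PhasorPoint(float(g), float(s))


class _AngleTable:
    """Unwrapped principal-point angles and hue anchors for one config."""

    def __init__(self, cfg: ColorMapConfig):
        c = resolve_center(cfg).as_array()
        pts = np.array([p.as_array() for p in cfg.principal_points])
        rel = pts - c
        radii = np.hypot(rel[:, 0], rel[:, 1])
        if np.any(radii < 1e-12):
            raise ValueError("a principal point coincides with the center")
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        if cfg.orientation == "auto":
            delta = np.angle(np.exp(1j * (theta[1] - theta[0])))
            orient = 1.0 if delta > 0 else -1.0
        else:
            orient = 1.0 if cfg.orientation == "anticlockwise" else -1.0
        u = np.mod(orient * (theta - theta[0]), TWO_PI)
        u[0] = 0.0
        # correct to strictly increasing in the chosen orientation
        for k in range(1, len(u)):
            if u[k] <= u[k - 1]:
                u[k] = min(u[k - 1] + 1e-9, TWO_PI - 1e-12)
        self.center = c
        self.theta0 = float(theta[0])
        self.orient = orient
        self.u = u  # ascending orientation-angles, u[0] = 0
        self.u_ext = np.append(u, TWO_PI)
        self.n = len(u)

    def angle_to_u(self, theta: np.ndarray) -> np.ndarray:
        return np.mod(self.orient * (theta - self.theta0), TWO_PI)

    def u_to_theta(self, u: float) -> float:
        return self.theta0 + self.orient * u


def principal_angles(cfg: ColorMapConfig) -> tuple[np.ndarray, np.ndarray]:
    """Angles of the principal points about the center (radians, in the
    chosen orientation, first point at 0, strictly increasing) and their
    hue anchors k/N, with the cyclic wrap anchor 1 appended."""
    table = _AngleTable(cfg)
    anchors = np.append(np.arange(table.n) / table.n, 1.0)
    return table.u_ext.copy(), anchors


# ---------------------------------------------------------------------------
# hue

def _hue_from_table(table: _AngleTable, gx: np.ndarray, sy: np.ndarray) -> np.ndarray:
    rel_g = gx - table.center[0]
    rel_s = sy - table.center[1]
    theta = np.arctan2(rel_s, rel_g)
    u = table.angle_to_u(theta)
    k = np.clip(np.searchsorted(table.u_ext, u, side="right") - 1, 0, table.n - 1)
    u_lo = table.u_ext[k]
    u_hi = table.u_ext[k + 1]
    frac = (u - u_lo) / (u_hi - u_lo)
    hue = (k + frac) / table.n
    # the center itself has no direction; hue 0 by convention (saturation 0)
    at_center = (rel_g == 0) & (rel_s == 0)
    hue = np.where(at_center, 0.0, hue)
    return np.mod(hue, 1.0)


def hue_of(p: PhasorPoint, cfg: ColorMapConfig) -> float:
    """Hue in [0, 1) of a phasor position (piecewise-linear in the angle)."""
    table = _AngleTable(cfg)
    return float(_hue_from_table(table, np.array(p.g), np.array(p.s)))


# ---------------------------------------------------------------------------
# saturation geometry

def _ray_polygon_distance(
    center: np.ndarray, dir_g: np.ndarray, dir_s: np.ndarray, poly: np.ndarray
) -> np.ndarray:
    """Nearest forward crossing of rays (center, dir) with a closed polygon.

    Edge parameters carry a small tolerance so a ray through a vertex is
    robust; double hits at a shared vertex collapse under the min.  NaN
    where the ray misses the polygon.
    """
    a = poly
    b = np.roll(poly, -1, axis=0)
    e = b - a  # (m, 2)
    q = a - center  # (m, 2)
    dg = dir_g[..., None]
    ds = dir_s[..., None]
    denom = dg * e[:, 1] - ds * e[:, 0]  # d x E, (..., m)
    qxe = q[:, 0] * e[:, 1] - q[:, 1] * e[:, 0]  # scalar per edge
    qxd = q[:, 0] * ds - q[:, 1] * dg  # (..., m)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = qxe / denom
        u = qxd / denom
    ok = (np.abs(denom) > 1e-15) & (u >= -1e-9) & (u <= 1 + 1e-9) & (t > _T_MIN)
    t = np.where(ok, t, np.inf)
    d1 = t.min(axis=-1)
    return np.where(np.isfinite(d1), d1, np.nan)


def _ray_semicircle_distance(
    center: np.ndarray, dir_g: np.ndarray, dir_s: np.ndarray
) -> np.ndarray:
    """Nearest forward crossing with the closed universal-semicircle boundary
    (arc (g-1/2)^2 + s^2 = 1/4, s >= 0, plus the diameter segment on s = 0)."""
    cg0, cs0 = SEMICIRCLE_CENTER
    r = SEMICIRCLE_RADIUS
    fg = center[0] - cg0
    fs = center[1] - cs0
    # circle: t^2 + 2 t (d.f) + |f|^2 - r^2 = 0
    bb = dir_g * fg + dir_s * fs
    cc = fg * fg + fs * fs - r * r
    disc = bb * bb - cc
    best = np.full(np.broadcast(dir_g, dir_s).shape, np.inf)
    with np.errstate(invalid="ignore"):
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
    for sign in (-1.0, 1.0):
        t = -bb + sign * sq
        s_at = center[1] + t * dir_s
        ok = np.isfinite(t) & (t > _T_MIN) & (s_at >= -1e-12)
        best = np.where(ok & (t < best), t, best)
    # diameter segment s = 0, 0 <= g <= 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t_diam = -center[1] / dir_s
        g_at = center[0] + t_diam * dir_g
    ok = (
        np.isfinite(t_diam)
        & (t_diam > _T_MIN)
        & (g_at >= -1e-12)
        & (g_at <= 1 + 1e-12)
    )
    best = np.where(ok & (t_diam < best), t_diam, best)
    return np.where(np.isfinite(best), best, np.nan)


def _geometry_arrays(
    table: _AngleTable,
    poly: np.ndarray,
    dir_g: np.ndarray,
    dir_s: np.ndarray,
    v1_0: float,
    v2: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    d1 = _ray_polygon_distance(table.center, dir_g, dir_s, poly)
    d2 = _ray_semicircle_distance(table.center, dir_g, dir_s)
    both = np.isfinite(d1) & np.isfinite(d2)
    # roles: d1 is the nearer crossing, d2 the farther
    lo = np.where(both, np.minimum(d1, d2), np.nan)
    hi = np.where(both, np.maximum(d1, d2), np.nan)
    # nonstandard fallbacks: a missing crossing inherits the other distance;
    # both missing -> semicircle radius.  Collapses the linear piece,
    # keeping the profile continuous and monotone.
    only1 = np.isfinite(d1) & ~np.isfinite(d2)
    only2 = ~np.isfinite(d1) & np.isfinite(d2)
    none = ~np.isfinite(d1) & ~np.isfinite(d2)
    lo = np.where(only1, d1, lo)
    hi = np.where(only1, d1, hi)
    lo = np.where(only2, d2, lo)
    hi = np.where(only2, d2, hi)
    lo = np.where(none, SEMICIRCLE_RADIUS, lo)
    hi = np.where(none, SEMICIRCLE_RADIUS, hi)
    lam = 0.5 * (lo + hi)
    v1_eff = np.clip(v2 - (v2 - v1_0) * (hi - lo) / hi, v1_0, v2)
    return lo, hi, lam, v1_eff


def _polygon(cfg: ColorMapConfig) -> np.ndarray:
    return np.array([p.as_array() for p in cfg.principal_points])


def saturation_geometry_of(p: PhasorPoint, cfg: ColorMapConfig) -> SaturationGeometry:
    """Crossing distances, decay constant, and corrected v1 along the
    half-line from the center through ``p``."""
    table = _AngleTable(cfg)
    rel = p.as_array() - table.center
    r = float(np.hypot(*rel))
    if r < 1e-15:
        raise ValueError("geometry undefined at the center point")
    dg, ds = rel / r
    lo, hi, lam, v1e = _geometry_arrays(
        table, _polygon(cfg), np.array(dg), np.array(ds), cfg.v1_uncorrected, cfg.v2
    )
    return SaturationGeometry(float(lo), float(hi), float(lam), float(v1e))


def _sat_profile(
    r: np.ndarray,
    d1: np.ndarray,
    d2: np.ndarray,
    lam: np.ndarray,
    v1e: np.ndarray,
    v2: float,
) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_part = v1e * np.sin(0.5 * np.pi * np.where(d1 > 0, r / d1, 0.0))
        gap = np.where(d2 > d1, d2 - d1, 1.0)
        lin_part = v1e + (v2 - v1e) * (r - d1) / gap
        exp_part = 1.0 - (1.0 - v2) * np.exp(-(r - d2) / lam)
    sat = np.where(r <= d1, sin_part, np.where(r <= d2, lin_part, exp_part))
    return np.where(r == 0, 0.0, sat)


def saturation_of(p: PhasorPoint, cfg: ColorMapConfig) -> float:
    """Saturation in [0, 1): zero at the center, v2 at the semicircle
    crossing, asymptotically 1 far outside."""
    table = _AngleTable(cfg)
    return float(
        _sat_from_table(table, _polygon(cfg), np.array(p.g), np.array(p.s), cfg)
    )


def _sat_from_table(
    table: _AngleTable,
    poly: np.ndarray,
    gx: np.ndarray,
    sy: np.ndarray,
    cfg: ColorMapConfig,
) -> np.ndarray:
    rel_g = gx - table.center[0]
    rel_s = sy - table.center[1]
    r = np.hypot(rel_g, rel_s)
    safe_r = np.where(r > 0, r, 1.0)
    dg = rel_g / safe_r
    ds = rel_s / safe_r
    lo, hi, lam, v1e = _geometry_arrays(
        table, poly, dg, ds, cfg.v1_uncorrected, cfg.v2
    )
    return _sat_profile(r, lo, hi, lam, v1e, cfg.v2)


def color_of(p: PhasorPoint, cfg: ColorMapConfig) -> tuple[float, float]:
    """(hue, saturation) of one phasor position."""
    return hue_of(p, cfg), saturation_of(p, cfg)


def phasor_colors(
    gx: np.ndarray, sy: np.ndarray, cfg: ColorMapConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (hue, saturation) for arrays of phasor coordinates."""
    table = _AngleTable(cfg)
    poly = _polygon(cfg)
    gx = np.asarray(gx, dtype=float)
    sy = np.asarray(sy, dtype=float)
    return _hue_from_table(table, gx, sy), _sat_from_table(table, poly, gx, sy, cfg)


def invert_color(hue: float, saturation: float, cfg: ColorMapConfig) -> PhasorPoint:
    """The unique phasor position with the given (hue, saturation).

    Direction from inverting the piecewise-linear angular map, radius from
    inverting the strictly monotone saturation profile along it.
    """
    if not 0.0 <= saturation < 1.0:
        raise ValueError("saturation must lie in [0, 1): no finite preimage")
    table = _AngleTable(cfg)
    c = table.center
    if saturation == 0.0:
        return PhasorPoint(float(c[0]), float(c[1]))
    hue = float(np.mod(hue, 1.0))
    n = table.n
    k = min(int(np.floor(hue * n)), n - 1)
    frac = hue * n - k
    u = table.u_ext[k] + frac * (table.u_ext[k + 1] - table.u_ext[k])
    theta = table.u_to_theta(u)
    dg, ds = np.cos(theta), np.sin(theta)
    lo, hi, lam, v1e = _geometry_arrays(
        table, _polygon(cfg), np.array(dg), np.array(ds), cfg.v1_uncorrected, cfg.v2
    )
    d1, d2, lam, v1e = float(lo), float(hi), float(lam), float(v1e)
    v2 = cfg.v2
    if saturation <= v1e:
        r = d1 * (2.0 / np.pi) * np.arcsin(saturation / v1e)
    elif saturation <= v2:
        r = d1 + (saturation - v1e) / (v2 - v1e) * (d2 - d1)
    else:
        r = d2 - lam * np.log((1.0 - saturation) / (1.0 - v2))
    return PhasorPoint(float(c[0] + r * dg), float(c[1] + r * ds))


# ---------------------------------------------------------------------------
# value channel and rendering

def intensity_transfer(normalized_intensity, rc: RenderConfig):
    """Map normalized intensity to the HSV value channel.

    Linear scale: identity.  Log scale with crossover ``x_f = x/100``:
    ``V = c*I`` below the crossover and ``V = c*x_f*(1 + ln(I/x_f))`` above,
    with ``c`` chosen so V(1) = 1 — continuous with continuous slope at the
    crossover.
    """
    i = np.asarray(normalized_intensity, dtype=float)
    scalar = i.ndim == 0
    if np.any(i < 0) or np.any(i > 1):
        warnings.warn("normalized intensity outside [0, 1]; clipping", stacklevel=2)
        i = np.clip(i, 0.0, 1.0)
    if rc.scale == "linear":
        v = i
    else:
        xf = rc.log_crossover_percent / 100.0
        c = 1.0 / (xf * (1.0 + np.log(1.0 / xf)))
        with np.errstate(divide="ignore"):
            log_branch = c * xf * (1.0 + np.log(np.where(i > xf, i / xf, 1.0)))
        v = np.where(i <= xf, c * i, log_branch)
    return float(v) if scalar else v


def render_image(
    field: PhasorField,
    cmap: ColorMapConfig,
    rc: RenderConfig | None = None,
) -> np.ndarray:
    """RGB rendering of a phasor field (float array in [0, 1], rows x cols x 3).

    Per valid pixel, HSV = (hue, saturation, transfer(I / I_max)); invalid
    pixels get the background color.
    """
    rc = rc or RenderConfig()
    rows, cols = field.shape
    out = np.empty((rows, cols, 3), dtype=float)
    out[:] = rc.background
    if not np.any(field.valid):
        warnings.warn("field has no valid pixels; rendering background only",
                      stacklevel=2)
        return out
    v_mask = field.valid
    hue, sat = phasor_colors(field.G[v_mask], field.S[v_mask], cmap)
    imax = float(field.intensity[v_mask].max())
    value = intensity_transfer(field.intensity[v_mask] / imax, rc)
    hsv = np.stack([hue, sat, value], axis=-1)
    out[v_mask] = hsv_to_rgb(hsv)
    return out


def render_legend(
    cmap: ColorMapConfig,
    resolution: int = 256,
    background: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Legend image: (hue, saturation) at full value sampled over the
    universal semicircle, S up, G right."""
    g = np.linspace(-0.05, 1.05, resolution)
    s = np.linspace(-0.05, 1.05, resolution)
    gg, ss = np.meshgrid(g, s[::-1])
    inside = ((gg - SEMICIRCLE_CENTER[0]) ** 2 + ss**2 <= SEMICIRCLE_RADIUS**2 + 1e-12) & (
        ss >= 0
    )
    hue, sat = phasor_colors(gg, ss, cmap)
    hsv = np.stack([hue, sat, np.ones_like(hue)], axis=-1)
    rgb = hsv_to_rgb(hsv)
    rgb[~inside] = background
    return rgb
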