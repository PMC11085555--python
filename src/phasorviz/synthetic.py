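"""Ground-truth FLIM scene and acquisition simulation.

Every pipeline stage is testable without instrument data: scenes are built
from species with known (multi)exponential decays, pixels mix species by
*intensity* (photon) fraction — matching the linear-combination rule of the
phasor plot — and acquisition draws Poisson counts per time bin at a stated
photon budget.  An instrument phase/modulation distortion can be applied to
exercise calibration.

Scene kinds emulate the qualitative structure of the samples this kind of
tool is pointed at: a uniform solution, bright crystal blobs in a dim
solved background, and cell-like blobs with spatially varying two-species
mixture fractions (free vs bound NAD(P)H, say).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import DecayStack, PhasorField, PhasorPoint, lifetime_to_phasor

__all__ = [
    "Species",
    "SceneSpec",
    "Scene",
    "build_scene",
    "simulate_stack",
    "distort_instrument",
    "mixture_phasor",
]


@dataclasses.dataclass(frozen=True)
class Species:
    """A fluorescent species: one or more decay components.

    ``amplitude_fractions`` are pre-exponential amplitudes (normalized to
    sum to 1); the species' photon-intensity weights are proportional to
    ``a_j * tau_j``.
    """

    name: str
    lifetimes_ns: tuple[float, ...]
    amplitude_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in np.atleast_1d(self.lifetimes_ns))
        object.__setattr__(self, "lifetimes_ns", taus)
        if any(t <= 0 for t in taus):
            raise ValueError("lifetimes must be positive")
        if self.amplitude_fractions is None:
            amps = tuple([1.0 / len(taus)] * len(taus))
        else:
            a = np.asarray(self.amplitude_fractions, dtype=float)
            if np.any(a < 0) or a.sum() <= 0:
                raise ValueError("amplitude fractions must be non-negative")
            amps = tuple(a / a.sum())
        if len(amps) != len(taus):
            raise ValueError("one amplitude per lifetime required")
        object.__setattr__(self, "amplitude_fractions", amps)

    def decay(self, t_ns: np.ndarray) -> np.ndarray:
        """Multi-exponential decay value at the given times."""
        t = np.asarray(t_ns, dtype=float)[..., None]
        a = np.asarray(self.amplitude_fractions)
        tau = np.asarray(self.lifetimes_ns)
        return np.sum(a * np.exp(-t / tau), axis=-1)

    def phasor(self, omega_rad_per_ns: float) -> PhasorPoint:
        """Continuum (analytic) phasor: intensity-weighted combination of
        the single-lifetime semicircle positions."""
        a = np.asarray(self.amplitude_fractions)
        tau = np.asarray(self.lifetimes_ns)
        w = a * tau
        w = w / w.sum()
        z = sum(
            wi * lifetime_to_phasor(ti, omega_rad_per_ns).as_complex()
            for wi, ti in zip(w, tau)
        )
        return PhasorPoint(z.real, z.imag)

    def sampled_phasor(
        self, bin_centers_ns: np.ndarray, omega_rad_per_ns: float, harmonic: int = 1
    ) -> PhasorPoint:
        """Phasor of the decay *as sampled* on the given bin centers (carries
        the small O((omega*dt)^2) discretization bias of the pipeline)."""
        c = self.decay(bin_centers_ns)
        phase = harmonic * omega_rad_per_ns * np.asarray(bin_centers_ns)
        total = c.sum()
        return PhasorPoint(
            float(np.sum(c * np.cos(phase)) / total),
            float(np.sum(c * np.sin(phase)) / total),
        )


def mixture_phasor(
    species: list[Species], fractions, omega_rad_per_ns: float
) -> PhasorPoint:
    """Analytic phasor of an intensity-fraction mixture of species."""
    f = np.asarray(fractions, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("intensity fractions must sum to 1")
    z = sum(fi * sp.phasor(omega_rad_per_ns).as_complex()
            for fi, sp in zip(f, species))
    return PhasorPoint(z.real, z.imag)


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Recipe for a synthetic scene.

    ``photons_per_pixel`` is the mean photon budget of occupied (foreground)
    pixels; ``background_photons`` the budget of the dim background in the
    crystals scene.  ``mixture_fractions`` (uniform scene only) are global
    per-species intensity fractions.  The instrument distortion rotates all
    phasors by ``phase_shift_rad`` and scales their modulation by
    ``modulation_scale``.  ``seed`` fixes all randomness.
    """

    shape: tuple[int, int] = (64, 64)
    species: tuple[Species, ...] = (
        Species("solution", (1.5,)),
        Species("crystal", (0.5, 4.0), (0.3, 0.7)),
    )
    kind: str = "uniform"  # uniform | crystals_in_solution | cell_blobs
    mixture_fractions: tuple[float, ...] | None = None
    photons_per_pixel: float = 10_000.0
    background_photons: float = 500.0
    n_blobs: int = 6
    blob_radius_px: tuple[float, float] = (3.0, 8.0)
    cell_fraction_range: tuple[float, float] = (0.2, 0.8)
    phase_shift_rad: float = 0.0
    modulation_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "crystals_in_solution", "cell_blobs"):
            raise ValueError(f"unknown scene kind {self.kind!r}")
        if self.photons_per_pixel < 0 or self.background_photons < 0:
            raise ValueError("photon budgets must be non-negative")
        if self.modulation_scale <= 0:
            raise ValueError("modulation scale must be positive")


@dataclasses.dataclass
class Scene:
    """Ground truth: per-species intensity-fraction maps and a photon map."""

    spec: SceneSpec
    fractions: np.ndarray  # (n_species, rows, cols), sums to 1 or 0
    photons: np.ndarray  # (rows, cols)


def _ellipse_coverage(
    shape: tuple[int, int], cy: float, cx: float, ry: float, rx: float,
    angle: float, subsample: int = 4,
) -> np.ndarray:
    """Fractional pixel coverage of a rotated ellipse (subpixel sampling),
    so blob edges produce genuinely mixed pixels."""
    rows, cols = shape
    off = (np.arange(subsample) + 0.5) / subsample - 0.5
    yy = np.arange(rows)[:, None, None, None] + off[None, None, :, None]
    xx = np.arange(cols)[None, :, None, None] + off[None, None, None, :]
    dy = yy - cy
    dx = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / rx
    v = (-sa * dx + ca * dy) / ry
    inside = (u * u + v * v) <= 1.0
    return inside.mean(axis=(2, 3))


def build_scene(spec: SceneSpec) -> Scene:
    """Deterministic (seeded) ground-truth fraction and photon maps."""
    rows, cols = spec.shape
    n_sp = len(spec.species)
    rng = np.random.default_rng(spec.seed)
    fractions = np.zeros((n_sp, rows, cols))
    photons = np.zeros((rows, cols))

    if spec.kind == "uniform":
        f = spec.mixture_fractions
        if f is None:
            f = tuple([1.0 / n_sp] * n_sp)
        f = np.asarray(f, dtype=float)
        if len(f) != n_sp or abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
            raise ValueError("mixture fractions must be one non-negative "
                             "value per species summing to 1")
        fractions[:] = f[:, None, None]
        photons[:] = spec.photons_per_pixel

    elif spec.kind == "crystals_in_solution":
        if n_sp != 2:
            raise ValueError("crystals scene needs exactly two species "
                             "(solution background, crystal blobs)")
        coverage = np.zeros((rows, cols))
        r_lo, r_hi = spec.blob_radius_px
        for _ in range(spec.n_blobs):
            cy = rng.uniform(0, rows)
            cx = rng.uniform(0, cols)
            ry = rng.uniform(r_lo, r_hi)
            rx = rng.uniform(r_lo, r_hi) * rng.uniform(1.0, 2.0)  # elongated
            ang = rng.uniform(0, np.pi)
            coverage = np.maximum(
                coverage, _ellipse_coverage((rows, cols), cy, cx, ry, rx, ang)
            )
        photons = (
            (1.0 - coverage) * spec.background_photons
            + coverage * spec.photons_per_pixel
        )
        with np.errstate(invalid="ignore"):
            f_crystal = np.where(
                photons > 0, coverage * spec.photons_per_pixel / photons, 0.0
            )
        fractions[1] = f_crystal
        fractions[0] = np.where(photons > 0, 1.0 - f_crystal, 0.0)

    else:  # cell_blobs
        if n_sp != 2:
            raise ValueError("cell scene needs exactly two species")
        f_lo, f_hi = spec.cell_fraction_range
        r_lo, r_hi = spec.blob_radius_px
        occupied = np.zeros((rows, cols), dtype=bool)
        f_map = np.zeros((rows, cols))
        yy, xx = np.mgrid[0:rows, 0:cols]
        for _ in range(spec.n_blobs):
            cy = rng.uniform(0, rows)
            cx = rng.uniform(0, cols)
            r = rng.uniform(r_lo, r_hi)
            f_blob = rng.uniform(f_lo, f_hi)
            inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            # mild radial gradient: mixture varies within each cell
            grad = 0.1 * (1.0 - ((yy - cy) ** 2 + (xx - cx) ** 2) / (r * r))
            f_map = np.where(inside, np.clip(f_blob + grad, 0.0, 1.0), f_map)
            occupied |= inside
        fractions[1] = np.where(occupied, f_map, 0.0)
        fractions[0] = np.where(occupied, 1.0 - f_map, 0.0)
        photons = np.where(occupied, spec.photons_per_pixel, 0.0)

    total = fractions.sum(axis=0)
    if not np.all((np.abs(total - 1.0) < 1e-9) | (total == 0.0)):
        raise ValueError("species fractions must sum to 1 where occupied")
    return Scene(spec, fractions, photons)


def _species_curves(
    spec: SceneSpec, bin_centers_ns: np.ndarray, period_ns: float
) -> np.ndarray:
    """Per-species expected bin profiles, normalized to unit sum, with the
    spec's instrument distortion applied.

    The phase shift delays the (periodic) decay by phi/omega, which rotates
    phasors by +phi at harmonic 1; the modulation scale blends the curve
    with its own mean, which multiplies every harmonic's modulation.  With
    point sampling at bin centers the realized rotation snaps to the bin
    resolution 2*pi/K, identically for every species — so calibration
    derived from a reference simulated with the same distortion cancels it
    exactly, which is the physical situation the distortion emulates.
    """
    omega = 2.0 * np.pi / period_ns
    delay = spec.phase_shift_rad / omega
    t_eff = np.mod(bin_centers_ns - delay, period_ns)
    curves = np.array([sp.decay(t_eff) for sp in spec.species])
    curves /= curves.sum(axis=1, keepdims=True)
    s = spec.modulation_scale
    if s != 1.0:
        if s > 1.0:
            raise ValueError(
                "modulation scale > 1 cannot be realized on non-negative "
                "counts; distort the phasor field instead"
            )
        curves = s * curves + (1.0 - s) * curves.mean(axis=1, keepdims=True)
    return curves


def simulate_stack(
    scene: Scene | SceneSpec,
    n_bins: int = 64,
    rep_rate_MHz: float = 80.0,
    seed: int | None = None,
    noiseless: bool = False,
) -> DecayStack:
    """Simulate a decay stack from a scene.

    Per pixel the expected curve is ``photons * sum_s f_s * profile_s``
    (``f_s`` are intensity fractions, so the pixel's analytic phasor is the
    linear combination of the species phasors).  Counts are Poisson draws,
    or the expectation itself when ``noiseless``.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 time bins")
    if isinstance(scene, SceneSpec):
        scene = build_scene(scene)
    spec = scene.spec
    period = 1000.0 / rep_rate_MHz
    t = (np.arange(n_bins) + 0.5) * period / n_bins
    curves = _species_curves(spec, t, period)  # (n_species, K)
    # (rows, cols, K) expectation
    expected = np.einsum("srx,sk->rxk", scene.fractions, curves)
    expected *= scene.photons[..., None]
    if noiseless:
        counts = expected
    else:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        counts = rng.poisson(expected).astype(np.int64)
    return DecayStack.from_counts(counts, rep_rate_MHz=rep_rate_MHz,
                                  bin_centers_ns=t)


def _distort_stack(
    stack: DecayStack, phase_shift: float, modulation_scale: float
) -> DecayStack:
    """Distort measured counts: exact circular FFT time shift (phase) plus
    blending with the per-pixel mean (modulation).  Small negative ringing
    from the shift is clipped and the per-pixel totals renormalized."""
    if modulation_scale > 1.0:
        raise ValueError("modulation scale > 1 cannot be realized on counts")
    k = stack.n_bins
    omega = stack.omega_rad_per_ns
    delay_bins = phase_shift / omega / (stack.period_ns / k)
    spec_f = np.fft.rfft(stack.counts, axis=2)
    n = np.arange(spec_f.shape[2])
    spec_f *= np.exp(-2j * np.pi * n * delay_bins / k)
    shifted = np.fft.irfft(spec_f, k, axis=2)
    out = (
        modulation_scale * shifted
        + (1.0 - modulation_scale) * shifted.mean(axis=2, keepdims=True)
    )
    totals = out.sum(axis=2, keepdims=True)
    out = np.clip(out, 0.0, None)
    new_totals = out.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(new_totals > 0, out * totals / new_totals, 0.0)
    return DecayStack(out, stack.period_ns, stack.rep_rate_MHz,
                      stack.bin_centers_ns)


def distort_curve(
    time_ns: np.ndarray,
    counts: np.ndarray,
    phase_shift_rad: float,
    modulation_scale: float,
    period_ns: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Distort a columnar decay curve on a uniform grid spanning one period.

    FFT circular shift (exact +phase rotation at harmonic 1) plus blending
    with the mean (exact modulation scaling).  The shifted values are kept
    as floats and may ring slightly negative near the decay's wrap; they are
    meant for calibration arithmetic, not for Poisson sampling.
    """
    t = np.asarray(time_ns, dtype=float)
    c = np.asarray(counts, dtype=float)
    k = len(c)
    dt = period_ns / k
    if not np.allclose(np.diff(t), dt):
        raise ValueError("curve must be uniformly sampled over one period")
    omega = 2.0 * np.pi / period_ns
    delay_bins = phase_shift_rad / omega / dt
    spec_f = np.fft.rfft(c)
    n = np.arange(len(spec_f))
    spec_f *= np.exp(-2j * np.pi * n * delay_bins / k)
    shifted = np.fft.irfft(spec_f, k)
    out = modulation_scale * shifted + (1.0 - modulation_scale) * shifted.mean()
    return t, out


def distort_instrument(obj, phase_shift_rad: float, modulation_scale: float):
    """Rotate phasors by +phase_shift and scale modulation; the exact inverse
    of ``apply_calibration`` with ``(m = 1/scale, phi = -shift)``.

    Accepts a PhasorField (exact complex multiplication) or a DecayStack
    (time-domain realization; scale restricted to (0, 1] there).
    """
    if modulation_scale <= 0:
        raise ValueError("modulation scale must be positive")
    if isinstance(obj, PhasorField):
        z = (obj.G + 1j * obj.S) * modulation_scale * np.exp(1j * phase_shift_rad)
        out = obj.copy()
        out.G = np.where(obj.valid, z.real, np.nan)
        out.S = np.where(obj.valid, z.imag, np.nan)
        return out
    if isinstance(obj, DecayStack):
        return _distort_stack(obj, phase_shift_rad, modulation_scale)
    raise TypeError("expected a PhasorField or DecayStack")
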