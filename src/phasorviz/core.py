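"""Phasor transform, lifetime conversions, calibration, and fraction recovery.

The phasor of a fluorescence decay ``I(t)`` observed over one laser period
``T`` at harmonic ``n`` is the normalized Fourier component

    G = sum_k I(t_k) cos(n*omega*t_k) / sum_k I(t_k)
    S = sum_k I(t_k) sin(n*omega*t_k) / sum_k I(t_k)

with ``omega = 2*pi/T``.  A monoexponential decay of lifetime ``tau`` lands
on the *universal semicircle* of center (1/2, 0) and radius 1/2:

    G = 1 / (1 + (omega*tau)^2),   S = omega*tau / (1 + (omega*tau)^2)

Mixtures of species fall inside the semicircle at the intensity-weighted
linear combination of the pure-species phasors; this linearity is what makes
fraction recovery by projection onto a segment meaningful.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "PhasorPoint",
    "DecayStack",
    "PhasorField",
    "CalibrationTransform",
    "compute_phasor_field",
    "lifetime_to_phasor",
    "phasor_to_lifetimes",
    "derive_calibration",
    "apply_calibration",
    "fraction_along_segment",
]

TWO_PI = 2.0 * np.pi

#: Universal-semicircle geometry: locus of monoexponential phasors.
SEMICIRCLE_CENTER = (0.5, 0.0)
SEMICIRCLE_RADIUS = 0.5


@dataclasses.dataclass(frozen=True)
class PhasorPoint:
    """A single (G, S) position in the phasor plot."""

    g: float
    s: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g) and np.isfinite(self.s)):
            raise ValueError("phasor coordinates must be finite")
        object.__setattr__(self, "g", float(self.g))
        object.__setattr__(self, "s", float(self.s))

    def as_array(self) -> np.ndarray:
        return np.array([self.g, self.s], dtype=float)

    def as_complex(self) -> complex:
        return complex(self.g, self.s)


@dataclasses.dataclass(frozen=True)
class DecayStack:
    """Per-pixel photon counts over time bins within one laser period.

    Parameters
    ----------
    counts : (rows, cols, K) array
        Non-negative counts per pixel per time bin.  Integer-valued for
        measured/Poisson data; float expectation values are accepted so
        that noiseless simulations flow through the same pipeline.
    period_ns : float
        Laser period ``T`` in nanoseconds.
    rep_rate_MHz : float
        Repetition frequency ``f``; must satisfy ``T = 1000 / f``.
    bin_centers_ns : (K,) array
        Time points of the bins, strictly increasing, inside ``[0, T)``.
    """

    counts: np.ndarray
    period_ns: float
    rep_rate_MHz: float
    bin_centers_ns: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        t = np.asarray(self.bin_centers_ns, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "bin_centers_ns", t)
        if counts.ndim != 3:
            raise ValueError("counts must be a (rows, cols, K) array")
        if not np.all(np.isfinite(counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        k = counts.shape[2]
        if k < 2:
            raise ValueError("need at least 2 time bins")
        if t.shape != (k,):
            raise ValueError("bin_centers_ns length must match the time axis")
        if np.any(np.diff(t) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if t[0] < 0 or t[-1] >= self.period_ns:
            raise ValueError("bin centers must lie in [0, period)")
        expected_period = 1000.0 / self.rep_rate_MHz
        if abs(self.period_ns - expected_period) > 1e-9 * expected_period:
            raise ValueError(
                f"period {self.period_ns} ns inconsistent with rep rate "
                f"{self.rep_rate_MHz} MHz (expected {expected_period} ns)"
            )

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        rep_rate_MHz: float = 80.0,
        bin_centers_ns: np.ndarray | None = None,
    ) -> "DecayStack":
        """Build a stack, placing bins at centers ``(k + 1/2) T / K`` if not given."""
        counts = np.asarray(counts)
        period = 1000.0 / rep_rate_MHz
        if bin_centers_ns is None:
            k = counts.shape[2]
            bin_centers_ns = (np.arange(k) + 0.5) * period / k
        return cls(counts, period, rep_rate_MHz, np.asarray(bin_centers_ns, float))

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def omega_rad_per_ns(self) -> float:
        """Fundamental angular frequency 2*pi/T in rad/ns."""
        return TWO_PI / self.period_ns


@dataclasses.dataclass
class PhasorField:
    """Per-pixel (G, S, intensity) with a validity mask.

    Invalid pixels (zero intensity) carry NaN in G and S and are excluded
    from every downstream computation.
    """

    G: np.ndarray
    S: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    harmonic: int = 1

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        shapes = {self.G.shape, self.S.shape, self.intensity.shape, self.valid.shape}
        if len(shapes) != 1:
            raise ValueError("G, S, intensity, valid must share one shape")
        if self.harmonic < 1:
            raise ValueError("harmonic must be a positive integer")
        if np.any(self.intensity[self.valid] < 0):
            raise ValueError("intensity must be non-negative where valid")
        if not np.all(np.isfinite(self.G[self.valid])) or not np.all(
            np.isfinite(self.S[self.valid])
        ):
            raise ValueError("G and S must be finite on valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.G.shape

    def copy(self) -> "PhasorField":
        return PhasorField(
            self.G.copy(), self.S.copy(), self.intensity.copy(),
            self.valid.copy(), self.harmonic,
        )

    def mean_phasor(self) -> PhasorPoint:
        """Intensity-weighted mean phasor over valid pixels."""
        w = self.intensity[self.valid]
        total = w.sum()
        if total <= 0:
            raise ValueError("field has no intensity")
        g = float(np.sum(w * self.G[self.valid]) / total)
        s = float(np.sum(w * self.S[self.valid]) / total)
        return PhasorPoint(g, s)


@dataclasses.dataclass(frozen=True)
class CalibrationTransform:
    """Rotation/scaling taking measured phasors onto their true positions.

    Derived from a reference fluorophore of known monoexponential lifetime
    (fluorescein at pH 11, 4.0 ns, is the conventional choice at 80 MHz).
    Applying the transform multiplies each phasor, as a complex number
    ``G + iS``, by ``m * exp(i*phi)``.
    """

    modulation_factor: float
    phase_shift_rad: float
    harmonic: int = 1
    reference_lifetime_ns: float = 4.0

    def __post_init__(self) -> None:
        if self.modulation_factor <= 0:
            raise ValueError("modulation factor must be positive")
        # wrap phase into (-pi, pi]
        phi = float(np.angle(np.exp(1j * self.phase_shift_rad)))
        if phi == -np.pi:
            phi = np.pi
        object.__setattr__(self, "phase_shift_rad", phi)

    @classmethod
    def identity(cls, harmonic: int = 1) -> "CalibrationTransform":
        return cls(1.0, 0.0, harmonic)

    def as_complex(self) -> complex:
        return self.modulation_factor * np.exp(1j * self.phase_shift_rad)

    def inverse(self) -> "CalibrationTransform":
        return CalibrationTransform(
            1.0 / self.modulation_factor,
            -self.phase_shift_rad,
            self.harmonic,
            self.reference_lifetime_ns,
        )


def compute_phasor_field(stack: DecayStack, harmonic: int = 1) -> PhasorField:
    """Discrete Fourier phasor transform of a decay stack, pixel by pixel.

    Pixels with zero total count are marked invalid (their phasor is 0/0)
    and carry NaN coordinates.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    k = stack.n_bins
    if harmonic >= k / 2:
        warnings.warn(
            f"harmonic {harmonic} >= K/2 = {k / 2}: the Fourier component is "
            "aliased; result computed anyway",
            stacklevel=2,
        )
    phase = harmonic * stack.omega_rad_per_ns * stack.bin_centers_ns
    cos_t = np.cos(phase)
    sin_t = np.sin(phase)
    counts = stack.counts.astype(float)
    intensity = counts.sum(axis=2)
    valid = intensity > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts @ cos_t / intensity
        s = counts @ sin_t / intensity
    g[~valid] = np.nan
    s[~valid] = np.nan
    return PhasorField(g, s, intensity, valid, harmonic=harmonic)


def lifetime_to_phasor(tau_ns: float, omega_rad_per_ns: float) -> PhasorPoint:
    """Phasor of a monoexponential decay: a point on the universal semicircle."""
    if tau_ns < 0:
        raise ValueError("lifetime must be non-negative")
    if omega_rad_per_ns <= 0:
        raise ValueError("omega must be positive")
    x = omega_rad_per_ns * tau_ns
    denom = 1.0 + x * x
    return PhasorPoint(1.0 / denom, x / denom)


def phasor_to_lifetimes(
    p: PhasorPoint, omega_rad_per_ns: float
) -> tuple[float, float]:
    """Phase and modulation lifetimes of a phasor position.

    ``tau_phase = tan(angle)/omega`` requires ``g > 0``;
    ``tau_mod = sqrt(1/(g^2+s^2) - 1)/omega`` requires ``0 < g^2+s^2 <= 1``.
    Positions outside those domains yield NaN rather than an exception: the
    lifetime is simply undefined there (e.g. uncorrelated background light).
    """
    if omega_rad_per_ns <= 0:
        raise ValueError("omega must be positive")
    g, s = p.g, p.s
    mod2 = g * g + s * s
    tau_phase = (s / g) / omega_rad_per_ns if g > 0 else float("nan")
    if 0 < mod2 <= 1:
        tau_mod = np.sqrt(1.0 / mod2 - 1.0) / omega_rad_per_ns
    else:
        tau_mod = float("nan")
    return float(tau_phase), float(tau_mod)


def _mean_phasor_of_curve(
    time_ns: np.ndarray, counts: np.ndarray, omega: float, harmonic: int
) -> PhasorPoint:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("reference decay has zero total counts")
    phase = harmonic * omega * np.asarray(time_ns, dtype=float)
    return PhasorPoint(
        float(np.sum(counts * np.cos(phase)) / total),
        float(np.sum(counts * np.sin(phase)) / total),
    )


def derive_calibration(
    reference,
    known_tau_ns: float = 4.0,
    harmonic: int = 1,
    rep_rate_MHz: float | None = None,
) -> CalibrationTransform:
    """Calibration transform from a reference of known monoexponential lifetime.

    Parameters
    ----------
    reference : DecayStack or (time_ns, counts) pair
        Measured reference decay.  A stack is reduced to its
        intensity-weighted mean phasor; a columnar curve to its phasor.
        For a columnar curve ``rep_rate_MHz`` must be given.
    known_tau_ns : float
        True lifetime of the reference (default 4.0 ns, fluorescein pH 11).

    The transform is the complex ratio expected/measured, so that applying
    it moves the measured mean phasor exactly onto
    ``lifetime_to_phasor(known_tau, n*omega)``.
    """
    if isinstance(reference, DecayStack):
        omega = reference.omega_rad_per_ns
        field = compute_phasor_field(reference, harmonic=harmonic)
        measured = field.mean_phasor()
    else:
        if rep_rate_MHz is None:
            raise ValueError("rep_rate_MHz is required for a columnar reference")
        omega = TWO_PI * rep_rate_MHz / 1000.0
        time_ns, counts = reference
        measured = _mean_phasor_of_curve(time_ns, counts, omega, harmonic)
    z_meas = measured.as_complex()
    if abs(z_meas) < 1e-12:
        raise ValueError(
            "measured reference phasor sits at the origin (noise-only "
            "reference?); cannot derive a calibration"
        )
    expected = lifetime_to_phasor(known_tau_ns, harmonic * omega)
    ratio = expected.as_complex() / z_meas
    return CalibrationTransform(
        modulation_factor=abs(ratio),
        phase_shift_rad=float(np.angle(ratio)),
        harmonic=harmonic,
        reference_lifetime_ns=known_tau_ns,
    )


def apply_calibration(field: PhasorField, t: CalibrationTransform) -> PhasorField:
    """Rotate/scale all valid phasors of a field; intensity and mask unchanged."""
    if t.harmonic != field.harmonic:
        raise ValueError(
            f"calibration harmonic {t.harmonic} != field harmonic {field.harmonic}"
        )
    z = (field.G + 1j * field.S) * t.as_complex()
    out = field.copy()
    out.G = np.where(field.valid, z.real, np.nan)
    out.S = np.where(field.valid, z.imag, np.nan)
    return out


def fraction_along_segment(
    p: PhasorPoint, end_a: PhasorPoint, end_b: PhasorPoint
) -> float:
    """Intensity fraction of species ``end_b`` for a phasor on segment a-b.

    The phasor of a two-species mixture is the intensity-weighted linear
    combination of the pure phasors, so the orthogonal projection of ``p``
    onto the segment, normalized by its length, is the fraction of the
    second species.  Clipped to [0, 1].
    """
    a = end_a.as_array()
    b = end_b.as_array()
    d = b - a
    length2 = float(d @ d)
    if length2 == 0.0:
        raise ValueError("segment endpoints coincide")
    f = float((p.as_array() - a) @ d / length2)
    return float(np.clip(f, 0.0, 1.0))
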