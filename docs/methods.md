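# Methods

## The phasor representation

A FLIM measurement gives, for every pixel, a photon-count decay histogram
`I(t_k)` over `K` time bins spanning one laser period `T = 1/f` (default
`f = 80 MHz`, `T = 12.5 ns`). The phasor of a pixel is the normalized first
Fourier component of that decay at `ω = 2πn/T` (harmonic `n = 1` by
default):

```
G = Σ_k I(t_k) cos(nω t_k) / Σ_k I(t_k)
S = Σ_k I(t_k) sin(nω t_k) / Σ_k I(t_k)
```

A monoexponential decay of lifetime `τ` maps to
`G = 1/(1+(ωτ)²)`, `S = ωτ/(1+(ωτ)²)` — a point on the *universal
semicircle* centered at `(1/2, 0)` with radius `1/2` (we use this standard
geometry throughout; it is the one consistent with the phasor identity
`G² + S² = G` and with published phasor plots). Mixtures of species fall
inside the semicircle at the photon-weighted linear combination of the pure
phasors, which is why `fraction_along_segment` (orthogonal projection onto
the segment joining two pure-species phasors, clipped to `[0, 1]`) is an
unbiased estimator of the intensity fraction.

Time bins are interpreted at bin centers `t_k = (k + 1/2)·T/K` when only
`K` is known; midpoint sampling cancels the first-order discretization bias
of the Fourier sums, leaving a relative bias `O((ω T/K)²)` (measured:
`2.5e-4` at `K = 64`, `1e-6` at `K = 1024` for `τ = 4 ns`). Pixels with zero
total counts have no phasor (0/0); they are flagged invalid, carry NaN, are
rendered as background, and are excluded from histograms and smoothing
weights. No background subtraction is performed: uncorrelated light shows
up honestly near the origin of the phasor plot. A constant-offset
subtraction could be layered on the `DecayStack` before the transform but
is deliberately not part of the default pipeline.

## Calibration

Instrument response delays and demodulates the measured decay, so raw
phasors are rotated and shrunk relative to their theoretical positions.
Calibration measures a reference fluorophore of known monoexponential
lifetime (fluorescein at pH 11, `τ = 4.0 ns`, is the conventional standard
at 80 MHz two-photon excitation) and stores the complex ratio

```
m·e^{iφ} = (expected phasor of τ_ref) / (measured mean phasor)
```

Applying the calibration multiplies every phasor `G + iS` by `m·e^{iφ}`.
The reference may be an image stack (reduced to its intensity-weighted mean
phasor) or a two-column `(time, counts)` decay curve; both reduce to one
mean phasor. A reference whose mean phasor sits at the origin (pure noise)
is rejected rather than producing an unbounded transform.

## The hue/saturation colormap

The core of the package is a bijective map from phasor position to
`(hue, saturation)`, anchored on an ordered list of **principal points**
(ideally the phasors of the pure species present) and a **center point**
(defaulting to their mean).

*Hue* encodes direction. The `N` principal points receive equidistant hues
`k/N`, with 0 and 1 both on the first point; the hue of an arbitrary
direction is the linear interpolation in angle between the two bracketing
principal directions, increasing clockwise or anticlockwise according to
the order of the given points (auto-detected from the first two). If the
given order is not angularly monotone, later angles are bumped minimally to
restore strict cyclic monotonicity.

*Saturation* encodes radial distance `r` from the center. Along the
half-line from the center through the phasor, let `d1` be the distance to
the nearest crossing of the closed polygon through the principal points and
`d2` the distance to the crossing of the universal-semicircle boundary
(the arc plus its closing diameter); roles are swapped if the semicircle is
hit first. The profile is

```
r ≤ d1        s(r) = v1_eff · sin(π/2 · r/d1)
d1 < r ≤ d2   s(r) = v1_eff + (v2 − v1_eff) · (r − d1)/(d2 − d1)
r > d2        s(r) = 1 − (1 − v2) · exp(−(r − d2)/λ),   λ = (d1 + d2)/2
```

with defaults `v2 = 0.95` and uncorrected `v1 = 0.85`. The first value is
corrected toward the second as the two crossings approach:
`v1_eff = v2 − (v2 − v1)·(d2 − d1)/d2`, clipped to `[v1, v2]`. This form
is the package's own choice satisfying the intended limits (`v1_eff → v2`
as `d1 → d2`; `v1_eff → v1` as `d1/d2 → 0`); it makes the profile
continuous, strictly increasing, exactly `v2` at the semicircle crossing,
and asymptotically 1.

Nonstandard geometries (center outside the polygon and/or the semicircle)
can leave a crossing undefined along some directions. The fallback sets the
missing distance equal to the available one (both missing: the semicircle
radius 1/2), which collapses the linear piece and preserves continuity and
monotonicity; the same single formula then covers every case.

Because hue is cyclically monotone in angle and saturation strictly
monotone in radius, the map is invertible: `invert_color` solves the
piecewise-linear angular map for the direction, then inverts the radial
profile along that direction. Round-trip error is at floating-point level
(tested `< 1e-9` on a 50×50 interior grid).

*Value* (brightness) encodes intensity, normalized to the per-image (or
per-histogram) maximum. The linear scale is the identity; the log scale is
linear up to `x%` of the maximum (default `x = 1`) and logarithmic above,
`V = c·x_f·(1 + ln(I/x_f))` with `c` fixed by `V(1) = 1` — continuous with
continuous slope at the crossover. HSV→RGB uses the standard hexcone
conversion; images are row-major with origin top-left, phasor plots are
drawn with S up and G right.

## Preprocessing

Intensity is smoothed with a normalized 2D Gaussian (default `σ = 1 px`,
kernel truncated at 4σ, reflective boundaries — reflection preserves mass
near edges and avoids a dark frame). G and S are smoothed with the same
Gaussian *weighted by the raw per-pixel intensities*; invalid pixels carry
zero weight and a pixel with no weighted support stays invalid. Low/high
thresholds are fractions of the maximum smoothed intensity: below the low
cut pixels are invalidated; above the high cut intensities are clipped but
kept (the high threshold exists to tame display dynamic range, not to
discard structure). Pipeline order: smooth → threshold → color/histogram.

## Phasor histogram

Each valid pixel deposits its intensity into the 0.02 × 0.02 bin (half-open
`[kb, (k+1)b)`, edges aligned at 0) containing its `(G, S)`; the plotted
range defaults to `[−0.05, 1.05]²`, snapped outward to bin edges, and
out-of-range phasors are counted in an overflow bucket with a warning.
Bin colors are taken at geometric bin centers (reproducible; the error is
resolution-limited to `b/√2`). Mass is conserved exactly.

## Synthetic scenes

The generator stands in for instrument data and defines the conditions the
test suite measures under:

- **Species** are multi-exponential decays (amplitudes `a_j`, lifetimes
  `τ_j`); their analytic phasor is the `a_jτ_j`-weighted mix of
  semicircle points.
- **Scenes**: `uniform` (one global mixture), `crystals_in_solution` (a few
  bright elliptical blobs at 10⁴ photons/pixel over a dim 500-photon
  background, with sub-pixel blob coverage producing genuinely mixed edge
  pixels), and `cell_blobs` (round cells on an empty background whose
  two-species fraction varies between and within cells). Default image
  64×64, `K = 64` bins, 80 MHz; mixture and recovery tests use `K = 256`
  where percent-level accuracy on sub-nanosecond lifetimes is asserted,
  since at `K = 64` the discretization bias of a 0.5 ns decay is itself
  ~1%.
- **Acquisition**: per-pixel expected curves are the intensity-fraction mix
  of unit-normalized species curves scaled to the photon budget; counts are
  Poisson draws (or the expectation itself in noiseless mode). All
  randomness flows from one seed.
- **Instrument distortion** rotates phasors by `+φ` and scales modulation
  by `m ∈ (0, 1]`. On expected curves the phase is realized as a periodic
  time delay and the modulation as blending with the curve mean; with
  point sampling the realized rotation snaps to the bin resolution
  `2π/K`, identically for every species, so a calibration derived from a
  reference simulated under the same distortion cancels it — which is the
  physical situation. On a `PhasorField` the distortion is an exact complex
  multiplication; on columnar curves an FFT shift makes it exact at
  harmonic 1.

What the generator does **not** emulate: full instrument response function
shapes (only phase/modulation distortion), incomplete-decay tail wrap from
previous pulses (negligible for `T/τ ≳ 3`; at `τ = 4 ns`, `T/τ ≈ 3.1`),
optical point-spread functions, detector afterpulsing, and dark counts.
Passing tests therefore demonstrate the correctness of the transform,
calibration algebra, colormap geometry, and statistical behavior under
Poisson noise — not robustness to every instrument artifact.

## Numerical choices

- Invalid-pixel sentinel: NaN in G/S; validity tracked in a boolean mask.
- Ray–polygon intersection uses 2D cross products with a `1e-9` tolerance
  on the edge parameter so rays through vertices are robust (duplicate
  vertex hits collapse under the nearest-crossing minimum).
- Ray–semicircle intersection solves the circle quadratic and the diameter
  line separately and takes the nearest forward crossing.
- The hue at the exact center is defined as 0 (saturation is 0 there, so
  the color is black/white regardless).
- Calibration phase is wrapped to `(−π, π]`.
- Stacks accept float (expectation) counts so noiseless simulations flow
  through the same code path; TIFF I/O enforces unsigned integers.

## Problem sizes

Test and demonstration runs use 48–64 px images, 64–256 time bins, and
10⁴–10⁵ photons per pixel — sizes at which the Poisson standard error of a
mean phasor (~`1/√(N_px · N_photons)`) is far below every asserted
tolerance, chosen as representative desk-scale versions of 512×512
acquisitions.

## Known limitations

- Multi-harmonic joint analysis and time-domain multi-exponential fitting
  are out of scope; the harmonic is a single integer per field.
- Hue interpolation beyond angular monotonicity correction is purely
  linear per wedge; no perceptual-uniformity correction is applied.
- The `v1` correction formula and the nonstandard-geometry fallbacks are
  self-consistent design choices (the intended limits are published, exact
  forms are not); they are clearly isolated in `colormap.py` should a
  reference implementation need to be matched bit-for-bit.
- Stack-level `distort_instrument` clips FFT ringing and renormalizes
  totals, so it is approximate (~`5e-3` in phasor space at `K = 256`);
  field- and curve-level distortion are exact.
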