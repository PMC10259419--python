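# Methods

## Coordinate and bin conventions

Images are row-major with 0-based indices. The azimuth φ is measured
counterclockwise from the +column axis; because rows increase downward, the
azimuth of a displacement (drow, dcol) is `atan2(-drow, dcol)`. In-plane
fiber orientations are axial quantities in [0°, 180°); inclinations α
(angle between the fiber axis and the section plane) lie in [0°, 90°].

All azimuthal profiles live on equally spaced cyclic grids with bin
*centers* at k·w for bin width w (w = 15° for 24-azimuth SLI stacks, 1° for
scatterometry integration, 5° for SAXS and FOD sampling). A pixel whose
azimuth falls exactly on a bin edge is assigned to the lower bin. Centering
segments on k·w (rather than labelling a [0°, 5°) segment by its midpoint
2.5°) keeps one uniform grid across modalities; only the labels, not the
sums, depend on this choice.

## Forward models (synthetic phantoms)

A phantom pixel carries up to three fiber populations (φ, α, weight,
tilt-sign). The generators are deliberately phenomenological: they
reproduce the *geometric* structure the analysis relies on, not the
physical optics of scattering.

**SLI.** Each population contributes two von Mises lobes
`exp(κ(cos(φ−c±Δ/2)−1))` on the 360° circle, centered at c ± Δ(α)/2 with
c = φ + 180° (tilt-sign +1) or c = φ (−1), on top of a constant baseline.
For α = 0 the lobes sit at φ ± 90° — perpendicular to the fiber — and their
mid-position mod 180° equals φ exactly. Defaults: κ = 20 (full width at
half maximum ≈ 30°, comparable to measured SLI peak widths), baseline 0.1
per unit population weight, 24 azimuths. The lobe shape is a design choice;
any smooth unimodal kernel with the same centers would do.

**Peak-distance calibration.** Δ(α) is pluggable via a monotone
`CalibrationCurve`. The shipped stand-in is Δ = 180°·cos α on a 1° grid —
monotone, with the correct endpoints Δ(0°) = 180°, Δ(90°) = 0°. It is a
stand-in for a physically simulated curve, not a fit to data; inverting
measured distances through it yields inclinations only up to that modeling
choice. Inversion uses linear interpolation; Δ outside the curve's range
raises rather than clamps, and exactly flat segments invert to their
midpoint α with a warning.

**SAXS.** A detector frame is a Gaussian radial ring at q₀ = 2π/d
(default d = 17.5 nm, the myelin layer periodicity; ring width 0.02 nm⁻¹)
multiplied by an azimuthal modulation: an isotropic floor plus, per
population, a 180°-periodic von Mises lobe pair centered perpendicular to
φ, scaled by weight × decay(α). The anisotropy decay defaults to cos α —
the observation it encodes is only that Bragg-peak anisotropy fades with
inclination, with no published functional form, so cos α is flagged as a
stand-in. The noiseless pattern is center-symmetric by construction.

**FOD.** The orientation density is a weighted sum of Watson-like lobes
`exp(κ((u·μ)²−1))` along each population's 3D axis, projected onto real
even-degree spherical harmonics (ℓmax = 8 by default) by Gauss–Legendre ×
trapezoidal quadrature (48 × 96 nodes — generous for ℓ ≤ 8 with κ ≈ 20).
Coefficient ordering: ℓ = 0, 2, …, ascending, m = −ℓ…ℓ within each degree,
with the usual real-harmonic convention (m < 0 ↦ √2·(−1)^m·Im Y, m > 0 ↦
√2·(−1)^m·Re Y).

**Noise.** Gaussian noise with σ = 1 % of the rendered dynamic range
(clipped at zero, since intensities are physical), or scaled Poisson
counts. Every stochastic step takes an explicit seed and uses
`numpy.random.default_rng`; rendering is bit-reproducible and changing only
the seed changes only the noise realization.

What the phantoms do **not** emulate: orientation dispersion within a
population, partial-volume mixing at region borders, detector point-spread
and flat-field structure, tissue background heterogeneity, and registration
error between modalities. Passing tests therefore demonstrate that the
*analysis chain* is correct and self-consistent, not that real tissue obeys
the forward models.

## Profile extraction

* Scatterometry: the pattern of pixel (r, c) is the stack read across all
  illumination positions; missing positions are flagged invalid.
* SLI integration: the pattern center is the global intensity argmax (ties:
  smallest row, then column); each 1° segment sums the intensities of all
  pixels whose center azimuth falls in it, out to the pattern border; the
  center pixel itself is excluded (it has no azimuth). Pixels are counted
  once, not area-weighted.
* SAXS integration: pixels with q inside the band are summed per 5°
  segment; the sum over valid bins equals the total unmasked band intensity
  exactly. The default band is [0.9, 1.1]·q_peak around the detected ring.
  Ring detection azimuthally averages 1-pixel annuli, takes the most
  prominent radial maximum (requiring prominence > 5 % of the radial
  amplitude), and refines it with a 3-point parabola.
* Center-symmetry completion: antipodal bins are averaged when both are
  valid, copied when one is; the operation is idempotent and its output
  satisfies I(φ) = I(φ+180°) at every valid bin.
* FOD sampling: the expansion is evaluated on unit directions in the plane
  orthogonal to a configurable normal (default (0,0,1), matching the image
  azimuth convention); antipodal symmetry is enforced bitwise and negative
  truncation ringing is clipped at zero.

## Peak analysis

Peaks are detected on the cyclic profile via a tripled copy of the signal
(so prominence walks may cross the 0°/360° seam), keeping the middle copy.
Prominence follows the standard definition — height above the higher of
the two neighboring minima, found by walking to higher ground — and the
filter keeps peaks with prominence strictly greater than 8 % of the profile
amplitude (max − min over valid bins; the threshold is relative, so the
analysis is scale-invariant). Width is the full width at
height − prominence/2 with linear interpolation. Profiles containing
invalid bins are scanned per contiguous valid run, so a peak interrupted by
a detector gap is not a peak.

Sub-bin refinement fits a parabola through the peak bin and its two cyclic
neighbors. At 15° sampling this leaves a systematic residual of up to ≈ 1°
for lobe positions between bins — within the ± 2.4° accuracy budget of the
24-azimuth geometry that the acceptance suite enforces.

Pairing: two peaks pair when their circular separation is 180° ± 35°.
With more than two peaks all pairings into admissible pairs are enumerated;
the pairing maximizing the number of pairs wins, ties broken by the
smallest total deviation from 180°. Each pair yields one orientation (the
pair's circular mid-position mod 180°, +90° in FOD mode); leftover peaks
yield none, so odd-peak profiles with no admissible pair produce no
orientation. At most three orientations are returned, ordered by summed
pair prominence. Single-peak pixels get Δ = 0 but, by default, no
orientation (a lone peak carries no pairing evidence); an opt-in flag
assigns peak ± 90° flagged low-confidence. No pre-smoothing is applied
before peak detection.

Peak distance: absent for 0 or ≥ 3 peaks, 0 for one peak, and the cyclic
separation (reported in [0°, 180°]) for two.

## Cross-modality comparison

Coarse maps are block-replicated onto the fine grid (truncated edge blocks
allowed); angles pass through external rigid registration via a single
rotation ρ applied mod 180°. Differences are axial:
d = ((a − b + 90) mod 180) − 90 ∈ [−90°, 90°), with exact ±90° mapped to
−90°. Only pixels where both maps report the same orientation count (1 or
2) are compared; for crossings both bijective pairings are evaluated and
the one with the smaller mean absolute difference is used. Histograms use
1° signed bins; summary statistics are the mean signed difference and the
median absolute difference per orientation-count class.
Multi-orientation prevalence is reported as unrounded fractions, and the
percentage increase is computed from those fractions. The
distance-vs-inclination table keeps only unidirectional pixels (one or two
peaks, at most one orientation). 3D comparisons use the sign-invariant
axial dot product |u·v| and its angle, optionally gated by FA > threshold
with FA computed from the rank-2 tensor eigenvalues in the standard closed
form.

## Problem sizes and numerical choices

The shipped validation runs use a 64×64 section (≈ 3100 tissue pixels),
24-azimuth profiles and single/60°-crossing regions; the inclination ramp
uses six 8×8 blocks at α = 0…75° in 15° steps. These sizes give stable
medians while keeping a full run in seconds; all statistics scale linearly
in pixel count. Degenerate inputs are handled explicitly: constant
profiles yield empty peak sets, all-zero scattering patterns and empty
masks raise, fully invalid profiles pass through symmetry completion
flagged.

## Known limitations

* Inclination is recovered only through the calibration curve and only for
  unidirectional pixels; crossing-fiber inclination is out of scope.
* For α ≳ 75° the SLI lobes merge at 15° sampling and Δ degrades to 0
  discontinuously; the broad scatter seen in real steep-fiber regions is
  not modeled.
* The 8 % prominence threshold is applied uniformly to all modalities,
  including FOD-derived profiles, where the equivalent lobe-amplitude
  cutoff of upstream software is not published.
* Registration between modalities is consumed (as a block factor plus
  rotation), never estimated.
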