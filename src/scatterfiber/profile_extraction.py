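"""Extraction of cyclic azimuthal intensity profiles from raw modality data.

Every modality handled by this package — scattered light imaging (SLI) in its
angular and scatterometry variants, scanning small-angle X-ray scattering
(SAXS), and diffusion-MRI fiber orientation distributions (FODs) — is reduced
to the same currency: the intensity :math:`I(\\varphi)` on a cyclic grid of
azimuth bins.  Peaks of that profile encode the in-plane fiber orientations,
and the distance between paired peaks encodes the out-of-plane inclination.

Coordinate conventions
----------------------
Images are row-major with 0-based pixel indices.  The azimuth is measured
counterclockwise from the +column axis, i.e. for a displacement
``(drow, dcol)`` from the pattern center the azimuth is
``atan2(-drow, dcol)`` (rows increase downward).  Azimuth bins are centered
on ``k * bin_width`` degrees; a pixel whose azimuth falls exactly on a bin
edge is assigned to the lower bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.special import sph_harm_y

from .errors import DegenerateInputError, GeometryError, RingNotFoundError

__all__ = [
    "AzimuthalProfile",
    "ScatteringPattern",
    "ProfileMap",
    "assemble_scatterometry_pattern",
    "sli_pattern_to_profile",
    "angular_stack_to_profiles",
    "saxs_pattern_to_profile",
    "complete_center_symmetry",
    "detect_myelin_ring",
    "sample_fod_profile",
    "real_sh_basis",
    "real_sh_n_coeffs",
    "lmax_from_n_coeffs",
    "pixel_azimuths_deg",
    "azimuth_bin_index",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AzimuthalProfile:
    """Intensity I(φ) on a cyclic, equally spaced azimuth grid.

    Parameters
    ----------
    values : ndarray, shape (n,)
        Bin intensities; nonnegative wherever ``valid``.
    bin_centers_deg : ndarray, shape (n,)
        Bin centers ``k * bin_width`` for k = 0..n-1; ``bin_width * n == 360``.
    valid : ndarray of bool, shape (n,)
        False marks bins without usable data (e.g. detector gaps).
    """

    values: np.ndarray
    bin_centers_deg: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_centers_deg = np.asarray(self.bin_centers_deg, dtype=float)
        n = self.values.size
        if n < 1 or self.bin_centers_deg.size != n:
            raise ValueError("values and bin_centers_deg must have equal nonzero length")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.size != n:
            raise ValueError("valid mask length mismatch")
        width = 360.0 / n
        expected = np.arange(n) * width
        if not np.allclose(self.bin_centers_deg, expected, atol=1e-9):
            raise ValueError("bin centers must be k*360/n for k=0..n-1")
        if np.any(self.values[self.valid] < -1e-12):
            raise ValueError("profile values must be nonnegative where valid")

    @classmethod
    def from_values(cls, values, valid=None) -> "AzimuthalProfile":
        values = np.asarray(values, dtype=float)
        n = values.size
        return cls(values, np.arange(n) * (360.0 / n), valid)

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def bin_width_deg(self) -> float:
        return 360.0 / self.values.size


@dataclass
class ScatteringPattern:
    """A single 2D scattering pattern.

    ``center`` is the point of maximum intensity for SLI scatterometry
    patterns and the beam center for SAXS frames.  ``calibration`` carries a
    :class:`~scatterfiber.synthetic_phantoms.DetectorGeometry` for SAXS and is
    ``None`` for SLI.
    """

    data: np.ndarray
    center: tuple[float, float]
    calibration: object | None = None
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("pattern data must be 2D")
        r, c = self.center
        if not (0 <= r < self.data.shape[0] and 0 <= c < self.data.shape[1]):
            raise ValueError("center must lie inside the pattern grid")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.data.shape:
            raise ValueError("valid_mask shape mismatch")


@dataclass
class ProfileMap:
    """Per-pixel azimuthal profiles on one shared bin grid.

    ``values`` has shape (rows, cols, n_bins); ``valid`` the same shape.
    """

    values: np.ndarray
    bin_centers_deg: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    modality: str = "sli_angular"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ProfileMap values must be (rows, cols, n_bins)")
        self.bin_centers_deg = np.asarray(self.bin_centers_deg, dtype=float)
        if self.bin_centers_deg.size != self.values.shape[2]:
            raise ValueError("bin grid does not match the profile length")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    def profile(self, row: int, col: int) -> AzimuthalProfile:
        return AzimuthalProfile(
            self.values[row, col], self.bin_centers_deg, self.valid[row, col]
        )


# ---------------------------------------------------------------------------
# Azimuth geometry helpers
# ---------------------------------------------------------------------------

def pixel_azimuths_deg(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Azimuth of every pixel center about ``center``, in [0, 360).

    Counterclockwise from the +column axis; rows increase downward, hence the
    sign flip on the row displacement.
    """
    rows, cols = np.indices(shape)
    dr = rows - center[0]
    dc = cols - center[1]
    az = np.degrees(np.arctan2(-dr, dc))
    return np.mod(az, 360.0)


def azimuth_bin_index(az_deg: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin index for azimuths on a grid with centers at k*360/n_bins.

    Pixels exactly on a bin edge go to the lower bin.
    """
    width = 360.0 / n_bins
    idx = np.ceil((np.asarray(az_deg, dtype=float) + width / 2.0) / width) - 1
    return np.mod(idx.astype(int), n_bins)


# ---------------------------------------------------------------------------
# SLI scatterometry
# ---------------------------------------------------------------------------

def assemble_scatterometry_pattern(stack: np.ndarray, pixel: tuple[int, int],
                                   valid_illuminations: np.ndarray | None = None
                                   ) -> ScatteringPattern:
    """Assemble the per-pixel scattering pattern from a scatterometry stack.

    ``stack`` has shape (grid_i, grid_j, rows, cols): one camera image per
    illumination position on a dense angular grid.  Reading the same image
    pixel across all illumination positions yields that pixel's scattering
    pattern, of shape (grid_i, grid_j).

    Parameters
    ----------
    stack : ndarray, (grid_i, grid_j, rows, cols)
    pixel : (row, col)
        Image pixel whose pattern is assembled.
    valid_illuminations : bool ndarray (grid_i, grid_j), optional
        False marks illumination positions that were not acquired; they are
        flagged invalid in the output mask.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4:
        raise ValueError("scatterometry stack must be 4D (grid_i, grid_j, rows, cols)")
    row, col = pixel
    if not (0 <= row < stack.shape[2] and 0 <= col < stack.shape[3]):
        raise IndexError(f"pixel {pixel} outside image of shape {stack.shape[2:]}")
    pattern = stack[:, :, row, col]
    mask = (np.ones(pattern.shape, dtype=bool) if valid_illuminations is None
            else np.asarray(valid_illuminations, dtype=bool))
    flat = np.argmax(np.where(mask, pattern, -np.inf))
    center = np.unravel_index(flat, pattern.shape)
    return ScatteringPattern(pattern, (int(center[0]), int(center[1])),
                             calibration=None, valid_mask=mask)


def sli_pattern_to_profile(pattern: ScatteringPattern,
                           bin_width_deg: float = 1.0) -> AzimuthalProfile:
    """Azimuthal profile of an SLI scattering pattern.

    The pattern center is the point of maximum intensity (ties broken by
    smallest row, then column).  Each bin sums the intensities of all pixels
    whose azimuth about the center falls in that segment, from the center out
    to the pattern border.  The center pixel itself has no azimuth and is
    excluded.
    """
    data = pattern.data
    mask = pattern.valid_mask
    if not np.any(data[mask] > 0):
        raise DegenerateInputError("all-zero pattern: center undefined")
    n_bins = int(round(360.0 / bin_width_deg))
    if not np.isclose(n_bins * bin_width_deg, 360.0):
        raise ValueError("bin_width_deg must divide 360")
    # argmax in row-major order -> smallest row, then column, on ties
    center = np.unravel_index(np.argmax(np.where(mask, data, -np.inf)), data.shape)
    az = pixel_azimuths_deg(data.shape, center)
    idx = azimuth_bin_index(az, n_bins)
    use = mask.copy()
    use[center] = False
    values = np.bincount(idx[use], weights=data[use], minlength=n_bins)
    counts = np.bincount(idx[use], minlength=n_bins)
    return AzimuthalProfile.from_values(values, valid=counts > 0)


# ---------------------------------------------------------------------------
# SLI angular stacks
# ---------------------------------------------------------------------------

def angular_stack_to_profiles(stack) -> ProfileMap:
    """Reinterpret an angular SLI stack as a map of azimuthal profiles.

    Each pixel's slice series over the illumination azimuths *is* its
    azimuthal profile; no resampling is performed.  A 24-image acquisition in
    15° steps yields 24-bin profiles on centers 0°, 15°, ..., 345°.
    """
    data = np.asarray(stack.data, dtype=float)
    azimuths = np.asarray(stack.azimuths_deg, dtype=float)
    if data.ndim != 3 or data.shape[2] != azimuths.size:
        raise ValueError("stack data must be (rows, cols, n_azimuths)")
    n = azimuths.size
    expected = np.arange(n) * (360.0 / n)
    if not np.allclose(azimuths, expected):
        raise ValueError("stack azimuths must be equally spaced covering [0, 360)")
    return ProfileMap(data, expected, modality="sli_angular")


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------

def _pattern_q_map(pattern: ScatteringPattern) -> np.ndarray:
    geom = pattern.calibration
    if geom is None:
        raise ValueError("SAXS operations require a pattern with detector calibration")
    rows, cols = np.indices(pattern.data.shape)
    r = np.hypot(rows - pattern.center[0], cols - pattern.center[1])
    return r * geom.q_per_pixel


def saxs_pattern_to_profile(pattern: ScatteringPattern,
                            q_band: tuple[float, float],
                            bin_width_deg: float = 5.0) -> AzimuthalProfile:
    """Azimuthal profile of a SAXS frame restricted to a q band.

    Pixels with scattering-vector magnitude q in ``q_band`` (typically a band
    around the myelin Bragg ring) are summed per azimuth segment.  Bins that
    receive no unmasked pixel are flagged invalid.  The sum over valid bins
    equals the total unmasked intensity in the band exactly.
    """
    qmin, qmax = q_band
    if not (qmax > qmin >= 0):
        raise ValueError("q_band must satisfy 0 <= qmin < qmax")
    q = _pattern_q_map(pattern)
    n_bins = int(round(360.0 / bin_width_deg))
    if not np.isclose(n_bins * bin_width_deg, 360.0):
        raise ValueError("bin_width_deg must divide 360")
    in_band = (q >= qmin) & (q <= qmax) & pattern.valid_mask
    az = pixel_azimuths_deg(pattern.data.shape, pattern.center)
    idx = azimuth_bin_index(az, n_bins)
    values = np.bincount(idx[in_band], weights=pattern.data[in_band], minlength=n_bins)
    counts = np.bincount(idx[in_band], minlength=n_bins)
    return AzimuthalProfile.from_values(values, valid=counts > 0)


def complete_center_symmetry(profile: AzimuthalProfile) -> AzimuthalProfile:
    """Fill detector gaps using the center-symmetry I(φ) = I(φ+180°).

    For each antipodal bin pair: both valid → averaged; one valid → copied to
    the other; neither → left invalid.  Idempotent, and the output satisfies
    I(φ) = I(φ+180°) at every valid bin.
    """
    n = profile.n_bins
    if n % 2 != 0:
        raise ValueError("center-symmetry completion needs an even number of bins")
    half = n // 2
    v = profile.values.astype(float).copy()
    ok = profile.valid.copy()
    out = np.full(n, np.nan)
    out_ok = np.zeros(n, dtype=bool)
    for k in range(half):
        a, b = k, k + half
        if ok[a] and ok[b]:
            m = 0.5 * (v[a] + v[b])
            out[a] = out[b] = m
            out_ok[a] = out_ok[b] = True
        elif ok[a]:
            out[a] = out[b] = v[a]
            out_ok[a] = out_ok[b] = True
        elif ok[b]:
            out[a] = out[b] = v[b]
            out_ok[a] = out_ok[b] = True
    out[~out_ok] = 0.0
    return AzimuthalProfile(out, profile.bin_centers_deg.copy(), out_ok)


def detect_myelin_ring(pattern: ScatteringPattern,
                       min_prominence_frac: float = 0.05
                       ) -> tuple[float, float]:
    """Locate the myelin Bragg ring in a SAXS frame.

    The radial intensity profile is computed by azimuthal averaging over
    unmasked pixels in 1-pixel annuli; the most prominent radial maximum is
    refined with 3-point parabolic interpolation.  Returns ``(q_peak,
    d_spacing)`` with ``d_spacing = 2π / q_peak`` (nm for q in nm⁻¹).

    Raises
    ------
    RingNotFoundError
        If no radial maximum rises above background (prominence below
        ``min_prominence_frac`` of the radial profile amplitude).
    """
    geom = pattern.calibration
    if geom is None:
        raise GeometryError("detect_myelin_ring requires detector calibration")
    rows, cols = np.indices(pattern.data.shape)
    r = np.hypot(rows - pattern.center[0], cols - pattern.center[1])
    r_idx = np.round(r).astype(int)
    mask = pattern.valid_mask
    n_r = r_idx[mask].max() + 1 if np.any(mask) else 0
    if n_r < 3:
        raise RingNotFoundError("pattern too small for a radial profile")
    sums = np.bincount(r_idx[mask], weights=pattern.data[mask], minlength=n_r)
    counts = np.bincount(r_idx[mask], minlength=n_r)
    with np.errstate(invalid="ignore"):
        radial = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    amplitude = radial.max() - radial.min()
    if amplitude <= 0:
        raise RingNotFoundError("flat radial profile")
    peaks, props = find_peaks(radial, prominence=min_prominence_frac * amplitude)
    if peaks.size == 0:
        raise RingNotFoundError("no radial maximum above background")
    best = peaks[np.argmax(props["prominences"])]
    # 3-point parabolic sub-bin refinement
    if 0 < best < n_r - 1:
        y0, y1, y2 = radial[best - 1], radial[best], radial[best + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    else:
        shift = 0.0
    r_peak = best + shift
    q_peak = r_peak * geom.q_per_pixel
    if q_peak <= 0:
        raise RingNotFoundError("radial maximum at the beam center")
    return float(q_peak), float(2.0 * np.pi / q_peak)


# ---------------------------------------------------------------------------
# FOD spherical harmonics
# ---------------------------------------------------------------------------

def real_sh_n_coeffs(lmax: int) -> int:
    """Number of real even-degree SH coefficients up to ``lmax``."""
    if lmax < 0 or lmax % 2 != 0:
        raise ValueError("lmax must be even and nonnegative")
    return (lmax + 1) * (lmax + 2) // 2


def lmax_from_n_coeffs(n: int) -> int:
    """Invert :func:`real_sh_n_coeffs`; raises if ``n`` fits no even lmax."""
    lmax = 0
    while real_sh_n_coeffs(lmax) < n:
        lmax += 2
    if real_sh_n_coeffs(lmax) != n:
        raise ValueError(f"{n} coefficients match no even-degree SH basis")
    return lmax


def real_sh_basis(lmax: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real even-degree spherical harmonic basis evaluated at (theta, phi).

    ``theta`` is the polar angle from +z, ``phi`` the azimuth, both in
    radians.  Coefficient ordering: degrees l = 0, 2, ..., lmax ascending,
    order m = -l ... +l within each degree.  Real harmonics follow the usual
    convention: m<0 → √2·(-1)^m·Im(Y_l^|m|), m=0 → Y_l^0,
    m>0 → √2·(-1)^m·Re(Y_l^m).  Returns shape ``theta.shape + (n_coeffs,)``.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(theta.shape + (real_sh_n_coeffs(lmax),))
    i = 0
    for ell in range(0, lmax + 1, 2):
        for m in range(-ell, ell + 1):
            y = sph_harm_y(ell, abs(m), theta, phi)
            if m < 0:
                out[..., i] = np.sqrt(2.0) * (-1) ** m * y.imag
            elif m == 0:
                out[..., i] = y.real
            else:
                out[..., i] = np.sqrt(2.0) * (-1) ** m * y.real
            i += 1
    return out


def _plane_basis(plane_normal) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(plane_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("plane_normal must be nonzero")
    n = n / norm
    seed = np.array([1.0, 0.0, 0.0])
    if abs(n @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def sample_fod_profile(sh_coeffs: np.ndarray, step_deg: float = 5.0,
                       plane_normal=(0.0, 0.0, 1.0)) -> AzimuthalProfile:
    """Sample a spherical-harmonic FOD on the section plane.

    The band-limited FOD (real even-degree SH; see :func:`real_sh_basis` for
    the ordering) is evaluated at unit directions spaced ``step_deg`` apart
    within the plane orthogonal to ``plane_normal``.  For the default normal
    (0,0,1) the in-plane azimuth φ coincides with the package-wide image
    azimuth convention.  Even degrees make the result exactly 180°-periodic.
    Negative sampled amplitudes (SH truncation ringing) are clipped to zero.
    """
    sh_coeffs = np.asarray(sh_coeffs, dtype=float).ravel()
    lmax = lmax_from_n_coeffs(sh_coeffs.size)
    n_bins = int(round(360.0 / step_deg))
    if not np.isclose(n_bins * step_deg, 360.0):
        raise ValueError("step_deg must divide 360")
    e1, e2 = _plane_basis(plane_normal)
    phi_plane = np.radians(np.arange(n_bins) * step_deg)
    dirs = np.outer(np.cos(phi_plane), e1) + np.outer(np.sin(phi_plane), e2)
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    basis = real_sh_basis(lmax, theta, phi)
    values = np.maximum(basis @ sh_coeffs, 0.0)
    if n_bins % 2 == 0:
        # antipodal symmetry is exact for even degrees; enforce it bitwise
        half = n_bins // 2
        values[half:] = values[:half]
    return AzimuthalProfile.from_values(values)
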