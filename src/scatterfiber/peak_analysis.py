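"""Cyclic peak detection and in-plane fiber orientation reconstruction.

This is the analysis core shared by all modalities: given an azimuthal
intensity profile per pixel, detect its peaks, keep those whose prominence
exceeds 8% of the profile amplitude (max − min), measure the full width at
half prominence, pair peaks that lie 180° ± 35° apart, and take each pair's
circular mid-position modulo 180° as one in-plane fiber orientation.  In
scattering geometries (SLI, SAXS) the profile lobes are perpendicular to the
fiber, so the mid-position of an antipodal lobe pair *is* the fiber
orientation; for FOD-derived profiles the lobes lie along the fiber and the
mid-position is rotated by 90°.

The distance Δ between the two peaks of a two-peak profile carries the
out-of-plane information: Δ = 180° for in-plane fibers and shrinks with
increasing inclination (see :mod:`scatterfiber.inclination_3d`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_prominences, peak_widths

from .profile_extraction import AzimuthalProfile, ProfileMap

__all__ = [
    "PeakSet",
    "OrientationMap",
    "ParameterMaps",
    "find_peaks_cyclic",
    "pair_peaks_to_orientations",
    "peak_distance",
    "analyze_profile_map",
    "cyclic_separation",
    "circular_mid_position",
    "DEFAULT_PROMINENCE_FRAC",
    "DEFAULT_PAIR_TOL_DEG",
]

# Peaks below 8% of the profile amplitude are treated as noise.
DEFAULT_PROMINENCE_FRAC = 0.08
# Peak pairs are accepted when they lie 180° ± 35° apart.
DEFAULT_PAIR_TOL_DEG = 35.0


@dataclass
class PeakSet:
    """Detected peaks of one cyclic azimuthal profile.

    Positions are sub-bin refined and sorted increasing in [0, 360);
    ``profile_amplitude`` is max − min of the source profile over its valid
    bins (the reference for the relative prominence threshold).
    """

    positions_deg: np.ndarray
    prominences: np.ndarray
    widths_deg: np.ndarray
    profile_amplitude: float

    def __post_init__(self) -> None:
        self.positions_deg = np.asarray(self.positions_deg, dtype=float)
        self.prominences = np.asarray(self.prominences, dtype=float)
        self.widths_deg = np.asarray(self.widths_deg, dtype=float)
        if not (self.positions_deg.size == self.prominences.size
                == self.widths_deg.size):
            raise ValueError("PeakSet arrays must have equal length")

    def __len__(self) -> int:
        return int(self.positions_deg.size)


@dataclass
class OrientationMap:
    """Per-pixel in-plane fiber orientations and peak statistics.

    ``orientations_deg`` has shape (rows, cols, 3) with axial angles in
    [0, 180) and NaN in unset slots; ``peak_distance_deg`` is NaN where
    undefined (no peaks, or more than two peaks).
    """

    orientations_deg: np.ndarray
    n_orientations: np.ndarray
    peak_distance_deg: np.ndarray
    n_peaks: np.ndarray

    def __post_init__(self) -> None:
        self.orientations_deg = np.asarray(self.orientations_deg, dtype=float)
        self.n_orientations = np.asarray(self.n_orientations, dtype=int)
        self.peak_distance_deg = np.asarray(self.peak_distance_deg, dtype=float)
        self.n_peaks = np.asarray(self.n_peaks, dtype=int)
        if self.orientations_deg.ndim != 3 or self.orientations_deg.shape[2] != 3:
            raise ValueError("orientations_deg must be (rows, cols, 3)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.orientations_deg.shape[:2]


@dataclass
class ParameterMaps:
    """Scalar per-pixel summaries of the azimuthal profiles."""

    average: np.ndarray
    maximum: np.ndarray
    minimum: np.ndarray
    mean_prominence: np.ndarray
    mean_width: np.ndarray


# ---------------------------------------------------------------------------
# Cyclic peak detection
# ---------------------------------------------------------------------------

def _refine_parabolic(values: np.ndarray, idx: int) -> float:
    """Sub-bin offset of a peak at ``idx`` from a 3-point parabola (cyclic)."""
    n = values.size
    y0, y1, y2 = values[(idx - 1) % n], values[idx], values[(idx + 1) % n]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def find_peaks_cyclic(profile: AzimuthalProfile,
                      prominence_frac: float = DEFAULT_PROMINENCE_FRAC) -> PeakSet:
    """Detect peaks of a cyclic azimuthal profile with prominence filtering.

    The profile is treated as periodic (wrap-around at 0°/360°).  Prominence
    of a peak is the vertical distance between its top and the higher of the
    two neighboring minima, found by walking left and right until higher
    ground; only peaks with prominence strictly larger than
    ``prominence_frac`` × (max − min) are retained.  Width is the full width
    at (height − prominence/2), linearly interpolated between bins, and peak
    positions are refined by a 3-point parabolic fit.

    Profiles containing invalid bins are analyzed per contiguous valid run
    (a peak interrupted by an invalid bin is not a peak); a constant profile
    yields an empty :class:`PeakSet`.
    """
    values = np.asarray(profile.values, dtype=float)
    valid = np.asarray(profile.valid, dtype=bool)
    n = values.size
    if valid.sum() < 8:
        raise ValueError("profile needs at least 8 valid bins")
    vmax = values[valid].max()
    vmin = values[valid].min()
    amplitude = float(vmax - vmin)
    width_deg = 360.0 / n
    if amplitude == 0:
        return PeakSet(np.empty(0), np.empty(0), np.empty(0), 0.0)
    threshold = prominence_frac * amplitude

    idxs: list[int] = []
    proms: list[float] = []
    widths: list[float] = []

    if valid.all():
        ext = np.concatenate([values, values, values])
        pk, _ = find_peaks(ext)
        pk = pk[(pk >= n) & (pk < 2 * n)]
        if pk.size:
            pr, lb, rb = peak_prominences(ext, pk)
            keep = pr > threshold
            pk, pr = pk[keep], pr[keep]
            if pk.size:
                w = peak_widths(ext, pk, rel_height=0.5,
                                prominence_data=(pr, lb[keep], rb[keep]))[0]
                idxs = list(pk - n)
                proms = list(pr)
                widths = list(w * width_deg)
    else:
        # rotate so index 0 is invalid, then scan linear valid runs
        k0 = int(np.argmin(valid))
        rv = np.roll(values, -k0)
        rm = np.roll(valid, -k0)
        pos = 0
        while pos < n:
            if not rm[pos]:
                pos += 1
                continue
            end = pos
            while end < n and rm[end]:
                end += 1
            seg = rv[pos:end]
            if seg.size >= 3:
                pk, _ = find_peaks(seg)
                if pk.size:
                    pr, lb, rb = peak_prominences(seg, pk)
                    keep = pr > threshold
                    pk, pr = pk[keep], pr[keep]
                    if pk.size:
                        w = peak_widths(seg, pk, rel_height=0.5,
                                        prominence_data=(pr, lb[keep], rb[keep]))[0]
                        idxs += [int((p + pos + k0) % n) for p in pk]
                        proms += list(pr)
                        widths += list(w * width_deg)
            pos = end

    positions = []
    for i, p in enumerate(idxs):
        left_ok = valid[(p - 1) % n]
        right_ok = valid[(p + 1) % n]
        shift = _refine_parabolic(values, p) if (left_ok and right_ok) else 0.0
        positions.append(np.mod((p + shift) * width_deg, 360.0))
    order = np.argsort(positions)
    return PeakSet(np.asarray(positions)[order], np.asarray(proms)[order],
                   np.asarray(widths)[order], amplitude)


# ---------------------------------------------------------------------------
# Peak pairing
# ---------------------------------------------------------------------------

def cyclic_separation(a_deg: float, b_deg: float) -> float:
    """Shorter arc between two azimuths, in [0, 180]."""
    d = abs(a_deg - b_deg) % 360.0
    return min(d, 360.0 - d)


def circular_mid_position(a_deg: float, b_deg: float) -> float:
    """Mid-position of the arc from a to b (shorter-arc midpoint), in [0, 360)."""
    span = (b_deg - a_deg) % 360.0
    if span > 180.0:
        a_deg, b_deg = b_deg, a_deg
        span = 360.0 - span
    return (a_deg + span / 2.0) % 360.0


def _enumerate_pairings(pair_ok: dict[tuple[int, int], float], n: int):
    """All maximal matchings over peaks with admissible pairs ``pair_ok``."""
    pairs = sorted(pair_ok)

    def rec(used: frozenset, start: int):
        best: list[list[tuple[int, int]]] = [[]]
        for k in range(start, len(pairs)):
            i, j = pairs[k]
            if i in used or j in used:
                continue
            for sub in rec(used | {i, j}, k + 1):
                best.append([pairs[k]] + sub)
        return best

    return rec(frozenset(), 0)


def pair_peaks_to_orientations(peaks: PeakSet,
                               pair_tol_deg: float = DEFAULT_PAIR_TOL_DEG,
                               mode: str = "scattering") -> list[float]:
    """Pair antipodal peaks into in-plane axial fiber orientations.

    Two peaks form a pair when their separation around the circle is
    180° ± ``pair_tol_deg``.  Each pair yields one orientation: the circular
    mid-position of the pair modulo 180° (``scattering`` mode, lobes
    perpendicular to the fiber) or that mid-position + 90° modulo 180°
    (``fod`` mode, lobes along the fiber).  When more than one pairing is
    possible, the assignment maximizing the number of pairs is chosen,
    ties broken by the smallest total deviation from 180°.  Leftover
    (unpairable) peaks yield no orientation.  At most three orientations are
    returned, ordered by decreasing summed pair prominence.
    """
    if mode not in ("scattering", "fod"):
        raise ValueError(f"unknown mode {mode!r}")
    pos = peaks.positions_deg
    n = len(peaks)
    if n < 2:
        return []
    pair_dev: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(n), 2):
        sep = cyclic_separation(pos[i], pos[j])
        dev = 180.0 - sep  # separation is always <= 180 in min-arc form
        if dev <= pair_tol_deg:
            pair_dev[(i, j)] = dev
    if not pair_dev:
        return []
    matchings = _enumerate_pairings(pair_dev, n)
    best = max(matchings,
               key=lambda m: (len(m), -sum(pair_dev[p] for p in m)))
    scored = []
    for i, j in best:
        mid = circular_mid_position(pos[i], pos[j]) % 180.0
        if mode == "fod":
            mid = (mid + 90.0) % 180.0
        scored.append((peaks.prominences[i] + peaks.prominences[j], mid))
    scored.sort(key=lambda t: -t[0])
    return [mid for _, mid in scored[:3]]


def peak_distance(peaks: PeakSet) -> float:
    """Peak distance Δ in degrees, for profiles with at most two peaks.

    0 peaks or more than 2 → NaN (undefined); 1 peak → 0; 2 peaks → their
    cyclic separation in [0, 180].
    """
    n = len(peaks)
    if n == 0 or n > 2:
        return float("nan")
    if n == 1:
        return 0.0
    return cyclic_separation(peaks.positions_deg[0], peaks.positions_deg[1])


# ---------------------------------------------------------------------------
# Map-level analysis
# ---------------------------------------------------------------------------

def analyze_profile_map(pmap: ProfileMap,
                        prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                        pair_tol_deg: float = DEFAULT_PAIR_TOL_DEG,
                        mode: str = "scattering",
                        single_peak_orientation: bool = False
                        ) -> tuple[OrientationMap, ParameterMaps]:
    """Run the full peak analysis on every pixel of a profile map.

    Produces the orientation map (up to three axial orientations per pixel,
    peak count, peak distance) and the scalar parameter maps (average,
    maximum, minimum of each profile; mean prominence and mean width of the
    retained peaks, NaN where no peak survives the prominence filter).

    ``single_peak_orientation`` optionally assigns an orientation to
    single-peak pixels (peak ± 90° mod 180° in scattering mode, the peak
    position itself in fod mode); off by default since a lone peak carries
    no pairing evidence.
    """
    rows, cols = pmap.shape
    orientations = np.full((rows, cols, 3), np.nan)
    n_orient = np.zeros((rows, cols), dtype=int)
    pdist = np.full((rows, cols), np.nan)
    n_peaks = np.zeros((rows, cols), dtype=int)
    average = np.full((rows, cols), np.nan)
    maximum = np.full((rows, cols), np.nan)
    minimum = np.full((rows, cols), np.nan)
    mean_prom = np.full((rows, cols), np.nan)
    mean_width = np.full((rows, cols), np.nan)

    for r in range(rows):
        for c in range(cols):
            prof = pmap.profile(r, c)
            vals = prof.values[prof.valid]
            if vals.size == 0:
                continue
            average[r, c] = vals.mean()
            maximum[r, c] = vals.max()
            minimum[r, c] = vals.min()
            peaks = find_peaks_cyclic(prof, prominence_frac)
            n_peaks[r, c] = len(peaks)
            if len(peaks):
                mean_prom[r, c] = peaks.prominences.mean()
                mean_width[r, c] = peaks.widths_deg.mean()
            pdist[r, c] = peak_distance(peaks)
            orients = pair_peaks_to_orientations(peaks, pair_tol_deg, mode)
            if not orients and single_peak_orientation and len(peaks) == 1:
                p = peaks.positions_deg[0]
                orients = [(p + 90.0) % 180.0 if mode == "scattering"
                           else p % 180.0]
            n_orient[r, c] = len(orients)
            for k, o in enumerate(orients):
                orientations[r, c, k] = o

    omap = OrientationMap(orientations, n_orient, pdist, n_peaks)
    params = ParameterMaps(average, maximum, minimum, mean_prom, mean_width)
    return omap, params
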