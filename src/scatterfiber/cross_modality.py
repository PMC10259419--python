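"""Pixel-wise comparison of fiber-orientation maps across modalities.

The modalities live on different grids (e.g. one SAXS pixel covers 33 × 33
SLI pixels for the vervet data, 50 × 50 for the human data), so the coarse
map is first block-replicated onto the fine grid.  Comparison is restricted
to pixels where both maps report the *same* number of orientations (one or
two): with two crossing orientations per pixel both bijective pairings are
evaluated and the one with the smaller mean absolute angular difference is
used.  All differences are axial (modulo 180°), reported signed in
[−90°, 90°).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peak_analysis import OrientationMap

__all__ = [
    "ComparisonResult",
    "upsample_to_grid",
    "rotate_orientations",
    "signed_axial_difference",
    "match_and_diff",
    "compare_orientation_maps",
    "multiplicity_stats",
    "distance_inclination_scatter",
    "dot_product_map",
]


@dataclass
class ComparisonResult:
    """Result of a pixel-wise orientation-map comparison.

    ``signed_diff_deg``/``abs_diff_deg`` have shape (rows, cols, 2) with NaN
    where undefined; ``histograms[k]`` holds the 1°-binned counts of signed
    differences over pixels with k matched orientations, on ``bin_edges``
    spanning [−90, 90).  ``stats[k]`` reports mean signed difference, median
    absolute difference and pixel count per orientation-count class.
    """

    signed_diff_deg: np.ndarray
    abs_diff_deg: np.ndarray
    matched_mask: np.ndarray
    histograms: dict[int, np.ndarray]
    bin_edges: np.ndarray
    stats: dict[int, dict[str, float]] = field(default_factory=dict)


def upsample_to_grid(coarse: OrientationMap, target_shape: tuple[int, int],
                     block: tuple[int, int]) -> OrientationMap:
    """Replicate a coarse orientation map onto a finer grid.

    Each coarse pixel's orientations are copied unchanged to its
    ``by × bx`` block of fine pixels (nearest-neighbor block replication).
    Truncated blocks at the image edges are allowed; the target shape must
    otherwise equal coarse shape × block.
    """
    by, bx = block
    cr, cc = coarse.shape
    tr, tc = target_shape
    if not (cr * by >= tr > (cr - 1) * by and cc * bx >= tc > (cc - 1) * bx):
        raise ValueError(
            f"target shape {target_shape} incompatible with coarse shape "
            f"{coarse.shape} and block {block}")

    def up(arr):
        return np.repeat(np.repeat(arr, by, axis=0), bx, axis=1)[:tr, :tc]

    return OrientationMap(up(coarse.orientations_deg),
                          up(coarse.n_orientations),
                          up(coarse.peak_distance_deg),
                          up(coarse.n_peaks))


def rotate_orientations(omap: OrientationMap, rho_deg: float) -> OrientationMap:
    """Rotate every in-plane orientation by ρ (mod 180°); counts and Δ unchanged.

    Used to carry angular data through an external rigid registration.
    """
    rotated = np.where(np.isnan(omap.orientations_deg),
                       np.nan,
                       np.mod(omap.orientations_deg + rho_deg, 180.0))
    return OrientationMap(rotated, omap.n_orientations.copy(),
                          omap.peak_distance_deg.copy(), omap.n_peaks.copy())


def signed_axial_difference(a_deg, b_deg):
    """Signed difference a − b of axial angles, wrapped into [−90, 90).

    d = ((a − b + 90) mod 180) − 90; exactly ±90 maps to −90.
    """
    return np.mod(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)
                  + 90.0, 180.0) - 90.0


def match_and_diff(orients_a, orients_b) -> list[float]:
    """Signed axial differences a − b under the best orientation pairing.

    Both lists must have the same length (1 or 2).  With two orientations
    per map, both bijective pairings are evaluated and the one with the
    smaller mean absolute difference is returned, in the order of
    ``orients_a``.
    """
    a = [float(x) for x in orients_a]
    b = [float(x) for x in orients_b]
    if len(a) != len(b) or not 1 <= len(a) <= 2:
        raise ValueError("match_and_diff needs two equal-length lists of 1 or 2 angles")
    if len(a) == 1:
        return [float(signed_axial_difference(a[0], b[0]))]
    straight = [float(signed_axial_difference(a[0], b[0])),
                float(signed_axial_difference(a[1], b[1]))]
    crossed = [float(signed_axial_difference(a[0], b[1])),
               float(signed_axial_difference(a[1], b[0]))]
    if np.mean(np.abs(crossed)) < np.mean(np.abs(straight)):
        return crossed
    return straight


def compare_orientation_maps(fine: OrientationMap,
                             coarse_upsampled: OrientationMap,
                             mask: np.ndarray | None = None) -> ComparisonResult:
    """Pixel-wise angular differences between two orientation maps.

    Only pixels where both maps carry the same orientation count (1 or 2)
    and ``mask`` is true are compared.  Per orientation-count class the
    signed differences are histogrammed in 1° bins over [−90, 90) and
    summarized by their mean and the median of the absolute differences.
    """
    if fine.shape != coarse_upsampled.shape:
        raise ValueError("orientation maps must share one grid")
    rows, cols = fine.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (rows, cols):
        raise ValueError("mask shape mismatch")

    signed = np.full((rows, cols, 2), np.nan)
    matched = (np.isin(fine.n_orientations, (1, 2))
               & (fine.n_orientations == coarse_upsampled.n_orientations)
               & mask)
    per_class: dict[int, list[float]] = {1: [], 2: []}
    for r, c in zip(*np.nonzero(matched)):
        k = int(fine.n_orientations[r, c])
        diffs = match_and_diff(list(fine.orientations_deg[r, c, :k]),
                               list(coarse_upsampled.orientations_deg[r, c, :k]))
        signed[r, c, :k] = diffs
        per_class[k].extend(diffs)

    edges = np.arange(-90.0, 90.0 + 1.0, 1.0)
    histograms: dict[int, np.ndarray] = {}
    stats: dict[int, dict[str, float]] = {}
    for k, diffs in per_class.items():
        arr = np.asarray(diffs, dtype=float)
        histograms[k] = np.histogram(arr, bins=edges)[0]
        stats[k] = {
            "n_pixels": int(np.sum(matched & (fine.n_orientations == k))),
            "n_differences": int(arr.size),
            "mean_signed_deg": float(arr.mean()) if arr.size else float("nan"),
            "median_abs_deg": float(np.median(np.abs(arr))) if arr.size else float("nan"),
        }
    return ComparisonResult(signed, np.abs(signed), matched, histograms,
                            edges, stats)


def multiplicity_stats(map_a: OrientationMap, map_b: OrientationMap,
                       mask: np.ndarray | None = None) -> dict[str, float]:
    """Prevalence of multi-orientation pixels in two maps, and its increase.

    ``frac_multi_*`` is the fraction of mask pixels with at least two
    orientations; ``pct_increase`` = 100·(frac_b/frac_a − 1) (NaN and
    flagged when frac_a = 0).
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share one grid")
    if mask is None:
        mask = np.ones(map_a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    fa = float(np.sum((map_a.n_orientations >= 2) & mask)) / n
    fb = float(np.sum((map_b.n_orientations >= 2) & mask)) / n
    undefined = fa == 0
    return {
        "frac_multi_a": fa,
        "frac_multi_b": fb,
        "pct_increase": float("nan") if undefined else 100.0 * (fb / fa - 1.0),
        "pct_increase_defined": not undefined,
        "n_mask_pixels": n,
    }


def distance_inclination_scatter(omap: OrientationMap, alpha_map: np.ndarray,
                                 mask: np.ndarray | None = None,
                                 region_labels: np.ndarray | None = None
                                 ) -> pd.DataFrame:
    """Table of (region, α, Δ) pairs for unidirectional-fiber pixels.

    Emits one row per pixel where the SLI profile had one or two peaks, at
    most one reconstructed orientation (no crossing), and the mask is true.
    ``alpha_map`` holds co-registered inclination angles in degrees.
    """
    rows, cols = omap.shape
    alpha_map = np.asarray(alpha_map, dtype=float)
    if alpha_map.shape != (rows, cols):
        raise ValueError("alpha_map grid mismatch")
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    if region_labels is None:
        region_labels = np.zeros((rows, cols), dtype=int)
    sel = (np.isin(omap.n_peaks, (1, 2)) & (omap.n_orientations <= 1)
           & np.asarray(mask, dtype=bool) & np.isfinite(alpha_map)
           & np.isfinite(omap.peak_distance_deg))
    rr, cc = np.nonzero(sel)
    return pd.DataFrame({
        "region": np.asarray(region_labels)[rr, cc],
        "alpha_deg": alpha_map[rr, cc],
        "delta_deg": omap.peak_distance_deg[rr, cc],
    })


def dot_product_map(vectors_a: np.ndarray, vectors_b: np.ndarray,
                    mask: np.ndarray | None = None,
                    fa_map: np.ndarray | None = None,
                    fa_threshold: float | None = None,
                    n_hist_bins: int = 50) -> dict:
    """Axial dot product of two 3D orientation-vector maps.

    ``vectors_*`` have shape (rows, cols, 3).  Per pixel the sign-invariant
    dot product |a·b| (after normalization) and the angular difference
    arccos|a·b| are computed; the median angular difference is reported over
    the mask, optionally gated by ``fa_map > fa_threshold``.  Pixels with a
    zero vector in either map are excluded and counted.
    """
    va = np.asarray(vectors_a, dtype=float)
    vb = np.asarray(vectors_b, dtype=float)
    if va.shape != vb.shape or va.ndim != 3 or va.shape[2] != 3:
        raise ValueError("vector maps must share shape (rows, cols, 3)")
    rows, cols = va.shape[:2]
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    na = np.linalg.norm(va, axis=2)
    nb = np.linalg.norm(vb, axis=2)
    ok = mask & (na > 0) & (nb > 0)
    if fa_map is not None and fa_threshold is not None:
        ok &= np.asarray(fa_map, dtype=float) > fa_threshold
    dot = np.full((rows, cols), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.abs(np.sum(va * vb, axis=2)) / np.where(na * nb > 0, na * nb, 1.0)
    dot[ok] = np.clip(raw[ok], 0.0, 1.0)
    ang = np.degrees(np.arccos(dot[ok]))
    hist, edges = np.histogram(dot[ok], bins=n_hist_bins, range=(0.0, 1.0))
    return {
        "dot_map": dot,
        "histogram": hist,
        "bin_edges": edges,
        "median_angle_deg": float(np.median(ang)) if ang.size else float("nan"),
        "n_pixels": int(ok.sum()),
        "n_excluded_zero_vectors": int(np.sum(mask & ((na == 0) | (nb == 0)))),
    }
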