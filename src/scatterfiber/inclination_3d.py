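"""Fiber inclination from SLI peak distance, and 3D comparison primitives.

For a single in-plane fiber bundle the two peaks of the SLI azimuthal
profile sit 180° apart; with increasing out-of-plane inclination α the two
lobes move toward each other, so the peak distance Δ decreases
monotonically.  A :class:`CalibrationCurve` maps α → Δ; its inverse turns
measured peak distances into inclination estimates.  The package ships a
stand-in curve Δ(α) = 180°·cos α (monotone, endpoints 180° → 0°); a curve
derived from physical scattering simulations can be substituted as a
2-column CSV (alpha_deg, delta_deg).

This module also provides the primitives used for 3D cross-modality
comparison: fractional anisotropy from tensor eigenvalues, the
sign-invariant (axial) dot product, and the (φ, α) → unit-vector bridge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import CalibrationRangeError

__all__ = [
    "CalibrationCurve",
    "TensorEigen",
    "distance_from_inclination",
    "inclination_from_distance",
    "fa_from_eigenvalues",
    "axial_dot",
    "inclination_vector",
    "load_calibration_csv",
    "default_calibration",
]


@dataclass
class CalibrationCurve:
    """Monotone map from fiber inclination α to SLI peak distance Δ.

    ``alpha_deg`` is strictly increasing in [0, 90]; ``delta_deg`` is
    monotone non-increasing with Δ(0) = 180° by convention.
    """

    alpha_deg: np.ndarray
    delta_deg: np.ndarray

    def __post_init__(self) -> None:
        self.alpha_deg = np.asarray(self.alpha_deg, dtype=float)
        self.delta_deg = np.asarray(self.delta_deg, dtype=float)
        if self.alpha_deg.size != self.delta_deg.size or self.alpha_deg.size < 2:
            raise ValueError("curve needs at least 2 matching (alpha, delta) rows")
        if np.any(np.diff(self.alpha_deg) <= 0):
            raise ValueError("alpha grid must be strictly increasing")
        if self.alpha_deg[0] < 0 or self.alpha_deg[-1] > 90:
            raise ValueError("alpha grid must lie in [0, 90]")
        if np.any(np.diff(self.delta_deg) > 1e-12):
            raise ValueError("delta must be monotone non-increasing in alpha")

    def __call__(self, alpha_deg):
        return distance_from_inclination(alpha_deg, self)


def load_calibration_csv(path) -> CalibrationCurve:
    """Load a calibration curve from a 2-column CSV (alpha_deg, delta_deg)."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return CalibrationCurve(arr[:, 0], arr[:, 1])


def default_calibration() -> CalibrationCurve:
    """The packaged stand-in curve Δ(α) = 180°·cos α on a 1° grid."""
    ref = resources.files("scatterfiber.data").joinpath("delta_alpha_standin.csv")
    with resources.as_file(ref) as path:
        return load_calibration_csv(path)


def distance_from_inclination(alpha_deg, curve: CalibrationCurve):
    """Peak distance Δ for inclination α, by linear interpolation."""
    alpha = np.asarray(alpha_deg, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 90):
        raise ValueError("alpha must lie in [0, 90]")
    if np.any(alpha < curve.alpha_deg[0]) or np.any(alpha > curve.alpha_deg[-1]):
        raise CalibrationRangeError("alpha outside the calibration grid")
    out = np.interp(alpha, curve.alpha_deg, curve.delta_deg)
    return float(out) if np.isscalar(alpha_deg) else out


def inclination_from_distance(delta_deg, curve: CalibrationCurve):
    """Inclination α for peak distance Δ (inverse of the calibration curve).

    Values of Δ outside the curve's range raise
    :class:`~scatterfiber.errors.CalibrationRangeError` (flagged rather than
    clamped).  On an exactly flat curve segment the segment's midpoint α is
    returned with a warning.
    """
    delta = np.asarray(delta_deg, dtype=float)
    dmin, dmax = curve.delta_deg[-1], curve.delta_deg[0]
    if np.any(delta < dmin - 1e-9) or np.any(delta > dmax + 1e-9):
        raise CalibrationRangeError(
            f"delta outside calibration range [{dmin}, {dmax}]")
    # np.interp needs increasing x: reverse the (delta, alpha) relation
    d_rev = curve.delta_deg[::-1]
    a_rev = curve.alpha_deg[::-1]
    flat = np.diff(curve.delta_deg) == 0
    if np.any(flat):
        warnings.warn("calibration curve has flat segments; inversion "
                      "returns segment midpoints there", stacklevel=2)
        out = np.empty(np.shape(delta))
        flat_pairs = [(curve.delta_deg[i], 0.5 * (curve.alpha_deg[i]
                                                  + curve.alpha_deg[i + 1]))
                      for i in np.nonzero(flat)[0]]
        base = np.interp(np.clip(delta, dmin, dmax), d_rev, a_rev)
        out = np.asarray(base, dtype=float)
        for d_flat, a_mid in flat_pairs:
            out = np.where(np.isclose(delta, d_flat), a_mid, out)
    else:
        out = np.interp(np.clip(delta, dmin, dmax), d_rev, a_rev)
    return float(out) if np.isscalar(delta_deg) else out


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy of a rank-2 tensor from its eigenvalues.

    FA = sqrt(1/2) · sqrt((λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²) / sqrt(λ1²+λ2²+λ3²),
    in [0, 1]; scale-invariant.  All-zero eigenvalues are undefined.
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    l3 = np.asarray(l3, dtype=float)
    if np.any(l1 < 0) or np.any(l2 < 0) or np.any(l3 < 0):
        raise ValueError("eigenvalues must be nonnegative")
    norm_sq = l1 ** 2 + l2 ** 2 + l3 ** 2
    if np.any(norm_sq == 0):
        raise ValueError("FA undefined for all-zero eigenvalues")
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    out = np.sqrt(0.5) * np.sqrt(num / norm_sq)
    return float(out) if out.ndim == 0 else out


@dataclass
class TensorEigen:
    """Sorted eigenvalues and principal axis of a rank-2 diffusion tensor."""

    eigenvalues: np.ndarray
    principal_axis: np.ndarray

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.principal_axis = np.asarray(self.principal_axis, dtype=float)
        if self.eigenvalues.shape != (3,):
            raise ValueError("eigenvalues must be a length-3 vector")
        if np.any(np.diff(self.eigenvalues) > 0) or np.any(self.eigenvalues < 0):
            raise ValueError("eigenvalues must be sorted descending, nonnegative")
        norm = np.linalg.norm(self.principal_axis)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("principal_axis must be unit-norm")

    @property
    def fa(self) -> float:
        return fa_from_eigenvalues(*self.eigenvalues)


def axial_dot(u, v) -> float:
    """|u·v| for unit vectors — the sign-invariant overlap of two axes.

    Inputs are normalized internally; zero-length vectors are an error.
    1 for parallel or antiparallel axes, 0 for orthogonal.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("axial_dot undefined for zero-length vectors")
    return float(min(abs(u @ v) / (nu * nv), 1.0))


def inclination_vector(phi_deg: float, alpha_deg: float) -> np.ndarray:
    """Unit 3-vector for in-plane orientation φ and inclination α.

    (cos α·cos φ, cos α·sin φ, sin α); α = 90° gives the plane normal
    regardless of φ.
    """
    if not (0.0 <= phi_deg < 180.0):
        raise ValueError("phi must be in [0, 180)")
    if not (0.0 <= alpha_deg <= 90.0):
        raise ValueError("alpha must be in [0, 90]")
    phi = np.radians(phi_deg)
    alpha = np.radians(alpha_deg)
    return np.array([np.cos(alpha) * np.cos(phi),
                     np.cos(alpha) * np.sin(phi),
                     np.sin(alpha)])
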