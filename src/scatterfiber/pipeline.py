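"""End-to-end validation runs: simulate → extract → peak analysis → compare.

`run_full_validation` drives the whole chain on a synthetic phantom and
emits the same style of summary statistics used for cross-modality
validation on real sections: per-class (one / two orientations) angular
difference histograms and medians against the ground truth, multi-
orientation prevalence, and the peak-distance-versus-inclination table.
Every run records its seed and a hash of the resolved configuration, so
repeated runs with the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cross_modality import (
    compare_orientation_maps,
    distance_inclination_scatter,
    multiplicity_stats,
)
from .inclination_3d import CalibrationCurve, default_calibration, load_calibration_csv
from .peak_analysis import OrientationMap, analyze_profile_map
from .profile_extraction import angular_stack_to_profiles
from .synthetic_phantoms import PhantomSection, build_phantom, render_sli_stack

logger = logging.getLogger("scatterfiber")

__all__ = [
    "RunConfig",
    "run_full_validation",
    "default_validation_layout",
    "ground_truth_orientation_map",
    "config_hash",
]


def default_validation_layout(shape=(64, 64)) -> list[dict]:
    """Two-region layout: unidirectional bundle + 60° crossing, with border.

    Mimics the canonical section geometry: a corpus-callosum-like
    unidirectional in-plane bundle (φ = 70°) and a corona-radiata-like
    crossing region (φ = 40° and 100°), embedded in a background frame.
    """
    r, c = shape
    m = max(r // 16, 1)  # background margin
    mid = c // 2
    return [
        {"name": "cc", "rect": (m, r - m, m, mid),
         "populations": [{"phi": 70.0}]},
        {"name": "cr", "rect": (m, r - m, mid, c - m),
         "populations": [{"phi": 40.0}, {"phi": 100.0}]},
    ]


@dataclass
class RunConfig:
    """Parameters of a full synthetic validation run."""

    shape: tuple[int, int] = (64, 64)
    layout: list | None = None          # None -> default_validation_layout
    n_azimuths: int = 24
    kappa: float = 20.0
    baseline: float = 0.1
    noise: dict | str = field(default_factory=lambda: {"kind": "gaussian",
                                                       "sigma": 0.01})
    seed: int = 0
    prominence_frac: float = 0.08
    pair_tol_deg: float = 35.0
    mode: str = "scattering"
    calibration_csv: str | None = None  # None -> packaged stand-in curve
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.shape = tuple(cfg.shape)
        return cfg

    def calibration(self) -> CalibrationCurve:
        if self.calibration_csv:
            return load_calibration_csv(self.calibration_csv)
        return default_calibration()


def _jsonable(obj):
    """Recursively convert numpy scalars and NaN to JSON-clean values."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    return obj


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def ground_truth_orientation_map(phantom: PhantomSection,
                                 curve: CalibrationCurve | None = None
                                 ) -> OrientationMap:
    """Orientation map implied directly by the phantom's ground truth.

    Orientations are the populations' φ values; the peak count is twice the
    population count (each population contributes a lobe pair) and the peak
    distance for single-population pixels is the calibration curve's Δ(α).
    """
    if curve is None:
        curve = default_calibration()
    rows, cols = phantom.shape
    orientations = phantom.phi_map()
    npop = phantom.n_populations()
    pdist = np.full((rows, cols), np.nan)
    for r in range(rows):
        for c in range(cols):
            pops = phantom.populations[r][c]
            if len(pops) == 1:
                pdist[r, c] = curve(pops[0].alpha)
    return OrientationMap(orientations, npop, pdist,
                          np.minimum(2 * npop, 6))


def run_full_validation(config: RunConfig) -> dict:
    """Execute the full synthetic validation chain; returns the report dict.

    Stages: phantom construction, SLI rendering, profile extraction, peak
    analysis, comparison with ground truth, multiplicity statistics and the
    peak-distance-vs-inclination table.  When ``config.out_dir`` is set the
    report (JSON), the histograms and the scatter table (CSV) are written
    there.
    """
    stage = "setup"
    try:
        curve = config.calibration()
        layout = config.layout or default_validation_layout(config.shape)

        stage = "simulate"
        phantom = build_phantom(layout, config.shape, seed=config.seed)
        stack = render_sli_stack(phantom, config.n_azimuths, config.kappa,
                                 config.baseline, config.noise,
                                 seed=config.seed, delta_curve=curve)

        stage = "extract"
        pmap = angular_stack_to_profiles(stack)

        stage = "peaks"
        omap, params = analyze_profile_map(pmap, config.prominence_frac,
                                           config.pair_tol_deg, config.mode)

        stage = "compare"
        truth = ground_truth_orientation_map(phantom, curve)
        comp = compare_orientation_maps(omap, truth, mask=phantom.tissue_mask)
        mult = multiplicity_stats(truth, omap, phantom.tissue_mask)
        alpha3 = phantom.alpha_map()
        alpha_single = np.where(phantom.n_populations() == 1,
                                alpha3[:, :, 0], np.nan)
        scatter = distance_inclination_scatter(omap, alpha_single,
                                               phantom.tissue_mask,
                                               phantom.region_labels)
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stats = {str(k): v for k, v in comp.stats.items()}
    region_summary = (scatter.groupby("region")[["alpha_deg", "delta_deg"]]
                      .median().rename(columns=lambda s: "median_" + s)
                      .reset_index().to_dict("records") if len(scatter) else [])
    report = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config_hash(config),
        },
        "classes": {
            "one_orientation": stats.get("1", {}),
            "two_orientations": stats.get("2", {}),
        },
        "multiplicity": mult,
        "scatter": {
            "n_rows": int(len(scatter)),
            "per_region_medians": region_summary,
        },
        "n_tissue_pixels": int(phantom.tissue_mask.sum()),
    }
    report = _jsonable(report)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
        scatter.to_csv(out / "distance_inclination.csv", index=False)
        for k, hist in comp.histograms.items():
            np.savetxt(out / f"histogram_{k}_orientations.csv",
                       np.column_stack([comp.bin_edges[:-1], hist]),
                       delimiter=",", header="bin_left_deg,count", comments="")
        from .io import write_orientation_maps
        write_orientation_maps(out / "maps", omap, params,
                               meta={"prominence_frac": config.prominence_frac,
                                     "pair_tol_deg": config.pair_tol_deg,
                                     "mode": config.mode,
                                     "n_azimuths": config.n_azimuths})
        logger.info("validation report written to %s", out)
    return report
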