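"""File formats: TIFF stacks, HDF5 frames/profiles, NIfTI SH maps.

Conventions
-----------
* Angular SLI stacks: multi-page grayscale TIFF (one page per illumination
  azimuth) plus a YAML sidecar ``<stem>.yaml`` recording the azimuths and
  the polar illumination angle θ.
* Scatterometry stacks: HDF5 with dataset ``/frames`` shaped
  (grid_i, grid_j, rows, cols).
* SAXS raster scans: HDF5 with ``/frames`` shaped
  (n_y, n_x, det_rows, det_cols) and a ``/geometry`` group carrying
  ``beam_center`` (row, col), ``q_per_pixel`` (nm⁻¹/px) and ``mask``.
* Profile maps: HDF5 with ``/profiles`` (rows, cols, n_bins),
  ``/bin_centers`` and ``/valid``; modality stored as an attribute.
* Orientation/parameter maps: one float32 multi-page TIFF per quantity,
  absent values encoded as NaN, plus a JSON sidecar with the analysis
  parameters.
* SH coefficient volumes: NIfTI with the 4th dimension indexing real
  even-degree SH coefficients (l ascending, m = −l..l within l; see
  ``real_sh_basis``); the ordering is recorded in the header description.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile
import yaml

from .peak_analysis import OrientationMap, ParameterMaps
from .profile_extraction import ProfileMap
from .synthetic_phantoms import DetectorGeometry, ImageStack

__all__ = [
    "write_image_stack", "read_image_stack",
    "write_scatterometry_h5", "read_scatterometry_h5",
    "write_saxs_h5", "read_saxs_h5",
    "write_profiles_h5", "read_profiles_h5",
    "write_orientation_maps", "read_orientation_maps",
    "write_sh_nifti", "read_sh_nifti",
]

_SH_DESCRIPTION = b"real even-degree SH, l ascending, m=-l..l within l"


# -- angular SLI stacks ------------------------------------------------------

def write_image_stack(path, stack: ImageStack) -> None:
    """Write an angular SLI stack as multi-page TIFF + YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(stack.data, 2, 0).astype(np.float32),
                     photometric="minisblack")
    sidecar = {
        "azimuths_deg": [float(a) for a in stack.azimuths_deg],
        "polar_deg": float(stack.polar_deg),
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_image_stack(path) -> ImageStack:
    path = Path(path)
    data = np.moveaxis(tifffile.imread(path), 0, 2).astype(float)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    return ImageStack(data, np.asarray(meta["azimuths_deg"], dtype=float),
                      polar_deg=float(meta.get("polar_deg", 45.0)))


# -- scatterometry -----------------------------------------------------------

def write_scatterometry_h5(path, frames: np.ndarray, meta: dict | None = None) -> None:
    """frames: (grid_i, grid_j, rows, cols)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=np.asarray(frames, dtype=np.float32))
        grp = f.create_group("meta")
        for k, v in (meta or {}).items():
            grp.attrs[k] = v


def read_scatterometry_h5(path) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        frames = f["frames"][()]
        meta = dict(f["meta"].attrs) if "meta" in f else {}
    return frames.astype(float), meta


# -- SAXS --------------------------------------------------------------------

def write_saxs_h5(path, frames: np.ndarray, geometry: DetectorGeometry) -> None:
    """frames: (n_y, n_x, det_rows, det_cols) raster of detector frames."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=np.asarray(frames, dtype=np.float32))
        g = f.create_group("geometry")
        g.attrs["beam_center"] = list(geometry.beam_center)
        g.attrs["q_per_pixel"] = float(geometry.q_per_pixel)
        g.create_dataset("mask", data=geometry.mask.astype(np.uint8))


def read_saxs_h5(path) -> tuple[np.ndarray, DetectorGeometry]:
    with h5py.File(path, "r") as f:
        frames = f["frames"][()].astype(float)
        g = f["geometry"]
        geom = DetectorGeometry(
            frame_shape=frames.shape[2:],
            beam_center=tuple(float(x) for x in g.attrs["beam_center"]),
            q_per_pixel=float(g.attrs["q_per_pixel"]),
            mask=g["mask"][()].astype(bool),
        )
    return frames, geom


# -- profile maps ------------------------------------------------------------

def write_profiles_h5(path, pmap: ProfileMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("profiles", data=pmap.values.astype(np.float32))
        f.create_dataset("bin_centers", data=pmap.bin_centers_deg)
        f.create_dataset("valid", data=pmap.valid.astype(np.uint8))
        f.attrs["modality"] = pmap.modality


def read_profiles_h5(path) -> ProfileMap:
    with h5py.File(path, "r") as f:
        return ProfileMap(f["profiles"][()].astype(float),
                          f["bin_centers"][()],
                          f["valid"][()].astype(bool),
                          modality=str(f.attrs.get("modality", "sli_angular")))


# -- orientation / parameter maps --------------------------------------------

def write_orientation_maps(out_dir, omap: OrientationMap,
                           params: ParameterMaps | None = None,
                           meta: dict | None = None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "orientations.tif",
                     np.moveaxis(omap.orientations_deg, 2, 0).astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(out_dir / "n_orientations.tif",
                     omap.n_orientations.astype(np.float32))
    tifffile.imwrite(out_dir / "peak_distance.tif",
                     omap.peak_distance_deg.astype(np.float32))
    tifffile.imwrite(out_dir / "n_peaks.tif", omap.n_peaks.astype(np.float32))
    if params is not None:
        pages = np.stack([params.average, params.maximum, params.minimum,
                          params.mean_prominence, params.mean_width])
        tifffile.imwrite(out_dir / "parameters.tif", pages.astype(np.float32),
                         photometric="minisblack")
    (out_dir / "analysis.json").write_text(json.dumps(meta or {}, indent=2))


def read_orientation_maps(out_dir) -> OrientationMap:
    out_dir = Path(out_dir)
    orientations = np.moveaxis(
        tifffile.imread(out_dir / "orientations.tif").astype(float), 0, 2)
    return OrientationMap(
        orientations,
        tifffile.imread(out_dir / "n_orientations.tif").astype(int),
        tifffile.imread(out_dir / "peak_distance.tif").astype(float),
        tifffile.imread(out_dir / "n_peaks.tif").astype(int),
    )


# -- SH NIfTI ----------------------------------------------------------------

def write_sh_nifti(path, coeffs: np.ndarray) -> None:
    """coeffs: (rows, cols, slices, n_coeffs) or (rows, cols, n_coeffs)."""
    coeffs = np.asarray(coeffs, dtype=np.float32)
    if coeffs.ndim == 3:
        coeffs = coeffs[:, :, None, :]
    img = nib.Nifti1Image(coeffs, affine=np.eye(4))
    img.header["descrip"] = _SH_DESCRIPTION
    nib.save(img, str(path))


def read_sh_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
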