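"""File formats: spot tables (CSV), optical configs (YAML/JSON), phase masks (PNG/TIFF).

Boundary units are micrometres for spot coordinates, nanometres for the
wavelength and millimetres for the focal length; everything is converted to
SI metres on read.  Phase masks are written as single-channel integer
images: grey level ``round(wrap(phi, 2*pi) / (2*pi) * L)`` with ``L`` the
configured 2π grey level (default 255).  Wrapping happens only here — the
in-memory hologram keeps unwrapped phases.  Row 0 of the image is row 0 of
the hologram (the top of the SLM).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .optics import Hologram, OpticalConfig, SpotSet

__all__ = [
    "read_spots_csv",
    "write_spots_csv",
    "load_optical_config",
    "write_phase_mask",
    "phase_mask_levels",
]

_SPOT_COLUMNS = ("x_um", "y_um", "z_um")


def read_spots_csv(path) -> SpotSet:
    """Read a spot table: columns ``x_um, y_um, z_um`` and optional ``weight``.

    Row order is preserved.  Non-numeric or non-finite cells raise an error
    naming the offending row (1-based, excluding the header).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty spot table") from None
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: spot table has a header but no rows")
    missing = [c for c in _SPOT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; need {list(_SPOT_COLUMNS)}")
    cols = list(_SPOT_COLUMNS) + (["weight"] if "weight" in frame.columns else [])
    numeric = frame[cols].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy()).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(f"{path}: non-numeric or non-finite value in data row {row}")
    coords = numeric[list(_SPOT_COLUMNS)].to_numpy() * 1e-6
    weights = None
    if "weight" in numeric.columns:
        weights = numeric["weight"].to_numpy()
        if np.any(weights <= 0):
            row = int(np.flatnonzero(weights <= 0)[0]) + 1
            raise ValueError(f"{path}: weight must be strictly positive (data row {row})")
    return SpotSet(coords, target_weights=weights)


def write_spots_csv(spots: SpotSet, path) -> None:
    """Inverse of :func:`read_spots_csv` (coordinates written in µm)."""
    frame = pd.DataFrame(spots.coords * 1e6, columns=list(_SPOT_COLUMNS))
    if spots.target_weights is not None:
        frame["weight"] = spots.target_weights
    frame.to_csv(path, index=False)


def load_optical_config(path) -> OpticalConfig:
    """Load an optical config from YAML or JSON.

    Keys: ``wavelength_nm, focal_length_mm, pixel_pitch_um, slm_rows,
    slm_cols`` and optional ``aperture`` ("full" | "circular").
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    required = ["wavelength_nm", "focal_length_mm", "pixel_pitch_um", "slm_rows", "slm_cols"]
    missing = [k for k in required if k not in data]
    if missing:
        raise ValueError(f"{path}: missing config key(s) {missing}")
    return OpticalConfig.from_units(
        wavelength_nm=float(data["wavelength_nm"]),
        focal_length_mm=float(data["focal_length_mm"]),
        pixel_pitch_um=float(data["pixel_pitch_um"]),
        slm_rows=int(data["slm_rows"]),
        slm_cols=int(data["slm_cols"]),
        aperture=data.get("aperture", "full"),
    )


def phase_mask_levels(holo: Hologram, grey_levels: int = 255) -> np.ndarray:
    """Integer grey levels of a hologram: ``round(wrap(phi)/(2*pi) * L)``.

    Values span [0, L]; a phase just below 2π maps to L (wrapping happens
    before rounding, so rounding never wraps a near-2π phase to 0).
    """
    if grey_levels < 1 or grey_levels > 65535:
        raise ValueError("grey_levels must lie in [1, 65535]")
    wrapped = np.mod(holo.phase, 2.0 * np.pi)
    levels = np.rint(wrapped / (2.0 * np.pi) * grey_levels)
    dtype = np.uint8 if grey_levels <= 255 else np.uint16
    return levels.astype(dtype)


def write_phase_mask(holo: Hologram, path, grey_levels: int = 255) -> None:
    """Write a hologram as an 8-bit (or 16-bit) grayscale PNG or TIFF mask.

    The format follows the file extension (.png / .tif / .tiff).  Output is
    deterministic: equal holograms give byte-identical files.
    """
    path = Path(path)
    levels = phase_mask_levels(holo, grey_levels)
    suffix = path.suffix.lower()
    if suffix == ".png":
        mode = "L" if levels.dtype == np.uint8 else "I;16"
        Image.fromarray(levels, mode=mode).save(path, format="PNG")
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, levels)
    else:
        raise ValueError(f"unsupported mask format {suffix!r}; use .png, .tif or .tiff")
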