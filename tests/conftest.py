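"""Shared fixtures and independent brute-force oracles.

The oracles evaluate the tip/tilt/defocus phase, the weighted superposition
and the spot-amplitude integral with scalar arithmetic (``math``/``cmath``
double loops over pixels), fully independently of the vectorized library
paths they are used to check.
"""

from __future__ import annotations

import cmath
import math

import numpy as np
import pytest

from holospots import OpticalConfig, make_pupil_grid


def oracle_pixel_coords(cfg: OpticalConfig, i: int, j: int) -> tuple[float, float]:
    p = cfg.pixel_pitch
    return (j - (cfg.n_cols - 1) / 2.0) * p, (i - (cfg.n_rows - 1) / 2.0) * p


def oracle_spot_phase(cfg: OpticalConfig, i: int, j: int, sx: float, sy: float, sz: float) -> float:
    """Scalar tip/tilt/defocus phase at pixel (i, j) for a spot at (sx, sy, sz)."""
    xp, yp = oracle_pixel_coords(cfg, i, j)
    lam, f = cfg.wavelength, cfg.focal_length
    return math.pi * sz / (lam * f * f) * (xp * xp + yp * yp) + 2.0 * math.pi / (lam * f) * (
        sx * xp + sy * yp
    )


def oracle_superpose(cfg: OpticalConfig, coords, theta, omega) -> np.ndarray:
    """Pixel-wise arg of the weighted sum of spot fields, scalar double loop."""
    out = np.zeros((cfg.n_rows, cfg.n_cols))
    for i in range(cfg.n_rows):
        for j in range(cfg.n_cols):
            total = 0j
            for (sx, sy, sz), th, w in zip(coords, theta, omega):
                total += w * cmath.exp(1j * (oracle_spot_phase(cfg, i, j, sx, sy, sz) + th))
            out[i, j] = cmath.phase(total)
    return out


def oracle_amplitude(cfg: OpticalConfig, phase_2d: np.ndarray, sx, sy, sz) -> complex:
    """Mean of exp(i*(phi_cgh - phi_spot)) over all pixels, scalar double loop."""
    total = 0j
    for i in range(cfg.n_rows):
        for j in range(cfg.n_cols):
            total += cmath.exp(1j * (phase_2d[i, j] - oracle_spot_phase(cfg, i, j, sx, sy, sz)))
    return total / (cfg.n_rows * cfg.n_cols)


@pytest.fixture(scope="session")
def cfg16() -> OpticalConfig:
    return OpticalConfig.from_units(800, 18, 9.2, 16, 16)


@pytest.fixture(scope="session")
def grid16(cfg16):
    return make_pupil_grid(cfg16)


@pytest.fixture(scope="session")
def cfg64() -> OpticalConfig:
    return OpticalConfig.from_units(800, 18, 9.2, 64, 64)


@pytest.fixture(scope="session")
def grid64(cfg64):
    return make_pupil_grid(cfg64)
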