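"""Pupil-plane optical model for multi-spot holography.

A phase-only spatial light modulator (SLM) sits in a plane conjugate to the
objective back aperture.  Under the Fourier-optics approximation, a spot at
image-space coordinates ``(x, y, z)`` is produced by the pupil phase

    phi(x', y') = (pi * z / (lambda * f**2)) * (x'**2 + y'**2)
                + (2 * pi / (lambda * f)) * (x * x' + y * y')

— a combination of tip, tilt and defocus — where ``(x', y')`` are physical
pixel coordinates on the SLM, ``lambda`` the wavelength and ``f`` the
equivalent focal length of the optical train.

The forward map from a hologram to the complex amplitude focused on spot *n*
is discretized as a mean over the active pixels,

    c_n = (1/M) * sum_m exp(i * (phi_cgh[m] - phi_n[m])),

so that ``|c_n| <= 1`` with equality for a perfect single-spot hologram, and
results do not depend on the pixel count.  Spot intensity is ``I_n = |c_n|**2``.

All lengths are SI metres internally; file/CLI boundaries use nm (wavelength),
mm (focal length) and µm (pitch, spot coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OpticalConfig",
    "PupilGrid",
    "Spot",
    "SpotSet",
    "Hologram",
    "PixelSubset",
    "make_pupil_grid",
    "spot_phase",
    "spot_amplitude",
    "all_spot_intensities",
    "addressable_field",
]

# Per-spot field caches above this size fall back to a streaming loop.
MAX_FIELD_CACHE_BYTES = 2 * 1024**3


@dataclass(frozen=True)
class OpticalConfig:
    """Optical constants and SLM geometry.  Lengths in metres.

    ``aperture`` selects the active pixel set: ``"full"`` uses the whole
    rectangular panel, ``"circular"`` restricts to the inscribed ellipse.
    """

    wavelength: float
    focal_length: float
    pixel_pitch: float
    n_rows: int
    n_cols: int
    aperture: str = "full"

    def __post_init__(self) -> None:
        for name in ("wavelength", "focal_length", "pixel_pitch"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive finite length, got {getattr(self, name)!r}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"pixel counts must be >= 1, got {self.n_rows}x{self.n_cols}")
        if self.aperture not in ("full", "circular"):
            raise ValueError(f"aperture must be 'full' or 'circular', got {self.aperture!r}")

    @classmethod
    def from_units(
        cls,
        wavelength_nm: float,
        focal_length_mm: float,
        pixel_pitch_um: float,
        slm_rows: int,
        slm_cols: int,
        aperture: str = "full",
    ) -> "OpticalConfig":
        """Build a config from the boundary units used in files and the CLI."""
        return cls(
            wavelength=wavelength_nm * 1e-9,
            focal_length=focal_length_mm * 1e-3,
            pixel_pitch=pixel_pitch_um * 1e-6,
            n_rows=int(slm_rows),
            n_cols=int(slm_cols),
            aperture=aperture,
        )


@dataclass(frozen=True)
class PupilGrid:
    """SLM pixel lattice with physical coordinates.

    ``x`` and ``y`` hold the centre coordinates of every pixel of the
    rectangular panel in row-major order, origin at the geometric centre.
    ``active`` indexes the pixels inside the configured aperture; the
    forward model sums over these ``M = len(active)`` pixels only.
    """

    config: OpticalConfig
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    active: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.config.n_rows, self.config.n_cols)

    @property
    def n_pixels(self) -> int:
        """Total pixel count of the rectangular panel."""
        return self.config.n_rows * self.config.n_cols

    @property
    def m(self) -> int:
        """Number of active pupil pixels (the M of the cost model)."""
        return int(self.active.size)


def make_pupil_grid(config: OpticalConfig) -> PupilGrid:
    """Lay out the SLM pixel lattice for ``config``.

    Pixel (i, j) sits at ``((j - (n_cols-1)/2) * pitch, (i - (n_rows-1)/2) * pitch)``,
    so the coordinate arrays are symmetric about zero up to half-pixel parity.
    """
    p = config.pixel_pitch
    jj = (np.arange(config.n_cols) - (config.n_cols - 1) / 2.0) * p
    ii = (np.arange(config.n_rows) - (config.n_rows - 1) / 2.0) * p
    x = np.tile(jj, config.n_rows)
    y = np.repeat(ii, config.n_cols)
    if config.aperture == "circular":
        rx = config.n_cols * p / 2.0
        ry = config.n_rows * p / 2.0
        active = np.flatnonzero((x / rx) ** 2 + (y / ry) ** 2 <= 1.0)
    else:
        active = np.arange(x.size)
    x.setflags(write=False)
    y.setflags(write=False)
    active.setflags(write=False)
    return PupilGrid(config=config, x=x, y=y, active=active)


@dataclass(frozen=True)
class Spot:
    """One target focus in image space: lateral x, y and axial defocus z (metres)."""

    x: float
    y: float
    z: float = 0.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError(f"spot coordinates must be finite, got ({self.x}, {self.y}, {self.z})")


class SpotSet:
    """Ordered collection of N target foci with optional per-spot target weights.

    Weights express the *relative intensity* requested for each spot; they
    default to uniform.  Internally stored as an (N, 3) coordinate array.
    """

    def __init__(self, spots: Sequence[Spot] | np.ndarray, target_weights: np.ndarray | None = None):
        if isinstance(spots, np.ndarray):
            coords = np.atleast_2d(np.asarray(spots, dtype=float))
        else:
            coords = np.array([(s.x, s.y, s.z) for s in spots], dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("spots must form a non-empty (N, 3) array of (x, y, z)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("spot coordinates must be finite")
        self.coords = coords
        self.coords.setflags(write=False)
        if target_weights is not None:
            w = np.asarray(target_weights, dtype=float)
            if w.shape != (len(self),) or not np.all(np.isfinite(w)) or np.any(w <= 0):
                raise ValueError("target_weights must be N strictly positive finite values")
            self.target_weights = w
            self.target_weights.setflags(write=False)
        else:
            self.target_weights = None

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __getitem__(self, n: int) -> Spot:
        return Spot(*self.coords[n])

    def __iter__(self):
        for row in self.coords:
            yield Spot(*row)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpotSet):
            return NotImplemented
        if not np.array_equal(self.coords, other.coords):
            return False
        a, b = self.target_weights, other.target_weights
        if (a is None) != (b is None):
            return False
        return a is None or np.array_equal(a, b)

    def weights(self) -> np.ndarray:
        """Target weights, normalized to sum to one (uniform when unset)."""
        n = len(self)
        if self.target_weights is None:
            return np.full(n, 1.0 / n)
        return self.target_weights / self.target_weights.sum()


@dataclass(frozen=True)
class Hologram:
    """Real-valued phase map (radians) over a pupil grid.

    Phases are kept unwrapped; the 2π-periodic interpretation is deferred to
    mask export.  ``phase`` has the panel shape ``(n_rows, n_cols)``.
    """

    grid: PupilGrid
    phase: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.phase.shape != self.grid.shape:
            raise ValueError(f"phase shape {self.phase.shape} does not match grid {self.grid.shape}")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("hologram phase must be finite everywhere")

    def flat(self) -> np.ndarray:
        """Phase over active pixels, flattened row-major."""
        return self.phase.reshape(-1)[self.grid.active]


@dataclass(frozen=True)
class PixelSubset:
    """Distinct indices into the active pixel list of a pupil grid."""

    indices: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        if self.indices.size == 0:
            raise ValueError("pixel subset must be non-empty")

    def __len__(self) -> int:
        return int(self.indices.size)


def _spot_phase_flat(grid: PupilGrid, coords: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
    """Tip/tilt/defocus phase of one spot over active pixels (or a subset of them)."""
    cfg = grid.config
    sel = grid.active if idx is None else grid.active[idx]
    xp = grid.x[sel]
    yp = grid.y[sel]
    sx, sy, sz = coords
    lam_f = cfg.wavelength * cfg.focal_length
    return (np.pi * sz / (cfg.wavelength * cfg.focal_length**2)) * (xp * xp + yp * yp) + (
        2.0 * np.pi / lam_f
    ) * (sx * xp + sy * yp)


def spot_phase(grid: PupilGrid, spot: Spot) -> Hologram:
    """Single-spot hologram: tip/tilt for (x, y) plus defocus for z, unwrapped.

    A spot at the origin of the focal plane gives the all-zero phase map.
    """
    phase = np.zeros(grid.n_pixels)
    phase[grid.active] = _spot_phase_flat(grid, np.array([spot.x, spot.y, spot.z]))
    return Hologram(grid=grid, phase=phase.reshape(grid.shape))


def spot_fields(grid: PupilGrid, spots: SpotSet, idx: np.ndarray | None = None) -> np.ndarray:
    """Unit fields ``exp(i * phi_n)`` for every spot, shape (N, P).

    ``idx`` restricts evaluation to a subset of active pixels.  This is the
    row-wise (implicit) view of the linear forward operator; it is built in
    per-spot passes and never used as a dense system matrix.
    """
    n_pix = grid.m if idx is None else int(np.asarray(idx).size)
    out = np.empty((len(spots), n_pix), dtype=complex)
    for n, row in enumerate(spots.coords):
        out[n] = np.exp(1j * _spot_phase_flat(grid, row, idx))
    return out


def spot_amplitude(
    holo: Hologram, spot_holo: Hologram, subset: PixelSubset | None = None
) -> complex:
    """Complex amplitude delivered to a spot: mean of ``exp(i*(phi_cgh - phi_n))``.

    With ``subset`` the mean runs over the subset pixels only (the compressed
    estimate used by the CS iterations); otherwise over the full active pupil.
    ``|result| <= 1`` always, with equality iff the phase difference is
    constant over the pixels visited.
    """
    if holo.grid is not spot_holo.grid and holo.grid.shape != spot_holo.grid.shape:
        raise ValueError("holograms must share one pupil grid")
    diff = holo.flat() - spot_holo.flat()
    if subset is not None:
        if np.any(subset.indices < 0) or np.any(subset.indices >= holo.grid.m):
            raise ValueError("subset indices out of range for this grid")
        diff = diff[subset.indices]
    return complex(np.exp(1j * diff).mean())


def all_spot_intensities(holo: Hologram, spots: SpotSet) -> np.ndarray:
    """Normalized intensity ``I_n = |c_n|**2`` of every spot, full pupil.

    On this scale a perfect single-spot hologram scores exactly 1.
    """
    phi_cgh = holo.flat()
    c = np.empty(len(spots), dtype=complex)
    for n, row in enumerate(spots.coords):
        c[n] = np.exp(1j * (phi_cgh - _spot_phase_flat(holo.grid, row))).mean()
    return np.abs(c) ** 2


def addressable_field(grid: PupilGrid) -> tuple[float, float, float]:
    """Half-extents (x_max, y_max, z_max) of the comfortably addressable field.

    Lateral: the Nyquist tilt limit ``lambda * f / (2 * pitch)`` per axis.
    Axial: the defocus for which the phase slope at the pupil edge reaches
    half the Nyquist limit, ``lambda * f**2 / (4 * r_max * pitch)`` with
    ``r_max`` the largest pixel radius.  Used by the benchmark generators to
    place spot patterns that span the field without aliasing.
    """
    cfg = grid.config
    x_max = cfg.wavelength * cfg.focal_length / (2.0 * cfg.pixel_pitch)
    y_max = x_max
    r_max = float(np.hypot(grid.x[grid.active], grid.y[grid.active]).max())
    z_max = cfg.wavelength * cfg.focal_length**2 / (4.0 * r_max * cfg.pixel_pitch)
    return x_max, y_max, z_max
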