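"""Synthetic target patterns for benchmarking the synthesis algorithms.

Three generators cover the standard benchmark conditions: a random 3D point
cloud (a typical sparse photostimulation request), a regular 2D grid (the
worst case for intensity uniformity, where the weighted algorithms earn
their keep), and planar point patterns tracing block-letter glyphs.
All coordinates are SI metres in image space.
"""

from __future__ import annotations

import numpy as np

from .optics import SpotSet

__all__ = ["random_spot_cloud", "grid_pattern", "glyph_pattern", "GLYPH_STROKES"]


def random_spot_cloud(
    n: int,
    lateral_extent: float,
    axial_extent: float,
    seed: int | np.random.Generator,
) -> SpotSet:
    """``n`` spots uniform in the box [-lx, lx]^2 x [-lz, lz].

    ``axial_extent = 0`` gives a planar (2D) pattern.
    """
    if n < 1:
        raise ValueError("need at least one spot")
    if lateral_extent <= 0 or axial_extent < 0:
        raise ValueError("lateral extent must be positive, axial extent non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.uniform(-lateral_extent, lateral_extent, n)
    y = rng.uniform(-lateral_extent, lateral_extent, n)
    z = rng.uniform(-axial_extent, axial_extent, n) if axial_extent > 0 else np.zeros(n)
    return SpotSet(np.column_stack([x, y, z]))


def grid_pattern(rows: int, cols: int, spacing: float) -> SpotSet:
    """``rows x cols`` spots on a centred rectangular lattice in the focal plane."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    jj = (np.arange(cols) - (cols - 1) / 2.0) * spacing
    ii = (np.arange(rows) - (rows - 1) / 2.0) * spacing
    gx, gy = np.meshgrid(jj, ii)
    return SpotSet(np.column_stack([gx.ravel(), gy.ravel(), np.zeros(rows * cols)]))


# Block-letter strokes on a unit box [0, 1] x [0, 1]; each letter is a list of
# polylines.  Geometry is only a deterministic source of spot coordinates.
GLYPH_STROKES: dict[str, list[list[tuple[float, float]]]] = {
    "T": [[(0.0, 1.0), (1.0, 1.0)], [(0.5, 1.0), (0.5, 0.0)]],
    "U": [[(0.0, 1.0), (0.0, 0.0), (1.0, 0.0), (1.0, 1.0)]],
    "D": [[(0.0, 0.0), (0.0, 1.0), (0.65, 1.0), (1.0, 0.7), (1.0, 0.3), (0.65, 0.0), (0.0, 0.0)]],
    "C": [[(1.0, 1.0), (0.0, 1.0), (0.0, 0.0), (1.0, 0.0)]],
    "E": [[(1.0, 1.0), (0.0, 1.0), (0.0, 0.0), (1.0, 0.0)], [(0.0, 0.5), (0.8, 0.5)]],
    "F": [[(1.0, 1.0), (0.0, 1.0), (0.0, 0.0)], [(0.0, 0.5), (0.8, 0.5)]],
    "H": [[(0.0, 1.0), (0.0, 0.0)], [(1.0, 1.0), (1.0, 0.0)], [(0.0, 0.5), (1.0, 0.5)]],
    "I": [[(0.5, 1.0), (0.5, 0.0)]],
    "L": [[(0.0, 1.0), (0.0, 0.0), (1.0, 0.0)]],
    "N": [[(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]],
    "O": [[(0.0, 0.0), (0.0, 1.0), (1.0, 1.0), (1.0, 0.0), (0.0, 0.0)]],
    "S": [[(1.0, 1.0), (0.0, 1.0), (0.0, 0.5), (1.0, 0.5), (1.0, 0.0), (0.0, 0.0)]],
    "V": [[(0.0, 1.0), (0.5, 0.0), (1.0, 1.0)]],
    "X": [[(0.0, 1.0), (1.0, 0.0)], [(0.0, 0.0), (1.0, 1.0)]],
}

_LETTER_GAP = 0.35  # horizontal gap between letters, in letter widths


def glyph_pattern(text: str, n_points: int, extent: float) -> SpotSet:
    """``n_points`` planar spots sampled along the strokes of block letters.

    Letters are laid out side by side and the whole word is scaled so its
    width equals ``extent`` (centred on the optical axis, z = 0).  Points sit
    at equal arc-length steps along the concatenated strokes, starting at the
    beginning of the first stroke, so the sampling is deterministic.
    """
    if not text:
        raise ValueError("text must be non-empty")
    if n_points < 1:
        raise ValueError("need at least one point")
    if extent <= 0:
        raise ValueError("extent must be positive")
    unknown = sorted({ch for ch in text.upper() if ch not in GLYPH_STROKES})
    if unknown:
        raise ValueError(
            f"unsupported character(s) {unknown}; supported: {''.join(sorted(GLYPH_STROKES))}"
        )
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []  # (start, end, length)
    for pos, ch in enumerate(text.upper()):
        offset = pos * (1.0 + _LETTER_GAP)
        for stroke in GLYPH_STROKES[ch]:
            pts = np.asarray(stroke, dtype=float) + np.array([offset, 0.0])
            for a, b in zip(pts[:-1], pts[1:]):
                length = float(np.hypot(*(b - a)))
                if length > 0:
                    segments.append((a, b, length))
    total = sum(s[2] for s in segments)
    # Arc-length positions k * L / n, k = 0..n-1 (first point on the first stroke).
    targets = np.arange(n_points) * total / n_points
    pts_out = np.empty((n_points, 2))
    cum = 0.0
    seg_iter = iter(segments)
    a, b, length = next(seg_iter)
    for k, t in enumerate(targets):
        while t > cum + length + 1e-12:
            cum += length
            a, b, length = next(seg_iter)
        frac = (t - cum) / length
        pts_out[k] = a + frac * (b - a)
    # Centre and scale: word width -> extent, aspect preserved.
    width = len(text) * 1.0 + (len(text) - 1) * _LETTER_GAP
    centre = np.array([width / 2.0, 0.5])
    scaled = (pts_out - centre) * (extent / width)
    return SpotSet(np.column_stack([scaled, np.zeros(n_points)]))
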