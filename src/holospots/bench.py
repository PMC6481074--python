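"""Benchmark protocol: compression sweeps and convergence traces.

The standard protocol runs each algorithm several times with different
random initializations (replicate r uses ``base_seed + r``) and reports the
mean and standard deviation of efficiency and uniformity, per compression
level, together with the instrumented operation count.  Sweeps cover
compression factors down to 1/256 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .algorithms import AlgoParams, Synthesizer
from .metrics import ConvergenceTrace, evaluate
from .optics import PupilGrid, SpotSet, addressable_field
from .patterns import glyph_pattern, grid_pattern, random_spot_cloud

__all__ = [
    "SweepResult",
    "DEFAULT_C_LEVELS",
    "compression_sweep",
    "convergence_curves",
    "replicate_stats",
    "benchmark_cloud",
    "benchmark_grid",
    "benchmark_glyph",
]

DEFAULT_C_LEVELS = (1.0, 1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32, 1 / 64, 1 / 128, 1 / 256)

# Standard benchmark pattern placement, as fractions of the addressable field
# (lateral half-extent x_max and half-Nyquist defocus z_max of the grid).
CLOUD_LATERAL_FRAC = 0.6
CLOUD_AXIAL_FRAC = 0.5
GRID_SPACING_FRAC = 0.12
GLYPH_EXTENT_FRAC = 1.4  # total word width relative to x_max (~70% of the field)


def benchmark_cloud(grid: PupilGrid, n: int = 100, seed: int = 7) -> SpotSet:
    """The standard random 3D benchmark cloud, scaled to the grid's field."""
    x_max, _, z_max = addressable_field(grid)
    return random_spot_cloud(n, CLOUD_LATERAL_FRAC * x_max, CLOUD_AXIAL_FRAC * z_max, seed)


def benchmark_grid(grid: PupilGrid, side: int = 10) -> SpotSet:
    """The regular in-plane spot lattice (uniformity worst case), default 10x10."""
    x_max, _, _ = addressable_field(grid)
    return grid_pattern(side, side, GRID_SPACING_FRAC * x_max)


def benchmark_glyph(grid: PupilGrid, text: str = "TUD", n_points: int = 25) -> SpotSet:
    """Planar letter-shaped pattern spanning most of the accessible field."""
    x_max, _, _ = addressable_field(grid)
    return glyph_pattern(text, n_points, GLYPH_EXTENT_FRAC * x_max)


@dataclass
class SweepResult:
    """Per-compression-level replicate statistics.

    ``table`` columns: compression, inv_compression, efficiency_mean,
    efficiency_sd, uniformity_mean, uniformity_sd, op_count, n_replicates.
    """

    table: pd.DataFrame
    variant: str
    iterations: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def replicate_stats(
    grid: PupilGrid,
    spots: SpotSet,
    params: AlgoParams,
    n_replicates: int,
    base_seed: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Efficiencies and uniformities over ``n_replicates`` seeded runs.

    Replicate r runs with seed ``base_seed + r``.  Returns (e, u, op_count);
    the operation count is identical across replicates by construction.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    synth = Synthesizer(grid, spots)
    es = np.empty(n_replicates)
    us = np.empty(n_replicates)
    ops = 0
    for r in range(n_replicates):
        p = AlgoParams(
            variant=params.variant,
            iterations=params.iterations,
            compression=params.compression,
            seed=base_seed + r,
            resample_subset=params.resample_subset,
        )
        result = synth.run(p)
        report = evaluate(result.hologram, spots)
        es[r], us[r] = report.efficiency, report.uniformity
        ops = result.op_count
    return es, us, ops


def compression_sweep(
    grid: PupilGrid,
    spots: SpotSet,
    variant: str,
    iterations: int,
    c_levels=DEFAULT_C_LEVELS,
    n_replicates: int = 10,
    base_seed: int = 0,
) -> SweepResult:
    """Replicate statistics of ``variant`` across compression levels.

    For the full-pupil variants (rs/gs/wgs) the compression level does not
    enter the computation; passing a single level just reproduces their
    plain replicate statistics.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for a standard deviation")
    levels = sorted(set(float(c) for c in c_levels), reverse=True)
    if any(not (0.0 < c <= 1.0) for c in levels):
        raise ValueError("compression levels must lie in (0, 1]")
    rows = []
    for c in levels:
        params = AlgoParams(variant=variant, iterations=iterations, compression=c)
        es, us, ops = replicate_stats(grid, spots, params, n_replicates, base_seed)
        rows.append(
            {
                "compression": c,
                "inv_compression": 1.0 / c,
                "efficiency_mean": es.mean(),
                "efficiency_sd": es.std(ddof=1),
                "uniformity_mean": us.mean(),
                "uniformity_sd": us.std(ddof=1),
                "op_count": ops,
                "n_replicates": n_replicates,
            }
        )
    return SweepResult(table=pd.DataFrame(rows), variant=variant, iterations=iterations)


def convergence_curves(
    grid: PupilGrid,
    spots: SpotSet,
    variant: str,
    iterations: int,
    compression: float = 1.0,
    seed: int = 0,
) -> ConvergenceTrace:
    """Per-iteration (efficiency, uniformity) of one seeded run.

    Entry k reports the full-pupil quality of the hologram after iteration k;
    for the compressed variants the intermediate entries evaluate the
    full-pupil superposition of the compressed state, so the single final
    weighted iteration of cs-wgs appears as a jump in the last entry.
    """
    params = AlgoParams(
        variant=variant,
        iterations=iterations,
        compression=compression,
        seed=seed,
        record_trace=True,
    )
    result = Synthesizer(grid, spots).run(params)
    assert result.trace is not None
    return result.trace
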