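"""Hologram quality metrics.

Two figures of merit summarize a multi-spot hologram, both computed from the
normalized per-spot intensities ``I_n``:

* efficiency ``e = sum_n I_n`` — the fraction of the delivered light landing
  on the target spots (under the mean-over-pixels amplitude normalization the
  total pupil throughput is 1, so a perfect single-spot hologram scores 1);
* uniformity ``u = 1 - (I_max - I_min) / (I_max + I_min)`` — 1 when every
  spot receives the same intensity, 0 when the dimmest spot is dark.

Spot intensity here is the single on-axis focal value of each target, not a
camera-window sum; for (near-)coincident spots the intensities are not
additive and ``e`` can exceed 1 — see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .optics import Hologram, SpotSet, all_spot_intensities

__all__ = ["efficiency", "uniformity", "QualityReport", "ConvergenceTrace", "evaluate"]


def _as_intensities(values) -> np.ndarray:
    i = np.asarray(values, dtype=float)
    if i.ndim != 1 or i.size < 1:
        raise ValueError("intensities must be a non-empty 1-D array")
    if not np.all(np.isfinite(i)) or np.any(i < 0):
        raise ValueError("intensities must be finite and non-negative")
    return i


def efficiency(intensities) -> float:
    """Fraction of total intensity directed at the target spots."""
    return float(_as_intensities(intensities).sum())


def uniformity(intensities) -> float:
    """``1 - (I_max - I_min)/(I_max + I_min)``; scale-invariant in the intensities."""
    i = _as_intensities(intensities)
    hi, lo = float(i.max()), float(i.min())
    if hi + lo == 0.0:
        raise ValueError("uniformity is undefined when all spot intensities are zero")
    return 1.0 - (hi - lo) / (hi + lo)


@dataclass(frozen=True)
class QualityReport:
    """Efficiency and uniformity of one hologram/pattern pair."""

    efficiency: float
    uniformity: float

    @classmethod
    def from_intensities(cls, intensities) -> "QualityReport":
        return cls(efficiency=efficiency(intensities), uniformity=uniformity(intensities))


@dataclass
class ConvergenceTrace:
    """Per-iteration quality record of an iterative run (entry k = after iteration k)."""

    reports: list[QualityReport]

    def __len__(self) -> int:
        return len(self.reports)

    def __getitem__(self, k: int) -> QualityReport:
        return self.reports[k]

    def __iter__(self) -> Iterable[QualityReport]:
        return iter(self.reports)

    @property
    def efficiencies(self) -> np.ndarray:
        return np.array([r.efficiency for r in self.reports])

    @property
    def uniformities(self) -> np.ndarray:
        return np.array([r.uniformity for r in self.reports])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.reports) + 1),
                "efficiency": self.efficiencies,
                "uniformity": self.uniformities,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def evaluate(holo: Hologram, spots: SpotSet) -> QualityReport:
    """Efficiency and uniformity of ``holo`` for the targets in ``spots``."""
    return QualityReport.from_intensities(all_spot_intensities(holo, spots))
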