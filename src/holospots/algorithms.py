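"""Multi-spot hologram synthesis: RS, GS, WGS and compressive-sensing variants.

All five algorithms share one synthesis primitive, the phase of the weighted
superposition of the single-spot fields,

    phi_cgh = arg sum_n omega_n * exp(i * (phi_n + theta_n)),

and differ only in how the per-spot phase offsets ``theta_n`` and amplitude
weights ``omega_n`` are chosen:

* **rs** — random superposition: random ``theta``, uniform weights, one pass.
* **gs** — Gerchberg–Saxton alternating projections: iteration 1 is the RS
  initialization; each further iteration re-estimates ``theta_n`` as the
  phase of the spot amplitude ``c_n = <exp(i*(phi_cgh - phi_n))>`` and
  superposes again.
* **wgs** — weighted GS: as GS, but each iteration also rescales the weights
  by the ratio of the mean spot amplitude modulus to each spot's own,
  ``omega_n <- omega_n * <|c|> / |c_n|``, equalizing the spot intensities.
* **cs-gs** — compressive-sensing GS: the first K-1 iterations run on a
  random subset of ``c*M`` pupil pixels (subset means replace full-pupil
  means); the K-th iteration takes the theta estimated from the subset state
  and performs a single full-pupil superposition.
* **cs-wgs** — K-1 compressed GS iterations, a full-pupil superposition of
  the compressed state, then exactly one full-pupil WGS iteration.

Every run is a pure function of (grid, spots, params): a single seeded
generator draws the theta initialization first and the pixel subset(s)
second.  ``op_count`` instruments the cost model by accumulating
``N * P`` for every synthesis pass over ``P`` pixels; theta/intensity
updates reuse the per-spot fields of the preceding pass and add nothing,
which reproduces the closed forms ``K*N*M`` (GS/WGS),
``(K-1)*N*c*M + N*M`` (CS-GS) and ``(K-1)*N*c*M + 2*N*M`` (CS-WGS) exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import ConvergenceTrace, QualityReport, efficiency, uniformity
from .optics import (
    MAX_FIELD_CACHE_BYTES,
    Hologram,
    PixelSubset,
    PupilGrid,
    SpotSet,
    spot_fields,
)

__all__ = [
    "AlgoParams",
    "RunResult",
    "Synthesizer",
    "random_offsets",
    "sample_pupil_subset",
    "superpose",
    "wgs_weight_update",
    "rs",
    "gs",
    "wgs",
    "cs_gs",
    "cs_wgs",
    "compute_hologram",
    "VARIANTS",
]

VARIANTS = ("rs", "gs", "wgs", "cs-gs", "cs-wgs")

# Guard against the weight update diverging on a near-dark spot.
WGS_INTENSITY_EPS = 1e-12
WGS_MAX_FACTOR = 10.0


@dataclass(frozen=True)
class AlgoParams:
    """Parameters of one synthesis run.

    ``compression`` is the fraction c of pupil pixels visited during the
    compressed iterations; it is meaningful for the cs-* variants only and
    must satisfy N/M < c for the compressive-sensing regime to apply (a
    warning is emitted below that).  ``resample_subset`` redraws the pixel
    subset before every compressed superposition instead of holding one
    subset for the whole run.
    """

    variant: str
    iterations: int = 50
    compression: float = 1.0
    seed: int = 0
    resample_subset: bool = False
    record_trace: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.variant == "cs-wgs" and self.iterations < 2:
            raise ValueError("cs-wgs needs at least 2 iterations (K-1 compressed + 1 weighted)")
        if not (0.0 < self.compression <= 1.0):
            raise ValueError(f"compression must lie in (0, 1], got {self.compression}")


@dataclass
class RunResult:
    """Output of one synthesis run."""

    hologram: Hologram
    theta: np.ndarray
    omega: np.ndarray
    op_count: int
    trace: ConvergenceTrace | None = None
    subset: PixelSubset | None = None
    params: AlgoParams | None = None


def random_offsets(n: int, seed: int | np.random.Generator) -> np.ndarray:
    """``n`` initial phase offsets drawn uniformly from [0, 2*pi)."""
    if n < 1:
        raise ValueError("need at least one offset")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(0.0, 2.0 * np.pi, n)


def sample_pupil_subset(
    grid: PupilGrid, c: float, seed: int | np.random.Generator
) -> PixelSubset:
    """Uniform random subset of ``max(1, round(c*M))`` distinct active pixels.

    ``c = 1`` returns all pixels in canonical order (so compressed code paths
    reduce bit-identically to their full-pupil counterparts).
    """
    if not (0.0 < c <= 1.0):
        raise ValueError(f"compression fraction must lie in (0, 1], got {c}")
    m = grid.m
    if c == 1.0:
        idx = np.arange(m)
    else:
        size = max(1, int(round(c * m)))
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.choice(m, size=size, replace=False)
    return PixelSubset(indices=idx, fraction=idx.size / m)


def wgs_weight_update(
    omega: np.ndarray,
    amplitudes: np.ndarray,
    targets: np.ndarray | None = None,
    eps: float = WGS_INTENSITY_EPS,
    max_factor: float = WGS_MAX_FACTOR,
) -> np.ndarray:
    """One weighted-GS weight update.

    Each weight is rescaled by the ratio of the mean spot-amplitude modulus
    to the spot's own modulus (the pupil overlap integral of the weighted
    iteration).  With per-spot ``targets`` (relative intensities) the moduli
    are first normalized by ``sqrt(target)`` so the update drives the
    intensities toward the requested proportions.  Spots whose intensity has
    fallen below ``eps`` have their ratio clamped to ``max_factor`` per
    update to keep the iteration from diverging.  The result is renormalized
    to sum to one (the superposition phase is scale-invariant).
    """
    a = np.abs(np.asarray(amplitudes, dtype=complex))
    if targets is not None:
        t = np.asarray(targets, dtype=float)
        a = a / np.sqrt(t / t.sum())
    intens = a * a
    ratio = a.mean() / np.maximum(a, 1e-300)
    ratio = np.where(intens < eps, np.minimum(ratio, max_factor), ratio)
    new = np.asarray(omega, dtype=float) * ratio
    return new / new.sum()


def superpose(
    spot_phases: Sequence[Hologram],
    theta: np.ndarray,
    omega: np.ndarray,
    subset: PixelSubset | None = None,
) -> Hologram:
    """Phase of the weighted superposition of single-spot fields.

    At each pixel (of ``subset`` if given, else of the full active pupil)
    the phase is ``arg sum_n omega_n * exp(i*(phi_n + theta_n))``.  Pixels
    outside the subset (and outside the aperture) are set to zero.  Where
    the superposed field cancels exactly, ``arg 0`` is taken as 0.
    """
    if len(spot_phases) == 0:
        raise ValueError("need at least one spot phase")
    grid = spot_phases[0].grid
    theta = np.asarray(theta, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if theta.shape != (len(spot_phases),) or omega.shape != (len(spot_phases),):
        raise ValueError("theta and omega must have one entry per spot")
    if np.any(omega < 0) or not np.any(omega > 0):
        raise ValueError("degenerate superposition: weights must be non-negative with at least one positive")
    rows = [h.flat() for h in spot_phases]
    if subset is not None:
        rows = [r[subset.indices] for r in rows]
    field_sum = np.zeros(rows[0].shape, dtype=complex)
    for w, th, r in zip(omega, theta, rows):
        field_sum += w * np.exp(1j * (r + th))
    phase = np.zeros(grid.n_pixels)
    sel = grid.active if subset is None else grid.active[subset.indices]
    phase[sel] = np.angle(field_sum)
    return Hologram(grid=grid, phase=phase.reshape(grid.shape))


class Synthesizer:
    """Runs the synthesis algorithms for one (grid, spots) pair.

    The per-spot unit fields ``exp(i*phi_n)`` over the active pixels are
    cached once (when their size fits ``max_cache_bytes``) so that every
    superposition and amplitude update is a single mat-vec; above the cap a
    streaming per-spot loop is used instead and nothing of size N×M is held.
    Reusable across seeds, which is what the benchmark replicates exploit.
    """

    def __init__(
        self,
        grid: PupilGrid,
        spots: SpotSet,
        max_cache_bytes: int = MAX_FIELD_CACHE_BYTES,
    ):
        self.grid = grid
        self.spots = spots
        self.n = len(spots)
        self.m = grid.m
        self._cache_ok = self.n * self.m * 16 <= max_cache_bytes
        self._full: np.ndarray | None = None
        w = spots.weights()
        omega0 = np.sqrt(w)
        self._omega0 = omega0 / omega0.sum()
        self._targets = w

    # -- field access -------------------------------------------------------

    def _full_fields(self) -> np.ndarray | None:
        if not self._cache_ok:
            return None
        if self._full is None:
            self._full = spot_fields(self.grid, self.spots)
        return self._full

    def _fields(self, idx: np.ndarray | None) -> np.ndarray | None:
        if idx is None:
            return self._full_fields()
        full = self._full_fields()
        if full is not None:
            # Advanced indexing along axis 1 yields an F-ordered copy; force C
            # order so BLAS takes the same path as the full-pupil mat-vecs and
            # c = 1 reduces bit-identically.
            return np.ascontiguousarray(full[:, idx])
        if self.n * idx.size * 16 <= MAX_FIELD_CACHE_BYTES:
            return spot_fields(self.grid, self.spots, idx)
        return None

    # -- primitives ---------------------------------------------------------

    def _superpose(self, theta, omega, idx, fields, counter) -> np.ndarray:
        """Flat phases of the weighted superposition over the selected pixels."""
        coeff = omega * np.exp(1j * theta)
        if fields is not None:
            total = coeff @ fields
        else:
            from .optics import _spot_phase_flat

            p = self.m if idx is None else idx.size
            total = np.zeros(p, dtype=complex)
            for n, row in enumerate(self.spots.coords):
                total += coeff[n] * np.exp(1j * _spot_phase_flat(self.grid, row, idx))
        counter[0] += self.n * (self.m if idx is None else int(idx.size))
        return np.angle(total)

    def _amplitudes(self, phases, idx, fields) -> np.ndarray:
        """Spot amplitudes ``c_n`` of a hologram given by flat ``phases`` over pixels ``idx``."""
        x = np.exp(1j * phases)
        if fields is not None:
            return (fields.conj() @ x) / x.size
        from .optics import _spot_phase_flat

        c = np.empty(self.n, dtype=complex)
        for n, row in enumerate(self.spots.coords):
            c[n] = (x * np.exp(-1j * _spot_phase_flat(self.grid, row, idx))).mean()
        return c

    def _to_hologram(self, flat_phases: np.ndarray) -> Hologram:
        phase = np.zeros(self.grid.n_pixels)
        phase[self.grid.active] = flat_phases
        return Hologram(grid=self.grid, phase=phase.reshape(self.grid.shape))

    def _report(self, c: np.ndarray) -> QualityReport:
        i = np.abs(c) ** 2
        return QualityReport(efficiency=efficiency(i), uniformity=uniformity(i))

    # -- the algorithms -----------------------------------------------------

    def run(self, params: AlgoParams) -> RunResult:
        if params.variant == "rs":
            return self._run_full(params, weighted=False, k_override=1)
        if params.variant in ("gs", "wgs"):
            return self._run_full(params, weighted=params.variant == "wgs")
        return self._run_cs(params, weighted=params.variant == "cs-wgs")

    def _run_full(self, params: AlgoParams, weighted: bool, k_override: int | None = None) -> RunResult:
        k_total = k_override if k_override is not None else params.iterations
        rng = np.random.default_rng(params.seed)
        theta = random_offsets(self.n, rng)
        omega = self._omega0
        counter = [0]
        fields = self._full_fields()
        trace: list[QualityReport] = []
        holo = self._superpose(theta, omega, None, fields, counter)
        for _ in range(2, k_total + 1):
            c = self._amplitudes(holo, None, fields)
            if params.record_trace:
                trace.append(self._report(c))
            theta = np.angle(c)
            if weighted:
                omega = wgs_weight_update(omega, c, targets=self._targets)
            holo = self._superpose(theta, omega, None, fields, counter)
        if params.record_trace:
            trace.append(self._report(self._amplitudes(holo, None, fields)))
        return RunResult(
            hologram=self._to_hologram(holo),
            theta=theta,
            omega=omega,
            op_count=counter[0],
            trace=ConvergenceTrace(trace) if params.record_trace else None,
            params=params,
        )

    def _run_cs(self, params: AlgoParams, weighted: bool) -> RunResult:
        k_total = params.iterations
        if params.compression * self.m < self.n:
            warnings.warn(
                f"compression {params.compression} puts c*M = {params.compression * self.m:.1f} "
                f"below N = {self.n}: outside the compressive-sensing regime N/M < c",
                stacklevel=3,
            )
        rng = np.random.default_rng(params.seed)
        theta = random_offsets(self.n, rng)
        omega = self._omega0
        counter = [0]
        fields_full = self._full_fields()
        subset = sample_pupil_subset(self.grid, params.compression, rng)
        idx = subset.indices
        fields_sub = self._fields(idx)
        trace: list[QualityReport] = []

        def trace_full_state(th, om) -> None:
            """Full-pupil quality of the compressed state (diagnostic, uncounted)."""
            coeff = om * np.exp(1j * th)
            if fields_full is not None:
                proxy = np.angle(coeff @ fields_full)
            else:
                proxy = self._superpose(th, om, None, fields_full, [0])
            trace.append(self._report(self._amplitudes(proxy, None, fields_full)))

        n_compressed = k_total - 1
        holo_sub = None
        if n_compressed >= 1:
            holo_sub = self._superpose(theta, omega, idx, fields_sub, counter)
            if params.record_trace:
                trace_full_state(theta, omega)
            for _ in range(2, n_compressed + 1):
                c = self._amplitudes(holo_sub, idx, fields_sub)
                theta = np.angle(c)
                if params.resample_subset:
                    subset = sample_pupil_subset(self.grid, params.compression, rng)
                    idx = subset.indices
                    fields_sub = self._fields(idx)
                holo_sub = self._superpose(theta, omega, idx, fields_sub, counter)
                if params.record_trace:
                    trace_full_state(theta, omega)

        if not weighted:
            # cs-gs: theta from the last compressed state, one full superposition.
            if holo_sub is not None:
                c = self._amplitudes(holo_sub, idx, fields_sub)
                theta = np.angle(c)
            holo = self._superpose(theta, omega, None, fields_full, counter)
            if params.record_trace:
                trace.append(self._report(self._amplitudes(holo, None, fields_full)))
        else:
            # cs-wgs: full superposition of the compressed state, then exactly
            # one full-pupil weighted iteration (theta and omega both update).
            holo = self._superpose(theta, omega, None, fields_full, counter)
            c = self._amplitudes(holo, None, fields_full)
            theta = np.angle(c)
            omega = wgs_weight_update(omega, c, targets=self._targets)
            holo = self._superpose(theta, omega, None, fields_full, counter)
            if params.record_trace:
                trace.append(self._report(self._amplitudes(holo, None, fields_full)))
        return RunResult(
            hologram=self._to_hologram(holo),
            theta=theta,
            omega=omega,
            op_count=counter[0],
            trace=ConvergenceTrace(trace) if params.record_trace else None,
            subset=subset,
            params=params,
        )


# -- module-level convenience wrappers --------------------------------------


def rs(grid: PupilGrid, spots: SpotSet, seed: int = 0, record_trace: bool = False) -> RunResult:
    """Random superposition: random offsets, uniform weights, one full pass."""
    params = AlgoParams(variant="rs", iterations=1, seed=seed, record_trace=record_trace)
    return Synthesizer(grid, spots).run(params)


def gs(grid: PupilGrid, spots: SpotSet, params: AlgoParams) -> RunResult:
    """Gerchberg–Saxton alternating projections on the full pupil."""
    return Synthesizer(grid, spots).run(_with_variant(params, "gs"))


def wgs(grid: PupilGrid, spots: SpotSet, params: AlgoParams) -> RunResult:
    """Weighted GS: per-spot amplitude weights equalize the spot intensities."""
    return Synthesizer(grid, spots).run(_with_variant(params, "wgs"))


def cs_gs(grid: PupilGrid, spots: SpotSet, params: AlgoParams) -> RunResult:
    """Compressive-sensing GS: K-1 subset iterations, one full superposition."""
    return Synthesizer(grid, spots).run(_with_variant(params, "cs-gs"))


def cs_wgs(grid: PupilGrid, spots: SpotSet, params: AlgoParams) -> RunResult:
    """Compressive-sensing WGS: CS iterations plus one final weighted full iteration."""
    return Synthesizer(grid, spots).run(_with_variant(params, "cs-wgs"))


def compute_hologram(grid: PupilGrid, spots: SpotSet, params: AlgoParams) -> RunResult:
    """Dispatch on ``params.variant``."""
    return Synthesizer(grid, spots).run(params)


def _with_variant(params: AlgoParams, variant: str) -> AlgoParams:
    if params.variant != variant:
        raise ValueError(f"params.variant is {params.variant!r}; expected {variant!r}")
    return params
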