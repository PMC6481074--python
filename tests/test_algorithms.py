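"""The five synthesis algorithms: reductions, determinism, cost model, quality ordering."""

import numpy as np
import pytest

from holospots import (
    AlgoParams,
    OpticalConfig,
    SpotSet,
    Synthesizer,
    compute_hologram,
    cs_gs,
    cs_wgs,
    evaluate,
    gs,
    make_pupil_grid,
    random_offsets,
    random_spot_cloud,
    rs,
    sample_pupil_subset,
    spot_phase,
    superpose,
    wgs,
    wgs_weight_update,
)
from holospots.optics import spot_fields

from conftest import oracle_superpose


@pytest.fixture(scope="module")
def spots10(grid64):
    return random_spot_cloud(10, 400e-6, 5e-3, seed=1)


class TestRandomOffsets:
    def test_deterministic_for_fixed_seed(self):
        assert np.array_equal(random_offsets(50, 123), random_offsets(50, 123))

    def test_values_in_range(self):
        th = random_offsets(1, 0)
        assert th.shape == (1,) and 0.0 <= th[0] < 2 * np.pi

    def test_mean_consistent_with_uniform_law(self):
        # mean of n uniform[0, 2pi) draws: sd of the mean = (2pi/sqrt(12))/sqrt(n)
        n = 10_000
        th = random_offsets(n, 42)
        sd_mean = 2 * np.pi / np.sqrt(12) / np.sqrt(n)
        assert abs(th.mean() - np.pi) < 5 * sd_mean


class TestPupilSubset:
    def test_full_compression_returns_canonical_order(self, grid64):
        sub = sample_pupil_subset(grid64, 1.0, 0)
        assert np.array_equal(sub.indices, np.arange(grid64.m))

    def test_paper_scale_subset_size(self):
        # c = 1/32 on the 1920 x 1152 panel: exactly 69120 pixels
        grid = make_pupil_grid(OpticalConfig.from_units(800, 18, 9.2, 1920, 1152))
        sub = sample_pupil_subset(grid, 1 / 32, 3)
        assert len(sub) == 69_120
        assert len(np.unique(sub.indices)) == len(sub)

    def test_deterministic_for_fixed_seed(self, grid64):
        a = sample_pupil_subset(grid64, 0.1, 9)
        b = sample_pupil_subset(grid64, 0.1, 9)
        assert np.array_equal(a.indices, b.indices)

    @pytest.mark.parametrize("c", [0.0, -0.5, 1.5])
    def test_invalid_fraction_rejected(self, grid64, c):
        with pytest.raises(ValueError):
            sample_pupil_subset(grid64, c, 0)


class TestSuperpose:
    def test_single_spot_reduces_to_shifted_phase(self, grid16):
        sp = spot_phase(grid16, SpotSet(np.array([[100e-6, 0, 0]]))[0])
        holo = superpose([sp], np.array([0.8]), np.array([0.3]))
        expected = np.angle(np.exp(1j * (sp.phase + 0.8)))
        assert holo.phase == pytest.approx(expected, abs=1e-12)

    def test_matches_scalar_loop_oracle(self):
        cfg = OpticalConfig.from_units(800, 18, 9.2, 8, 8)
        grid = make_pupil_grid(cfg)
        coords = np.array([[100e-6, -30e-6, 0], [-150e-6, 60e-6, 1e-3], [0, 200e-6, -2e-3]])
        spots = SpotSet(coords)
        theta = random_offsets(3, 5)
        omega = np.array([0.5, 0.3, 0.2])
        holo = superpose([spot_phase(grid, s) for s in spots], theta, omega)
        assert holo.phase == pytest.approx(oracle_superpose(cfg, coords, theta, omega), abs=1e-12)

    def test_zero_weights_rejected(self, grid16):
        sp = spot_phase(grid16, SpotSet(np.array([[0, 0, 0]]))[0])
        with pytest.raises(ValueError, match="degenerate"):
            superpose([sp, sp], np.zeros(2), np.zeros(2))

    def test_destructive_interference_stays_finite(self, grid16):
        # two identical spots in antiphase cancel (to rounding); the arg of the
        # vanishing field must still be a finite phase, exact zero giving arg 0
        sp = spot_phase(grid16, SpotSet(np.array([[100e-6, 0, 0]]))[0])
        holo = superpose([sp, sp], np.array([0.0, np.pi]), np.array([0.5, 0.5]))
        assert np.all(np.isfinite(holo.phase))


class TestReductions:
    def test_gs_single_iteration_is_rs(self, grid64, spots10):
        a = rs(grid64, spots10, seed=3)
        b = gs(grid64, spots10, AlgoParams(variant="gs", iterations=1, seed=3))
        assert np.array_equal(a.hologram.phase, b.hologram.phase)

    def test_cs_gs_full_compression_is_gs_bitwise(self, grid64, spots10):
        p = AlgoParams(variant="cs-gs", iterations=20, compression=1.0, seed=3)
        a = cs_gs(grid64, spots10, p)
        b = gs(grid64, spots10, AlgoParams(variant="gs", iterations=20, seed=3))
        assert np.array_equal(a.hologram.phase, b.hologram.phase)

    def test_cs_gs_single_iteration_is_rs(self, grid64, spots10):
        p = AlgoParams(variant="cs-gs", iterations=1, compression=0.25, seed=3)
        a = cs_gs(grid64, spots10, p)
        b = rs(grid64, spots10, seed=3)
        assert np.array_equal(a.hologram.phase, b.hologram.phase)

    def test_cs_wgs_full_compression_is_gs_plus_one_weighted_step(self, grid64, spots10):
        K = 12
        w = cs_wgs(grid64, spots10, AlgoParams(variant="cs-wgs", iterations=K, compression=1.0, seed=3))
        g = gs(grid64, spots10, AlgoParams(variant="gs", iterations=K - 1, seed=3))
        fields = spot_fields(grid64, spots10)
        c = (fields.conj() @ np.exp(1j * g.hologram.flat())) / grid64.m
        theta = np.angle(c)
        omega = wgs_weight_update(g.omega, c, targets=spots10.weights())
        manual = superpose([spot_phase(grid64, s) for s in spots10], theta, omega)
        assert w.hologram.phase == pytest.approx(manual.phase, abs=1e-12)


class TestDeterminismAndLimits:
    @pytest.mark.parametrize("variant", ["rs", "gs", "wgs", "cs-gs", "cs-wgs"])
    def test_pure_function_of_seed(self, grid64, spots10, variant):
        p = AlgoParams(variant=variant, iterations=5, compression=0.25, seed=17)
        a = compute_hologram(grid64, spots10, p)
        b = compute_hologram(grid64, spots10, p)
        assert np.array_equal(a.hologram.phase, b.hologram.phase)
        assert a.op_count == b.op_count

    @pytest.mark.parametrize("variant", ["rs", "gs", "wgs", "cs-gs", "cs-wgs"])
    def test_single_spot_is_perfect(self, grid64, variant):
        spots = SpotSet(np.array([[200e-6, -100e-6, 2e-3]]))
        p = AlgoParams(variant=variant, iterations=4, compression=0.5, seed=1)
        rep = evaluate(compute_hologram(grid64, spots, p).hologram, spots)
        assert rep.efficiency == pytest.approx(1.0, abs=1e-9)
        assert rep.uniformity == pytest.approx(1.0, abs=1e-9)

    def test_single_spot_gs_perfect_at_every_iteration(self, grid64):
        spots = SpotSet(np.array([[150e-6, 80e-6, 0.0]]))
        p = AlgoParams(variant="gs", iterations=5, seed=0, record_trace=True)
        trace = gs(grid64, spots, p).trace
        assert trace.efficiencies == pytest.approx(np.ones(5), abs=1e-9)

    def test_below_compressive_regime_warns(self, grid16):
        spots = random_spot_cloud(100, 300e-6, 0, seed=0)
        p = AlgoParams(variant="cs-gs", iterations=3, compression=0.1, seed=0)
        with pytest.warns(UserWarning, match="compressive-sensing regime"):
            cs_gs(grid16, spots, p)

    def test_resample_subset_changes_result(self, grid64, spots10):
        fixed = cs_gs(grid64, spots10, AlgoParams(variant="cs-gs", iterations=10, compression=0.1, seed=4))
        res = cs_gs(
            grid64,
            spots10,
            AlgoParams(variant="cs-gs", iterations=10, compression=0.1, seed=4, resample_subset=True),
        )
        assert not np.array_equal(fixed.hologram.phase, res.hologram.phase)
        assert res.op_count == fixed.op_count


class TestCostModel:
    @pytest.mark.parametrize(
        "n_spots,k,c",
        [(3, 5, 0.25), (7, 12, 1 / 8), (10, 20, 1 / 32)],
    )
    def test_op_counts_match_closed_forms(self, grid64, n_spots, k, c):
        spots = random_spot_cloud(n_spots, 400e-6, 3e-3, seed=n_spots)
        m = grid64.m
        s = max(1, round(c * m))
        assert rs(grid64, spots, seed=0).op_count == n_spots * m
        assert gs(grid64, spots, AlgoParams(variant="gs", iterations=k, seed=0)).op_count == k * n_spots * m
        assert (
            wgs(grid64, spots, AlgoParams(variant="wgs", iterations=k, seed=0)).op_count
            == k * n_spots * m
        )
        p = AlgoParams(variant="cs-gs", iterations=k, compression=c, seed=0)
        assert cs_gs(grid64, spots, p).op_count == (k - 1) * n_spots * s + n_spots * m
        p = AlgoParams(variant="cs-wgs", iterations=k, compression=c, seed=0)
        assert cs_wgs(grid64, spots, p).op_count == (k - 1) * n_spots * s + 2 * n_spots * m


class TestWeightUpdate:
    def test_equal_amplitudes_leave_weights_unchanged(self):
        omega = np.array([0.25, 0.25, 0.25, 0.25])
        c = np.full(4, 0.3 + 0.1j)
        assert wgs_weight_update(omega, c) == pytest.approx(omega, abs=1e-15)

    def test_dim_spot_gains_weight(self):
        omega = np.full(3, 1 / 3)
        c = np.array([0.5, 0.5, 0.25], dtype=complex)
        new = wgs_weight_update(omega, c)
        assert new[2] > new[0] == new[1]
        assert new.sum() == pytest.approx(1.0)

    def test_dark_spot_ratio_clamped(self):
        omega = np.full(2, 0.5)
        c = np.array([0.5, 1e-9], dtype=complex)  # intensity 1e-18 < guard
        new = wgs_weight_update(omega, c)
        # dark spot's ratio clamps to 10, bright spot's is mean/|c| = 0.5;
        # normalization preserves the ratio of ratios
        assert new[1] / new[0] == pytest.approx(10.0 / 0.5, rel=1e-6)
        assert np.isfinite(new).all()


class TestQualityOrdering:
    def test_gs_beats_rs_on_small_cloud(self, grid64, spots10):
        wins = 0
        for seed in range(10):
            e_rs = evaluate(rs(grid64, spots10, seed=seed).hologram, spots10).efficiency
            e_gs = evaluate(
                gs(grid64, spots10, AlgoParams(variant="gs", iterations=50, seed=seed)).hologram,
                spots10,
            ).efficiency
            wins += e_gs > e_rs
        assert wins >= 9

    def test_gs_efficiency_settles_within_a_few_tens_of_iterations(self):
        # the GS efficiency trace converges within a few tens of iterations:
        # late per-iteration changes are an order of magnitude below early ones
        grid = make_pupil_grid(OpticalConfig.from_units(800, 18, 9.2, 128, 128))
        spots = random_spot_cloud(50, 400e-6, 4e-3, seed=2)
        p = AlgoParams(variant="gs", iterations=50, seed=0, record_trace=True)
        e = gs(grid, spots, p).trace.efficiencies
        deltas = np.abs(np.diff(e))
        assert deltas[-10:].mean() < deltas[:5].mean() / 10
        assert np.all(deltas[-10:] < 1e-3)
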