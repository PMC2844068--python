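"""Descriptive trajectory metrics: frequencies, regression, growth, persistence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polguide.circular import ANGLE_COLUMNS, AngleSeries, extract_angles
from polguide.errors import FitError, ValidationError
from polguide.field import AttractantParams
from polguide.io import TrajectorySet
from polguide.metrics import (
    chi2_frequency_test,
    filter_pre_penetration,
    growth_rate_profile,
    persistence_length,
    radial_frequencies,
    turning_response,
)
from polguide.sim import MotilityParams, SimConfig, simulate
from polguide.synth import SynthConfig, generate_trajectories

from conftest import empty_ovules, make_ovules, make_trajectories


def angle_rows(theta_mp, theta_tip, distance=30.0, **overrides):
    """Minimal valid AngleSeries from parallel angle arrays."""
    n = len(theta_mp)
    base = {
        "tube_id": ["a"] * n,
        "t_min": 20.0 * (np.arange(n) + 1),
        "x_um": np.zeros(n),
        "y_um": np.zeros(n),
        "dir_x": np.ones(n),
        "dir_y": np.zeros(n),
        "l1_um": np.full(n, 50.0),
        "l2_um": np.full(n, 50.0),
        "rate_um_min": np.full(n, 2.5),
        "theta_tip_rad": np.asarray(theta_tip, float),
        "theta_mp_rad": np.asarray(theta_mp, float),
        "delta_theta_rad": np.asarray(theta_mp, float) - np.asarray(theta_tip, float),
        "distance_um": np.full(n, float(distance)),
        "nearest_ovule": ["ov0"] * n,
        "approaching": np.cos(theta_mp) >= 0,
        "pre_penetration": [True] * n,
    }
    base.update(overrides)
    return AngleSeries(pd.DataFrame(base, columns=ANGLE_COLUMNS))


class TestPrePenetrationFilter:
    def ovules(self, pen_time):
        return make_ovules([("ov0", 100.0, 0.0, True, 0.0, pen_time)])

    def test_samples_before_any_penetration_unchanged(self):
        angles = angle_rows([0.1, 0.2], [0.0, 0.1])
        out = filter_pre_penetration(angles, self.ovules(1000.0))
        assert len(out) == len(angles)

    def test_sample_at_penetration_time_excluded(self):
        angles = angle_rows([0.1, 0.2], [0.0, 0.1])  # t = 20, 40
        angles.data["pre_penetration"] = angles.data["t_min"] < 40.0
        out = filter_pre_penetration(angles, self.ovules(40.0))
        assert list(out.data["t_min"]) == [20.0]

    def test_never_penetrated_functional_ovule_excluded(self):
        angles = angle_rows([0.1], [0.0], pre_penetration=[False])
        out = filter_pre_penetration(angles, self.ovules(np.nan))
        assert len(out) == 0

    def test_heat_treated_dataset_passes_through(self):
        angles = angle_rows([0.1], [0.0], pre_penetration=[False])
        heat = make_ovules([("ov0", 100.0, 0.0, False, 120.0, np.nan)])
        assert len(filter_pre_penetration(angles, heat)) == 1


class TestRadialFrequencies:
    def two_step_tube(self, d0, d1):
        # tube moving radially along +x toward/away from an ovule at origin
        return make_trajectories([("a", 0.0, d0, 0.0), ("a", 20.0, d1, 0.0)])

    def origin_ovule(self):
        return make_ovules([("ov0", 0.0, 0.0, True, 0.0, np.nan)])

    def test_inward_move_counts_closer(self):
        freq = radial_frequencies(self.two_step_tube(120.0, 60.0), self.origin_ovule())
        row = freq.data.iloc[2]  # [100, 150)
        assert (row["n_total"], row["n_closer"], row["n_farther"]) == (1, 1, 0)

    def test_exhaustive_three_tube_toy(self):
        rows = []
        for tid, d1 in [("a", 160.0), ("b", 60.0), ("c", 120.0)]:
            rows += [(tid, 0.0, 120.0, 0.0), (tid, 20.0, d1, 0.0)]
        freq = radial_frequencies(make_trajectories(rows), self.origin_ovule())
        row = freq.data.iloc[2]
        assert row["n_total"] == 3
        assert row["f_closer"] == pytest.approx(1 / 3)
        assert row["f_farther"] == pytest.approx(1 / 3)
        assert row["se_closer"] == pytest.approx(np.sqrt((1 / 3) * (2 / 3) / 3))

    def test_counts_conserved_with_same_bin_reconstructible(self):
        cfg = SynthConfig(n_tubes=40, seed=3, duration=200.0)
        traj, ovules, _ = generate_trajectories(cfg)
        freq = radial_frequencies(traj, ovules)
        assert (freq.n_same >= 0).all()
        assert (
            freq.data["n_closer"] + freq.data["n_farther"] + freq.n_same
            == freq.data["n_total"]
        ).all()

    def test_time_reversal_swaps_closer_and_farther(self):
        # undirected growth has no arrow of time: reversing every
        # trajectory exchanges the total closer and farther counts exactly
        rng = np.random.default_rng(10)
        n = 200
        radii = rng.uniform(20.0, 240.0, n)
        angs = rng.uniform(0, 2 * np.pi, n)
        pos = np.column_stack([radii * np.cos(angs), radii * np.sin(angs)])
        heads = rng.uniform(0, 2 * np.pi, n)
        dirs = np.column_stack([np.cos(heads), np.sin(heads)])
        ovules = self.origin_ovule()
        cfg = SimConfig(
            ovules=ovules, initial_positions=pos, initial_directions=dirs,
            turning=False, slowing=False, seed=1, duration=200.0,
            capture_radius=1e-6, escape_radius=1e6, record_interval=20.0,
        )
        res = simulate(cfg, AttractantParams(), MotilityParams())
        traj = TrajectorySet(res.paths, position_noise_sd=0.0)
        rev = res.paths.copy()
        rev["t_min"] = rev.groupby("tube_id")["t_min"].transform(
            lambda t: t.max() - t[::-1].to_numpy()
        )
        rev[["x_um", "y_um"]] = (
            res.paths.groupby("tube_id")[["x_um", "y_um"]]
            .transform(lambda c: c[::-1].to_numpy())
        )
        traj_rev = TrajectorySet(rev, position_noise_sd=0.0)
        # max_dist must cover every sample or boundary pairs are counted
        # in one direction only
        fwd = radial_frequencies(traj, ovules, max_dist=2000.0)
        bwd = radial_frequencies(traj_rev, ovules, max_dist=2000.0)
        assert fwd.data["n_closer"].sum() == bwd.data["n_farther"].sum()
        assert fwd.data["n_farther"].sum() == bwd.data["n_closer"].sum()


class TestChi2FrequencyTest:
    def table(self, n_yes, n_total):
        df = pd.DataFrame(
            {
                "bin_lo_um": [0.0], "bin_hi_um": [50.0],
                "n_total": [n_total], "n_closer": [n_yes], "n_farther": [0],
                "f_closer": [n_yes / n_total], "f_farther": [0.0],
                "se_closer": [0.0], "se_farther": [0.0],
            }
        )
        from polguide.metrics import FreqTable

        return FreqTable(df)

    def test_identical_tables_give_p_one(self):
        p = chi2_frequency_test([self.table(30, 100), self.table(30, 100)], 0, "closer")
        assert p == pytest.approx(1.0)

    def test_two_by_two_matches_hand_computation(self):
        # 30/100 vs 10/100; pooled p = 0.2; chi2 = sum (O-E)^2/E
        # = 100/20 + 100/80 + 100/20 + 100/80 = 12.5 (no continuity correction)
        p = chi2_frequency_test([self.table(30, 100), self.table(10, 100)], 0, "closer")
        assert p == pytest.approx(stats.chi2.sf(12.5, df=1), rel=1e-9)

    def test_order_invariance(self):
        tables = [self.table(30, 100), self.table(10, 100), self.table(22, 80)]
        assert chi2_frequency_test(tables, 0, "closer") == pytest.approx(
            chi2_frequency_test(tables[::-1], 0, "closer")
        )


class TestTurningResponse:
    def test_noiseless_line_recovered_exactly(self):
        rng = np.random.default_rng(0)
        theta_mp = rng.uniform(-np.pi, np.pi, 50)
        fit = turning_response(angle_rows(theta_mp, 0.3 * np.sin(theta_mp)), 0, 50)
        assert fit.A == pytest.approx(0.3, abs=1e-12)
        assert fit.epsilon == pytest.approx(0.0, abs=1e-12)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_null_calibration(self):
        # theta_tip independent of theta_mp: slope within 2 SE in >= 90% of seeds
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            theta_mp = rng.uniform(-np.pi, np.pi, 500)
            fit = turning_response(angle_rows(theta_mp, rng.normal(0, 0.3, 500)), 0, 50)
            hits += abs(fit.A) < 2 * fit.se_A
        assert hits >= 27

    def test_parameter_recovery_with_noise(self):
        rng = np.random.default_rng(5)
        theta_mp = rng.uniform(-np.pi, np.pi, 1000)
        theta_tip = 0.3 * np.sin(theta_mp) + rng.normal(0, 0.2, 1000)
        fit = turning_response(angle_rows(theta_mp, theta_tip), 0, 50)
        assert abs(fit.A - 0.3) < 3 * fit.se_A
        assert fit.residual_sd == pytest.approx(0.2, rel=0.1)

    def test_zero_variance_band_raises(self):
        with pytest.raises(FitError):
            turning_response(angle_rows(np.zeros(10), np.zeros(10)), 0, 50)

    def test_response_decreases_with_distance_in_full_model(self):
        # the fitted-model consistency loop: simulated tubes respond more
        # strongly near the micropyle than at 150-200 µm
        cfg = SynthConfig(n_tubes=500, seed=21)
        traj, ovules, _ = generate_trajectories(cfg)
        angles = extract_angles(traj, ovules)
        near = turning_response(angles, 0.0, 50.0)
        far = turning_response(angles, 150.0, 200.0)
        assert near.A >= far.A
        assert far.A > 0


class TestGrowthProfile:
    def test_constant_speed_tube_gives_flat_profile(self, straight_tube):
        ovule = make_ovules([("ov0", 250.0, 0.0, True, 0.0, np.nan)])
        prof = growth_rate_profile(straight_tube, ovule)
        populated = prof.data.dropna(subset=["mean_rate_um_min"])
        assert len(populated) > 0
        np.testing.assert_allclose(populated["mean_rate_um_min"], 2.0)

    def test_single_step_rate_arithmetic(self):
        traj = make_trajectories([("a", 0.0, 100.0, 0.0), ("a", 20.0, 60.0, 0.0)])
        ovules = make_ovules([("ov0", 0.0, 0.0, True, 0.0, np.nan)])
        prof = growth_rate_profile(traj, ovules)
        row = prof.data[prof.data["r_um"] == 100.0].iloc[0]
        assert row["mean_rate_um_min"] == pytest.approx(2.0)
        assert row["n"] == 1

    def test_empty_windows_reported_with_zero_n(self, straight_tube):
        far = make_ovules([("ov0", 0.0, 5000.0, True, 0.0, np.nan)])
        prof = growth_rate_profile(straight_tube, far)
        assert (prof.data["n"] == 0).all()
        assert prof.data["mean_rate_um_min"].isna().all()

    def test_slowing_model_profile_increases_with_distance(self):
        # tubes slowing near micropyles: mean rate should not decrease with
        # distance over the close range
        cfg = SynthConfig(n_tubes=300, seed=17, position_noise_sd=0.0)
        traj, ovules, _ = generate_trajectories(cfg)
        prof = growth_rate_profile(traj, ovules, grid_lo=10.0, grid_hi=50.0)
        rates = prof.data.dropna(subset=["mean_rate_um_min"])
        rates = rates[rates["n"] >= 20]["mean_rate_um_min"].to_numpy()
        assert len(rates) >= 3
        # allow small non-monotonicity from sampling noise
        assert rates[-1] > rates[0]
        assert np.all(np.diff(rates) > -0.25)


class TestPersistenceLength:
    def test_straight_tubes_have_infinite_persistence(self):
        rows = []
        for tid in ["a", "b"]:
            rows += [(tid, 20.0 * i, 40.0 * i, 0.0) for i in range(10)]
        fit = persistence_length(make_trajectories(rows, noise_sd=0.0), max_lag=200.0)
        np.testing.assert_allclose(fit.curve["mean_cos"], 1.0, atol=1e-9)
        assert fit.L == np.inf

    def test_recovery_from_random_tubes(self):
        # scaled-down version of the full recovery experiment (see the
        # acceptance suite for the 58-tube protocol)
        cfg = SimConfig(
            ovules=empty_ovules(),
            initial_positions=np.zeros((20, 2)),
            initial_directions=np.tile([1.0, 0.0], (20, 1)),
            turning=False, slowing=False, seed=8, duration=200.0,
            escape_radius=1e9, record_interval=20.0,
        )
        res = simulate(cfg, AttractantParams(), MotilityParams(L=1000.0))
        fit = persistence_length(TrajectorySet(res.paths, position_noise_sd=0.0))
        assert fit.L == pytest.approx(1000.0, rel=0.25)

    def test_monte_carlo_ci_contains_estimate(self):
        cfg = SimConfig(
            ovules=empty_ovules(),
            initial_positions=np.zeros((10, 2)),
            initial_directions=np.tile([1.0, 0.0], (10, 1)),
            turning=False, slowing=False, seed=9, duration=200.0,
            escape_radius=1e9, record_interval=20.0,
        )
        res = simulate(cfg, AttractantParams(), MotilityParams(L=1000.0))
        traj = TrajectorySet(res.paths, position_noise_sd=2.0)
        fit = persistence_length(traj, n_mc=20, seed=4)
        assert fit.ci_L is not None and fit.ci_L[0] < fit.ci_L[1]

    def test_too_short_tubes_raise(self):
        with pytest.raises(FitError):
            persistence_length(
                make_trajectories([("a", 0.0, 0.0, 0.0), ("a", 20.0, 1.0, 0.0)]),
                resample_step=5.0,
            )
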