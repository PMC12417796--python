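"""Forward simulation, synthetic data generation, and the MAPE metric."""

import numpy as np
import pytest

import kinetransfer as kt
from kinetransfer.simulate import (Experiment, dataset_from_csv,
                                   dataset_to_csv, default_sample_times,
                                   generate_dataset, mape, simulate)


class TestSimulate:
    def test_washout_initial_state_stays_fixed(self, target):
        traj = simulate(target, [0.0, 5.0, 0.0], default_sample_times())
        assert np.allclose(traj[:, 0], 0.0, atol=1e-10)   # X stays 0
        assert np.allclose(traj[:, 2], 0.0, atol=1e-10)   # P stays 0
        assert np.allclose(traj[:, 1], 5.0, atol=1e-6)    # S constant

    def test_source_substrate_never_increases(self, source):
        traj = simulate(source, [0.1, 10.0, 0.0], np.arange(0, 145, 2.0))
        assert np.all(np.diff(traj[:, 1]) <= 1e-9)

    def test_target_biomass_decays_with_equal_growth_and_decay_rates(self, target):
        # Contois growth is strictly below mu_m, and mu_d equals mu_m, so
        # net biomass growth is negative from the start
        traj = simulate(target, [0.3, 8.0, 0.0], np.arange(0, 145, 2.0))
        assert np.all(np.diff(traj[:, 0]) < 0)
        # decay continues after substrate depletion: dX/dt < 0 at S = 0
        assert target.evaluate([0.5, 0.0, 0.2])[0] < 0

    def test_against_fine_grid_euler_oracle(self, target):
        y0 = np.array([0.2, 10.0, 0.0])
        t_grid = np.array([0.0, 14.0, 28.0, 42.0])
        # independent brute-force integrator: explicit Euler, 0.001 h steps
        y = y0.copy()
        euler = [y0.copy()]
        h = 0.001
        for k in range(int(42.0 / h)):
            y = y + h * target.evaluate(y)
            if abs((k + 1) * h % 14.0) < h / 2:
                euler.append(y.copy())
        euler = np.array(euler)
        traj = simulate(target, y0, t_grid)
        assert np.allclose(traj, euler, atol=1e-4)

    def test_fixed_step_mode_agrees_with_reference(self, target):
        y0 = [0.3, 6.0, 0.0]
        times = default_sample_times()
        ref = simulate(target, y0, times)
        fixed = simulate(target, y0, times, mode="fixed", fixed_steps=576)
        assert np.allclose(fixed, ref, rtol=1e-4, atol=1e-6)

    def test_invalid_inputs_rejected(self, target):
        with pytest.raises(ValueError):
            simulate(target, [-0.1, 5.0, 0.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            simulate(target, [0.1, 5.0, 0.0], [0.0, 2.0, 1.0])


class TestGenerateDataset:
    def test_sampling_grid_has_eleven_points(self):
        times = default_sample_times(144.0, 14.0)
        assert len(times) == 11
        assert times[0] == 0.0 and times[-1] == 140.0
        assert np.all(np.diff(times) == 14.0)

    def test_zero_noise_equals_simulation(self, target):
        ds = kt.generate_dataset(target, 2, noise_sd=0.0, seed=3)
        for e in ds.experiments:
            truth = simulate(target, e.y0, e.sample_times)
            assert np.allclose(e.observations, truth)

    def test_noise_level_monte_carlo(self, target):
        # 10 000 replicate observations of one true value: the empirical
        # relative s.d. must sit within 3 Monte-Carlo standard errors of 5%
        rng = np.random.default_rng(5)
        true_value = 4.2
        obs = true_value * (1 + rng.normal(0, 0.05, size=10_000))
        rel_sd = obs.std() / obs.mean()
        mc_se = 0.05 / np.sqrt(2 * 10_000)
        assert abs(rel_sd - 0.05) < 3 * mc_se

    def test_initial_conditions_inside_ranges(self, target):
        ds = kt.generate_dataset(target, 8, seed=11)
        y0s = np.array([e.y0 for e in ds.experiments])
        assert np.all((y0s[:, 0] >= 0.1) & (y0s[:, 0] <= 0.5))
        assert np.all((y0s[:, 1] >= 1.0) & (y0s[:, 1] <= 10.0))
        assert np.all(y0s[:, 2] == 0.0)

    def test_bit_reproducible_for_seed(self, target):
        a = kt.generate_dataset(target, 3, seed=9)
        b = kt.generate_dataset(target, 3, seed=9)
        for ea, eb in zip(a.experiments, b.experiments):
            assert np.array_equal(ea.observations, eb.observations)

    def test_observations_clipped_nonnegative(self, target):
        ds = kt.generate_dataset(target, 4, noise_sd=0.5, seed=2)
        for e in ds.experiments:
            assert np.all(e.observations >= 0.0)

    def test_empty_range_rejected(self, target):
        with pytest.raises(ValueError, match="empty"):
            kt.generate_dataset(target, 1,
                                {"X": (0.5, 0.1), "S": (1, 10), "P": (0, 0)})


class TestMape:
    def test_perfect_prediction_is_zero(self, rng):
        obs = rng.uniform(1, 5, size=(7, 3))
        assert mape(obs, obs) == 0.0

    def test_uniform_ten_percent_overprediction(self, rng):
        obs = rng.uniform(1, 5, size=(7, 3))   # all well above the floor
        assert mape(1.1 * obs, obs) == pytest.approx(10.0)

    def test_small_case_against_hand_computation(self):
        obs = np.array([[2.0, 4.0], [1.0, 5.0]])
        pred = np.array([[2.2, 3.0], [0.8, 6.0]])
        # |err|/|obs|: 0.1, 0.25, 0.2, 0.2 -> mean 0.1875 -> 18.75%
        assert mape(pred, obs) == pytest.approx(18.75)

    def test_floor_prevents_blowup_at_early_near_zero_product(self):
        # first sample of a state that later reaches 5.0: denominator is
        # floored at 1% of the state maximum instead of the raw 1e-9
        obs = np.array([[1e-9], [5.0]])
        pred = obs + np.array([[0.01], [0.0]])
        # floored error: 0.01 / 0.05 = 20% on the first point, 0 on the other
        assert mape(pred, obs) == pytest.approx(10.0, rel=1e-3)

    def test_all_zero_observations_rejected(self):
        with pytest.raises(ValueError):
            mape(np.ones((3, 2)), np.zeros((3, 2)))


class TestCsvRoundTrip:
    def test_dataset_round_trip(self, target, tmp_path):
        ds = kt.generate_dataset(target, 3, seed=4)
        path = tmp_path / "data.csv"
        dataset_to_csv(ds, path)
        again = dataset_from_csv(path)
        assert again.ne == ds.ne and again.ni == ds.ni
        assert again.state_names == ds.state_names
        for ea, eb in zip(ds.experiments, again.experiments):
            assert np.allclose(ea.observations, eb.observations)
            assert np.allclose(ea.y0, eb.y0)
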