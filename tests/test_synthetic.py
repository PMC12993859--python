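"""Generator contracts: schedules, determinism, growth structure, trajectories."""

import warnings

import numpy as np
import pandas as pd
import pytest

from nutrimon.synthetic import (
    ExperimentDesign,
    GrowthModel,
    Trajectories,
    anova_ss,
    channel_reflectance,
    fit_logistic,
    logistic,
    make_trajectories,
    render_cube,
    simulate_experiment,
)


class TestDesignValidation:
    def test_default_design_is_feasible(self):
        d = ExperimentDesign()
        assert len(d.sampling_days) * d.samples_per_tank_per_day <= d.plants_per_tank

    def test_infeasible_sampling_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            ExperimentDesign(plants_per_tank=10)

    def test_sampling_day_outside_window_raises(self):
        with pytest.raises(ValueError, match="sampling days"):
            ExperimentDesign(sampling_days=(3, 11, 14, 18, 21, 23, 25))

    def test_bad_fertilizer_fraction_raises(self):
        with pytest.raises(ValueError, match="fraction"):
            ExperimentDesign(treatments=(("T1", 1.0), ("T2", 0.0), ("T3", 0.25)))


class TestSimulateExperiment:
    def test_default_design_yields_315_ground_truth_rows(self):
        states, gt = simulate_experiment(ExperimentDesign(seed=1))
        assert len(gt) == 9 * 7 * 5
        counts = gt.groupby(["tank_id", "DAT"]).size()
        assert (counts == 5).all()

    def test_no_sampling_days_all_plants_survive(self, quiet_model):
        design = ExperimentDesign(sampling_days=(), seed=1, plants_per_tank=6)
        states, gt = simulate_experiment(design, quiet_model)
        assert gt.empty
        last = states.groupby("plant_id")["DAT"].max()
        assert (last == design.imaging_end).all()

    def test_sampled_plants_emit_no_states_after_sampling(self, small_design, quiet_model):
        states, gt = simulate_experiment(small_design, quiet_model)
        for _, row in gt.iterrows():
            later = states[(states["plant_id"] == row["plant_id"])
                           & (states["DAT"] > row["DAT"])]
            assert later.empty

    def test_same_seed_byte_identical_tables(self, small_design, quiet_model):
        a = simulate_experiment(small_design, quiet_model)
        b = simulate_experiment(small_design, quiet_model)
        assert a[0].to_csv() == b[0].to_csv()
        assert a[1].to_csv() == b[1].to_csv()

    def test_state_invariants(self, small_experiment):
        states, _ = small_experiment
        assert (states["FW_g"] > 0).all()
        assert (states["DM_g"] < states["FW_g"]).all()
        for nut in ("N", "P", "K", "Ca", "Mg", "S"):
            assert (states[f"{nut}_pct"] > 0).all()
        # living plants grow monotonically
        for _, grp in states.groupby("plant_id"):
            fw = grp.sort_values("DAT")["FW_g"].to_numpy()
            assert (np.diff(fw) >= 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_treatment_ordering_at_final_day(self, seed):
        design = ExperimentDesign(plants_per_tank=8, sampling_days=(), seed=seed)
        states, _ = simulate_experiment(design, GrowthModel())
        end = states[states["DAT"] == design.imaging_end].groupby("treatment")["FW_g"].mean()
        assert end["T1"] >= end["T2"] >= end["T3"]

    def test_half_strength_calibration_anchor(self):
        """T2 final fresh weight ~78.9% of control under the noise-free model."""
        design = ExperimentDesign(plants_per_tank=8, sampling_days=(), seed=0)
        model = GrowthModel(tank_sd=0.0, residual_sd=0.0, conc_residual_sd=0.0)
        states, _ = simulate_experiment(design, model)
        end = states[states["DAT"] == 26].groupby("treatment")["FW_g"].mean()
        assert end["T2"] / end["T1"] == pytest.approx(0.789, abs=0.005)


class TestVarianceStructure:
    def test_treatment_dominates_between_group_variance(self):
        model = GrowthModel(tank_sd=0.01, residual_sd=0.002, conc_residual_sd=0.0)
        design = ExperimentDesign(plants_per_tank=8, sampling_days=(), seed=3)
        states, _ = simulate_experiment(design, model)
        final = states[states["DAT"] == 26]
        between, within = anova_ss(final["FW_g"], final["treatment"])
        assert between > 10 * within

    def test_logistic_parameter_recovery_noise_free(self):
        model = GrowthModel(tank_sd=0.0, residual_sd=0.0, conc_residual_sd=0.0)
        design = ExperimentDesign(plants_per_tank=6, sampling_days=(), seed=0)
        states, _ = simulate_experiment(design, model)
        for _, frac in design.treatments:
            name = {1.0: "T1", 0.5: "T2", 0.25: "T3"}[frac]
            grp = states[states["treatment"] == name].groupby("DAT")["FW_g"].mean()
            a, r, t0 = fit_logistic(grp.index, grp.to_numpy())
            expected_a = model.fw_asymptote_g * frac**model.fw_depletion_exponent
            assert a == pytest.approx(expected_a, abs=1e-6)
            assert r == pytest.approx(model.fw_rate, abs=1e-6)
            assert t0 == pytest.approx(model.fw_midpoint_dat, abs=1e-6)


class TestRenderCube:
    def test_noise_free_pixels_equal_link_prediction(self, small_experiment, quiet_model):
        states, _ = small_experiment
        night = states[(states["DAT"] == 10)].head(4)
        cube, masks = render_cube(night, quiet_model, size=(64, 96),
                                  rng=np.random.default_rng(0))
        for _, state in night.iterrows():
            mask = masks[state["plant_id"]]
            expected = channel_reflectance(quiet_model, state)
            for ch in expected:
                vals = cube.channel(ch)[mask]
                np.testing.assert_allclose(vals, expected[ch])

    def test_background_outside_masks(self, small_experiment, quiet_model):
        states, _ = small_experiment
        night = states[states["DAT"] == 10].head(2)
        cube, masks = render_cube(night, quiet_model, size=(64, 96),
                                  rng=np.random.default_rng(0))
        outside = ~np.logical_or.reduce(list(masks.values()))
        np.testing.assert_allclose(cube.data[:, outside], quiet_model.background)

    def test_masks_are_disjoint(self, small_experiment, quiet_model):
        states, _ = small_experiment
        night = states[states["DAT"] == 20].head(6)
        _, masks = render_cube(night, quiet_model, size=(64, 96),
                               rng=np.random.default_rng(0))
        stack = np.stack(list(masks.values()))
        assert stack.sum(axis=0).max() <= 1

    def test_too_small_canvas_raises(self, small_experiment, quiet_model):
        states, _ = small_experiment
        night = states[states["DAT"] == 10]
        with pytest.raises(ValueError, match="too small"):
            render_cube(night, quiet_model, size=(8, 8))

    def test_no_plants_raises(self, small_experiment, quiet_model):
        states, _ = small_experiment
        with pytest.raises(ValueError, match="at least one"):
            render_cube(states.head(0), quiet_model)


@pytest.fixture(scope="module")
def traj(small_experiment):
    states, _ = small_experiment
    return make_trajectories(states, feature_columns=["FW_g", "N_pct"])


class TestTrajectories:
    def test_sampled_plant_trajectory_ends_at_sampling_day(self, small_experiment, traj):
        _, gt = small_experiment
        row = gt.iloc[0]
        series = traj.series[row["plant_id"]]
        assert series.index.max() == row["DAT"]
        assert series.index.min() == 4

    def test_unsampled_plant_spans_full_window(self, small_experiment, traj):
        states, gt = small_experiment
        unsampled = sorted(set(states["plant_id"]) - set(gt["plant_id"]))[0]
        series = traj.series[unsampled]
        assert list(series.index) == list(range(4, 27))

    def test_window_excludes_truncated_plants(self, small_experiment, traj):
        _, gt = small_experiment
        early = gt[gt["DAT"] == 11]["plant_id"].iloc[0]
        vals, pids, _ = traj.windows("FW_g", 22, start_dat=4)
        assert early not in pids
        assert vals.shape[1] == 22

    def test_interior_gap_interpolated(self):
        rows = [
            {"plant_id": "p1", "tank_id": "t", "treatment": "T1", "DAT": d, "x": float(d)}
            for d in (4, 5, 7, 8)  # DAT 6 missing
        ]
        traj = Trajectories(pd.DataFrame(rows))
        assert traj.series["p1"].loc[6, "x"] == pytest.approx(6.0)

    def test_single_observation_plant_excluded_with_warning(self):
        rows = [
            {"plant_id": "p1", "tank_id": "t", "treatment": "T1", "DAT": 4, "x": 1.0},
            {"plant_id": "p2", "tank_id": "t", "treatment": "T1", "DAT": 4, "x": 1.0},
            {"plant_id": "p2", "tank_id": "t", "treatment": "T1", "DAT": 5, "x": 2.0},
        ]
        with pytest.warns(UserWarning, match="fewer than 2"):
            traj = Trajectories(pd.DataFrame(rows))
        assert "p1" not in traj.series and "p2" in traj.series

    def test_window_length_below_two_raises(self, traj):
        with pytest.raises(ValueError):
            traj.windows("FW_g", 1)


def test_logistic_midpoint_is_half_asymptote():
    assert logistic(16.0, 250.0, 0.35, 16.0) == pytest.approx(125.0)
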