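"""Tests for MMSE fitting, the error surface and degeneracy detection."""

import numpy as np
import pytest

from methkin import conditions, dyad_model, estimation, synthetic_data
from methkin.estimation import (
    FitSpec,
    Surface,
    find_local_minima,
    grid_search,
    mmse_objective,
    normalize_series,
    predict_levels,
    r_squared,
)
from methkin.types import (
    DyadStateVector,
    ObservationSeries,
    RateParameters,
    ValidationError,
)


def noiseless_series(params, initial, times, include_hmc=True):
    m, h = predict_levels(params, np.asarray(times, dtype=float), initial)
    return ObservationSeries(times=times, five_mC=m,
                             five_hmC=h if include_hmc else None)


class TestObjective:
    def test_zero_at_the_generating_parameters(self, two_i, serum_state,
                                               course_times):
        obs = noiseless_series(two_i, serum_state, course_times)
        assert mmse_objective(two_i, obs, serum_state) <= 1e-12

    def test_constant_offset_gives_offset_squared(self, two_i, serum_state,
                                                  course_times):
        m, _ = predict_levels(two_i, course_times, serum_state)
        obs = ObservationSeries(times=course_times, five_mC=m + 0.03)
        assert mmse_objective(two_i, obs, serum_state) == pytest.approx(
            0.03**2, rel=1e-9
        )

    def test_expectation_under_noise_is_the_noise_variance(
        self, two_i, serum, serum_state
    ):
        # mean of squared i.i.d. N(0, sd) residuals ~ sd^2 (chi^2 spread)
        sd, n = 0.01, 400
        times = np.linspace(0.0, 336.0, n)
        obs = synthetic_data.generate_timecourse(
            serum, two_i, 0.0, times, synthetic_data.NoiseModel(sd, seed=5)
        )
        mmse = mmse_objective(two_i, obs, serum_state)
        se = sd**2 * np.sqrt(2.0 / n)  # sd of the mean of chi2_1 terms
        assert abs(mmse - sd**2) < 3 * se

    def test_joint_objective_pools_hmc_residuals(self, two_i, serum_state,
                                                 course_times):
        m, h = predict_levels(two_i, course_times, serum_state)
        obs = ObservationSeries(times=course_times, five_mC=m, five_hmC=h + 0.02)
        only_mc = mmse_objective(two_i, obs, serum_state)
        joint = mmse_objective(two_i, obs, serum_state, include_hmc=True)
        assert only_mc <= 1e-12
        assert joint == pytest.approx(0.02**2 / 2, rel=1e-9)


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.array([0.7, 0.5, 0.3, 0.2])
        assert r_squared(y, y) == 1.0

    def test_mean_prediction_scores_zero(self):
        y = np.array([0.7, 0.5, 0.3, 0.2])
        pred = np.full_like(y, y.mean())
        assert r_squared(pred, y) == pytest.approx(0.0, abs=1e-12)

    def test_constant_observation_is_undefined(self):
        with pytest.raises(ValidationError):
            r_squared(np.array([0.1, 0.2]), np.array([0.5, 0.5]))


class TestGridSearch:
    def test_recovers_on_grid_truth_from_noiseless_data(
        self, serum, serum_state, course_times
    ):
        truth = RateParameters.with_schedule(0.4, 0.1, 24.0, 0.5, 0.1)
        obs = noiseless_series(truth, serum_state, course_times)
        spec = FitSpec(base=truth, free={"p1_final": 11, "p2": 11},
                       refine=False)
        fit = grid_search(obs, serum_state, spec)
        assert fit.best_values == {"p1_final": 0.1, "p2": 0.5}
        assert fit.mmse <= 1e-15

    def test_halving_curve_identifies_maintenance_knockout(self, serum_state):
        truth = RateParameters(p1=0.0, p2=0.0, p3=0.0)
        times = np.arange(0.0, 81.0, 16.0)
        obs = noiseless_series(truth, serum_state, times)
        spec = FitSpec(base=truth, free={"p2": 51}, refine=False)
        fit = grid_search(obs, serum_state, spec)
        assert fit.best_values["p2"] == 0.0

    def test_deterministic_and_tie_broken_lexicographically(
        self, two_i, serum, serum_state, course_times
    ):
        obs = synthetic_data.generate_timecourse(
            serum, two_i, 0.0, course_times, synthetic_data.NoiseModel(0.01, 7)
        )
        spec = FitSpec(base=two_i, free={"p1_final": 15, "p2": 15})
        a = grid_search(obs, serum_state, spec)
        b = grid_search(obs, serum_state, spec)
        assert a.best_values == b.best_values  # bitwise identical
        assert np.array_equal(a.surface.values, b.surface.values)

    def test_empty_free_set_evaluates_fixed_point(self, two_i, serum_state,
                                                  course_times):
        obs = noiseless_series(two_i, serum_state, course_times)
        fit = grid_search(obs, serum_state, FitSpec(base=two_i, free={}))
        assert fit.best is two_i
        assert fit.mmse <= 1e-12

    def test_refinement_beats_a_coarse_grid(self, serum, serum_state):
        truth = serum.updated(p2=0.83)  # off any coarse grid node
        times = np.linspace(0.0, 168.0, 9)
        obs = noiseless_series(truth, serum_state, times)
        spec_c = FitSpec(base=serum, free={"p2": 11}, refine=False)
        spec_r = FitSpec(base=serum, free={"p2": 11}, refine=True)
        coarse = grid_search(obs, serum_state, spec_c)
        refined = grid_search(obs, serum_state, spec_r)
        assert refined.mmse < coarse.mmse
        assert refined.best_values["p2"] == pytest.approx(0.83, abs=1e-4)

    def test_surface_is_unimodal_along_p2_at_truth(self, serum, serum_state):
        times = np.linspace(0.0, 168.0, 9)
        obs = noiseless_series(serum, serum_state, times)
        spec = FitSpec(base=serum, free={"p2": 41}, refine=False)
        fit = grid_search(obs, serum_state, spec)
        v = fit.surface.values
        k = int(np.argmin(v))
        assert np.all(np.diff(v[: k + 1]) <= 0)
        assert np.all(np.diff(v[k:]) >= 0)

    def test_too_few_observations_rejected(self, two_i, serum_state):
        obs = ObservationSeries(times=[0.0, 16.0], five_mC=[0.7, 0.6])
        with pytest.raises(ValidationError):
            grid_search(obs, serum_state, FitSpec(base=two_i, free={"p2": 5}))

    def test_parameter_recovery_at_study_noise(self, serum, two_i,
                                               serum_state, course_times):
        # 20 seeded replicates at 1-percentage-point noise: median absolute
        # recovery error of p2 and p1_final stays within 0.05
        errs_p2, errs_p1f = [], []
        for seed in range(20):
            obs = synthetic_data.generate_timecourse(
                serum, two_i, 0.0, course_times,
                synthetic_data.NoiseModel(0.01, seed),
            )
            spec = FitSpec(base=two_i, free={"p1_final": 21, "p2": 21})
            fit = grid_search(obs, serum_state, spec)
            errs_p2.append(abs(fit.best_values["p2"] - two_i.p2))
            errs_p1f.append(
                abs(fit.best_values["p1_final"] - two_i.p1_schedule.p1_final)
            )
        assert np.median(errs_p2) <= 0.05
        assert np.median(errs_p1f) <= 0.05


class TestLocalMinima:
    @staticmethod
    def brute_force_minima(values):
        """Independent oracle: direct neighbor scan."""
        mins = []
        for idx in np.ndindex(values.shape):
            ok = True
            for ax in range(values.ndim):
                for step in (-1, 1):
                    j = list(idx)
                    j[ax] += step
                    if 0 <= j[ax] < values.shape[ax]:
                        if values[tuple(j)] < values[idx]:
                            ok = False
            if ok:
                mins.append(idx)
        return mins

    def test_two_hand_placed_basins_found_in_mmse_order(self):
        x = np.linspace(0.0, 1.0, 41)
        y = np.linspace(0.0, 1.0, 41)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        v = np.minimum(
            (xx - 0.2) ** 2 + (yy - 0.3) ** 2 + 0.01,
            (xx - 0.8) ** 2 + (yy - 0.7) ** 2,
        )
        surface = Surface(axis_names=("p2", "p3"), axes=(x, y), values=v)
        minima = find_local_minima(surface)
        oracle = self.brute_force_minima(v)
        assert {m.index for m in minima} == set(oracle)
        assert len(minima) == 2
        assert minima[0].mmse < minima[1].mmse
        assert minima[0].params == pytest.approx({"p2": 0.8, "p3": 0.7})

    def test_single_basin_yields_one_minimum(self):
        x = np.linspace(0.0, 1.0, 21)
        v = (x - 0.4) ** 2
        surface = Surface(axis_names=("p2",), axes=(x,), values=v)
        assert len(find_local_minima(surface)) == 1

    def test_plateau_merged_into_one_minimum(self):
        v = np.array([3.0, 1.0, 1.0, 1.0, 2.0])
        x = np.linspace(0, 1, 5)
        surface = Surface(axis_names=("p2",), axes=(x,), values=v)
        minima = find_local_minima(surface)
        assert len(minima) == 1
        assert minima[0].index == (1,)  # lexicographically smallest of ties

    def test_fast_decay_5mc_only_fit_is_degenerate(self):
        # maintenance loss and TET oxidation trade off against each other:
        # a 5mC-only objective admits multiple minima whose 5mC courses
        # agree within noise but whose 5hmC predictions diverge >2-fold
        initial = DyadStateVector(uu=0.15, um=0.10, mm=0.75)
        truth = RateParameters(p1=0.02, p2=0.3, p3=0.3)
        times = np.arange(0.0, 97.0, 16.0)
        obs = synthetic_data.generate_timecourse(
            truth, truth, 0.0, times, synthetic_data.NoiseModel(0.005, 42),
            initial=initial,
        )
        spec = FitSpec(
            base=truth, free={"p2": 31, "p3": 31},
            bounds={"p2": (0.0, 0.9), "p3": (0.0, 0.6)}, refine=False,
        )
        fit = grid_search(obs, initial, spec)
        near = [m for m in fit.minima if m.mmse < 4 * fit.mmse]
        assert len(near) >= 2
        curves = []
        for m in near:
            pm, ph = predict_levels(truth.updated(**m.params), times, initial)
            curves.append((pm, ph))
        for pm, _ in curves:
            assert np.max(np.abs(pm - curves[0][0])) < 3 * 0.005
        peaks = [ph.max() for _, ph in curves]
        assert max(peaks) > 2 * min(peaks)


class TestNormalize:
    def test_to_initial_rescales_to_unity_at_t0(self):
        obs = ObservationSeries(
            times=[0.0, 16.0, 32.0], five_mC=[0.8, 0.6, 0.4],
            five_hmC=[0.02, 0.03, 0.01],
        )
        out = normalize_series(obs, "to_initial")
        assert out.five_mC[0] == 1.0
        np.testing.assert_allclose(out.five_mC, [1.0, 0.75, 0.5])
        assert out.five_hmC[0] == 1.0

    def test_none_mode_is_identity(self):
        obs = ObservationSeries(times=[0.0, 16.0, 32.0],
                                five_mC=[0.8, 0.6, 0.4])
        assert normalize_series(obs, "none") is obs

    def test_zero_reference_rejected(self):
        obs = ObservationSeries(times=[0.0, 16.0, 32.0],
                                five_mC=[0.0, 0.6, 0.4])
        with pytest.raises(ValidationError):
            normalize_series(obs, "to_initial")
        with pytest.raises(ValidationError):
            normalize_series(obs, "to_reference", reference=0.0)

    def test_fit_is_scale_invariant(self, serum, two_i, serum_state,
                                    course_times):
        obs = synthetic_data.generate_timecourse(
            serum, two_i, 0.0, course_times, synthetic_data.NoiseModel(0.01, 9)
        )
        spec = FitSpec(base=two_i, free={"p2": 21}, refine=False)
        plain = grid_search(obs, serum_state, spec)
        scaled = grid_search(
            normalize_series(obs, "to_initial"), serum_state, spec
        )
        assert plain.best_values == scaled.best_values
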