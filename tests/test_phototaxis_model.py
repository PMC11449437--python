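"""BCRW heading updates, Poisson jump decisions, simulation and fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hydrataxis import (
    NoiseDistribution,
    calibrate_w,
    default_params,
    jump_occurs,
    simulate_animal,
    simulate_cohort,
    step_heading,
    step_position,
)
from hydrataxis.exceptions import FitError
from hydrataxis.phototaxis_model import (
    FitSettings,
    fit_model,
    load_params,
    params_from_dict,
    params_to_dict,
    save_params,
    simulate_heading_changes,
)

POINT = 1e-12  # effectively deterministic noise scale


def quiet_params(**over):
    """Defaults with (near-)zero noise for deterministic limits."""
    over.setdefault("phi_noise", NoiseDistribution(mu=0.0, sigma=POINT, nu=5.0))
    over.setdefault("delta_noise", NoiseDistribution(mu=0.0, sigma=POINT, nu=5.0))
    return default_params(**over)


class TestStepHeading:
    def test_pure_bias_limit(self):
        params = quiet_params(w=1.0)
        assert step_heading(123.0, params, 0) == pytest.approx(0.0, abs=1e-6)

    def test_pure_persistence_limit(self):
        params = quiet_params(w=0.0)
        assert step_heading(57.0, params, 0) == pytest.approx(57.0, abs=1e-6)

    def test_even_mixture(self):
        params = quiet_params(w=0.5)
        assert step_heading(90.0, params, 0) == pytest.approx(45.0, abs=1e-6)

    def test_wrap_rule(self):
        params = quiet_params(w=0.0, delta_noise=NoiseDistribution(mu=20.0, sigma=POINT, nu=5.0))
        assert step_heading(170.0, params, 0) == pytest.approx(-170.0, abs=1e-6)

    @given(theta=st.floats(-180.0, 180.0), w=st.floats(0.0, 1.0), seed=st.integers(0, 100))
    def test_result_always_wrapped(self, theta, w, seed):
        out = step_heading(theta, default_params(w=w), seed)
        assert -180.0 < out <= 180.0


class TestJumpOccurs:
    def test_zero_rate_never_jumps(self):
        assert not np.any(jump_occurs(0.0, 20.0, 0, size=10_000))

    def test_half_probability_at_log_two(self):
        lam_dt = np.log(2.0)  # lam * dt(h) = ln 2 -> p = 1/2
        draws = jump_occurs(lam_dt, 3600.0, 19, size=100_000)
        assert 0.495 <= draws.mean() <= 0.505

    def test_counts_superpose_to_poisson_mean(self):
        rng = np.random.default_rng(20)
        counts = [jump_occurs(2.0, 20.0, rng, size=1440).sum() for _ in range(500)]
        assert 15.4 <= np.mean(counts) <= 16.6


class TestStepPosition:
    @pytest.mark.parametrize(
        "foot, theta, d, expected",
        [((30, 2), 0.0, 5.0, (25, 2)), ((30, 2), 180.0, 5.0, (35, 2)), ((30, 4), 90.0, 3.0, (30, 3))],
    )
    def test_examples(self, foot, theta, d, expected, geometry):
        np.testing.assert_allclose(step_position(foot, theta, d, geometry), expected, atol=1e-12)

    def test_zero_distance_is_identity(self, geometry):
        np.testing.assert_array_equal(step_position((30, 2), 45.0, 0.0, geometry), (30, 2))

    def test_x_clamped_at_light_wall(self, geometry):
        assert step_position((2, 2), 0.0, 5.0, geometry)[0] == 0.0

    def test_mirror_mode_preserves_distance(self, geometry):
        out = step_position((2, 2), 0.0, 5.0, geometry, wall_mode="mirror")
        assert np.linalg.norm(out - (2, 2)) == pytest.approx(5.0)
        assert 0 <= out[0] <= geometry.lane_length


class TestSimulateAnimal:
    def test_deterministic_descent_and_crossing(self, geometry):
        params = quiet_params(w=1.0, lambda_starved=500.0)
        traj = simulate_animal(params, "starved", geometry, 1)
        x = traj.foot_xy[:, 0]
        assert np.all(np.diff(x) <= 1e-12)
        assert traj.crossed
        assert x[-1] < geometry.phototaxis_threshold

    def test_zero_rate_never_moves(self, geometry):
        params = default_params(lambda_starved=0.0)
        traj = simulate_animal(params, "starved", geometry, 2)
        assert not traj.crossed
        assert np.all(traj.foot_xy == traj.foot_xy[0])
        assert len(traj.times) == 1441  # full horizon at 20 s steps

    def test_seed_determinism(self, geometry):
        a = simulate_animal(default_params(), "starved", geometry, 3)
        b = simulate_animal(default_params(), "starved", geometry, 3)
        np.testing.assert_array_equal(a.foot_xy, b.foot_xy)
        np.testing.assert_array_equal(a.heading, b.heading)
        np.testing.assert_array_equal(a.jump_flags, b.jump_flags)

    def test_invariants_headings_and_lane(self, geometry):
        for seed in range(5):
            traj = simulate_animal(default_params(), "fed", geometry, seed)
            assert np.all((traj.heading > -180.0) & (traj.heading <= 180.0))
            assert traj.foot_xy[:, 0].min() >= 0 and traj.foot_xy[:, 0].max() <= geometry.lane_length
            assert traj.foot_xy[:, 1].min() >= 0 and traj.foot_xy[:, 1].max() <= geometry.lane_width
            assert traj.crossed == (traj.foot_xy[-1, 0] < geometry.phototaxis_threshold)

    def test_termination_at_first_crossing(self, geometry):
        traj = simulate_animal(default_params(), "starved", geometry, 4)
        if traj.crossed:
            assert np.all(traj.foot_xy[:-1, 0] >= geometry.phototaxis_threshold)
            assert traj.crossing_time == pytest.approx(traj.times[-1] / 3600.0)

    def test_start_conditions_in_zone(self, geometry):
        for seed in range(10):
            traj = simulate_animal(default_params(lambda_starved=0.0), "starved", geometry, seed)
            assert geometry.start_zone[0] <= traj.foot_xy[0, 0] <= geometry.start_zone[1]
            assert 0 <= traj.foot_xy[0, 1] <= geometry.lane_width


class TestSimulateCohort:
    def test_cohort_size(self, geometry):
        trajs = simulate_cohort(default_params(horizon=0.2), "starved", 30, geometry, 5)
        assert len(trajs) == 30

    def test_fed_active_fraction_binomial(self, geometry):
        trajs = simulate_cohort(default_params(horizon=0.05), "fed", 1000, geometry, 6)
        n_active = sum(t.subclass == "active" for t in trajs)
        assert 440 <= n_active <= 560

    def test_cohort_determinism(self, geometry):
        a = simulate_cohort(default_params(horizon=0.5), "fed", 5, geometry, 7)
        b = simulate_cohort(default_params(horizon=0.5), "fed", 5, geometry, 7)
        for ta, tb in zip(a, b):
            assert ta.subclass == tb.subclass
            np.testing.assert_array_equal(ta.foot_xy, tb.foot_xy)


def _poisson_summary(rng, n, lam, T=8.0, cutoff=3):
    from hydrataxis.behavior_extraction import BehavioralSummary, JumpEvent

    out = []
    for i in range(n):
        k = int(rng.poisson(lam * T))
        dists = 3.0 + rng.uniform(-1.0, 1.0, size=k)
        jumps = [
            JumpEvent(t_before=60.0 * j, t_after=60.0 * j + 20.0,
                      from_xy=(30.0, 2.0), to_xy=(30.0 - d, 2.0), distance=d)
            for j, d in enumerate(dists)
        ]
        s = BehavioralSummary(
            animal_id=f"x{i}", theta_series=np.zeros(3), signed_heading_series=np.zeros(3),
            theta_times=np.arange(3.0), jumps=jumps, N_h=k, T_h=T, lambda_hat=k / T,
            crossed=False, crossing_time=None,
            activity_class="inactive" if k <= cutoff else "active",
        )
        out.append(s)
    return out


class TestFitModel:
    def test_rate_recovery_from_poisson_cohorts(self):
        rng = np.random.default_rng(21)
        summaries = {
            "starved": _poisson_summary(rng, 50, 2.0),
            "fed": _poisson_summary(rng, 25, 0.8) + _poisson_summary(rng, 25, 0.1),
        }
        dth = np.concatenate([rng.standard_t(5, 2000) * 30.0])
        params = fit_model(summaries, np.clip(dth, -179.9, 179.9), FitSettings())
        assert params.lambda_starved == pytest.approx(2.0, rel=0.25)
        assert params.lambda_fed_active == pytest.approx(0.8, rel=0.35)  # classification shifts it up
        assert params.lambda_fed_inactive <= 0.2

    def test_degenerate_fed_split_raises_unless_allowed(self):
        rng = np.random.default_rng(22)
        summaries = {
            "starved": _poisson_summary(rng, 10, 2.0),
            "fed": _poisson_summary(rng, 10, 3.0),  # all active with high probability
        }
        if all(s.activity_class == "active" for s in summaries["fed"]):
            dth = np.clip(rng.standard_t(5, 500) * 30.0, -179.9, 179.9)
            with pytest.raises(FitError):
                fit_model(summaries, dth, FitSettings())
            params = fit_model(summaries, dth, FitSettings(allow_empty_subclass=True))
            assert params.fed_active_fraction == 1.0
            assert params.lambda_fed_inactive == 0.0

    def test_kde_mean_tracks_pooled_distances(self):
        rng = np.random.default_rng(23)
        summaries = {
            "starved": _poisson_summary(rng, 20, 2.0),
            "fed": _poisson_summary(rng, 20, 1.0),
        }
        dth = np.clip(rng.standard_t(5, 500) * 30.0, -179.9, 179.9)
        params = fit_model(summaries, dth, FitSettings())
        pooled = [j.distance for g in summaries.values() for s in g for j in s.jumps]
        assert params.jump_kde.mean() == pytest.approx(np.mean(pooled), rel=0.05)


class TestCalibrateW:
    def test_self_consistent_recovery(self):
        params = default_params()
        obs = simulate_heading_changes(params, 0.8, 40, 1440, np.random.default_rng(24))
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 2)
        w = calibrate_w(obs, params, grid, seed=25)
        assert abs(w - 0.8) <= 0.1 + 1e-9

    def test_limit_separation(self):
        params = default_params()
        obs = simulate_heading_changes(params, 0.0, 40, 1440, np.random.default_rng(26))
        assert calibrate_w(obs, params, [0.0, 1.0], seed=27) == 0.0

    def test_deterministic_selection(self):
        params = default_params()
        obs = simulate_heading_changes(params, 0.6, 20, 500, np.random.default_rng(28))
        grid = [0.2, 0.4, 0.6, 0.8]
        assert calibrate_w(obs, params, grid, seed=29) == calibrate_w(obs, params, grid, seed=29)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            calibrate_w(np.zeros(10), default_params(), [], seed=0)


class TestSerialization:
    def test_params_round_trip(self, tmp_path):
        params = default_params(w=0.65, lambda_starved=1.7)
        path = save_params(params, tmp_path / "params.json")
        back = load_params(path)
        assert back.w == params.w
        assert back.lambda_starved == params.lambda_starved
        np.testing.assert_allclose(back.jump_kde.data, params.jump_kde.data)
        assert params_from_dict(params_to_dict(params)).phi_noise == params.phi_noise
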