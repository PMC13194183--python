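"""Synthetic cohort: parameter sampling, observers, agents, full study."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sps

from maware import cohort
from maware.cohort import (
    AgentParams,
    ObserverParams,
    ParamDist,
    default_calibration,
    expected_blind_error,
    expected_control_yes_rate,
    generate_study,
    sample_cohort,
    simulate_blind_reach,
    simulate_response,
    simulate_trajectory,
    yes_probability,
)
from maware.kinematics import endpoint_at_radius, mp_compensation
from maware.task_design import (
    Effector,
    Mode,
    TargetSide,
    Task,
    TaskGeometry,
    TrialSpec,
    apply_deviation,
    bearing_deg,
    target_bearing,
)


def _degenerate_calibration(n=4):
    """All between-participant SDs zero: every participant equals the means."""
    cal = default_calibration(n)
    zero = lambda d: ParamDist(d.mean, 0.0, d.low, d.high)  # noqa: E731
    return dataclasses.replace(
        cal,
        observer_mu={k: zero(v) for k, v in cal.observer_mu.items()},
        observer_slope={k: zero(v) for k, v in cal.observer_slope.items()},
        agent_gain={k: zero(v) for k, v in cal.agent_gain.items()},
        agent_motor_noise={k: zero(v) for k, v in cal.agent_motor_noise.items()},
        agent_blind_noise={k: zero(v) for k, v in cal.agent_blind_noise.items()},
        agent_duration={k: zero(v) for k, v in cal.agent_duration.items()},
    )


class TestSampleCohort:
    def test_contract_and_invariants(self, calibration):
        parts = sample_cohort(calibration, seed=0)
        assert len(parts) == 20
        for p in parts:
            for obs in p.observers.values():
                assert obs.mu > 0 and obs.sigma > 0
                assert 0 <= obs.lapse_high <= 0.15
            for agent in p.agents.values():
                assert 0 <= agent.compensation_gain <= 1
                assert agent.movement_duration > 0

    def test_zero_sd_gives_identical_participants(self):
        cal = _degenerate_calibration()
        parts = sample_cohort(cal, seed=5)
        key = (Effector.HAND, Task.SINGLE)
        mus = {p.observers[key].mu for p in parts}
        assert len(mus) == 1
        assert mus.pop() == pytest.approx(cal.observer_mu[key].mean)

    def test_latent_factor_correlation(self):
        # the copula's underlying normals correlate at latent_strength;
        # mild truncation distorts the sample correlation only slightly
        cal = default_calibration(n_participants=2000)
        parts = sample_cohort(cal, seed=2)
        hand = np.array([p.observers[(Effector.HAND, Task.SINGLE)].mu for p in parts])
        body = np.array(
            [p.observers[(Effector.FULL_BODY, Task.SINGLE)].mu for p in parts]
        )
        r = np.corrcoef(hand, body)[0, 1]
        assert r == pytest.approx(cal.latent_strength, abs=0.03)

    def test_marginal_is_truncated_normal(self):
        cal = default_calibration(n_participants=4000)
        parts = sample_cohort(cal, seed=3)
        key = (Effector.HAND, Task.DUAL)
        mus = np.array([p.observers[key].mu for p in parts])
        dist = cal.observer_mu[key]
        assert mus.min() >= dist.low and mus.max() <= dist.high
        assert mus.mean() == pytest.approx(dist._frozen().mean(), abs=0.5)


class TestObserver:
    def test_midpoint_probability(self):
        obs = ObserverParams(mu=20.0, sigma=8.0)
        assert yes_probability(20.0, Mode.DIVERGING, obs) == pytest.approx(0.5)

    def test_ceiling_lapse_at_zero_deviation(self):
        obs = ObserverParams(mu=30.0, sigma=1.0, lapse_high=0.09)
        assert yes_probability(0.0, Mode.CONTROL, obs) == pytest.approx(0.91, abs=1e-6)

    def test_monotone_non_increasing(self):
        obs = ObserverParams(mu=22.0, sigma=12.0, lapse_high=0.05, mode_shift=3.0)
        for mode in (Mode.CONVERGING, Mode.DIVERGING):
            probs = [yes_probability(d, mode, obs) for d in (0, 7.5, 15, 22.5, 30)]
            assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_converging_shift_raises_yes_rate(self):
        obs = ObserverParams(mu=15.0, sigma=8.0, mode_shift=3.0)
        assert yes_probability(15.0, Mode.CONVERGING, obs) > yes_probability(
            15.0, Mode.DIVERGING, obs
        )

    def test_response_matches_probability(self, rng):
        obs = ObserverParams(mu=15.0, sigma=8.0)
        trial = TrialSpec(0, Effector.HAND, Task.SINGLE, TargetSide.RIGHT, 15.0)
        yes = np.mean([simulate_response(trial, obs, rng) for _ in range(4000)])
        assert yes == pytest.approx(
            yes_probability(15.0, trial.mode, obs), abs=0.025
        )


class TestBlindReach:
    def test_noiseless_reach_hits_target(self, rng):
        agent = AgentParams(0.8, 2.0, blind_noise_sd=0.0)
        target = np.array([50.0, 100.0])
        assert np.allclose(simulate_blind_reach(agent, target, rng), target)

    def test_rayleigh_mean(self, rng):
        s = 10.0
        agent = AgentParams(0.8, 2.0, blind_noise_sd=s)
        target = np.array([0.0, 118.0])
        errs = [
            np.hypot(*(simulate_blind_reach(agent, target, rng) - target))
            for _ in range(100_000)
        ]
        assert np.mean(errs) == pytest.approx(s * math.sqrt(math.pi / 2), rel=0.01)

    def test_analytic_expectations_match_published_means(self, calibration):
        # lapse/noise calibration was solved from the published summaries
        assert expected_control_yes_rate(calibration, "full_body") == pytest.approx(
            0.899, abs=1e-3
        )
        assert expected_control_yes_rate(calibration, "hand") == pytest.approx(
            0.913, abs=1e-3
        )
        assert expected_blind_error(calibration, "hand") == pytest.approx(26.0, rel=0.02)
        assert expected_blind_error(calibration, "full_body") == pytest.approx(
            18.0, rel=0.02
        )


class TestTrajectory:
    @pytest.fixture()
    def quiet_agent(self):
        return AgentParams(
            compensation_gain=1.0,
            motor_noise_sd=0.0,
            blind_noise_sd=10.0,
            movement_duration=1.0,
        )

    def test_unperturbed_straight_path(self, geometry, rng, quiet_agent):
        trial = TrialSpec(0, Effector.HAND, Task.SINGLE, TargetSide.RIGHT, 0.0)
        traj = simulate_trajectory(trial, quiet_agent, geometry, rng)
        bearings = bearing_deg(traj.xy[1:, 0], traj.xy[1:, 1])
        assert np.allclose(bearings, 25.0, atol=1e-9)
        end = endpoint_at_radius(traj, geometry)
        assert bearing_deg(end[0], end[1]) == pytest.approx(25.0, abs=1e-9)

    def test_full_compensation_geometry(self, geometry, rng, quiet_agent):
        # gain 1: post-onset heading rotated by -alpha. Because the first
        # 25 mm are travelled before the feedback deviates, the endpoint
        # bearing from the origin carries a residual asin(r0 sin a / R)
        # relative to the rotated heading; the cursor lands that residual
        # short of the target rather than exactly on it.
        alpha, theta_t = 30.0, target_bearing(geometry, TargetSide.RIGHT)
        trial = TrialSpec(0, Effector.HAND, Task.SINGLE, TargetSide.RIGHT, alpha)
        traj = simulate_trajectory(trial, quiet_agent, geometry, rng)
        end = endpoint_at_radius(traj, geometry)
        cursor = apply_deviation(end, alpha, geometry)
        residual = math.degrees(
            math.asin(
                geometry.deviation_onset_mm
                * math.sin(math.radians(alpha))
                / geometry.target_radius_mm
            )
        )
        assert bearing_deg(end[0], end[1]) == pytest.approx(
            theta_t - alpha + residual, abs=0.2
        )
        assert bearing_deg(cursor[0], cursor[1]) == pytest.approx(
            theta_t + residual, abs=0.2
        )
        # and the compensation measured from the onset point is the full alpha
        assert mp_compensation(traj, trial, geometry) == pytest.approx(alpha, abs=0.5)

    def test_zero_gain_heads_at_target(self, geometry, rng):
        agent = AgentParams(0.0, 0.0, 10.0, movement_duration=1.0)
        trial = TrialSpec(0, Effector.HAND, Task.SINGLE, TargetSide.RIGHT, 30.0)
        traj = simulate_trajectory(trial, agent, geometry, rng)
        end = endpoint_at_radius(traj, geometry)
        assert bearing_deg(end[0], end[1]) == pytest.approx(25.0, abs=1e-9)
        cursor = apply_deviation(end, 30.0, geometry)
        assert bearing_deg(cursor[0], cursor[1]) == pytest.approx(55.0, abs=1e-9)

    @pytest.mark.parametrize("gain", [0.0, 0.4, 0.6, 1.0])
    @pytest.mark.parametrize("alpha", [-30.0, -7.5, 15.0, 22.5])
    def test_mp_equals_gain_times_deviation(self, geometry, rng, gain, alpha):
        agent = AgentParams(gain, 0.0, 10.0, movement_duration=1.0)
        trial = TrialSpec(0, Effector.HAND, Task.SINGLE, TargetSide.LEFT, alpha)
        traj = simulate_trajectory(trial, agent, geometry, rng)
        mp = mp_compensation(traj, trial, geometry)
        # tolerance: bearing error from one linear-interpolation sample at
        # the deviation-onset corner
        step = 1.875 * geometry.target_radius_mm * 1.15 / agent.movement_duration
        step /= geometry.sampling_rate_hz
        tol = math.degrees(
            step
            * math.sin(math.radians(gain * abs(alpha)))
            / (geometry.target_radius_mm - geometry.deviation_onset_mm)
        )
        assert mp == pytest.approx(gain * abs(alpha), abs=tol + 1e-9)


class TestGenerateStudy:
    def test_shape_and_counts(self, small_study):
        trials = small_study.trials
        assert len(trials) == 6 * 4 * 88
        assert len(small_study.blind) == 6 * 2 * 60
        counts = trials.groupby(["participant", "effector", "task"]).size()
        assert (counts == 88).all()
        ctrl = trials[trials.deviation_deg == 0]
        assert (ctrl.groupby(["participant", "effector", "task"]).size() == 24).all()

    def test_determinism(self):
        cal = default_calibration(n_participants=3)
        a = generate_study(cal, seed=9, include_trajectories=False)
        b = generate_study(cal, seed=9, include_trajectories=False)
        assert a.trials.equals(b.trials)
        assert a.blind.equals(b.blind)
        assert a.truth == b.truth

    def test_truth_sidecar_roundtrip(self, small_study):
        # the sidecar records the parameters actually used for generation
        truth = small_study.truth
        assert set(truth["participants"]) == set(small_study.trials.participant.unique())
        for pid, rec in truth["participants"].items():
            obs = rec["observers"]["hand:single"]
            assert obs["mu"] > 0 and obs["sigma"] > 0

    def test_control_yes_rate_dominates_largest_deviation(self, small_study):
        for rec in small_study.truth["participants"].values():
            for obs in rec["observers"].values():
                p = ObserverParams(**obs)
                assert yes_probability(0.0, Mode.CONTROL, p) >= yes_probability(
                    30.0, Mode.DIVERGING, p
                )

    def test_file_roundtrip(self, tmp_path):
        cal = default_calibration(n_participants=2)
        data = generate_study(cal, seed=4, out_dir=tmp_path)
        assert (tmp_path / "trials.csv").exists()
        assert (tmp_path / "truth.json").exists()
        pairs = list(cohort.read_trajectories(tmp_path / "trajectories.jsonl"))
        assert len(pairs) == len(data.trajectories)
        pid, traj = pairs[0]
        assert pid == data.trajectories[0][0]
        assert np.allclose(traj.xy, data.trajectories[0][1].xy, atol=1e-3)
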