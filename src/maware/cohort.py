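"""Synthetic participants for the action-monitoring and blind-reaching tasks.

Two generative pieces per participant:

* an *observer* that answers the self-attribution question. The yes
  probability is a descending cumulative Gaussian of the absolute
  deviation with an upper lapse (ceiling below 1, matching the ~90%
  self-attribution of veridical trials) and an additive threshold shift
  on converging trials;
* an *agent* that produces reaching trajectories: a minimum-jerk radial
  speed profile aimed at the target, with a proportional correction of
  the imposed visual rotation beyond the deviation onset, angular
  endpoint noise, and isotropic endpoint noise for blind reaches.

Between-participant parameter variation is truncated normal per
(effector, task) condition; a shared participant-level latent factor
(Gaussian copula) induces a configurable positive correlation of the
psychometric parameters between effectors. Default calibrations target
the published group summaries: Table-style threshold/slope means and
SDs per condition, ~89.9%/91.3% control-trial self-attribution (full
body/hand), and 26/18 mm blind-reaching error means.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinematics import Trajectory
from .task_design import (
    Effector,
    Mode,
    TargetSide,
    Task,
    TaskGeometry,
    TrialSpec,
    build_subblock,
    target_bearing,
    target_positions,
)

N_BLIND_TRIALS = 60  # scored blind reaches per participant per effector

_RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)


class CalibrationError(ValueError):
    """Raised for infeasible cohort calibrations."""


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal distribution of one parameter across participants."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise CalibrationError("parameter SD must be >= 0")
        if not self.low < self.high:
            raise CalibrationError("truncation bounds must satisfy low < high")
        if self.sd == 0 and not self.low <= self.mean <= self.high:
            raise CalibrationError("degenerate distribution outside bounds")

    def _frozen(self):
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return sps.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function (degenerate SD=0 returns the mean)."""
        if self.sd == 0:
            return np.full_like(np.asarray(u, dtype=float), self.mean)
        return self._frozen().ppf(u)

    def expect(self, fn, n_nodes: int = 96) -> float:
        """Gauss-Legendre expectation of fn(x) under the distribution."""
        if self.sd == 0:
            return float(fn(np.asarray([self.mean]))[0])
        nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
        u = 0.5 * (nodes + 1.0)
        return float(np.sum(0.5 * weights * fn(self.ppf(u))))


@dataclass(frozen=True)
class ObserverParams:
    """Psychometric observer of one participant in one condition.

    mu: true threshold (PSE, deg); sigma: spread (deg); lapse_low: yes
    floor at large deviations; lapse_high: 1 - yes ceiling at zero
    deviation; mode_shift: additive PSE shift on converging trials (deg).
    """

    mu: float
    sigma: float
    lapse_low: float = 0.0
    lapse_high: float = 0.0
    mode_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma <= 0:
            raise CalibrationError("mu and sigma must be positive")
        if not (0 <= self.lapse_low <= 0.15 and 0 <= self.lapse_high <= 0.15):
            raise CalibrationError("lapse rates must lie in [0, 0.15]")

    @property
    def slope(self) -> float:
        return 1.0 / self.sigma


@dataclass(frozen=True)
class AgentParams:
    """Motor agent of one participant for one effector."""

    compensation_gain: float
    motor_noise_sd: float  # deg, endpoint angular noise
    blind_noise_sd: float  # mm, isotropic endpoint noise without feedback
    blind_bias: float = 0.0  # mm, radial bias of blind reaches
    movement_duration: float = 1.2  # s
    correction_lag: float = 0.0  # s after deviation onset before correcting
    response_time_mean: float = 1.2  # s

    def __post_init__(self) -> None:
        if not 0 <= self.compensation_gain <= 1:
            raise CalibrationError("compensation_gain must lie in [0, 1]")
        if self.motor_noise_sd < 0 or self.blind_noise_sd < 0:
            raise CalibrationError("noise SDs must be >= 0")
        if self.movement_duration <= 0:
            raise CalibrationError("movement_duration must be positive")


@dataclass(frozen=True)
class Participant:
    """Sampled generative parameters of one synthetic participant."""

    pid: str
    observers: dict[tuple[Effector, Task], ObserverParams]
    agents: dict[Effector, AgentParams]


@dataclass(frozen=True)
class CohortCalibration:
    """Population distributions of the generative parameters.

    `observer_mu` / `observer_slope` are keyed by (effector, task);
    agent distributions by effector. `latent_strength` is the
    correlation of the underlying normals of mu (and of slope) across
    conditions within a participant.
    """

    n_participants: int = 20
    observer_mu: dict[tuple[Effector, Task], ParamDist] = field(default_factory=dict)
    observer_slope: dict[tuple[Effector, Task], ParamDist] = field(default_factory=dict)
    lapse_high: dict[Effector, float] = field(default_factory=dict)
    mode_shift_deg: float = 3.0
    agent_gain: dict[Effector, ParamDist] = field(default_factory=dict)
    agent_motor_noise: dict[Effector, ParamDist] = field(default_factory=dict)
    agent_blind_noise: dict[Effector, ParamDist] = field(default_factory=dict)
    agent_duration: dict[Effector, ParamDist] = field(default_factory=dict)
    response_time_mean_s: dict[Effector, float] = field(default_factory=dict)
    latent_strength: float = 0.75

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise CalibrationError("n_participants must be >= 2")
        if not 0 <= self.latent_strength < 1:
            raise CalibrationError("latent_strength must lie in [0, 1)")


# ---------------------------------------------------------------------------
# default calibration


# published group summaries used as generative targets: threshold and
# slope (mean, SD across participants) per effector x task
_TABLE_MU = {
    (Effector.HAND, Task.SINGLE): (26.81, 12.33),
    (Effector.HAND, Task.DUAL): (22.86, 8.07),
    (Effector.FULL_BODY, Task.SINGLE): (22.01, 9.21),
    (Effector.FULL_BODY, Task.DUAL): (20.57, 6.77),
}
_TABLE_SLOPE = {
    (Effector.HAND, Task.SINGLE): (0.077, 0.035),
    (Effector.HAND, Task.DUAL): (0.070, 0.025),
    (Effector.FULL_BODY, Task.SINGLE): (0.081, 0.040),
    (Effector.FULL_BODY, Task.DUAL): (0.078, 0.027),
}
#: control-trial self-attribution rates the lapse ceilings are solved for
CONTROL_YES_TARGET = {Effector.HAND: 0.913, Effector.FULL_BODY: 0.899}
#: blind-reaching mean endpoint errors (mm) the noise SDs are solved for
BLIND_ERROR_TARGET_MM = {Effector.HAND: 26.0, Effector.FULL_BODY: 18.0}
BLIND_ERROR_SD_MM = {Effector.HAND: 9.0, Effector.FULL_BODY: 6.0}
# visually guided endpoint angle errors, deg (mean unsigned error)
_GUIDED_ANGLE_ERROR = {Effector.HAND: 2.5, Effector.FULL_BODY: 4.0}

_MU_BOUNDS = (2.0, 60.0)
_SLOPE_BOUNDS = (0.02, 0.25)


def _mean_control_phi(cal_mu: ParamDist, cal_slope: ParamDist) -> float:
    """E[Phi(mu * slope)] over independent truncated-normal mu, slope."""

    def outer(mus: np.ndarray) -> np.ndarray:
        return np.array(
            [
                cal_slope.expect(lambda sl, m=m: sps.norm.cdf(m * sl))
                for m in np.atleast_1d(mus)
            ]
        )

    return cal_mu.expect(outer)


def expected_control_yes_rate(
    calibration: CohortCalibration, effector: Effector | str
) -> float:
    """Analytic population control-trial yes rate, pooled over tasks."""
    effector = Effector(effector)
    lam = calibration.lapse_high[effector]
    vals = [
        _mean_control_phi(
            calibration.observer_mu[(effector, task)],
            calibration.observer_slope[(effector, task)],
        )
        for task in (Task.SINGLE, Task.DUAL)
    ]
    return (1.0 - lam) * float(np.mean(vals))


def expected_blind_error(
    calibration: CohortCalibration, effector: Effector | str
) -> float:
    """Analytic population mean blind-reach error, mm.

    For isotropic Gaussian endpoint noise with SD s and radial bias b the
    per-trial error is Rice distributed with mean s * sqrt(pi/2) *
    L_{1/2}(-b^2 / 2 s^2); with the default zero bias this reduces to the
    Rayleigh mean s * sqrt(pi/2), averaged over the truncated-normal
    population distribution of s.
    """
    effector = Effector(effector)
    dist = calibration.agent_blind_noise[effector]
    # bias is 0 in the default model: Rayleigh mean, exact and fast
    return dist.expect(lambda s: s * _RAYLEIGH_MEAN)


def solve_lapse_high(
    target_rate: float,
    mu_dists: list[ParamDist],
    slope_dists: list[ParamDist],
) -> float:
    """Lapse ceiling reproducing a target control-trial yes rate."""
    phi = float(np.mean([_mean_control_phi(m, s) for m, s in zip(mu_dists, slope_dists)]))
    lam = 1.0 - target_rate / phi
    if not 0 <= lam <= 0.15:
        raise CalibrationError(
            f"required lapse_high {lam:.3f} outside [0, 0.15]; "
            "target control yes rate infeasible under this calibration"
        )
    return lam


def default_calibration(n_participants: int = 20) -> CohortCalibration:
    """Cohort calibration matching the study's published summaries."""
    observer_mu = {
        key: ParamDist(m, s, *_MU_BOUNDS) for key, (m, s) in _TABLE_MU.items()
    }
    observer_slope = {
        key: ParamDist(m, s, *_SLOPE_BOUNDS) for key, (m, s) in _TABLE_SLOPE.items()
    }
    lapse_high = {
        eff: solve_lapse_high(
            CONTROL_YES_TARGET[eff],
            [observer_mu[(eff, t)] for t in (Task.SINGLE, Task.DUAL)],
            [observer_slope[(eff, t)] for t in (Task.SINGLE, Task.DUAL)],
        )
        for eff in (Effector.HAND, Effector.FULL_BODY)
    }
    # blind-reach noise from the Rayleigh mean relation: E|err| = s sqrt(pi/2)
    agent_blind_noise = {
        eff: ParamDist(
            BLIND_ERROR_TARGET_MM[eff] / _RAYLEIGH_MEAN,
            BLIND_ERROR_SD_MM[eff] / _RAYLEIGH_MEAN,
            2.0,
            60.0,
        )
        for eff in (Effector.HAND, Effector.FULL_BODY)
    }
    # angular noise from the folded-normal mean: E|eps| = sd sqrt(2/pi)
    agent_motor_noise = {
        eff: ParamDist(_GUIDED_ANGLE_ERROR[eff] * _RAYLEIGH_MEAN, 0.6, 0.3, 12.0)
        for eff in (Effector.HAND, Effector.FULL_BODY)
    }
    return CohortCalibration(
        n_participants=n_participants,
        observer_mu=observer_mu,
        observer_slope=observer_slope,
        lapse_high=lapse_high,
        mode_shift_deg=3.0,
        agent_gain={
            Effector.HAND: ParamDist(0.85, 0.08, 0.3, 1.0),
            Effector.FULL_BODY: ParamDist(0.82, 0.08, 0.3, 1.0),
        },
        agent_motor_noise=agent_motor_noise,
        agent_blind_noise=agent_blind_noise,
        agent_duration={
            Effector.HAND: ParamDist(1.0, 0.15, 0.5, 2.5),
            Effector.FULL_BODY: ParamDist(1.5, 0.2, 0.6, 3.0),
        },
        response_time_mean_s={Effector.HAND: 1.1, Effector.FULL_BODY: 1.4},
        latent_strength=0.75,
    )


# ---------------------------------------------------------------------------
# sampling


_CONDITIONS = [
    (eff, task)
    for eff in (Effector.HAND, Effector.FULL_BODY)
    for task in (Task.SINGLE, Task.DUAL)
]


def _copula_draw(
    rng: np.random.Generator, n: int, n_conditions: int, strength: float
) -> np.ndarray:
    """Correlated uniforms, shape (n, n_conditions): Gaussian copula with a
    single shared latent factor of the given correlation."""
    z = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, n_conditions))
    x = math.sqrt(strength) * z + math.sqrt(1.0 - strength) * eps
    return sps.norm.cdf(x)


def sample_cohort(
    calibration: CohortCalibration, seed: int | np.random.Generator = 0
) -> list[Participant]:
    """Draw a cohort of synthetic participants.

    Stream order (fixed, documented): mu copula, slope copula, then per
    effector gain, motor noise, blind noise, duration uniforms.
    Marginals are exactly truncated normal; the shared latent factor
    correlates mu (and slope) across conditions at `latent_strength`.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = calibration.n_participants
    u_mu = _copula_draw(rng, n, len(_CONDITIONS), calibration.latent_strength)
    u_slope = _copula_draw(rng, n, len(_CONDITIONS), calibration.latent_strength)
    mus = {
        cond: calibration.observer_mu[cond].ppf(u_mu[:, j])
        for j, cond in enumerate(_CONDITIONS)
    }
    slopes = {
        cond: calibration.observer_slope[cond].ppf(u_slope[:, j])
        for j, cond in enumerate(_CONDITIONS)
    }
    agent_draws: dict[tuple[Effector, str], np.ndarray] = {}
    for eff in (Effector.HAND, Effector.FULL_BODY):
        for name, dist in (
            ("gain", calibration.agent_gain[eff]),
            ("motor", calibration.agent_motor_noise[eff]),
            ("blind", calibration.agent_blind_noise[eff]),
            ("duration", calibration.agent_duration[eff]),
        ):
            agent_draws[(eff, name)] = dist.ppf(rng.uniform(size=n))

    participants = []
    for i in range(n):
        observers = {
            cond: ObserverParams(
                mu=float(mus[cond][i]),
                sigma=1.0 / float(slopes[cond][i]),
                lapse_low=0.0,
                lapse_high=calibration.lapse_high[cond[0]],
                mode_shift=calibration.mode_shift_deg,
            )
            for cond in _CONDITIONS
        }
        agents = {
            eff: AgentParams(
                compensation_gain=float(agent_draws[(eff, "gain")][i]),
                motor_noise_sd=float(agent_draws[(eff, "motor")][i]),
                blind_noise_sd=float(agent_draws[(eff, "blind")][i]),
                blind_bias=0.0,
                movement_duration=float(agent_draws[(eff, "duration")][i]),
                correction_lag=0.0,
                response_time_mean=calibration.response_time_mean_s[eff],
            )
            for eff in (Effector.HAND, Effector.FULL_BODY)
        }
        participants.append(
            Participant(pid=f"p{i:02d}", observers=observers, agents=agents)
        )
    return participants


# ---------------------------------------------------------------------------
# trial-level simulation


def yes_probability(
    deviation_deg: float, mode: Mode | str, obs: ObserverParams
) -> float:
    """P(yes | trial): descending cumulative Gaussian of |deviation| with
    lapses; converging trials get the additive threshold shift."""
    d = abs(deviation_deg)
    mu_eff = obs.mu + (obs.mode_shift if Mode(mode) == Mode.CONVERGING else 0.0)
    core = 1.0 - sps.norm.cdf((d - mu_eff) / obs.sigma)
    return float(obs.lapse_low + (1.0 - obs.lapse_low - obs.lapse_high) * core)


def simulate_response(
    trial: TrialSpec, obs: ObserverParams, rng: np.random.Generator
) -> bool:
    """One yes/no self-attribution response."""
    return bool(rng.uniform() < yes_probability(trial.deviation_deg, trial.mode, obs))


#: fraction of the target radius by which simulated paths overshoot, so
#: the target-radius crossing always exists even under angular noise
_OVERSHOOT = 1.15
_HOLD_S = 0.8  # stationary tail so the stillness completion rule can fire


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _solve_tau_cross(overshoot: float) -> float:
    """Phase of the minimum-jerk profile at which the target radius is
    crossed, i.e. min_jerk(tau) == 1/overshoot."""
    from scipy.optimize import brentq

    return float(brentq(lambda tau: _min_jerk(tau) - 1.0 / overshoot, 0.0, 1.0))


#: the profile is time-scaled so the target-radius crossing occurs at
#: `movement_duration`; deceleration into the overshoot takes the rest
TAU_CROSS = _solve_tau_cross(_OVERSHOOT)


def simulate_trajectory(
    trial: TrialSpec,
    agent: AgentParams,
    geometry: TaskGeometry,
    rng: np.random.Generator,
) -> Trajectory:
    """One reaching trajectory under rotated visual feedback.

    The effector heads straight at the target with a minimum-jerk
    radial profile. Once the path crosses the deviation onset (plus the
    correction lag) the heading rotates by -gain * deviation (plus the
    trial's angular endpoint noise), i.e. the agent cancels the fraction
    `gain` of the imposed cursor rotation. A stationary tail is appended
    so completion detection can operate.
    """
    theta_t = target_bearing(geometry, trial.target_side)
    eps = rng.normal(0.0, agent.motor_noise_sd) if agent.motor_noise_sd > 0 else 0.0
    alpha = trial.deviation_deg
    d = agent.movement_duration
    fs = geometry.sampling_rate_hz
    path_len = geometry.target_radius_mm * _OVERSHOOT
    r0 = geometry.deviation_onset_mm

    total = d / TAU_CROSS  # movement ends here; target radius crossed at d
    n_move = int(np.ceil(total * fs)) + 1
    t = np.arange(0, n_move + int(np.ceil(_HOLD_S * fs))) / fs
    s = path_len * _min_jerk(np.clip(t / total, 0.0, 1.0))  # arc length along path

    theta_pre = theta_t
    theta_post = theta_t - agent.compensation_gain * alpha + eps
    lag_extra = 0.0
    if agent.correction_lag > 0:
        # arc length travelled during the lag approximated at peak speed
        lag_extra = agent.correction_lag * 1.875 * path_len / d
    s_turn = min(r0 + lag_extra, path_len)

    u_pre = np.array([math.sin(math.radians(theta_pre)), math.cos(math.radians(theta_pre))])
    u_post = np.array(
        [math.sin(math.radians(theta_post)), math.cos(math.radians(theta_post))]
    )
    turn_point = s_turn * u_pre
    xy = np.where(
        (s <= s_turn)[:, None],
        s[:, None] * u_pre,
        turn_point[None, :] + (s - s_turn)[:, None] * u_post,
    )
    return Trajectory(t=t, xy=xy, trial=trial)


def simulate_blind_reach(
    agent: AgentParams, target: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Endpoint of one blind reach: target + isotropic Gaussian noise,
    plus an optional radial bias along the target direction."""
    target = np.asarray(target, dtype=float)
    endpoint = target + rng.normal(0.0, agent.blind_noise_sd, size=2)
    if agent.blind_bias != 0.0:
        endpoint = endpoint + agent.blind_bias * target / np.hypot(*target)
    return endpoint


# ---------------------------------------------------------------------------
# full study assembly


@dataclass
class StudyData:
    """In-memory synthetic study: trial table, blind reaches, trajectories,
    and the ground-truth parameter sidecar."""

    trials: pd.DataFrame
    blind: pd.DataFrame
    trajectories: Optional[list[tuple[str, Trajectory]]]  # (participant, trajectory)
    truth: dict
    seed: int


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(
    calibration: Optional[CohortCalibration] = None,
    geometry: Optional[TaskGeometry] = None,
    seed: int = 0,
    include_trajectories: bool = True,
    out_dir: Optional[str | Path] = None,
) -> StudyData:
    """Simulate the full two-effector study.

    Per participant: one 88-trial sub-block per effector x task (responses,
    response times, and optionally trajectories) plus 60 blind reaches per
    effector. Deterministic given `seed`; when `out_dir` is given, writes
    trials.csv, blind_reaching.csv, trajectories.jsonl and truth.json.
    """
    calibration = calibration or default_calibration()
    geometry = geometry or TaskGeometry()
    root = np.random.SeedSequence(seed)
    ss_cohort, ss_trials = root.spawn(2)
    participants = sample_cohort(calibration, np.random.default_rng(ss_cohort))
    targets = target_positions(geometry)

    trial_rows: list[dict] = []
    blind_rows: list[dict] = []
    trajectories = [] if include_trajectories else None

    for participant, ss_p in zip(participants, ss_trials.spawn(len(participants))):
        rng = np.random.default_rng(ss_p)
        for cond_index, (eff, task) in enumerate(_CONDITIONS):
            obs = participant.observers[(eff, task)]
            agent = participant.agents[eff]
            block = build_subblock(
                eff, task, geometry, seed=(_child_seed(ss_p) + cond_index) % (2**31)
            )
            for trial in block.trials:
                yes = simulate_response(trial, obs, rng)
                rt = max(0.2, rng.normal(agent.response_time_mean, 0.3))
                trial_rows.append(
                    {
                        "participant": participant.pid,
                        "effector": eff.value,
                        "task": task.value,
                        "trial_index": trial.trial_index,
                        "target_side": trial.target_side.value,
                        "deviation_deg": trial.deviation_deg,
                        "mode": trial.mode.value,
                        "response_yes": int(yes),
                        "response_time_s": round(rt, 4),
                    }
                )
                if include_trajectories:
                    traj = simulate_trajectory(trial, agent, geometry, rng)
                    trajectories.append((participant.pid, traj))
        for eff in (Effector.HAND, Effector.FULL_BODY):
            agent = participant.agents[eff]
            for k in range(N_BLIND_TRIALS):
                side = TargetSide.LEFT if k % 2 == 0 else TargetSide.RIGHT
                endpoint = simulate_blind_reach(agent, targets[side], rng)
                blind_rows.append(
                    {
                        "participant": participant.pid,
                        "effector": eff.value,
                        "trial_index": k,
                        "target_side": side.value,
                        "endpoint_x_mm": round(float(endpoint[0]), 6),
                        "endpoint_y_mm": round(float(endpoint[1]), 6),
                    }
                )

    truth = {
        "seed": seed,
        "participants": {
            p.pid: {
                "observers": {
                    f"{eff.value}:{task.value}": asdict(p.observers[(eff, task)])
                    for eff, task in _CONDITIONS
                },
                "agents": {eff.value: asdict(p.agents[eff]) for eff in p.agents},
            }
            for p in participants
        },
    }
    data = StudyData(
        trials=pd.DataFrame(trial_rows),
        blind=pd.DataFrame(blind_rows),
        trajectories=trajectories,
        truth=truth,
        seed=seed,
    )
    if out_dir is not None:
        write_study(data, out_dir, geometry)
    return data


def write_study(data: StudyData, out_dir: str | Path, geometry: TaskGeometry) -> None:
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        data.trials.to_csv(out / "trials.csv", index=False)
        data.blind.to_csv(out / "blind_reaching.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(data.truth, fh, indent=1)
        with open(out / "geometry.json", "w") as fh:
            json.dump(asdict(geometry), fh, indent=1)
        if data.trajectories is not None:
            with open(out / "trajectories.jsonl", "w") as fh:
                for pid, traj in data.trajectories:
                    rec = {
                        "participant": pid,
                        "trial": {
                            "trial_index": traj.trial.trial_index,
                            "effector": traj.trial.effector.value,
                            "task": traj.trial.task.value,
                            "target_side": traj.trial.target_side.value,
                            "deviation_deg": traj.trial.deviation_deg,
                        },
                        "t": np.round(traj.t, 5).tolist(),
                        "x": np.round(traj.xy[:, 0], 4).tolist(),
                        "y": np.round(traj.xy[:, 1], 4).tolist(),
                    }
                    fh.write(json.dumps(rec) + "\n")
    except OSError as err:
        raise OSError(f"failed writing study files under {out}: {err}") from err


def read_trajectories(path: str | Path) -> Iterator[tuple[str, Trajectory]]:
    """Stream (participant id, Trajectory) pairs from a trajectories.jsonl."""
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            tr = rec["trial"]
            trial = TrialSpec(
                trial_index=tr["trial_index"],
                effector=Effector(tr["effector"]),
                task=Task(tr["task"]),
                target_side=TargetSide(tr["target_side"]),
                deviation_deg=float(tr["deviation_deg"]),
            )
            yield rec["participant"], Trajectory(
                t=np.asarray(rec["t"]),
                xy=np.column_stack([rec["x"], rec["y"]]),
                trial=trial,
            )
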