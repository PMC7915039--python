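"""Seeded synthetic glove sensor trials and grasp-move-place trajectories.

This module stands in for the raw data of a sensor-glove training study:

* 10-second, 40 Hz, 10-channel (5 force + 5 flex) grasp trials organised
  into a per-subject training corpus (20 *hold* and 20 *tap* trials per
  grip — precision pinch, tri-pod, whole-hand — plus 5 *rest* trials);
* 120 Hz 3-D object-centre trajectories for a grasp-move-place task,
  organised per subject into three sessions (one per feedback mode) of
  pre (15) / training (30) / post (15) trial blocks.

The generator reproduces the statistical structure the downstream
analysis relies on: a steady hold plateau whose per-channel band defines
"secure" grasp, near-equal index/thumb force in pinch but weak thumb
opposition in tri-pod/whole-hand grips (so an analytical force-equilibrium
detector degrades there), and per-trial drift of the kinematic metrics
(improvement under feedback, mild fatigue decline without).

All randomness flows from a single master seed through counter-based
``numpy.random.SeedSequence`` derivation, so identical arguments produce
byte-identical output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Grip",
    "Protocol",
    "Block",
    "FeedbackMode",
    "SensorFrame",
    "GraspTrial",
    "TrainingCorpus",
    "ObjectTrajectory",
    "LearningParams",
    "TrialRecord",
    "SubjectSession",
    "StudyDataset",
    "generate_grasp_trial",
    "generate_training_corpus",
    "generate_task_trajectory",
    "generate_study",
    "BLOCK_SIZES",
    "METRICS",
    "V_MAX",
    "SENSOR_RATE",
    "CAMERA_RATE",
]

# ---------------------------------------------------------------------------
# Enumerations and constants
# ---------------------------------------------------------------------------


class Grip(str, Enum):
    PINCH = "pinch"
    TRIPOD = "tripod"
    WHOLE_HAND = "whole_hand"
    NONE = "none"


class Protocol(str, Enum):
    HOLD = "hold"
    TAP = "tap"
    REST = "rest"


class Block(str, Enum):
    PRE = "pre"
    TRAINING = "training"
    POST = "post"


class FeedbackMode(str, Enum):
    NF = "NF"   # no feedback
    IF = "IF"   # immediate feedback on secure-grasp detection
    IBF = "IBF"  # intentional-binding feedback (delay ramp 1 s -> 0 s)


V_MAX = 3.3           # sensor supply voltage, V
SENSOR_RATE = 40.0    # glove sampling rate, Hz
CAMERA_RATE = 120.0   # motion-capture sampling rate, Hz
TRIAL_DURATION = 10.0  # grasp trial length, s

DIGITS = ("thumb", "index", "middle", "ring", "little")
GRIP_DIGITS = {
    Grip.PINCH: (0, 1),
    Grip.TRIPOD: (0, 1, 2),
    Grip.WHOLE_HAND: (0, 1, 2, 3, 4),
}

# Plateau shape: logistic rise/fall envelope; the 5 s hold window sits
# well inside the plateau so edge frames stay within the labeling band.
_HOLD_ON = 1.8      # s, envelope midpoint of the rise
_HOLD_OFF = 8.2     # s, envelope midpoint of the fall
_HOLD_TAU = 0.08    # s, logistic time constant
_WINDOW = (2.5, 7.5)  # s, annotated steady-hold window

FORCE_LEVEL = 2.0   # V, nominal force plateau for a firmly engaged digit
FLEX_LEVEL = 1.5    # V, nominal flex plateau for an engaged digit
# per-digit engagement multipliers (thumb..little)
_DIGIT_GAIN = np.array([1.0, 1.0, 0.95, 0.90, 0.85])
THUMB_OPPOSITION_FRACTION = 0.15  # thumb force fraction in tri-pod / whole-hand
_TRIAL_GAIN_SD = 0.02    # common per-trial amplitude jitter (fraction)
_COMMON_DRIFT_AMP = 0.015  # slow common-mode plateau drift (fraction)
_PINCH_DIFF_AMP = 0.025   # anti-phase index/thumb drift; keeps the pair within 5 %
DEFAULT_NOISE_SD = 0.02 * FORCE_LEVEL  # additive voltage noise, 2 % of plateau
REST_NOISE_SD = 0.005 * V_MAX          # rest-trial noise floor

METRICS = ("completion_time", "pathlength", "placement_error")
BLOCK_SIZES = {Block.PRE: 15, Block.TRAINING: 30, Block.POST: 15}

MODES = (FeedbackMode.NF, FeedbackMode.IF, FeedbackMode.IBF)


def _sub_seed(seed: int, *key: int) -> np.random.SeedSequence:
    """Counter-based child seed: reproducible and order-independent."""
    return np.random.SeedSequence([int(seed), *[int(k) for k in key]])


# ---------------------------------------------------------------------------
# Sensor-trial types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorFrame:
    """One 25 ms sample of the 10 glove channels."""

    t: float
    force: np.ndarray  # (5,) V, thumb..little
    flex: np.ndarray   # (5,) V, thumb..little

    @property
    def volts(self) -> np.ndarray:
        return np.concatenate([self.force, self.flex])


@dataclass
class GraspTrial:
    """A 10 s, 40 Hz glove recording with grip/protocol tags.

    ``volts`` is (n_frames, 10): columns 0-4 force, 5-9 flex, digit order
    thumb..little.  ``hold_window`` is an inclusive (start, end) frame
    index pair annotating the steady hold, present only for hold trials.
    """

    grip: Grip
    protocol: Protocol
    t: np.ndarray
    volts: np.ndarray
    hold_window: tuple[int, int] | None
    seed: int
    v_max: float = V_MAX

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def frame(self, i: int) -> SensorFrame:
        return SensorFrame(float(self.t[i]), self.volts[i, :5].copy(),
                           self.volts[i, 5:].copy())

    @property
    def force(self) -> np.ndarray:
        return self.volts[:, :5]

    @property
    def flex(self) -> np.ndarray:
        return self.volts[:, 5:]


@dataclass
class TrainingCorpus:
    """All grasp trials recorded for one subject in one glove session."""

    subject_id: str
    trials: list[GraspTrial]

    def by_protocol(self, protocol: Protocol) -> list[GraspTrial]:
        return [tr for tr in self.trials if tr.protocol == protocol]

    def by_grip(self, grip: Grip) -> list[GraspTrial]:
        return [tr for tr in self.trials if tr.grip == grip]


# ---------------------------------------------------------------------------
# Sensor-trial generation
# ---------------------------------------------------------------------------


def _hold_envelope(t: np.ndarray) -> np.ndarray:
    rise = 1.0 / (1.0 + np.exp(-(t - _HOLD_ON) / _HOLD_TAU))
    fall = 1.0 / (1.0 + np.exp((t - _HOLD_OFF) / _HOLD_TAU))
    return rise * fall


def _tap_envelope(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sum of short (< 0.5 s) contact bursts, one per tap."""
    centers = np.linspace(1.5, 8.5, 8) + rng.uniform(-0.1, 0.1, 8)
    amps = rng.uniform(0.5, 1.0, 8)
    env = np.zeros_like(t)
    for c, a in zip(centers, amps):
        env += a * np.exp(-0.5 * ((t - c) / 0.08) ** 2)
    return np.clip(env, 0.0, 1.0)


def generate_grasp_trial(
    grip: Grip | str,
    protocol: Protocol | str,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    *,
    thumb_fraction: float = THUMB_OPPOSITION_FRACTION,
    v_max: float = V_MAX,
    rate: float = SENSOR_RATE,
) -> GraspTrial:
    """Generate one 10 s glove trial.

    Hold trials show a rise -> plateau -> fall on the grip's active
    channels with a 5 s annotated hold window; tap trials show short
    contact bursts; rest trials are baseline noise only.  For pinch, the
    index and thumb force plateaus are constructed within 5 % of each
    other (anti-phase slow drift); for tri-pod and whole-hand the thumb
    plateau is ``thumb_fraction`` of the opposing digits' level, which is
    what defeats a thumb-opposition equilibrium test on those grips.
    """
    grip = Grip(grip)
    protocol = Protocol(protocol)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if protocol == Protocol.REST and grip != Grip.NONE:
        raise ValueError("rest trials must use grip='none'")
    if protocol != Protocol.REST and grip == Grip.NONE:
        raise ValueError(f"protocol {protocol.value!r} requires a real grip")

    n = int(round(TRIAL_DURATION * rate)) + 1
    t = np.arange(n) / rate
    volts = np.zeros((n, 10))
    rng = np.random.default_rng(_sub_seed(seed, 0))
    # noise scales with each channel's engagement level (with a floor for
    # idle channels), so "noise_sd" is the SD on a fully engaged channel
    # and a weakly opposed thumb stays labelable within its own band
    sigma = np.full(10, 0.25)

    hold_window = None
    if protocol != Protocol.REST:
        digits = GRIP_DIGITS[grip]
        env = (_hold_envelope(t) if protocol == Protocol.HOLD
               else _tap_envelope(t, rng))
        gain = 1.0 + rng.normal(0.0, _TRIAL_GAIN_SD)
        common = 1.0 + _COMMON_DRIFT_AMP * np.sin(
            2 * np.pi * rng.uniform(0.4, 0.8) * t + rng.uniform(0, 2 * np.pi))
        # anti-phase index/thumb load sharing: the pair trades force back
        # and forth as the grip micro-adjusts, dwelling near the extremes
        # (saturated sine), while the instantaneous ratio stays within
        # 2*amp/(1+amp) ~ 4.9 % by construction
        diff = _PINCH_DIFF_AMP * np.tanh(2.5 * np.sin(
            2 * np.pi * rng.uniform(0.4, 0.8) * t
            + rng.uniform(0, 2 * np.pi))) / np.tanh(2.5)
        for d in digits:
            level = FORCE_LEVEL * _DIGIT_GAIN[d] * gain
            chan = level * env * common
            frac = _DIGIT_GAIN[d]
            if grip == Grip.PINCH:
                if d == 0:
                    chan = chan * (1.0 - diff)
                elif d == 1:
                    chan = chan * (1.0 + diff)
            elif d == 0:
                chan = chan * thumb_fraction
                frac *= thumb_fraction
            volts[:, d] = chan
            volts[:, 5 + d] = FLEX_LEVEL * _DIGIT_GAIN[d] * gain * env * common
            sigma[d] = max(0.25, frac)
            sigma[5 + d] = _DIGIT_GAIN[d]
        if protocol == Protocol.HOLD:
            i0 = int(np.searchsorted(t, _WINDOW[0]))
            i1 = int(np.searchsorted(t, _WINDOW[1], side="right")) - 1
            hold_window = (i0, i1)

    if noise_sd > 0:
        if protocol == Protocol.REST:
            sigma[:] = 1.0
        volts = volts + rng.normal(0.0, 1.0, volts.shape) \
            * (noise_sd * sigma)[None, :]
    volts = np.clip(volts, 0.0, v_max)

    return GraspTrial(grip=grip, protocol=protocol, t=t, volts=volts,
                      hold_window=hold_window, seed=int(seed), v_max=v_max)


def generate_training_corpus(
    subject_id: str,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    *,
    n_hold: int = 20,
    n_tap: int = 20,
    n_rest: int = 5,
    thumb_fraction: float = THUMB_OPPOSITION_FRACTION,
) -> TrainingCorpus:
    """One subject's glove-training corpus.

    Default composition: 20 hold + 20 tap trials for each of the three
    grips plus 5 rest trials (125 trials).  Rest trials use the rest
    noise floor (0.5 % of v_max) unless ``noise_sd`` is zero.
    """
    grips = (Grip.PINCH, Grip.TRIPOD, Grip.WHOLE_HAND)
    trials: list[GraspTrial] = []
    counter = 0
    for protocol, count in ((Protocol.HOLD, n_hold), (Protocol.TAP, n_tap)):
        for grip in grips:
            for _ in range(count):
                sub = int(_sub_seed(seed, counter).generate_state(1)[0] % (2**31))
                trials.append(generate_grasp_trial(
                    grip, protocol, noise_sd, sub,
                    thumb_fraction=thumb_fraction))
                counter += 1
    rest_sd = 0.0 if noise_sd == 0 else max(noise_sd, REST_NOISE_SD)
    for _ in range(n_rest):
        sub = int(_sub_seed(seed, counter).generate_state(1)[0] % (2**31))
        trials.append(generate_grasp_trial(Grip.NONE, Protocol.REST,
                                           rest_sd, sub))
        counter += 1
    return TrainingCorpus(subject_id=subject_id, trials=trials)


# ---------------------------------------------------------------------------
# Task-trajectory types
# ---------------------------------------------------------------------------


@dataclass
class ObjectTrajectory:
    """Timestamped 3-D object-centre positions for one task trial.

    ``table_plane`` is (point, unit normal); ``configured`` records the
    metric triple the trajectory was constructed to realise, which the
    kinematic scoring should recover (exactly for placement error, to
    within resampling tolerance for time and pathlength).
    """

    timestamps: np.ndarray        # (n,) s
    positions: np.ndarray         # (n, 3) m
    target_center: np.ndarray     # (3,) m, on the table plane
    table_point: np.ndarray       # (3,) m
    table_normal: np.ndarray      # (3,) unit
    trial_index: int
    block: Block
    feedback_mode: FeedbackMode
    configured: dict[str, float] = field(default_factory=dict)


@dataclass
class LearningParams:
    """Effect structure of the feedback-training study.

    Metric keys are ``completion_time`` (s), ``pathlength`` (m),
    ``placement_error`` (m).  Slopes are metric units per training trial
    (negative = improvement, the no-feedback mode carries a positive
    fatigue slope); post effects are post-block minus pre-block means in
    metric units.  ``*_sd`` entries are between-subject SDs of the
    corresponding quantity and ``trial_sd`` is within-subject per-trial
    noise.  Defaults emulate a 17-subject able-bodied cohort.
    """

    baseline_mean: dict[str, float]
    baseline_cv: dict[str, float]
    trial_sd: dict[str, float]
    slope: dict[FeedbackMode, dict[str, float]]
    slope_sd: dict[str, float]
    post_effect: dict[FeedbackMode, dict[str, float]]
    post_effect_sd: dict[str, float]

    @classmethod
    def default(cls) -> "LearningParams":
        return cls(
            baseline_mean={"completion_time": 1.48, "pathlength": 0.25,
                           "placement_error": 0.0056},
            baseline_cv={"completion_time": 0.24, "pathlength": 0.07,
                         "placement_error": 0.12},
            trial_sd={"completion_time": 0.13, "pathlength": 0.010,
                      "placement_error": 0.0015},
            slope={
                FeedbackMode.NF: {"completion_time": 0.0067,
                                  "pathlength": 2.64e-4,
                                  "placement_error": 2.40e-5},
                FeedbackMode.IF: {"completion_time": -0.0023,
                                  "pathlength": -1.15e-4,
                                  "placement_error": -1.32e-5},
                FeedbackMode.IBF: {"completion_time": -0.0048,
                                   "pathlength": -2.58e-4,
                                   "placement_error": -8.63e-6},
            },
            slope_sd={"completion_time": 0.0055, "pathlength": 2.3e-4,
                      "placement_error": 9.1e-5},
            post_effect={
                FeedbackMode.NF: {"completion_time": 0.0156,
                                  "pathlength": 0.0022,
                                  "placement_error": 8.65e-4},
                FeedbackMode.IF: {"completion_time": -0.0831,
                                  "pathlength": -0.0017,
                                  "placement_error": 1.81e-4},
                FeedbackMode.IBF: {"completion_time": -0.090,
                                   "pathlength": -0.0065,
                                   "placement_error": 7.06e-5},
            },
            post_effect_sd={"completion_time": 0.126, "pathlength": 0.0072,
                            "placement_error": 0.0015},
        )

    @classmethod
    def noiseless(cls, **overrides) -> "LearningParams":
        """Defaults with every random component switched off."""
        p = cls.default()
        zero = {m: 0.0 for m in METRICS}
        p.baseline_cv = dict(zero)
        p.trial_sd = dict(zero)
        p.slope_sd = dict(zero)
        p.post_effect_sd = dict(zero)
        for key, val in overrides.items():
            setattr(p, key, val)
        return p

    def validate(self) -> None:
        for m in METRICS:
            if self.baseline_mean[m] <= 0:
                raise ValueError(f"baseline mean for {m} must be > 0")
            if self.trial_sd[m] < 0:
                raise ValueError(f"trial SD for {m} must be >= 0")

    def draw_subject(self, rng: np.random.Generator) -> "LearningParams":
        """Resolve between-subject random effects into a subject-level copy."""
        sub = copy.deepcopy(self)
        for m in METRICS:
            scale = 1.0 + rng.normal(0.0, self.baseline_cv[m])
            sub.baseline_mean[m] = max(0.2 * self.baseline_mean[m],
                                       self.baseline_mean[m] * scale)
            sub.baseline_cv[m] = 0.0
        for mode in MODES:
            for m in METRICS:
                sub.slope[mode][m] += rng.normal(0.0, self.slope_sd[m])
                sub.post_effect[mode][m] += rng.normal(
                    0.0, self.post_effect_sd[m])
        for m in METRICS:
            sub.slope_sd[m] = 0.0
            sub.post_effect_sd[m] = 0.0
        return sub

    def expected_value(self, metric: str, block: Block | str,
                       trial_index: int, mode: FeedbackMode | str) -> float:
        """Noise-free metric value for a given block position."""
        block = Block(block)
        mode = FeedbackMode(mode)
        base = self.baseline_mean[metric]
        if block == Block.TRAINING:
            return base + self.slope[mode][metric] * (trial_index - 1)
        if block == Block.POST:
            return base + self.post_effect[mode][metric]
        return base


# ---------------------------------------------------------------------------
# Task-trajectory generation
# ---------------------------------------------------------------------------

_START_OFFSET = 0.20   # m, start-to-target straight-line distance
_OBJECT_HALF_HEIGHT = 0.02  # m, object centre height at rest (4 cm cube)
_LIFT_HEIGHT = 0.02    # m, lift bump above the carry line
_REST_PAD = 0.3        # s of rest before and after the move
_MIN_MOVE_TIME = 0.4   # s, feasibility floor for completion time


def _minjerk(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _path_arclength(dist_vec, perp, normal, bow, n_quad=2001):
    """Arc length of the bowed lift path gamma(u), u in [0, 1]."""
    u = np.linspace(0.0, 1.0, n_quad)
    dgds = (dist_vec[None, :]
            + np.pi * np.cos(np.pi * u)[:, None]
            * (bow * perp + _LIFT_HEIGHT * normal)[None, :])
    return float(np.trapezoid(np.linalg.norm(dgds, axis=1), u))


def generate_task_trajectory(
    block: Block | str,
    trial_index: int,
    feedback_mode: FeedbackMode | str,
    params: LearningParams,
    seed: int = 0,
    *,
    rate: float = CAMERA_RATE,
) -> ObjectTrajectory:
    """Generate one grasp-move-place object trajectory.

    The path is a minimum-jerk point-to-point profile in the table plane
    with a 2 cm lift bump and a lateral bow whose amplitude is solved so
    the geometric arc length equals the trial's realised pathlength; the
    end point is offset from the target centre by the realised placement
    error.  Realised metrics are the learning-model expectation for this
    (block, trial, mode) plus zero-mean Gaussian per-trial noise, so
    kinematic scoring recovers the configured effect structure.
    """
    block = Block(block)
    mode = FeedbackMode(feedback_mode)
    params.validate()
    n_block = BLOCK_SIZES[block]
    if not 1 <= trial_index <= n_block:
        raise ValueError(
            f"trial_index {trial_index} outside {block.value} block "
            f"of {n_block} trials")

    rng = np.random.default_rng(_sub_seed(seed, 1))
    realized = {}
    for m in METRICS:
        mu = params.expected_value(m, block, trial_index, mode)
        sd = params.trial_sd[m]
        realized[m] = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    move_time = max(_MIN_MOVE_TIME, realized["completion_time"])
    err = max(0.0, realized["placement_error"])

    normal = np.array([0.0, 0.0, 1.0])
    table_point = np.zeros(3)
    target = np.zeros(3)                      # on the table plane
    z0 = _OBJECT_HALF_HEIGHT
    start = target + np.array([_START_OFFSET, 0.0, 0.0]) + z0 * normal
    theta = rng.uniform(0.0, 2 * np.pi)
    end = target + err * np.array([np.cos(theta), np.sin(theta), 0.0]) \
        + z0 * normal

    dist_vec = end - start
    d_hat = dist_vec / np.linalg.norm(dist_vec)
    perp = np.cross(normal, d_hat)
    perp /= np.linalg.norm(perp)

    min_len = _path_arclength(dist_vec, perp, normal, 0.0)
    pathlen = max(realized["pathlength"], min_len + 1e-9)
    realized["pathlength"] = pathlen
    realized["completion_time"] = move_time
    realized["placement_error"] = err
    if pathlen > min_len + 1e-12:
        hi = 0.05
        while _path_arclength(dist_vec, perp, normal, hi) < pathlen:
            hi *= 2.0
        bow = brentq(
            lambda a: _path_arclength(dist_vec, perp, normal, a) - pathlen,
            0.0, hi, xtol=1e-12)
    else:
        bow = 0.0

    total = 2 * _REST_PAD + move_time
    n = int(np.floor(total * rate)) + 1
    t = np.arange(n) / rate
    u = np.clip((t - _REST_PAD) / move_time, 0.0, 1.0)
    s = _minjerk(u)
    positions = (start[None, :] + s[:, None] * dist_vec[None, :]
                 + np.sin(np.pi * s)[:, None]
                 * (bow * perp + _LIFT_HEIGHT * normal)[None, :])

    return ObjectTrajectory(
        timestamps=t, positions=positions, target_center=target,
        table_point=table_point, table_normal=normal,
        trial_index=int(trial_index), block=block, feedback_mode=mode,
        configured=realized)


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    """One task trial: realised metric values plus optional trajectory."""

    subject_id: str
    feedback_mode: FeedbackMode
    block: Block
    trial_index: int
    metrics: dict[str, float]
    trajectory: ObjectTrajectory | None = None


@dataclass
class SubjectSession:
    subject_id: str
    feedback_mode: FeedbackMode
    trials: list[TrialRecord]
    subject_params: LearningParams


@dataclass
class StudyDataset:
    """All sessions of a feedback-training study (3 per subject)."""

    sessions: list[SubjectSession]
    params: LearningParams
    seed: int

    @property
    def subject_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.sessions:
            if s.subject_id not in seen:
                seen.append(s.subject_id)
        return seen

    def to_frame(self):
        """Long per-trial metrics table (pandas DataFrame)."""
        import pandas as pd

        rows = []
        for sess in self.sessions:
            for tr in sess.trials:
                rows.append({
                    "subject": tr.subject_id,
                    "mode": tr.feedback_mode.value,
                    "block": tr.block.value,
                    "trial": tr.trial_index,
                    **{m: tr.metrics[m] for m in METRICS},
                })
        return pd.DataFrame(rows)


def generate_study(
    n_subjects: int,
    params: LearningParams | None = None,
    seed: int = 0,
    *,
    with_trajectories: bool = False,
) -> StudyDataset:
    """Generate a full study: ``n_subjects`` x 3 sessions x 60 trials.

    Between-subject random effects (baseline scaling, slope and
    post-effect heterogeneity) are drawn per subject; within-subject
    trial noise is drawn per trial.  With ``with_trajectories=True`` each
    trial also carries a 120 Hz object trajectory realising its metric
    values, suitable for end-to-end kinematic scoring.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = params if params is not None else LearningParams.default()
    params.validate()

    sessions: list[SubjectSession] = []
    for si in range(n_subjects):
        subject_id = f"S{si + 1:02d}"
        sub_rng = np.random.default_rng(_sub_seed(seed, si, 0))
        sub_params = params.draw_subject(sub_rng)
        for mi, mode in enumerate(MODES):
            trials: list[TrialRecord] = []
            for bi, block in enumerate(
                    (Block.PRE, Block.TRAINING, Block.POST)):
                for k in range(1, BLOCK_SIZES[block] + 1):
                    trial_seed = int(_sub_seed(seed, si, mi, bi, k)
                                     .generate_state(1)[0] % (2**31))
                    if with_trajectories:
                        traj = generate_task_trajectory(
                            block, k, mode, sub_params, trial_seed)
                        metrics = dict(traj.configured)
                    else:
                        traj = None
                        rng = np.random.default_rng(_sub_seed(trial_seed, 1))
                        metrics = {}
                        for m in METRICS:
                            mu = sub_params.expected_value(m, block, k, mode)
                            sd = sub_params.trial_sd[m]
                            metrics[m] = mu + (rng.normal(0.0, sd)
                                               if sd > 0 else 0.0)
                        metrics["placement_error"] = max(
                            0.0, metrics["placement_error"])
                        metrics["completion_time"] = max(
                            _MIN_MOVE_TIME, metrics["completion_time"])
                    trials.append(TrialRecord(
                        subject_id=subject_id, feedback_mode=mode,
                        block=block, trial_index=k, metrics=metrics,
                        trajectory=traj))
            sessions.append(SubjectSession(
                subject_id=subject_id, feedback_mode=mode, trials=trials,
                subject_params=sub_params))
    return StudyDataset(sessions=sessions, params=params, seed=int(seed))
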