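"""Feedback scheduling and secure-grasp onset detection.

Three feedback modes are supported for the 30-trial training block:
no feedback (NF), immediate feedback (IF) on secure-grasp detection,
and intentional-binding feedback (IBF) in which the detection-to-beep
delay ramps linearly from 1 s on trial 1 to 0 s on the final trial —
a per-trial decrement of 1/29 s (~34 ms) for 30 trials.  Events are
simulation-time records: a 100 ms beep at detection time plus delay,
and an LED interval from beep onset until object release.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import AnnModel, predict, round_output
from .synth import FeedbackMode, GraspTrial, SENSOR_RATE

__all__ = [
    "FeedbackSchedule",
    "FeedbackEvent",
    "build_schedule",
    "detect_secure_onset",
    "emit_events",
    "BEEP_DURATION",
]

BEEP_DURATION = 0.100  # s


@dataclass
class FeedbackSchedule:
    """Per-trial detection-to-feedback delays for one training block."""

    mode: FeedbackMode
    n_trials: int
    delays: np.ndarray | None   # (n_trials,) s; None for NF

    def delay(self, trial_index: int) -> float:
        if not 1 <= trial_index <= self.n_trials:
            raise ValueError(
                f"trial_index {trial_index} outside schedule of "
                f"{self.n_trials} trials")
        if self.delays is None:
            raise ValueError("NF schedule defines no delays")
        return float(self.delays[trial_index - 1])


@dataclass
class FeedbackEvent:
    """One beep/LED emission within a trial's clock."""

    trial_index: int
    t_detect: float
    beep_onset: float
    beep_duration: float = BEEP_DURATION
    led_on: float | None = None
    led_off: float | None = None
    led_truncated: bool = False


def build_schedule(mode: FeedbackMode | str,
                   n_trials: int = 30) -> FeedbackSchedule:
    """Build the delay schedule for one training block.

    IBF: delay(k) = (n_trials - k) / (n_trials - 1) seconds — 1 s on the
    first trial, 0 s on the last, strictly decreasing in equal steps.
    """
    mode = FeedbackMode(mode)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if mode == FeedbackMode.NF:
        delays = None
    elif mode == FeedbackMode.IF:
        delays = np.zeros(n_trials)
    else:
        if n_trials < 2:
            raise ValueError("IBF ramp requires at least 2 trials")
        k = np.arange(1, n_trials + 1)
        delays = (n_trials - k) / (n_trials - 1)
    return FeedbackSchedule(mode=mode, n_trials=n_trials, delays=delays)


def detect_secure_onset(
    model: AnnModel,
    trial_stream: GraspTrial | np.ndarray,
    debounce_frames: int = 1,
    *,
    rate: float = SENSOR_RATE,
) -> float | None:
    """Timestamp of the first debounced run of secure-grasp predictions.

    Returns the time of the first frame beginning a run of at least
    ``debounce_frames`` consecutive frames whose rounded network output
    is 1, or None if no such run exists.  Detection is causal: the
    result depends only on frames at or before the returned time plus
    the debounce lookahead.
    """
    if debounce_frames < 1:
        raise ValueError("debounce_frames must be >= 1")
    if isinstance(trial_stream, GraspTrial):
        t = trial_stream.t
        volts = trial_stream.volts
    else:
        volts = np.atleast_2d(np.asarray(trial_stream, dtype=float))
        t = np.arange(len(volts)) / rate
    if len(volts) == 0:
        raise ValueError("empty stream")
    hits = round_output(predict(model, volts)).astype(bool)
    run = 0
    for i, h in enumerate(hits):
        run = run + 1 if h else 0
        if run >= debounce_frames:
            return float(t[i - debounce_frames + 1])
    return None


def emit_events(
    schedule: FeedbackSchedule,
    trial_index: int,
    t_detect: float | None,
    t_release: float | None = None,
) -> FeedbackEvent | None:
    """Construct the beep/LED event for one trial, if any.

    NF schedules (and undetected trials) emit nothing.  The beep starts
    at ``t_detect`` plus the trial's scheduled delay; the LED turns on
    with the beep and stays on until release.  If the delayed onset
    falls after release the event is emitted with an empty LED interval
    and flagged as truncated.
    """
    if not 1 <= trial_index <= schedule.n_trials:
        raise ValueError(
            f"trial_index {trial_index} outside schedule of "
            f"{schedule.n_trials} trials")
    if schedule.mode == FeedbackMode.NF or t_detect is None:
        return None
    if t_release is not None and t_release <= t_detect:
        raise ValueError("t_release must follow t_detect")
    onset = t_detect + schedule.delay(trial_index)
    truncated = t_release is not None and onset > t_release
    return FeedbackEvent(
        trial_index=trial_index,
        t_detect=float(t_detect),
        beep_onset=float(onset),
        led_on=float(onset),
        led_off=(float(onset) if truncated
                 else (float(t_release) if t_release is not None else None)),
        led_truncated=truncated)
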