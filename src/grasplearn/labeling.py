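"""Secure/insecure frame labeling and train/validation/test assembly.

A frame is "secure" when every *active* channel lies within a relative
band (default +-10 %) of its mean voltage over the steady hold period;
all other frames, including every frame of tap and rest trials that
falls outside the band, are "insecure".  The band is applied only to
channels whose hold mean clears an activity floor (default 5 % of
v_max); applying a relative band to near-zero channels would make it
degenerate.  Set ``activity_floor=0`` to force the band onto all 10
channels.

Hold statistics are pooled per grip across a subject's hold trials; tap
trials borrow the statistics of their own grip and rest trials borrow
the pinch statistics, so the one rule labels the whole corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import Grip, GraspTrial, Protocol, TrainingCorpus, V_MAX

__all__ = [
    "HoldStatistics",
    "LabeledDataset",
    "compute_hold_statistics",
    "pool_hold_statistics",
    "label_frames",
    "assemble_dataset",
    "SPLITS",
]

SPLITS = ("train", "val", "test")
DEFAULT_TOL = 0.10
DEFAULT_ACTIVITY_FLOOR = 0.05


@dataclass
class HoldStatistics:
    """Per-channel hold-window means and activity flags for one grip."""

    means: np.ndarray   # (10,) V
    active: np.ndarray  # (10,) bool
    v_max: float
    activity_floor: float

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


@dataclass
class LabeledDataset:
    """Pooled per-frame features with secure labels and split assignment."""

    features: np.ndarray   # (N, 10) V
    labels: np.ndarray     # (N,) uint8, 1 = secure
    split: np.ndarray      # (N,) str in {train, val, test}
    trial_id: np.ndarray   # (N,) int, index into the source corpus
    frame_idx: np.ndarray  # (N,) int
    grip: np.ndarray       # (N,) str
    protocol: np.ndarray   # (N,) str
    tol: float
    activity_floor: float
    seed: int

    def __len__(self) -> int:
        return len(self.labels)

    def rows(self, split: str | None = None,
             grip: str | Grip | None = None) -> np.ndarray:
        """Boolean row mask for a split and/or grip stratum."""
        mask = np.ones(len(self), dtype=bool)
        if split is not None:
            mask &= self.split == split
        if grip is not None:
            mask &= self.grip == Grip(grip).value
        return mask

    @property
    def class_counts(self) -> dict[str, dict[int, int]]:
        out: dict[str, dict[int, int]] = {}
        for s in SPLITS:
            m = self.split == s
            secure = int(self.labels[m].sum())
            out[s] = {1: secure, 0: int(m.sum()) - secure}
        return out


def _window_frames(trial: GraspTrial) -> np.ndarray:
    if trial.protocol != Protocol.HOLD or trial.hold_window is None:
        raise ValueError("hold statistics require a hold trial with an "
                         "annotated hold window")
    i0, i1 = trial.hold_window
    if not (0 <= i0 <= i1 < trial.n_frames):
        raise ValueError("hold window out of bounds")
    return trial.volts[i0:i1 + 1]


def compute_hold_statistics(
    trial: GraspTrial,
    activity_floor: float = DEFAULT_ACTIVITY_FLOOR,
) -> HoldStatistics:
    """Per-channel means over one trial's hold window, with activity flags."""
    frames = _window_frames(trial)
    means = frames.mean(axis=0)
    active = means >= activity_floor * trial.v_max
    return HoldStatistics(means=means, active=active, v_max=trial.v_max,
                          activity_floor=activity_floor)


def pool_hold_statistics(
    trials: list[GraspTrial],
    activity_floor: float = DEFAULT_ACTIVITY_FLOOR,
) -> HoldStatistics:
    """Grip-level statistics: means over all hold-window frames pooled."""
    if not trials:
        raise ValueError("no hold trials to pool")
    frames = np.vstack([_window_frames(tr) for tr in trials])
    v_max = trials[0].v_max
    means = frames.mean(axis=0)
    active = means >= activity_floor * v_max
    return HoldStatistics(means=means, active=active, v_max=v_max,
                          activity_floor=activity_floor)


def label_frames(
    trial: GraspTrial | np.ndarray,
    stats: HoldStatistics,
    tol: float = DEFAULT_TOL,
) -> np.ndarray:
    """Binary secure label per frame.

    A frame is secure (1) iff for every active channel c,
    ``|v_c - mean_c| <= tol * mean_c``.  Accepts a :class:`GraspTrial`
    or a raw (N, 10) voltage array.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if stats.n_active == 0:
        raise ValueError("no active channels: uninformative grip context")
    volts = trial.volts if isinstance(trial, GraspTrial) else np.asarray(trial)
    if volts.ndim != 2 or volts.shape[1] != stats.means.shape[0]:
        raise ValueError("expected an (N, 10) voltage array")
    mu = stats.means[stats.active]
    dev = np.abs(volts[:, stats.active] - mu)
    return np.all(dev <= tol * mu, axis=1).astype(np.uint8)


def _split_sizes(n: int, fractions: tuple[float, float, float]) -> list[int]:
    sizes = [int(round(f * n)) for f in fractions[:-1]]
    sizes.append(n - sum(sizes))
    if min(sizes) < 0:
        raise ValueError("fractions produce a negative split size")
    return sizes


def assemble_dataset(
    corpus: TrainingCorpus,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    *,
    tol: float = DEFAULT_TOL,
    activity_floor: float = DEFAULT_ACTIVITY_FLOOR,
    by_trial: bool = False,
) -> LabeledDataset:
    """Label a subject's corpus and assign a 70/15/15 split.

    All grips are pooled into one per-subject dataset.  The default
    split is random by frame; ``by_trial=True`` instead splits whole
    trials, which avoids leaking temporally adjacent frames across
    splits at the cost of coarser proportions.
    """
    if not corpus.trials:
        raise ValueError("empty corpus")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")

    grip_stats: dict[Grip, HoldStatistics] = {}
    for grip in (Grip.PINCH, Grip.TRIPOD, Grip.WHOLE_HAND):
        holds = [tr for tr in corpus.by_grip(grip)
                 if tr.protocol == Protocol.HOLD]
        if holds:
            grip_stats[grip] = pool_hold_statistics(holds, activity_floor)
    if not grip_stats:
        raise ValueError("corpus contains no hold trials")
    rest_context = grip_stats.get(Grip.PINCH,
                                  next(iter(grip_stats.values())))

    feats, labels, trial_ids, frame_idx, grips, protocols = \
        [], [], [], [], [], []
    for ti, tr in enumerate(corpus.trials):
        stats = (rest_context if tr.protocol == Protocol.REST
                 else grip_stats[tr.grip])
        y = label_frames(tr, stats, tol)
        feats.append(tr.volts)
        labels.append(y)
        trial_ids.append(np.full(tr.n_frames, ti))
        frame_idx.append(np.arange(tr.n_frames))
        grips.append(np.full(tr.n_frames, tr.grip.value, dtype=object))
        protocols.append(np.full(tr.n_frames, tr.protocol.value,
                                 dtype=object))

    features = np.vstack(feats)
    labels = np.concatenate(labels)
    trial_id = np.concatenate(trial_ids)
    frame_idx = np.concatenate(frame_idx)
    grip_col = np.concatenate(grips).astype(str)
    proto_col = np.concatenate(protocols).astype(str)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    n = len(labels)
    split = np.empty(n, dtype="U5")
    if by_trial:
        n_trials = len(corpus.trials)
        order = rng.permutation(n_trials)
        sizes = _split_sizes(n_trials, fractions)
        trial_split = np.empty(n_trials, dtype="U5")
        stop = 0
        for name, size in zip(SPLITS, sizes):
            trial_split[order[stop:stop + size]] = name
            stop += size
        split[:] = trial_split[trial_id]
    else:
        order = rng.permutation(n)
        sizes = _split_sizes(n, fractions)
        stop = 0
        for name, size in zip(SPLITS, sizes):
            split[order[stop:stop + size]] = name
            stop += size

    return LabeledDataset(
        features=features, labels=labels.astype(np.uint8), split=split,
        trial_id=trial_id, frame_idx=frame_idx, grip=grip_col,
        protocol=proto_col, tol=tol, activity_floor=activity_floor,
        seed=int(seed))
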