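"""From labeled trials to model-ready sample sets.

Resampling, subject-wise splitting, per-channel standardization, sliding
one-step-ahead windows and minority-class undersampling.  Every step is a
pure function of its inputs and seeds; scaler statistics and class
balancing only ever see training trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from gaitphase.events import UNLABELED, GaitEvent, PhaseSequence
from gaitphase.trial import Trial


@dataclass
class WindowSet:
    """Sliding-window samples: ``inputs[j]`` holds ``w`` consecutive
    12-channel time steps and ``targets[j]`` the phase label ``offset``
    steps after the window's last row."""

    inputs: np.ndarray  # (n_samples, w, 12)
    targets: np.ndarray  # (n_samples,)
    w: int
    offset: int
    subject_ids: np.ndarray
    trial_ids: np.ndarray
    end_indices: np.ndarray

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets length mismatch")
        if np.any(self.targets == UNLABELED):
            raise ValueError("WindowSet targets must not contain UNLABELED")

    def __len__(self) -> int:
        return len(self.targets)

    def class_counts(self, n_classes: int = 4) -> np.ndarray:
        return np.bincount(self.targets, minlength=n_classes)

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(
            inputs=self.inputs[idx],
            targets=self.targets[idx],
            w=self.w,
            offset=self.offset,
            subject_ids=self.subject_ids[idx],
            trial_ids=self.trial_ids[idx],
            end_indices=self.end_indices[idx],
        )

    @classmethod
    def concatenate(cls, sets: list["WindowSet"]) -> "WindowSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        w, offset = sets[0].w, sets[0].offset
        if any(s.w != w or s.offset != offset for s in sets):
            raise ValueError("mixed (w, offset) in concatenate")
        return cls(
            inputs=np.concatenate([s.inputs for s in sets]),
            targets=np.concatenate([s.targets for s in sets]),
            w=w,
            offset=offset,
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
            trial_ids=np.concatenate([s.trial_ids for s in sets]),
            end_indices=np.concatenate([s.end_indices for s in sets]),
        )


@dataclass(frozen=True)
class SplitSpec:
    """Subject-wise split: all sessions of ``test_subjects`` go to test;
    per train subject one seeded-random session becomes validation."""

    train_subjects: frozenset
    test_subjects: frozenset
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_subjects", frozenset(self.train_subjects))
        object.__setattr__(self, "test_subjects", frozenset(self.test_subjects))
        if self.train_subjects & self.test_subjects:
            raise ValueError(
                f"subjects in both partitions: {sorted(self.train_subjects & self.test_subjects)}"
            )


class DegenerateChannelError(ValueError):
    pass


@dataclass
class ChannelScaler:
    """Per-channel affine map to zero mean / unit variance, fitted on the
    pooled training trials only."""

    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def fit(self, trials: list[Trial]) -> "ChannelScaler":
        pooled = np.concatenate([t.imu for t in trials], axis=1)
        self.mean = pooled.mean(axis=1)
        self.sd = pooled.std(axis=1)
        bad = np.flatnonzero(self.sd <= 0)
        if len(bad):
            self.mean = self.sd = None
            raise DegenerateChannelError(f"zero-variance channels: {bad.tolist()}")
        return self

    def transform(self, trial: Trial) -> Trial:
        if not self.fitted:
            raise RuntimeError("scaler not fitted")
        return trial.with_imu((trial.imu - self.mean[:, None]) / self.sd[:, None])


def fit_scaler(train_trials: list[Trial]) -> ChannelScaler:
    return ChannelScaler().fit(train_trials)


def apply_scaler(scaler: ChannelScaler, trial: Trial) -> Trial:
    return scaler.transform(trial)


def resample_trial(
    trial: Trial,
    fs_out: float,
    labels: PhaseSequence | None = None,
    events: list[GaitEvent] | None = None,
    numtaps: int = 101,
):
    """Decimate a trial to ``fs_out`` (integer factor required).

    IMU channels pass through a zero-phase FIR low-pass (cutoff
    0.4*fs_out) before index decimation; contact channels and labels are
    decimated by plain index selection and events re-indexed by integer
    division, keeping all three representations aligned.
    """
    factor = trial.fs / fs_out
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"fs {trial.fs} not an integer multiple of fs_out {fs_out}")
    factor = int(round(factor))
    if factor == 1:
        return (trial, labels, events)

    taps = signal.firwin(numtaps, cutoff=0.4 * fs_out, fs=trial.fs)
    imu = signal.filtfilt(taps, [1.0], trial.imu, axis=1)[:, ::factor]
    out = replace(
        trial,
        imu=imu,
        contact_left=trial.contact_left[::factor],
        contact_right=trial.contact_right[::factor],
        fs=fs_out,
    )
    new_labels = None
    if labels is not None:
        new_labels = PhaseSequence(
            labels=labels.labels[::factor], reference_side=labels.reference_side
        )
    new_events = None
    if events is not None:
        new_events = [replace(ev, index=ev.index // factor) for ev in events]
    return out, new_labels, new_events


def split_subjects(
    trials: list[Trial], spec: SplitSpec
) -> tuple[list[Trial], list[Trial], list[Trial]]:
    """Partition trials into (train, validation, test) subject-wise."""
    by_subject: dict[str, list[Trial]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    known = spec.train_subjects | spec.test_subjects
    unknown = set(by_subject) - known
    if unknown:
        raise ValueError(f"subjects not in split spec: {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    train, val, test = [], [], []
    for subject in sorted(by_subject):
        sessions = sorted(by_subject[subject], key=lambda t: t.trial_id)
        if subject in spec.test_subjects:
            test.extend(sessions)
            continue
        if len(sessions) < 2:
            raise ValueError(
                f"train subject {subject} has {len(sessions)} session(s); need >= 2"
            )
        val_idx = int(rng.integers(len(sessions)))
        for i, s in enumerate(sessions):
            (val if i == val_idx else train).append(s)
    return train, val, test


def make_windows(
    trial: Trial,
    labels: PhaseSequence,
    w: int = 20,
    offset: int = 1,
) -> WindowSet:
    """Build one-step-ahead sliding windows from a labeled trial.

    Sample ``j`` has input rows ``j .. j+w-1`` and target label index
    ``j+w-1+offset``; windows whose target is UNLABELED or beyond the
    trial end are dropped.  A fully labeled trial with ``offset=1``
    yields exactly ``n - w`` samples.
    """
    n = trial.n_samples
    if len(labels.labels) != n:
        raise ValueError("labels not aligned to trial samples")
    x = trial.imu.T  # (n, 12)
    empty = WindowSet(
        inputs=np.empty((0, w, x.shape[1])),
        targets=np.empty(0, dtype=np.int64),
        w=w,
        offset=offset,
        subject_ids=np.empty(0, dtype=object),
        trial_ids=np.empty(0, dtype=object),
        end_indices=np.empty(0, dtype=np.int64),
    )
    if n <= w:
        return empty
    starts = np.arange(n - w + 1)
    target_idx = starts + w - 1 + offset
    keep = target_idx < n
    starts, target_idx = starts[keep], target_idx[keep]
    targets = labels.labels[target_idx]
    keep = targets != UNLABELED
    starts, target_idx, targets = starts[keep], target_idx[keep], targets[keep]
    if len(starts) == 0:
        return empty
    windows = np.lib.stride_tricks.sliding_window_view(x, w, axis=0)
    inputs = np.ascontiguousarray(windows[starts].transpose(0, 2, 1))
    m = len(starts)
    return WindowSet(
        inputs=inputs,
        targets=targets.astype(np.int64),
        w=w,
        offset=offset,
        subject_ids=np.full(m, trial.subject_id, dtype=object),
        trial_ids=np.full(m, trial.trial_id, dtype=object),
        end_indices=(starts + w - 1).astype(np.int64),
    )


class BalancingError(ValueError):
    pass


def balance_classes(windows: WindowSet, seed: int, n_classes: int = 4) -> WindowSet:
    """Undersample (without replacement) so every class matches the
    smallest class count.  Training data only; order is re-sorted by
    original position so provenance stays stable under the seed."""
    counts = windows.class_counts(n_classes)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0).tolist()
        raise BalancingError(f"classes with zero samples: {empty}")
    m = int(counts.min())
    rng = np.random.default_rng(seed)
    chosen = []
    for c in range(n_classes):
        idx = np.flatnonzero(windows.targets == c)
        chosen.append(rng.choice(idx, size=m, replace=False))
    order = np.sort(np.concatenate(chosen))
    return windows.subset(order)
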