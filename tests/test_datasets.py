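"""Dataset builder: resampling, splitting, scaling, windows, balancing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitphase.datasets import (
    BalancingError,
    DegenerateChannelError,
    SplitSpec,
    WindowSet,
    balance_classes,
    fit_scaler,
    make_windows,
    resample_trial,
    split_subjects,
)
from gaitphase.events import UNLABELED, PhaseSequence
from gaitphase.trial import Trial


def _trial(imu, fs=200.0, subject="S00", trial_id="T00"):
    n = imu.shape[1]
    return Trial(
        imu=imu,
        contact_left=np.zeros(n, dtype=int),
        contact_right=np.zeros(n, dtype=int),
        fs=fs,
        subject_id=subject,
        trial_id=trial_id,
    )


def _labels(values, side="right"):
    return PhaseSequence(labels=np.asarray(values), reference_side=side)


class TestResample:
    def test_constant_preserved(self):
        trial = _trial(np.full((12, 2000), 3.7))
        out, _, _ = resample_trial(trial, 100)
        assert np.allclose(out.imu, 3.7)
        assert out.fs == 100

    def test_length_halved(self):
        trial = _trial(np.zeros((12, 48000)))
        out, _, _ = resample_trial(trial, 100)
        assert out.n_samples == 24000

    def test_sinusoid_amplitude_preserved(self):
        t = np.arange(4000) / 200.0
        imu = np.tile(np.sin(2 * np.pi * 2.0 * t), (12, 1))
        out, _, _ = resample_trial(_trial(imu), 100)
        mid = out.imu[0, 200:-200]  # avoid filter edge effects
        assert abs(mid.max() - 1.0) < 0.01
        assert abs(mid.min() + 1.0) < 0.01

    def test_labels_and_events_reindexed(self):
        from gaitphase.events import HS, GaitEvent

        trial = _trial(np.zeros((12, 400)))
        labels = _labels(np.repeat([0, 1, 2, 3], 100))
        events = [GaitEvent(101, "right", HS)]
        out, out_labels, out_events = resample_trial(trial, 100, labels, events)
        assert len(out_labels.labels) == 200
        assert (out_labels.labels == np.repeat([0, 1, 2, 3], 50)).all()
        assert out_events[0].index == 50

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            resample_trial(_trial(np.zeros((12, 400))), 150)


def _session_trials(n_subjects, per_subject):
    rng = np.random.default_rng(0)
    return [
        _trial(rng.normal(size=(12, 50)), subject=f"S{s}", trial_id=f"T{t}")
        for s in range(n_subjects)
        for t in range(per_subject)
    ]


class TestSplitSubjects:
    def test_arithmetic(self):
        trials = _session_trials(3, 4)
        spec = SplitSpec(train_subjects={"S0", "S1"}, test_subjects={"S2"}, seed=0)
        train, val, test = split_subjects(trials, spec)
        assert (len(train), len(val), len(test)) == (6, 2, 4)

    def test_deterministic(self):
        trials = _session_trials(4, 3)
        spec = SplitSpec(train_subjects={"S0", "S1", "S2"}, test_subjects={"S3"}, seed=5)
        a = split_subjects(trials, spec)
        b = split_subjects(trials, spec)
        for pa, pb in zip(a, b):
            assert [(t.subject_id, t.trial_id) for t in pa] == [
                (t.subject_id, t.trial_id) for t in pb
            ]

    def test_partition_property(self):
        trials = _session_trials(4, 3)
        spec = SplitSpec(train_subjects={"S0", "S1"}, test_subjects={"S2", "S3"})
        parts = split_subjects(trials, spec)
        keys = [{(t.subject_id, t.trial_id) for t in p} for p in parts]
        assert keys[0] | keys[1] | keys[2] == {
            (t.subject_id, t.trial_id) for t in trials
        }
        assert not (keys[0] & keys[1] or keys[0] & keys[2] or keys[1] & keys[2])

    def test_no_subject_in_two_partitions(self):
        trials = _session_trials(4, 3)
        spec = SplitSpec(train_subjects={"S0", "S1"}, test_subjects={"S2", "S3"})
        train, val, test = split_subjects(trials, spec)
        train_subj = {t.subject_id for t in train} | {t.subject_id for t in val}
        assert not train_subj & {t.subject_id for t in test}

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="both"):
            SplitSpec(train_subjects={"S0"}, test_subjects={"S0"})

    def test_single_session_train_subject_rejected(self):
        trials = _session_trials(2, 1)
        spec = SplitSpec(train_subjects={"S0"}, test_subjects={"S1"})
        with pytest.raises(ValueError, match="session"):
            split_subjects(trials, spec)


class TestScaler:
    def test_two_point_channel(self):
        imu = np.tile(np.array([[1.0, 3.0]]), (12, 1))
        scaler = fit_scaler([_trial(imu)])
        out = scaler.transform(_trial(imu))
        assert np.allclose(out.imu[:, 0], -1.0)
        assert np.allclose(out.imu[:, 1], 1.0)

    def test_self_transform_standardizes(self):
        rng = np.random.default_rng(1)
        trials = [_trial(rng.normal(2.0, 3.0, size=(12, 500))) for _ in range(3)]
        scaler = fit_scaler(trials)
        pooled = np.concatenate([scaler.transform(t).imu for t in trials], axis=1)
        assert np.all(np.abs(pooled.mean(axis=1)) < 1e-6)
        assert np.all(np.abs(pooled.std(axis=1) - 1.0) < 1e-6)

    def test_val_keeps_train_statistics(self):
        train = _trial(np.random.default_rng(0).normal(0, 1, size=(12, 500)))
        val = _trial(np.random.default_rng(1).normal(5, 1, size=(12, 500)))
        out = fit_scaler([train]).transform(val)
        assert np.all(out.imu.mean(axis=1) > 1.0)  # train stats leave val offset

    def test_degenerate_channel_rejected(self):
        imu = np.random.default_rng(0).normal(size=(12, 100))
        imu[4] = 2.0
        with pytest.raises(DegenerateChannelError, match="4"):
            fit_scaler([_trial(imu)])


class TestMakeWindows:
    def test_count_and_alignment(self):
        rng = np.random.default_rng(2)
        trial = _trial(rng.normal(size=(12, 100)))
        labels = _labels(rng.integers(0, 4, 100))
        ws = make_windows(trial, labels, w=20, offset=1)
        assert len(ws) == 80
        assert np.allclose(ws.inputs[0], trial.imu[:, 0:20].T)
        assert ws.targets[0] == labels.labels[20]
        assert np.allclose(ws.inputs[-1], trial.imu[:, 79:99].T)
        assert ws.targets[-1] == labels.labels[99]
        assert ws.end_indices[-1] == 98

    def test_no_room_for_target(self):
        trial = _trial(np.zeros((12, 20)))
        ws = make_windows(trial, _labels(np.zeros(20, dtype=int)), w=20)
        assert len(ws) == 0

    def test_unlabeled_targets_dropped(self):
        trial = _trial(np.zeros((12, 100)))
        lab = np.zeros(100, dtype=int)
        lab[50:60] = UNLABELED
        ws = make_windows(trial, _labels(lab), w=20, offset=1)
        assert len(ws) == 70
        assert not np.any((ws.end_indices + 1 >= 50) & (ws.end_indices + 1 < 60))

    @given(
        n=st.integers(25, 400),
        w=st.integers(1, 24),
    )
    @settings(max_examples=100, deadline=None)
    def test_window_count_law(self, n, w):
        trial = _trial(np.zeros((12, n)))
        ws = make_windows(trial, _labels(np.zeros(n, dtype=int)), w=w, offset=1)
        assert len(ws) == n - w


class TestBalanceClasses:
    def _windows(self, targets):
        targets = np.asarray(targets)
        m = len(targets)
        return WindowSet(
            inputs=np.arange(m * 20 * 12, dtype=float).reshape(m, 20, 12),
            targets=targets,
            w=20,
            offset=1,
            subject_ids=np.array([f"S{i}" for i in range(m)], dtype=object),
            trial_ids=np.full(m, "T0", dtype=object),
            end_indices=np.arange(m),
        )

    def test_min_count_rule(self):
        targets = np.concatenate([np.zeros(10), np.ones(30), np.full(12, 2), np.full(28, 3)])
        out = balance_classes(self._windows(targets.astype(int)), seed=0)
        assert out.class_counts().tolist() == [10, 10, 10, 10]
        assert len(out) == 40

    def test_already_balanced_unchanged(self):
        out = balance_classes(self._windows(np.repeat([0, 1, 2, 3], 5)), seed=0)
        assert out.class_counts().tolist() == [5, 5, 5, 5]

    def test_subset_of_input(self):
        ws = self._windows(np.random.default_rng(0).integers(0, 4, 100))
        out = balance_classes(ws, seed=3)
        original = {tuple(row) for row in ws.inputs.reshape(len(ws), -1)}
        for row in out.inputs.reshape(len(out), -1):
            assert tuple(row) in original

    def test_deterministic(self):
        ws = self._windows(np.random.default_rng(0).integers(0, 4, 100))
        a = balance_classes(ws, seed=7)
        b = balance_classes(ws, seed=7)
        assert (a.end_indices == b.end_indices).all()
        assert (a.subject_ids == b.subject_ids).all()

    def test_zero_class_rejected(self):
        with pytest.raises(BalancingError, match="3"):
            balance_classes(self._windows(np.repeat([0, 1, 2], 5)), seed=0)

    def test_class_conditional_mean_preserved(self):
        rng = np.random.default_rng(8)
        targets = rng.integers(0, 4, 4000)
        ws = self._windows(targets)
        ws.inputs = rng.normal(size=(4000, 20, 12)) + targets[:, None, None]
        out = balance_classes(ws, seed=1)
        for c in range(4):
            before = ws.inputs[ws.targets == c].mean()
            after = out.inputs[out.targets == c].mean()
            assert abs(before - after) < 0.05


class TestWindowSetContainer:
    def test_rejects_unlabeled_targets(self):
        with pytest.raises(ValueError, match="UNLABELED"):
            WindowSet(
                inputs=np.zeros((1, 20, 12)),
                targets=np.array([UNLABELED]),
                w=20,
                offset=1,
                subject_ids=np.array(["S0"], dtype=object),
                trial_ids=np.array(["T0"], dtype=object),
                end_indices=np.array([19]),
            )

    def test_concatenate_mixed_w_rejected(self):
        def mk(w):
            return WindowSet(
                inputs=np.zeros((1, w, 12)),
                targets=np.array([0]),
                w=w,
                offset=1,
                subject_ids=np.array(["S0"], dtype=object),
                trial_ids=np.array(["T0"], dtype=object),
                end_indices=np.array([w - 1]),
            )

        with pytest.raises(ValueError, match="mixed"):
            WindowSet.concatenate([mk(20), mk(10)])
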