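"""Event detection and phase labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitphase.events import (
    HS,
    LR,
    LS,
    PSW,
    SW,
    TO,
    UNLABELED,
    GaitEvent,
    PhaseLabelingError,
    binarize_contact,
    detect_events,
    label_phases,
    phase_duration_summary,
)


# ---------------------------------------------------------------- binarize
class TestBinarizeContact:
    def test_threshold(self):
        out = binarize_contact(np.array([0.0, 0.2, 0.9, 1.0]), 0.5)
        assert out.tolist() == [0, 0, 1, 1]

    def test_all_below(self):
        assert binarize_contact(np.array([0.1, 0.4]), 0.5).tolist() == [0, 0]

    def test_zero_threshold_nonnegative(self):
        assert binarize_contact(np.array([0.0, 2.0, 0.3]), 0.0).tolist() == [1, 1, 1]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            binarize_contact(np.array([0.0, np.nan]), 0.5)


# ------------------------------------------------------------------ detect
def _oracle_detect(contact, min_samples):
    """Independent run-based oracle: repeatedly flip the shortest interior
    run below min_samples, then read edges."""
    vals = list(contact)
    while True:
        runs = []
        start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[start]:
                runs.append((start, i))
                start = i
        short = [
            (b - a, a, b)
            for j, (a, b) in enumerate(runs)
            if 0 < j < len(runs) - 1 and b - a < min_samples
        ]
        if not short:
            break
        _, a, b = min(short)
        for i in range(a, b):
            vals[i] = 1 - vals[i]
    events = []
    for i in range(1, len(vals)):
        if vals[i] == 1 and vals[i - 1] == 0:
            events.append((i, HS))
        elif vals[i] == 0 and vals[i - 1] == 1:
            events.append((i, TO))
    return events


class TestDetectEvents:
    def test_single_stance(self):
        ev = detect_events(np.array([0, 0, 1, 1, 1, 0, 0]), fs=100, min_gap=0)
        assert [(e.index, e.type) for e in ev] == [(2, HS), (5, TO)]

    def test_leading_stance_has_no_hs(self):
        ev = detect_events(np.array([1, 1, 0, 0]), fs=100, min_gap=0)
        assert [(e.index, e.type) for e in ev] == [(2, TO)]

    def test_empty(self):
        assert detect_events(np.array([]), fs=100) == []

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            detect_events(np.array([0, 2, 1]), fs=100)

    def test_dropout_debounced(self):
        contact = np.zeros(300, dtype=int)
        contact[50:150] = 1
        clean = detect_events(contact, fs=100, min_gap=0.05)
        contact[99] = 0  # 1-sample dropout inside stance; min_gap*fs = 5
        assert detect_events(contact, fs=100, min_gap=0.05) == clean

    @given(
        bits=st.lists(st.integers(0, 1), min_size=2, max_size=80),
        min_samples=st.integers(0, 6),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle(self, bits, min_samples):
        contact = np.array(bits)
        got = detect_events(contact, fs=1.0, min_gap=float(min_samples))
        assert [(e.index, e.type) for e in got] == _oracle_detect(bits, min_samples)

    @given(bits=st.lists(st.integers(0, 1), min_size=2, max_size=80))
    @settings(max_examples=100, deadline=None)
    def test_alternation(self, bits):
        ev = detect_events(np.array(bits), fs=1.0, min_gap=0)
        for a, b in zip(ev, ev[1:]):
            assert a.index < b.index
            assert a.type != b.type


# ------------------------------------------------------------------- label
def _ev(side, pairs):
    return [GaitEvent(i, side, t) for i, t in pairs]


def _oracle_labels(events_left, events_right, n, reference="right"):
    """Per-sample rule checker: for sample s inside a complete chain
    (R.HS, C.TO, C.HS, R.TO, R.HS), apply the interval rules directly."""
    ref = events_right if reference == "right" else events_left
    contra = events_left if reference == "right" else events_right
    ref_hs = [e.index for e in ref if e.type == HS]
    ref_to = [e.index for e in ref if e.type == TO]
    con_hs = [e.index for e in contra if e.type == HS]
    con_to = [e.index for e in contra if e.type == TO]
    labels = np.full(n, UNLABELED)
    for h in ref_hs:
        nxt = [x for x in ref_hs if x > h]
        ct = [x for x in con_to if x > h]
        if not nxt or not ct:
            continue
        ch = [x for x in con_hs if x > ct[0]]
        rt = [x for x in ref_to if x > h]
        if not ch or not rt:
            continue
        if not (h < ct[0] < ch[0] < rt[0] < nxt[0]):
            continue
        labels[h:ct[0]] = LR
        labels[ct[0]:ch[0]] = LS
        labels[ch[0]:rt[0]] = PSW
        labels[rt[0]:nxt[0]] = SW
    return labels


class TestLabelPhases:
    events_left = _ev("left", [(10, TO), (50, HS)])
    events_right = _ev("right", [(0, HS), (60, TO), (100, HS)])

    def test_worked_example(self):
        seq = label_phases(self.events_left, self.events_right, 110)
        assert (seq.labels[0:10] == LR).all()
        assert (seq.labels[10:50] == LS).all()
        assert (seq.labels[50:60] == PSW).all()
        assert (seq.labels[60:100] == SW).all()
        oracle = _oracle_labels(self.events_left, self.events_right, 110)
        assert (seq.labels == oracle).all()

    def test_tail_unlabeled(self):
        seq = label_phases(self.events_left, self.events_right, 120)
        assert (seq.labels[100:120] == UNLABELED).all()

    def test_periodic_durations(self):
        # 1.0 s cycle, stance 0.6, offset 0.5 at 200 Hz -> 20/80/20/80
        fs = 200
        right = []
        left = []
        for k in range(4):
            right += [(k * 200, HS), (k * 200 + 120, TO)]
            left += [(k * 200 + 100, HS), (k * 200 + 220, TO)]
        left = [(20, TO)] + left[:-1]  # truncated pre-cycle stance
        seq = label_phases(_ev("left", sorted(left)), _ev("right", right), 800)
        runs = [(l, b - a) for l, a, b in seq.runs() if l != UNLABELED]
        assert runs[:4] == [(LR, 20), (LS, 80), (PSW, 20), (SW, 80)]
        summary = phase_duration_summary(seq, fs)
        assert summary["LR"]["mean"] == pytest.approx(0.10)
        assert summary["LS"]["mean"] == pytest.approx(0.40)
        assert summary["PSw"]["mean"] == pytest.approx(0.10)
        assert summary["Sw"]["mean"] == pytest.approx(0.40)

    def test_alternation_violation(self):
        bad = _ev("right", [(0, HS), (50, HS)])
        with pytest.raises(PhaseLabelingError, match="alternate"):
            label_phases(self.events_left, bad, 110)

    def test_interleaving_violation(self):
        # reference TO before contralateral HS breaks the chain
        left = _ev("left", [(10, TO), (80, HS)])
        right = _ev("right", [(0, HS), (60, TO), (100, HS)])
        with pytest.raises(PhaseLabelingError, match="0"):
            label_phases(left, right, 110)

    def test_event_out_of_range(self):
        with pytest.raises(PhaseLabelingError, match="out of range"):
            label_phases(self.events_left, self.events_right, 90)

    def test_symmetry_label_multiset(self):
        """Swapping sides and the reference yields the same per-cycle
        label multiset."""
        right = []
        left = []
        for k in range(5):
            right += [(k * 200, HS), (k * 200 + 120, TO)]
            left += [(k * 200 + 100, HS), (k * 200 + 220, TO)]
        left = [(20, TO)] + left[:-1]
        a = label_phases(_ev("left", sorted(left)), _ev("right", right), 1000, "right")
        b = label_phases(
            _ev("left", right), _ev("right", sorted(left)), 1000, "left"
        )
        ca = np.bincount(a.labels[a.labels >= 0], minlength=4)
        cb = np.bincount(b.labels[b.labels >= 0], minlength=4)
        assert (ca == cb).all()


class TestPhaseDurationSummary:
    def test_single_cycle_sd_zero(self):
        seq = label_phases(
            TestLabelPhases.events_left, TestLabelPhases.events_right, 110
        )
        summary = phase_duration_summary(seq, 100)
        assert all(v["sd"] == 0.0 for v in summary.values())

    def test_all_unlabeled_empty(self):
        seq = label_phases([], [], 50)
        assert phase_duration_summary(seq, 100) == {}
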