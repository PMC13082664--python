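"""Gait event detection and four-phase labeling.

Heel strike (HS) is the 0->1 transition of a foot-contact channel, toe off
(TO) the 1->0 transition.  With a reference leg R and contralateral leg C,
each complete gait cycle is partitioned into four half-open intervals::

    LR  = [R.HS,  next C.TO)     loading response (double support)
    LS  = [C.TO,  next C.HS)     late stance (single support)
    PSw = [C.HS,  next R.TO)     pre-swing (double support)
    Sw  = [R.TO,  next R.HS)     swing

Samples not covered by a complete HS->...->HS chain are left UNLABELED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LR, LS, PSW, SW = 0, 1, 2, 3
UNLABELED = -1

PHASE_NAMES = {LR: "LR", LS: "LS", PSW: "PSw", SW: "Sw", UNLABELED: "UNLABELED"}

HS = "HS"
TO = "TO"


class PhaseLabelingError(ValueError):
    """Raised when event streams cannot be labeled consistently."""


@dataclass(frozen=True, order=True)
class GaitEvent:
    """A single gait event: (sample index, side, HS/TO)."""

    index: int
    side: str
    type: str

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("event index must be >= 0")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        if self.type not in (HS, TO):
            raise ValueError(f"type must be HS/TO, got {self.type!r}")


@dataclass
class PhaseSequence:
    """Per-sample phase labels for one reference leg.

    ``labels`` uses the coding LR=0, LS=1, PSw=2, Sw=3, UNLABELED=-1.
    """

    labels: np.ndarray
    reference_side: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.reference_side not in ("left", "right"):
            raise ValueError("reference_side must be 'left' or 'right'")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def runs(self) -> list[tuple[int, int, int]]:
        """Contiguous runs as (label, start, stop) with half-open stop."""
        lab = self.labels
        if len(lab) == 0:
            return []
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate([[0], change])
        stops = np.concatenate([change, [len(lab)]])
        return [(int(lab[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def binarize_contact(contact: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold an analog force-like contact signal to a 0/1 series."""
    contact = np.asarray(contact, dtype=float)
    if not np.all(np.isfinite(contact)):
        raise ValueError("contact signal contains non-finite values")
    return (contact >= threshold).astype(np.int8)


def _runs_of(binary: np.ndarray) -> list[tuple[int, int, int]]:
    """(value, start, stop) runs of a 0/1 series, half-open stop."""
    if len(binary) == 0:
        return []
    change = np.flatnonzero(np.diff(binary)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(binary)]])
    return [(int(binary[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def _debounce(binary: np.ndarray, min_samples: int) -> np.ndarray:
    """Flip interior runs shorter than ``min_samples`` into their neighbors.

    Runs are removed shortest-first (ties: earliest) and the run list is
    recomputed after each merge, so a dropout never splits a long segment.
    Boundary runs are kept: a short leading/trailing segment is genuine
    partial stance or swing, not noise to absorb.
    """
    out = np.asarray(binary).copy()
    while True:
        runs = _runs_of(out)
        interior = [
            (stop - start, start, stop)
            for i, (_, start, stop) in enumerate(runs)
            if 0 < i < len(runs) - 1 and stop - start < min_samples
        ]
        if not interior:
            return out
        _, start, stop = min(interior)
        out[start:stop] = 1 - out[start]


def detect_events(
    contact: np.ndarray,
    fs: float,
    min_gap: float = 0.05,
    side: str = "right",
) -> list[GaitEvent]:
    """Extract HS/TO events from a binary contact series.

    Contact and airborne segments shorter than ``min_gap`` seconds are
    merged into their neighbors before edges are extracted, debouncing
    sensor dropouts.  HS is emitted at the index of the first 1 of a
    contact segment, TO at the index of the first 0 after it.
    """
    contact = np.asarray(contact)
    if len(contact) == 0:
        return []
    if not np.all((contact == 0) | (contact == 1)):
        raise ValueError("contact series must be binary; see binarize_contact")
    min_samples = int(round(min_gap * fs))
    clean = _debounce(contact.astype(np.int8), min_samples)
    diff = np.diff(clean)
    events = [GaitEvent(int(i) + 1, side, HS) for i in np.flatnonzero(diff == 1)]
    events += [GaitEvent(int(i) + 1, side, TO) for i in np.flatnonzero(diff == -1)]
    events.sort()
    return events


def _validate_alternation(events: list[GaitEvent], side: str) -> None:
    prev = None
    for ev in events:
        if ev.side != side:
            raise PhaseLabelingError(
                f"event at index {ev.index} has side {ev.side}, expected {side}"
            )
        if prev is not None:
            if ev.index <= prev.index:
                raise PhaseLabelingError(
                    f"{side} events not strictly increasing at index {ev.index}"
                )
            if ev.type == prev.type:
                raise PhaseLabelingError(
                    f"{side} events must alternate HS/TO; "
                    f"repeated {ev.type} at index {ev.index}"
                )
        prev = ev


def _next_event(events: list[GaitEvent], etype: str, after: int) -> GaitEvent | None:
    for ev in events:
        if ev.type == etype and ev.index > after:
            return ev
    return None


def label_phases(
    events_left: list[GaitEvent],
    events_right: list[GaitEvent],
    n_samples: int,
    reference_side: str = "right",
) -> PhaseSequence:
    """Assign the four phase labels to every sample of a trial.

    Only complete reference cycles — a chain R.HS < C.TO < C.HS < R.TO <
    next R.HS — receive labels; everything else stays UNLABELED.  Event
    streams whose interleaving breaks the chain ordering (e.g. a reference
    TO arriving before the contralateral HS) raise
    :class:`PhaseLabelingError` naming the offending sample index.
    """
    _validate_alternation(events_left, "left")
    _validate_alternation(events_right, "right")
    for ev in events_left + events_right:
        if ev.index >= n_samples:
            raise PhaseLabelingError(
                f"event index {ev.index} out of range for n_samples={n_samples}"
            )
    if reference_side == "right":
        ref, contra = events_right, events_left
    else:
        ref, contra = events_left, events_right

    labels = np.full(n_samples, UNLABELED, dtype=np.int64)
    for ev in ref:
        if ev.type != HS:
            continue
        r_hs = ev.index
        c_to = _next_event(contra, TO, r_hs)
        if c_to is None:
            break
        c_hs = _next_event(contra, HS, c_to.index)
        r_to = _next_event(ref, TO, r_hs)
        next_hs = _next_event(ref, HS, r_hs)
        if c_hs is None or r_to is None or next_hs is None:
            break
        if not (r_hs < c_to.index < c_hs.index < r_to.index < next_hs.index):
            raise PhaseLabelingError(
                "event interleaving violates the LR->LS->PSw->Sw chain "
                f"in the cycle starting at reference HS index {r_hs}"
            )
        labels[r_hs:c_to.index] = LR
        labels[c_to.index:c_hs.index] = LS
        labels[c_hs.index:r_to.index] = PSW
        labels[r_to.index:next_hs.index] = SW
    return PhaseSequence(labels=labels, reference_side=reference_side)


def phase_duration_summary(phases: PhaseSequence, fs: float) -> dict[str, dict[str, float]]:
    """Mean/sd duration (seconds) of each labeled phase over contiguous runs."""
    durations: dict[int, list[float]] = {}
    for label, start, stop in phases.runs():
        if label == UNLABELED:
            continue
        durations.setdefault(label, []).append((stop - start) / fs)
    return {
        PHASE_NAMES[label]: {
            "mean": float(np.mean(d)),
            "sd": float(np.std(d)),
            "count": len(d),
        }
        for label, d in sorted(durations.items())
    }
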