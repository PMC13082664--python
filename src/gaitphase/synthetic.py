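"""Synthetic bilateral gait trials with known ground-truth events and phases.

Each leg follows a periodic heel-strike schedule with ~60% stance duty
cycle and a half-cycle left/right offset.  IMU channels are rendered as
phase-locked Gaussian bumps (one bump per phase occurrence, amplitude
taken from a per-channel-per-phase template scaled by a subject factor)
plus additive white noise, so phases are discriminative but smooth.

All randomness flows through seeded generators derived from
``GaitSimParams.seed``; the generated dataset is a pure function of the
parameter set.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from gaitphase.events import HS, TO, GaitEvent, PhaseSequence, label_phases
from gaitphase.trial import IMU_CHANNELS, Trial

#: One row per IMU channel (left block then right block), one column per
#: phase (LR, LS, PSw, Sw).  Values are free parameters chosen to give each
#: phase a distinct multi-channel signature; they are not calibrated to any
#: particular hardware.
_BLOCK = np.array(
    [
        [1.0, -0.6, 1.4, -1.0],
        [-0.8, 1.2, 0.5, 0.9],
        [0.6, 0.4, -1.2, -0.5],
        [1.3, -1.0, 0.8, 1.1],
        [-0.5, 0.9, -0.7, 1.4],
        [0.9, 0.3, 1.1, -1.3],
    ]
)
DEFAULT_TEMPLATE_AMPLITUDES = np.vstack([_BLOCK, _BLOCK[::-1] * np.array([1, -1, 1, -1])])


@dataclass(frozen=True)
class GaitSimParams:
    """Parameters of the bilateral gait simulator."""

    n_subjects: int = 4
    trials_per_subject: int = 2
    trial_duration: float = 30.0
    fs: float = 200.0
    cycle_mean: float = 1.1
    cycle_cv: float = 0.03
    stance_fraction: float = 0.60
    contralateral_offset: float = 0.50
    template_amplitudes: np.ndarray = field(
        default_factory=lambda: DEFAULT_TEMPLATE_AMPLITUDES.copy()
    )
    noise_sigma: float = 0.05
    subject_amp_sd: float = 0.10
    subject_cadence_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must be in (0, 1)")
        if not 0 <= self.contralateral_offset < 1:
            raise ValueError("contralateral_offset must be in [0, 1)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.cycle_mean <= 0:
            raise ValueError("cycle_mean must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        amps = np.asarray(self.template_amplitudes, dtype=float)
        if amps.shape != (len(IMU_CHANNELS), 4):
            raise ValueError("template_amplitudes must have shape (12, 4)")
        object.__setattr__(self, "template_amplitudes", amps)

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.fs))


@dataclass
class SimulatedTrial(Trial):
    """A rendered trial plus the ground truth used to render it."""

    truth_events: list[GaitEvent] = field(default_factory=list)
    truth_phases: PhaseSequence | None = None


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "big")


def _subject_factors(params: GaitSimParams, subject_id: str) -> tuple[float, float]:
    """(amplitude, cadence) multipliers, log-normal, fixed per subject."""
    rng = np.random.default_rng([params.seed, _stable_hash(subject_id)])
    amp = float(np.exp(rng.normal(0.0, params.subject_amp_sd)))
    cadence = float(np.exp(rng.normal(0.0, params.subject_cadence_sd)))
    return amp, cadence


# (hs, to) sample-index pairs; None marks an event clipped off by the
# trial boundary (leading stance without HS, trailing stance without TO).
StancePairs = list[tuple[int | None, int | None]]


def simulate_subject_cycles(
    params: GaitSimParams,
    subject_id: str,
    rng: np.random.Generator,
) -> dict[str, StancePairs]:
    """Draw one trial's bilateral (HS, TO) schedule.

    Right-leg heel strikes are cumulative sums of per-cycle durations
    drawn around ``cycle_mean`` (scaled by the subject's cadence factor);
    each toe off trails its heel strike by ``stance_fraction`` of the
    cycle and the left leg is shifted by ``contralateral_offset`` of the
    cycle.  One extra cycle is simulated before t=0 so the left leg's
    truncated leading stance appears in the contact channel.
    """
    if params.trial_duration < 2 * params.cycle_mean:
        raise ValueError("trial_duration must cover at least two cycles")
    _, cadence = _subject_factors(params, subject_id)
    mean = params.cycle_mean * cadence
    sd = params.cycle_cv * mean
    n_samples = params.n_samples

    def draw_cycle() -> float:
        if sd == 0:
            return mean
        return float(np.clip(rng.normal(mean, sd), 0.5 * mean, 1.5 * mean))

    # pre-cycle so the contralateral leg has history before t=0
    d_pre = draw_cycle()
    cycles: list[tuple[float, float]] = [(-d_pre, d_pre)]  # (right HS time, duration)
    t = 0.0
    while t < params.trial_duration:
        d = draw_cycle()
        cycles.append((t, d))
        t += d

    def clip_pair(hs_t: float, to_t: float) -> tuple[int | None, int | None] | None:
        hs = int(round(hs_t * params.fs))
        to = int(round(to_t * params.fs))
        if to <= 0 or hs >= n_samples:
            return None
        return (hs if hs >= 0 else None, to if to < n_samples else None)

    out: dict[str, StancePairs] = {"left": [], "right": []}
    for hs_t, d in cycles:
        pair = clip_pair(hs_t, hs_t + params.stance_fraction * d)
        if pair is not None:
            out["right"].append(pair)
        l_hs = hs_t + params.contralateral_offset * d
        pair = clip_pair(l_hs, l_hs + params.stance_fraction * d)
        if pair is not None:
            out["left"].append(pair)
    return out


def _pairs_to_events(pairs: StancePairs, side: str) -> list[GaitEvent]:
    """Contact-visible events: a clipped HS/TO never yields an event and a
    stance starting at sample 0 has no detectable heel strike."""
    events = []
    for hs, to in pairs:
        if hs is not None and hs > 0:
            events.append(GaitEvent(hs, side, HS))
        if to is not None:
            events.append(GaitEvent(to, side, TO))
    return sorted(events)


def _contact_series(pairs: StancePairs, n_samples: int) -> np.ndarray:
    contact = np.zeros(n_samples, dtype=np.int8)
    for hs, to in pairs:
        contact[(hs or 0):(n_samples if to is None else to)] = 1
    return contact


def render_trial(
    events: dict[str, StancePairs],
    params: GaitSimParams,
    rng: np.random.Generator,
    subject_id: str = "S00",
    trial_id: str = "T00",
) -> SimulatedTrial:
    """Render contact channels, IMU signals and ground-truth phases.

    Each side's six channels are phase-locked to that side's own cycle:
    for every contiguous run of a phase, a Gaussian bump (center at the
    run midpoint, sigma = run length / 6) scaled by
    ``template_amplitudes[channel, phase]`` and the subject amplitude
    factor is added, then white noise of sd ``noise_sigma``.
    """
    n = params.n_samples
    amp_factor, _ = _subject_factors(params, subject_id)
    contact = {side: _contact_series(events[side], n) for side in ("left", "right")}
    truth = {side: _pairs_to_events(events[side], side) for side in ("left", "right")}

    imu = np.zeros((len(IMU_CHANNELS), n))
    t_axis = np.arange(n, dtype=float)
    for si, side in enumerate(("left", "right")):
        side_phases = label_phases(truth["left"], truth["right"], n, reference_side=side)
        rows = slice(6 * si, 6 * si + 6)
        amps = params.template_amplitudes[rows, :] * amp_factor
        for label, start, stop in side_phases.runs():
            if label < 0:
                continue
            length = stop - start
            center = start + (length - 1) / 2.0
            sigma = max(length / 6.0, 1.0)
            bump = np.exp(-0.5 * ((t_axis[start:stop] - center) / sigma) ** 2)
            imu[rows, start:stop] += amps[:, label][:, None] * bump[None, :]
    if params.noise_sigma > 0:
        imu += rng.normal(0.0, params.noise_sigma, size=imu.shape)

    truth_phases = label_phases(truth["left"], truth["right"], n, reference_side="right")
    return SimulatedTrial(
        imu=imu,
        contact_left=contact["left"],
        contact_right=contact["right"],
        fs=params.fs,
        subject_id=subject_id,
        trial_id=trial_id,
        truth_events=truth["left"] + truth["right"],
        truth_phases=truth_phases,
    )


def generate_dataset(params: GaitSimParams) -> list[SimulatedTrial]:
    """All subjects x trials, reproducible from ``params.seed`` alone."""
    trials = []
    for s in range(params.n_subjects):
        subject_id = f"S{s:02d}"
        for t in range(params.trials_per_subject):
            trial_id = f"T{t:02d}"
            rng = np.random.default_rng([params.seed, s, t])
            schedule = simulate_subject_cycles(params, subject_id, rng)
            trials.append(render_trial(schedule, params, rng, subject_id, trial_id))
    return trials
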