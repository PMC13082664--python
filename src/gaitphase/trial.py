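"""Core trial container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Channel order of the 12-row IMU matrix and of the canonical trial CSV.
IMU_CHANNELS = [
    f"{side}_{kind}_{axis}"
    for side in ("left", "right")
    for kind in ("acc", "gyro")
    for axis in ("x", "y", "z")
]


@dataclass
class Trial:
    """One subject-session recording.

    Attributes
    ----------
    imu:
        ``(12, n_samples)`` float array, rows ordered as :data:`IMU_CHANNELS`.
    contact_left, contact_right:
        Binary (0/1) foot-contact series of length ``n_samples``.
    fs:
        Sampling rate in Hz.
    subject_id, trial_id:
        Identifiers; a subject never appears in more than one split partition.
    """

    imu: np.ndarray
    contact_left: np.ndarray
    contact_right: np.ndarray
    fs: float
    subject_id: str
    trial_id: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.imu = np.asarray(self.imu, dtype=float)
        if self.imu.ndim != 2 or self.imu.shape[0] != len(IMU_CHANNELS):
            raise ValueError(
                f"imu must be (12, n_samples), got {self.imu.shape}"
            )
        if not np.all(np.isfinite(self.imu)):
            raise ValueError("imu matrix contains non-finite values")
        n = self.imu.shape[1]
        self.contact_left = np.asarray(self.contact_left)
        self.contact_right = np.asarray(self.contact_right)
        for name, c in (("contact_left", self.contact_left),
                        ("contact_right", self.contact_right)):
            if c.shape != (n,):
                raise ValueError(f"{name} length {c.shape} != n_samples {n}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.imu.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_imu(self, imu: np.ndarray) -> "Trial":
        """Copy of this trial with a replaced IMU matrix (same length)."""
        return replace(self, imu=imu)
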