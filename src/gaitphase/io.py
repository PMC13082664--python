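"""Readers and writers for the canonical on-disk formats.

Canonical trial CSV: ``time_s``, the 12 IMU columns named
``{side}_{acc|gyro}_{x|y|z}``, then ``contact_left``, ``contact_right``.
Labels CSV: ``sample_index, label_code, label_name``.  WindowSets are
persisted as ``.npz`` archives with a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from gaitphase.datasets import WindowSet
from gaitphase.events import PHASE_NAMES, GaitEvent, PhaseSequence
from gaitphase.synthetic import GaitSimParams, SimulatedTrial
from gaitphase.trial import IMU_CHANNELS, Trial

TRIAL_COLUMNS = ["time_s", *IMU_CHANNELS, "contact_left", "contact_right"]


class TrialFormatError(ValueError):
    pass


def write_trial_csv(trial: Trial, path: str | Path) -> Path:
    path = Path(path)
    time_s = np.arange(trial.n_samples) / trial.fs
    frame = pd.DataFrame({"time_s": time_s})
    for i, name in enumerate(IMU_CHANNELS):
        frame[name] = trial.imu[i]
    frame["contact_left"] = trial.contact_left.astype(int)
    frame["contact_right"] = trial.contact_right.astype(int)
    frame.to_csv(path, index=False, float_format="%.8g")
    return path


def read_trial_csv(path: str | Path, subject_id: str | None = None,
                   trial_id: str | None = None) -> Trial:
    """Read a canonical trial CSV; fs is inferred from the time column.

    Missing required columns or an irregular time grid raise
    :class:`TrialFormatError`; unknown extra columns are ignored with a
    warning.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialFormatError(f"{path.name}: missing columns {missing}")
    extra = [c for c in frame.columns if c not in TRIAL_COLUMNS]
    if extra:
        warnings.warn(f"{path.name}: ignoring unknown columns {extra}")
    t = frame["time_s"].to_numpy()
    steps = np.diff(t)
    if len(steps) == 0:
        raise TrialFormatError(f"{path.name}: need at least two samples")
    if np.any(steps <= 0):
        row = int(np.argmax(steps <= 0)) + 1
        raise TrialFormatError(f"{path.name}: time_s not increasing at row {row}")
    if np.ptp(steps) > 1e-6 * steps.mean():
        row = int(np.argmax(np.abs(steps - steps.mean()))) + 1
        raise TrialFormatError(f"{path.name}: irregular sampling near row {row}")
    fs = 1.0 / steps.mean()
    if subject_id is None or trial_id is None:
        stem_parts = path.stem.split("_")
        subject_id = subject_id or (stem_parts[0] if stem_parts else path.stem)
        trial_id = trial_id or (stem_parts[1] if len(stem_parts) > 1 else "T00")
    return Trial(
        imu=frame[IMU_CHANNELS].to_numpy().T,
        contact_left=frame["contact_left"].to_numpy(),
        contact_right=frame["contact_right"].to_numpy(),
        fs=float(round(fs, 6)),
        subject_id=subject_id,
        trial_id=trial_id,
    )


def write_truth_sidecar(trial: SimulatedTrial, params: GaitSimParams,
                        path: str | Path) -> Path:
    path = Path(path)
    params_dict = dataclasses.asdict(params)
    params_dict["template_amplitudes"] = np.asarray(
        params.template_amplitudes
    ).tolist()
    payload = {
        "subject_id": trial.subject_id,
        "trial_id": trial.trial_id,
        "fs": trial.fs,
        "events": [
            {"index": ev.index, "side": ev.side, "type": ev.type}
            for ev in sorted(trial.truth_events)
        ],
        "params": params_dict,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_truth_sidecar(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["events"] = [
        GaitEvent(e["index"], e["side"], e["type"]) for e in payload["events"]
    ]
    return payload


def write_labels_csv(phases: PhaseSequence, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "sample_index": np.arange(phases.n_samples),
            "label_code": phases.labels,
            "label_name": [PHASE_NAMES[int(v)] for v in phases.labels],
        }
    )
    frame.to_csv(path, index=False)
    return path


def read_labels_csv(path: str | Path, reference_side: str = "right") -> PhaseSequence:
    frame = pd.read_csv(path)
    for col in ("sample_index", "label_code"):
        if col not in frame.columns:
            raise TrialFormatError(f"{Path(path).name}: missing column {col}")
    return PhaseSequence(labels=frame["label_code"].to_numpy(),
                         reference_side=reference_side)


def save_window_set(ws: WindowSet, path: str | Path, manifest: dict | None = None) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        inputs=ws.inputs,
        targets=ws.targets,
        subject_ids=ws.subject_ids.astype(str),
        trial_ids=ws.trial_ids.astype(str),
        end_indices=ws.end_indices,
        w=ws.w,
        offset=ws.offset,
    )
    if manifest is not None:
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def save_checkpoint(model, path: str | Path, metadata: dict | None = None) -> Path:
    """Model weights as .npz plus a JSON metadata sidecar."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    if metadata is not None:
        path.with_suffix(".meta.json").write_text(json.dumps(metadata, indent=1))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint_into(model, path: str | Path) -> None:
    with np.load(path, allow_pickle=False) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})


def load_window_set(path: str | Path) -> WindowSet:
    with np.load(path, allow_pickle=False) as archive:
        return WindowSet(
            inputs=archive["inputs"],
            targets=archive["targets"],
            w=int(archive["w"]),
            offset=int(archive["offset"]),
            subject_ids=archive["subject_ids"].astype(object),
            trial_ids=archive["trial_ids"].astype(object),
            end_indices=archive["end_indices"],
        )
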