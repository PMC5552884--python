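"""On-disk containers: array-based recordings, trial tables, epoch sets.

A session is stored as a directory:

* ``recording.npz`` -- the signal matrix plus event arrays;
* ``recording.json`` -- channel names, sampling rate, metadata;
* ``trials.csv`` -- the behavioural table (one row per trial).

Epoch sets use the same pattern (``epochs.npz`` + JSON sidecar carrying the
lock types, trial indices and channel names).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ContinuousRecording, EpochSet, EventMarker

_KINDS = ("stimulus_onset", "response")


def save_recording(rec: ContinuousRecording, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    kinds = np.array([_KINDS.index(e.kind) for e in rec.events], dtype=int)
    np.savez_compressed(
        path / "recording.npz",
        data=rec.data,
        event_kind=kinds,
        event_sample=np.array([e.sample_index for e in rec.events], dtype=int),
        event_trial=np.array([e.trial_index for e in rec.events], dtype=int),
    )
    (path / "recording.json").write_text(
        json.dumps(
            {"channel_names": rec.channel_names, "sampling_rate": rec.sampling_rate}
        )
    )


def load_recording(path: str | Path) -> ContinuousRecording:
    path = Path(path)
    meta = json.loads((path / "recording.json").read_text())
    with np.load(path / "recording.npz") as npz:
        events = [
            EventMarker(_KINDS[k], int(s), int(t))
            for k, s, t in zip(npz["event_kind"], npz["event_sample"], npz["event_trial"])
        ]
        return ContinuousRecording(
            data=npz["data"],
            channel_names=list(meta["channel_names"]),
            sampling_rate=float(meta["sampling_rate"]),
            events=events,
        )


def save_trials(trials: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)


def load_trials(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_epoch_set(epochs: EpochSet, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path / "epochs.npz",
        stimulus=epochs.stimulus,
        response=epochs.response,
        trial_indices=epochs.trial_indices,
    )
    (path / "epochs.json").write_text(
        json.dumps(
            {
                "channel_names": epochs.channel_names,
                "locks": ["stimulus", "response"],
                "excluded": list(map(int, epochs.excluded)),
            }
        )
    )


def load_epoch_set(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = json.loads((path / "epochs.json").read_text())
    with np.load(path / "epochs.npz") as npz:
        return EpochSet(
            stimulus=npz["stimulus"],
            response=npz["response"],
            trial_indices=npz["trial_indices"],
            channel_names=list(meta["channel_names"]),
            excluded=list(meta["excluded"]),
        )
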