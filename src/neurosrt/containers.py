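"""In-memory containers for EEG trials and datasets, with HDF5 + JSON I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EegTrial", "EegDataset", "CLEAN", "save_dataset", "load_dataset"]

#: Condition token for the clean-speech (no noise) condition.
CLEAN = "clean"


def condition_key(snr_db) -> str:
    """Canonical string key for a condition label (float dB or 'clean')."""
    if isinstance(snr_db, str):
        return snr_db
    return f"{float(snr_db):+.2f}"


@dataclass
class EegTrial:
    """One trial of multichannel EEG with its stimulus envelope.

    ``data`` is (channels, samples); ``condition`` is the SNR in dB or
    the token ``"clean"``; ``envelope`` is the stimulus envelope at the
    same rate (present for synthetic data and after alignment for real
    data).
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str]
    condition: float | str
    trial_id: str = ""
    participant_id: str = ""
    envelope: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (channels, samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels must match the number of data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EegDataset:
    """All trials of one participant plus simulation ground truth (if any)."""

    trials: list[EegTrial]
    channel_labels: list[str]
    rate: float
    participant_id: str = ""
    conditions: list = field(default_factory=list)
    ground_truth: dict | None = None

    def by_condition(self, condition) -> list[EegTrial]:
        key = condition_key(condition)
        return [t for t in self.trials if condition_key(t.condition) == key]

    @property
    def noise_conditions(self) -> list[float]:
        return [c for c in self.conditions if not isinstance(c, str)]


def save_dataset(dataset: EegDataset, h5path: str) -> None:
    """Write a dataset to HDF5 with a JSON sidecar (<path>.json).

    The sidecar carries conditions, seeds, and the serializable part of
    the ground truth; arrays live in the HDF5 container.
    """
    import h5py

    with h5py.File(h5path, "w") as fh:
        fh.attrs["rate"] = dataset.rate
        fh.attrs["participant_id"] = dataset.participant_id
        fh.attrs["channel_labels"] = json.dumps(dataset.channel_labels)
        for i, tr in enumerate(dataset.trials):
            grp = fh.create_group(f"trial_{i:04d}")
            grp.create_dataset("data", data=tr.data)
            if tr.envelope is not None:
                grp.create_dataset("envelope", data=tr.envelope)
            grp.attrs["condition"] = condition_key(tr.condition)
            grp.attrs["trial_id"] = tr.trial_id
            grp.attrs["seed"] = -1 if tr.seed is None else tr.seed

    sidecar = {
        "participant_id": dataset.participant_id,
        "rate": dataset.rate,
        "conditions": [condition_key(c) for c in dataset.conditions],
        "n_trials": len(dataset.trials),
        "ground_truth": _jsonable(dataset.ground_truth),
    }
    with open(h5path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_dataset(h5path: str) -> EegDataset:
    import h5py

    with open(h5path + ".json") as fh:
        sidecar = json.load(fh)
    trials = []
    with h5py.File(h5path, "r") as fh:
        labels = json.loads(fh.attrs["channel_labels"])
        rate = float(fh.attrs["rate"])
        pid = str(fh.attrs["participant_id"])
        for name in sorted(k for k in fh if k.startswith("trial_")):
            grp = fh[name]
            cond = grp.attrs["condition"]
            cond = cond if cond == CLEAN else float(cond)
            seed = int(grp.attrs["seed"])
            trials.append(
                EegTrial(
                    data=grp["data"][()],
                    rate=rate,
                    channel_labels=labels,
                    condition=cond,
                    trial_id=str(grp.attrs["trial_id"]),
                    participant_id=pid,
                    envelope=grp["envelope"][()] if "envelope" in grp else None,
                    seed=None if seed == -1 else seed,
                )
            )
    conditions = [c if c == CLEAN else float(c) for c in sidecar["conditions"]]
    return EegDataset(
        trials=trials,
        channel_labels=labels,
        rate=rate,
        participant_id=pid,
        conditions=conditions,
        ground_truth=sidecar.get("ground_truth"),
    )


def _jsonable(obj):
    if obj is None:
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
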