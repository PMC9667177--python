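"""Core in-memory containers and their on-disk array-container format.

Epoched EEG is held as a plain ``trials x channels x samples`` array plus a
per-trial metadata table.  On disk each ``Epochs`` object becomes a pair of
files: a little-endian float32 ``.npy`` array and a JSON sidecar carrying the
sampling rate, epoch start time, channel names and the metadata records, so a
cohort is portable without any binary container library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: metadata columns every epoch table carries (extra columns are preserved)
METADATA_COLUMNS = ("subject", "phase", "context", "condition", "success")


@dataclass
class Epochs:
    """Epoched multichannel EEG with aligned per-trial metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    t0
        Time of the first sample in seconds relative to the trial event
        (movie onset for encoding, word-cue onset for retrieval).
    channel_names
        One name per channel, in data order.
    metadata
        DataFrame with one row per trial.
    """

    data: np.ndarray
    fs: float
    t0: float
    channel_names: list[str]
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length mismatch")
        if len(self.metadata) not in (0, self.data.shape[0]):
            raise ValueError("metadata length must equal trial count")
        if len(self.metadata) == 0:
            self.metadata = pd.DataFrame(index=range(self.data.shape[0]))
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        """Time axis in seconds relative to the trial event."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy_with(self, **kw) -> "Epochs":
        args = dict(
            data=self.data,
            fs=self.fs,
            t0=self.t0,
            channel_names=list(self.channel_names),
            metadata=self.metadata.copy(),
        )
        args.update(kw)
        return Epochs(**args)

    # ------------------------------------------------------------------ I/O
    def save(self, directory: str | Path, stem: str) -> None:
        """Write ``<stem>.npy`` (float32) and ``<stem>.json`` sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / f"{stem}.npy", self.data.astype("<f4"))
        sidecar = {
            "fs": float(self.fs),
            "t0": float(self.t0),
            "channel_names": list(self.channel_names),
            "metadata": json.loads(self.metadata.to_json(orient="records")),
        }
        (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory: str | Path, stem: str) -> "Epochs":
        directory = Path(directory)
        data = np.load(directory / f"{stem}.npy")
        sidecar = json.loads((directory / f"{stem}.json").read_text())
        meta = pd.DataFrame(sidecar["metadata"])
        return cls(
            data=data.astype(np.float64),
            fs=sidecar["fs"],
            t0=sidecar["t0"],
            channel_names=sidecar["channel_names"],
            metadata=meta,
        )

    def export_metadata(self, path: str | Path) -> None:
        """Delimited-text export of the per-trial metadata."""
        self.metadata.to_csv(path, sep="\t", index=False)
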