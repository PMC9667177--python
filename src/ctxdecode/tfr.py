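"""Complex Morlet time-frequency decomposition and decoding features.

Power is computed by convolving each trial/channel signal with L2-normalized
complex Morlet wavelets (Gaussian-windowed complex exponentials with
sigma_t = width / (2 pi f)) and squaring the magnitude, on a 4-45 Hz / 1 Hz
grid sampled every 0.05 s by default.  The heavy convolution is delegated to
MNE-Python's ``tfr_array_morlet``; this module owns the grid, the edge-
validity bookkeeping, and the feature constructions used by the decoder
(whole-window averages for encoding, single-bin slices for the 85-bin
retrieval grid) and by the univariate analysis (log power against a pre-cue
baseline).

Decoding features deliberately receive no baseline correction; across-trial
z-scoring of every (channel, frequency) feature replaces it.  Normalization
statistics are computed on training trials only and frozen onto any other
matrix (test folds, retrieval bins), keeping cross-validation honest; pooled
normalization over all trials is available for comparison.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Epochs

logger = logging.getLogger(__name__)

#: default analysis grid: 4..45 Hz in 1 Hz steps (42 frequencies)
DEFAULT_FREQS = np.arange(4.0, 46.0)
DEFAULT_TIME_STEP = 0.05
DEFAULT_WIDTH = 5.0
#: retrieval testing grid: 85 bins from -0.2 to 4.0 s in 0.05 s steps
RETRIEVAL_BIN_TIMES = np.round(np.arange(-0.2, 4.0 + 1e-9, 0.05), 10)

# half-support (in units of sigma_t) beyond which a wavelet is treated as
# overrunning the epoch edge; 2.5 sigma covers >98% of the Gaussian mass
EDGE_SIGMA = 2.5


@dataclass
class TFRStack:
    """Trials x channels x frequencies x time-bins power with coordinates."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    valid: np.ndarray | None = None  # (n_freqs, n_times) bool

    def __post_init__(self):
        if self.power.ndim != 4:
            raise ValueError("power must be 4-D (trials, channels, freqs, times)")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones((len(self.freqs), len(self.times)), dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    @property
    def n_channels(self) -> int:
        return self.power.shape[1]

    # ------------------------------------------------------------------ I/O
    def save(self, directory, stem: str) -> None:
        """Array container (.npy float32) plus a JSON sidecar with the
        frequency/time grids, channel names, validity and metadata."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / f"{stem}.npy", self.power.astype("<f4"))
        sidecar = {
            "freqs": self.freqs.tolist(),
            "times": self.times.tolist(),
            "channel_names": list(self.channel_names),
            "valid": self.valid.astype(int).tolist(),
            "metadata": json.loads(self.metadata.to_json(orient="records")),
        }
        (directory / f"{stem}.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, directory, stem: str) -> "TFRStack":
        import json
        from pathlib import Path

        directory = Path(directory)
        power = np.load(directory / f"{stem}.npy").astype(np.float64)
        sc = json.loads((directory / f"{stem}.json").read_text())
        return cls(
            power=power,
            freqs=np.asarray(sc["freqs"], float),
            times=np.asarray(sc["times"], float),
            channel_names=sc["channel_names"],
            metadata=pd.DataFrame(sc["metadata"]),
            valid=np.asarray(sc["valid"], bool),
        )


@dataclass
class FeatureMatrix:
    """Trials x features matrix with a channel-major (channel, freq) index."""

    values: np.ndarray
    feature_index: list[tuple[str, float]]
    normalization: str | tuple = "raw"
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def index_hash(self) -> str:
        payload = repr(self.feature_index).encode()
        return hashlib.sha1(payload).hexdigest()

    def subset(self, keep: np.ndarray) -> "FeatureMatrix":
        """Column subset keeping the index aligned (for searchlights)."""
        keep = np.asarray(keep)
        return FeatureMatrix(
            values=self.values[:, keep],
            feature_index=[self.feature_index[i] for i in keep],
            normalization=self.normalization,
            metadata=self.metadata,
        )


def wavelet_sigma_t(freq: float, width: float) -> float:
    """Temporal SD of the Morlet envelope: width cycles / (2 pi f)."""
    return width / (2.0 * np.pi * freq)


def morlet_tfr(
    epochs: Epochs,
    freqs: np.ndarray = DEFAULT_FREQS,
    time_step: float = DEFAULT_TIME_STEP,
    width: float = DEFAULT_WIDTH,
) -> TFRStack:
    """Complex Morlet power on a decimated time grid.

    ``time_step`` must be an integer number of samples.  Bins whose wavelet
    (+- 2.5 sigma_t at that frequency) overruns the epoch are marked invalid
    in ``TFRStack.valid``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    if width < 1:
        raise ValueError("wavelet width must be >= 1 cycle")
    decim = time_step * epochs.fs
    if abs(decim - round(decim)) > 1e-6:
        raise ValueError(
            f"time_step {time_step} s is not an integer number of samples "
            f"at fs={epochs.fs}"
        )
    decim = int(round(decim))
    epoch_len = epochs.n_samples / epochs.fs
    lowest_support = 2 * EDGE_SIGMA * wavelet_sigma_t(freqs.min(), width)
    if epoch_len < lowest_support:
        raise ValueError(
            f"epoch ({epoch_len:.2f} s) shorter than the lowest-frequency "
            f"wavelet support ({lowest_support:.2f} s)"
        )

    from mne.time_frequency import tfr_array_morlet

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        power = tfr_array_morlet(
            epochs.data.astype(np.float64),
            sfreq=epochs.fs,
            freqs=freqs,
            n_cycles=width,
            output="power",
            decim=decim,
            zero_mean=True,
        )
    # L2-normalized wavelets respond to a unit sinusoid with power ~ 1/f;
    # equalize the per-frequency gain so ridge power tracks amplitude^2
    # independent of frequency (feature z-scoring and log-baselining are
    # insensitive to this, but it makes raw power comparable across rows)
    power = power * freqs[None, None, :, None]
    times = epochs.times()[::decim]
    t_start, t_end = epochs.times()[0], epochs.times()[-1]
    half = EDGE_SIGMA * width / (2 * np.pi * freqs)
    valid = (times[None, :] - half[:, None] >= t_start - 1e-9) & (
        times[None, :] + half[:, None] <= t_end + 1e-9
    )
    return TFRStack(
        power=power.astype(np.float64),
        freqs=freqs,
        times=times,
        channel_names=list(epochs.channel_names),
        metadata=epochs.metadata.copy(),
        valid=valid,
    )


def _feature_index(tfr: TFRStack) -> list[tuple[str, float]]:
    # channel-major ordering: all frequencies of channel 0, then channel 1, ...
    return [(ch, float(f)) for ch in tfr.channel_names for f in tfr.freqs]


def window_average_features(tfr: TFRStack, t0: float, t1: float) -> FeatureMatrix:
    """Mean power over bins in [t0, t1] per (channel, frequency).

    Only bins valid at every frequency enter the average; an empty window is
    an error.
    """
    all_valid = tfr.valid.all(axis=0)
    in_win = (tfr.times >= t0 - 1e-9) & (tfr.times <= t1 + 1e-9)
    use = in_win & all_valid
    if not use.any():
        raise ValueError(f"no valid time bins in window [{t0}, {t1}]")
    if in_win.sum() != use.sum():
        logger.warning(
            "window [%g, %g]: %d edge-invalid bins excluded",
            t0,
            t1,
            int(in_win.sum() - use.sum()),
        )
    mean = tfr.power[:, :, :, use].mean(axis=-1)  # (tr, ch, fr)
    values = mean.reshape(tfr.n_trials, -1)
    return FeatureMatrix(values, _feature_index(tfr), "raw", tfr.metadata.copy())


def bin_features(tfr: TFRStack, t: float, tol: float = 1e-9) -> FeatureMatrix:
    """Single-bin slice at grid time ``t`` (same feature order as windows)."""
    d = np.abs(tfr.times - t)
    i = int(np.argmin(d))
    if d[i] > tol:
        raise ValueError(f"time {t} is not on the bin grid (nearest {tfr.times[i]})")
    if not tfr.valid[:, i].all():
        logger.warning("bin at t=%g s is edge-invalid for some frequencies", t)
    values = tfr.power[:, :, :, i].reshape(tfr.n_trials, -1)
    return FeatureMatrix(values, _feature_index(tfr), "raw", tfr.metadata.copy())


def normalize_across_trials(
    train: FeatureMatrix,
    others: list[FeatureMatrix] | None = None,
    eps: float = 1e-12,
):
    """Z-score each feature using mean/SD (sample SD, ddof=1) from ``train``.

    The frozen statistics are applied unchanged to every matrix in
    ``others``.  Features with SD below ``eps`` are zeroed (and counted in
    the log) rather than divided.
    Returns ``(train_normalized, others_normalized, (mean, sd))``.
    """
    if train.n_trials < 2:
        raise ValueError("need >= 2 training trials per feature to normalize")
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=1)
    dead = sd < eps
    if dead.any():
        logger.warning("%d features with ~zero SD set to 0", int(dead.sum()))
    sd_safe = np.where(dead, 1.0, sd)

    def apply(fm: FeatureMatrix) -> FeatureMatrix:
        v = (fm.values - mean) / sd_safe
        v[:, dead] = 0.0
        return FeatureMatrix(
            v, list(fm.feature_index), ("zscore", mean, sd), fm.metadata
        )

    out_train = apply(train)
    out_others = [apply(o) for o in (others or [])]
    return out_train, out_others, (mean, sd)


def log_baseline_tfr(
    tfr: TFRStack, base_window: tuple[float, float] = (-1.0, 0.0), floor: float = 1e-20
) -> TFRStack:
    """Log power relative to the mean log power in ``base_window``.

    Used by the univariate analysis only; decoding features stay raw.
    """
    b0, b1 = base_window
    in_base = (tfr.times >= b0 - 1e-9) & (tfr.times <= b1 + 1e-9)
    if not in_base.any():
        raise ValueError(f"baseline window [{b0}, {b1}] has no bins")
    power = tfr.power
    if (power <= 0).any():
        warnings.warn("non-positive power floored before log", UserWarning)
        power = np.maximum(power, floor)
    logp = np.log(power)
    base = logp[:, :, :, in_base].mean(axis=-1, keepdims=True)
    return TFRStack(
        power=logp - base,
        freqs=tfr.freqs,
        times=tfr.times,
        channel_names=list(tfr.channel_names),
        metadata=tfr.metadata.copy(),
        valid=tfr.valid.copy(),
    )
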