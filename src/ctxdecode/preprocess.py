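"""Deterministic epoch preprocessing.

Covers the minimal, fully reproducible steps applied to epoched data before
spectral decomposition: linked-mastoid re-referencing, whole-epoch mean
baseline removal, anti-aliased integer-factor downsampling, and metadata-
driven trial selection.  Manual artifact screening and ICA are inherently
interactive and are replaced by an externally supplied keep-mask hook.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import filtfilt, firwin

from .containers import Epochs

logger = logging.getLogger(__name__)


def rereference_linked_mastoids(epochs: Epochs, left: str, right: str) -> Epochs:
    """Subtract the mean of the two mastoid channels from every channel.

    The mastoid channels themselves are dropped from the output.
    """
    names = epochs.channel_names
    for ch in (left, right):
        if ch not in names:
            raise KeyError(f"mastoid channel {ch!r} not present")
    li, ri = names.index(left), names.index(right)
    ref = 0.5 * (epochs.data[:, li, :] + epochs.data[:, ri, :])
    keep = [i for i, n in enumerate(names) if n not in (left, right)]
    data = epochs.data[:, keep, :] - ref[:, None, :]
    return epochs.copy_with(data=data, channel_names=[names[i] for i in keep])


def baseline_epoch_mean(epochs: Epochs) -> Epochs:
    """Remove each trial x channel temporal mean (whole-epoch baseline)."""
    data = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    return epochs.copy_with(data=data)


def downsample(epochs: Epochs, target_fs: float) -> Epochs:
    """Anti-alias low-pass then decimate to ``target_fs``.

    The decimation factor must be an integer.  The anti-alias filter is a
    zero-phase FIR (applied forward and backward) with cutoff at 0.4 x
    ``target_fs``, leaving a transition band below the new Nyquist.
    """
    q = epochs.fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError(
            f"target_fs {target_fs} must divide fs {epochs.fs} (factor {q:.3f})"
        )
    q = int(round(q))
    if q == 1:
        return epochs.copy_with()
    numtaps = max(33, 16 * q + 1)
    taps = firwin(numtaps, 0.4 * target_fs, fs=epochs.fs)
    filtered = filtfilt(taps, [1.0], epochs.data, axis=-1)
    data = filtered[..., ::q]
    return epochs.copy_with(data=data, fs=target_fs)


def select_trials(epochs: Epochs, predicate) -> Epochs:
    """Keep trials whose metadata row satisfies ``predicate``.

    ``predicate`` maps a metadata row (pandas Series) to bool.  Trial order
    is preserved; an empty selection is legal but logged as a warning.
    """
    mask = epochs.metadata.apply(predicate, axis=1).to_numpy(dtype=bool)
    n_kept = int(mask.sum())
    if n_kept == 0:
        logger.warning("select_trials: empty selection (0 of %d)", len(mask))
    else:
        logger.info("select_trials: kept %d of %d trials", n_kept, len(mask))
    return epochs.copy_with(
        data=epochs.data[mask], metadata=epochs.metadata.loc[mask]
    )


def apply_keep_mask(epochs: Epochs, keep: np.ndarray) -> Epochs:
    """Externally supplied artifact keep-mask (stands in for manual screening)."""
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (epochs.n_trials,):
        raise ValueError("keep mask must have one entry per trial")
    return epochs.copy_with(data=epochs.data[keep], metadata=epochs.metadata.loc[keep])
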