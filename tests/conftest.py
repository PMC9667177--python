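"""Shared fixtures: small synthetic cohorts and feature sets.

Simulation sizes here are deliberately reduced (few channels, 100 Hz, coarse
frequency grids) so the full suite runs quickly on one CPU; the generator
and pipeline code paths are identical to experiment-scale runs.
"""

import logging
import warnings

import numpy as np
import pandas as pd
import pytest

import ctxdecode as cx

logging.disable(logging.WARNING)
warnings.filterwarnings("ignore", message=".*did not converge.*")


def small_config(**kw) -> cx.SimConfig:
    """A fast cohort configuration; override any field via kwargs."""
    base = dict(
        n_subjects=4,
        n_channels=8,
        fs=100.0,
        n_blocks=4,
        pairs_per_condition_per_block=2,
        snr=1.5,
        seed=123,
    )
    base.update(kw)
    return cx.SimConfig(**base)


SMALL_FREQS = np.arange(4.0, 25.0, 4.0)  # 6 frequencies


@pytest.fixture(scope="session")
def cohort_hi_snr() -> cx.SyntheticCohort:
    """4-subject cohort with clearly decodable context signatures."""
    return cx.generate_cohort(small_config())


@pytest.fixture(scope="session")
def encoding_features(cohort_hi_snr):
    """Per-subject encoding window-average features and context labels."""
    feats, labels = [], []
    for sid in cohort_hi_snr.subject_ids:
        enc = cohort_hi_snr.subjects[sid]["encoding"]
        tfr = cx.morlet_tfr(enc, freqs=SMALL_FREQS)
        feats.append(cx.window_average_features(tfr, 0.0, 6.0))
        labels.append(enc.metadata["context"].to_numpy())
    return feats, labels


def make_epochs(data, fs=100.0, t0=0.0, names=None, metadata=None) -> cx.Epochs:
    data = np.asarray(data, dtype=float)
    if names is None:
        names = [f"CH{i + 1:02d}" for i in range(data.shape[1])]
    md = metadata if metadata is not None else pd.DataFrame(index=range(len(data)))
    return cx.Epochs(data=data, fs=fs, t0=t0, channel_names=names, metadata=md)
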