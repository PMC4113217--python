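"""Glue between sessions and the two decoders' feature representations.

The generator emits 100 Hz epochs directly (the acquisition chain — 1 kHz
recording, hardware band-pass, 45 Hz low-pass, downsampling — is treated as
upstream), so the online chain applied here is: baseline correction,
interval-mean feature extraction, and, for the unsupervised decoder only,
per-trial normalization plus the bias feature.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .preprocessing import (
    EpochSet,
    FeatureMatrix,
    baseline_correct,
    extract_features,
    normalize_and_bias,
    reject_outlier_epochs,
)
from .synthetic import SyntheticSession

__all__ = [
    "session_epochs",
    "raw_features",
    "unsupervised_features",
    "supervised_training_set",
]


def session_epochs(
    session: SyntheticSession, blocks: Optional[Sequence[int]] = None
) -> EpochSet:
    """Baseline-corrected epochs of the selected blocks (all by default)."""
    if blocks is None:
        es = session.epochs
    else:
        mask = np.isin(session.block_ids, np.asarray(blocks))
        es = session.epochs.select(mask)
    return baseline_correct(es)


def raw_features(
    session: SyntheticSession, blocks: Optional[Sequence[int]] = None
) -> tuple[FeatureMatrix, np.ndarray]:
    """Un-normalized 372-dim features plus per-trial ground truth."""
    es = session_epochs(session, blocks)
    fm = extract_features(es)
    truth = np.array([session.trials[t].attended for t in fm.trials])
    return fm, truth


def unsupervised_features(
    session: SyntheticSession, blocks: Optional[Sequence[int]] = None
) -> tuple[FeatureMatrix, np.ndarray]:
    """Normalized, bias-augmented features for the unsupervised decoder."""
    fm, truth = raw_features(session, blocks)
    return normalize_and_bias(fm), truth


def supervised_training_set(
    session: SyntheticSession,
    blocks: Sequence[int] = (0,),
    *,
    reject_outliers: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled calibration data for the LDA baseline.

    Returns (X, y): un-normalized feature vectors and boolean target labels,
    after the calibration-only variance-based outlier rejection.
    """
    es = session_epochs(session, blocks)
    if reject_outliers:
        es, _ = reject_outlier_epochs(es)
    fm = extract_features(es)
    attended = np.array([session.trials[t].attended for t in fm.trial_ids])
    y = fm.stimulus_ids == attended
    return fm.X, y
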