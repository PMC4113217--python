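"""Online ERP preprocessing chain.

Mirrors the online pipeline of a fast auditory ERP speller: causal Chebyshev
type-2 low-pass on the continuous signal, epoching to [-200, 700] ms around
stimulus onsets, pre-stimulus baseline subtraction, a variance-based outlier
rejection applied to calibration data only, interval-mean features
(12 intervals x channels = 372 features by default), and — for the
unsupervised decoder only — per-trial feature normalization plus a constant
bias feature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "FeatureMatrix",
    "DEFAULT_INTERVALS_MS",
    "DEFAULT_WINDOW_S",
    "causal_lowpass",
    "acausal_bandpass",
    "epoch_and_baseline",
    "baseline_correct",
    "reject_outlier_epochs",
    "reject_outlier_channels",
    "extract_features",
    "normalize_and_bias",
    "resample_to",
]

#: epoch window relative to stimulus onset, seconds
DEFAULT_WINDOW_S = (-0.2, 0.7)
#: baseline estimation interval, seconds
DEFAULT_BASELINE_S = (-0.2, 0.0)

#: the 12 feature intervals in ms post stimulus: five short windows for the
#: early transient components, seven longer ones for the late slow components.
DEFAULT_INTERVALS_MS = (
    (100, 130), (130, 160), (160, 190), (190, 220), (220, 250),
    (250, 300), (300, 350), (350, 400), (400, 450), (450, 500),
    (500, 600), (600, 700),
)


@dataclass
class EpochSet:
    """Per-presentation EEG epochs with stimulus identity and trial membership.

    ``epochs`` has shape (n_epochs, n_channels, n_samples); all epochs share
    the window and sampling rate.
    """

    epochs: np.ndarray
    sampling_rate: float
    window: tuple[float, float] = DEFAULT_WINDOW_S
    stimulus_ids: Optional[np.ndarray] = None
    trial_ids: Optional[np.ndarray] = None
    channel_names: Optional[list[str]] = None

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        for name in ("stimulus_ids", "trial_ids"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=int)
                if v.shape != (len(self),):
                    raise ValueError(f"{name} must have one entry per epoch")
                setattr(self, name, v)

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.window[0] + np.arange(self.n_samples) / self.sampling_rate

    def select(self, index: np.ndarray) -> "EpochSet":
        return EpochSet(
            epochs=self.epochs[index],
            sampling_rate=self.sampling_rate,
            window=self.window,
            stimulus_ids=None if self.stimulus_ids is None else self.stimulus_ids[index],
            trial_ids=None if self.trial_ids is None else self.trial_ids[index],
            channel_names=self.channel_names,
        )


@dataclass
class FeatureMatrix:
    """Per-epoch feature vectors grouped by trial.

    ``X`` has shape (n_epochs, D) with D = n_channels * n_intervals, or D + 1
    once the constant bias feature is appended (``has_bias``).
    """

    X: np.ndarray
    stimulus_ids: np.ndarray
    trial_ids: np.ndarray
    normalized: bool = False
    has_bias: bool = False

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.stimulus_ids = np.asarray(self.stimulus_ids, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        n = self.X.shape[0]
        if self.stimulus_ids.shape != (n,) or self.trial_ids.shape != (n,):
            raise ValueError("stimulus_ids/trial_ids must have one entry per epoch")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    @property
    def trials(self) -> np.ndarray:
        """Distinct trial identifiers in order of first appearance."""
        _, idx = np.unique(self.trial_ids, return_index=True)
        return self.trial_ids[np.sort(idx)]

    def trial_slice(self, trial_id: int) -> "FeatureMatrix":
        m = self.trial_ids == trial_id
        return FeatureMatrix(
            self.X[m], self.stimulus_ids[m], self.trial_ids[m],
            normalized=self.normalized, has_bias=self.has_bias,
        )


def causal_lowpass(
    data: np.ndarray, sampling_rate: float, cutoff: float = 40.0,
    *, order: int = 5, attenuation_db: float = 20.0,
) -> np.ndarray:
    """Forward-only Chebyshev type-2 low-pass (stop edge *cutoff*, 20 dB).

    Operates along the last axis; strictly causal, as required for online use.
    """
    if cutoff >= sampling_rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below Nyquist ({sampling_rate / 2} Hz)"
        )
    sos = signal.cheby2(order, attenuation_db, cutoff, btype="low",
                        fs=sampling_rate, output="sos")
    return signal.sosfilt(sos, np.asarray(data, dtype=float), axis=-1)


def acausal_bandpass(
    data: np.ndarray, sampling_rate: float,
    band: tuple[float, float] = (0.5, 20.0), *, order: int = 4,
) -> np.ndarray:
    """Zero-phase forward-backward Butterworth band-pass (visualization path only)."""
    lo, hi = band
    if not 0 < lo < hi < sampling_rate / 2:
        raise ValueError("band edges must satisfy 0 < lo < hi < Nyquist")
    sos = signal.butter(order, (lo, hi), btype="band", fs=sampling_rate, output="sos")
    data = np.asarray(data, dtype=float)
    padlen = min(3 * (2 * order + 1), data.shape[-1] - 1)
    return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


def epoch_and_baseline(
    continuous: np.ndarray,
    sampling_rate: float,
    onsets_s: Sequence[float],
    *,
    window: tuple[float, float] = DEFAULT_WINDOW_S,
    baseline: tuple[float, float] = DEFAULT_BASELINE_S,
    stimulus_ids: Optional[Sequence[int]] = None,
    trial_ids: Optional[Sequence[int]] = None,
) -> tuple[EpochSet, np.ndarray]:
    """Cut epochs around stimulus onsets and subtract the pre-stimulus baseline.

    Returns the epoch set and the indices of the onsets that were kept; onsets
    whose window exceeds the signal bounds are skipped with a logged warning.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_ch, n_samp = continuous.shape
    n_win = int(round((window[1] - window[0]) * sampling_rate))
    epochs, kept = [], []
    for i, t in enumerate(onsets_s):
        start = int(round((t + window[0]) * sampling_rate))
        if start < 0 or start + n_win > n_samp:
            logger.warning("onset %d at %.3f s too close to signal edge; skipped", i, t)
            continue
        epochs.append(continuous[:, start:start + n_win])
        kept.append(i)
    kept = np.asarray(kept, dtype=int)
    arr = (np.stack(epochs) if epochs
           else np.empty((0, n_ch, n_win)))
    es = EpochSet(
        arr, sampling_rate, window,
        stimulus_ids=None if stimulus_ids is None else np.asarray(stimulus_ids)[kept],
        trial_ids=None if trial_ids is None else np.asarray(trial_ids)[kept],
    )
    return baseline_correct(es, baseline=baseline), kept


def baseline_correct(
    epochs: EpochSet, baseline: tuple[float, float] = DEFAULT_BASELINE_S
) -> EpochSet:
    """Subtract each channel's mean over the baseline interval from each epoch."""
    t = epochs.times
    m = (t >= baseline[0]) & (t < baseline[1])
    if not m.any():
        raise ValueError("baseline interval contains no samples")
    corrected = epochs.epochs - epochs.epochs[:, :, m].mean(axis=2, keepdims=True)
    out = replace(epochs)
    out.epochs = corrected
    return out


def _epoch_variances(epochs: EpochSet, per_channel: bool) -> np.ndarray:
    if per_channel:
        # max across channels of the per-channel sample variance
        return epochs.epochs.var(axis=2).max(axis=1)
    # variance of all channel-sample values pooled into one scalar per epoch
    flat = epochs.epochs.reshape(len(epochs), -1)
    return flat.var(axis=1)


def reject_outlier_epochs(
    epochs: EpochSet,
    *,
    factor: float = 2.5,
    percentile: float = 90.0,
    per_channel: bool = False,
) -> tuple[EpochSet, np.ndarray]:
    """Remove high-variance epochs (calibration data only).

    The threshold is the 90th percentile (linear interpolation between order
    statistics) of the per-epoch variances; epochs whose variance exceeds
    ``factor`` (2.5) times that threshold are rejected.  Returns the kept
    epochs and the indices of the rejected ones.
    """
    n = len(epochs)
    if n < 2:
        raise ValueError("need at least 2 epochs to estimate a variance threshold")
    if n < 10:
        warnings.warn("fewer than 10 epochs: percentile threshold is unreliable")
    variances = _epoch_variances(epochs, per_channel)
    threshold = np.percentile(variances, percentile)
    rejected = np.nonzero(variances > factor * threshold)[0]
    kept_mask = np.ones(n, dtype=bool)
    kept_mask[rejected] = False
    return epochs.select(kept_mask), rejected


def reject_outlier_channels(
    epochs: EpochSet, *, factor: float = 2.5, percentile: float = 90.0
) -> tuple[EpochSet, np.ndarray]:
    """Offline utility: drop channels whose pooled variance is an outlier.

    Not part of the online chain; mirrors the offline-only channel cleaning.
    """
    v = epochs.epochs.transpose(1, 0, 2).reshape(epochs.n_channels, -1).var(axis=1)
    threshold = np.percentile(v, percentile)
    bad = np.nonzero(v > factor * threshold)[0]
    keep = np.setdiff1d(np.arange(epochs.n_channels), bad)
    out = replace(epochs)
    out.epochs = epochs.epochs[:, keep, :]
    if epochs.channel_names is not None:
        out.channel_names = [epochs.channel_names[i] for i in keep]
    return out, bad


def interval_sample_slices(
    intervals_ms: Sequence[tuple[float, float]],
    sampling_rate: float,
    window: tuple[float, float],
    n_samples: int,
) -> list[slice]:
    """Sample index ranges (end-exclusive) of the feature intervals."""
    slices = []
    for a, b in intervals_ms:
        if a / 1000.0 < window[0] - 1e-9 or b / 1000.0 > window[1] + 1e-9:
            raise ValueError(f"interval [{a}, {b}] ms outside epoch window {window}")
        start = int(round((a / 1000.0 - window[0]) * sampling_rate))
        stop = int(round((b / 1000.0 - window[0]) * sampling_rate))
        stop = min(stop, n_samples)
        if stop <= start:
            raise ValueError(f"interval [{a}, {b}] ms contains no samples")
        slices.append(slice(start, stop))
    return slices


def extract_features(
    epochs: EpochSet,
    intervals_ms: Sequence[tuple[float, float]] = DEFAULT_INTERVALS_MS,
) -> FeatureMatrix:
    """Interval-mean features: mean potential per channel per interval.

    With 31 channels and the 12 default intervals this yields 372-dimensional
    feature vectors, concatenated channel-major (channel 0's 12 intervals
    first).
    """
    if epochs.stimulus_ids is None or epochs.trial_ids is None:
        raise ValueError("epochs need stimulus_ids and trial_ids for decoding features")
    slices = interval_sample_slices(
        intervals_ms, epochs.sampling_rate, epochs.window, epochs.n_samples
    )
    feats = np.stack(
        [epochs.epochs[:, :, s].mean(axis=2) for s in slices], axis=2
    )  # (n_epochs, n_channels, n_intervals)
    X = feats.reshape(len(epochs), -1)
    return FeatureMatrix(X, epochs.stimulus_ids, epochs.trial_ids)


def normalize_and_bias(features: FeatureMatrix) -> FeatureMatrix:
    """Per-trial feature-wise z-scoring plus a constant bias feature of 1.

    Within every trial each feature is shifted to zero mean and scaled to unit
    variance over that trial's epochs; a feature that is constant within a
    trial is set to zero (guarded, with a warning) rather than producing NaN.
    The bias feature lets the decoder control its offset directly.
    """
    if features.has_bias:
        raise ValueError("features already carry a bias column")
    X = features.X.copy()
    for t in features.trials:
        m = features.trial_ids == t
        if m.sum() < 2:
            raise ValueError(f"trial {t} has fewer than 2 epochs")
        block = X[m]
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        zero = sd == 0
        if zero.any():
            warnings.warn(
                f"trial {t}: {int(zero.sum())} constant feature(s) set to zero"
            )
        sd[zero] = 1.0
        block = (block - mu) / sd
        block[:, zero] = 0.0
        X[m] = block
    X = np.hstack([X, np.ones((X.shape[0], 1))])
    return FeatureMatrix(
        X, features.stimulus_ids, features.trial_ids, normalized=True, has_bias=True
    )


def resample_to(
    data: np.ndarray, sampling_rate: float, target_rate: float
) -> np.ndarray:
    """Polyphase resampling utility for imported real data (upstream step)."""
    from fractions import Fraction

    frac = Fraction(target_rate / sampling_rate).limit_denominator(1000)
    return signal.resample_poly(
        np.asarray(data, dtype=float), frac.numerator, frac.denominator, axis=-1
    )
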