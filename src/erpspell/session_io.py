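"""Serialized formats: NPZ sessions (format v1), decoder checkpoints, CSV export.

NPZ is the canonical container — dense numeric arrays and no dependencies
beyond numpy.  Session files round-trip bit-exactly and carry generator
provenance (seed, parameters, package version) plus a format-version tag;
readers refuse unknown future versions with a clear error.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .paradigm import StimulusSequence, Trial
from .preprocessing import EpochSet, FeatureMatrix
from .synthetic import SyntheticSession
from .unsupervised import ClassifierPool

__all__ = [
    "SESSION_FORMAT_VERSION",
    "FormatError",
    "write_session",
    "read_session",
    "save_pool",
    "load_pool",
    "features_to_csv",
]

SESSION_FORMAT_VERSION = 1


class FormatError(ValueError):
    """A session/checkpoint file is corrupt, truncated or of an unknown version."""


def _package_version() -> str:
    from . import __version__

    return __version__


def write_session(path: Union[str, Path], session: SyntheticSession) -> None:
    """Write a session to the package NPZ format (lossless round-trip)."""
    soa = session.trials[0].sequence.soa if session.trials else 0.175
    meta = dict(
        seed=session.seed,
        difference_amplitude=session.difference_amplitude,
        package_version=_package_version(),
    )
    np.savez(
        path,
        format_version=np.array(SESSION_FORMAT_VERSION),
        epochs=session.epochs.epochs,
        sampling_rate=np.array(session.epochs.sampling_rate),
        window=np.array(session.epochs.window),
        stimulus_ids=session.epochs.stimulus_ids,
        trial_ids=session.epochs.trial_ids,
        block_ids=session.block_ids,
        attended=session.attended,
        n_stimuli=np.array(session.n_stimuli),
        n_iterations=np.array(session.n_iterations),
        soa=np.array(soa),
        channel_names=np.array(session.epochs.channel_names, dtype="U8"),
        meta_json=np.array(json.dumps(meta)),
    )


_REQUIRED_FIELDS = (
    "format_version", "epochs", "sampling_rate", "window", "stimulus_ids",
    "trial_ids", "block_ids", "attended", "n_stimuli", "n_iterations", "soa",
    "channel_names", "meta_json",
)


def read_session(path: Union[str, Path]) -> SyntheticSession:
    """Read a v1 session file; raises FormatError naming the failing field."""
    try:
        data = np.load(path, allow_pickle=False)
    except (OSError, ValueError, zipfile.BadZipFile) as err:
        raise FormatError(f"{path}: not a readable NPZ file ({err})") from err
    with data:
        for f in _REQUIRED_FIELDS:
            if f not in data:
                raise FormatError(f"{path}: missing field {f!r}")
        version = int(data["format_version"])
        if version != SESSION_FORMAT_VERSION:
            raise FormatError(
                f"{path}: unknown format version {version} "
                f"(this reader supports {SESSION_FORMAT_VERSION})"
            )
        try:
            meta = json.loads(str(data["meta_json"]))
        except json.JSONDecodeError as err:
            raise FormatError(f"{path}: corrupt field 'meta_json'") from err

        K = int(data["n_stimuli"])
        J = int(data["n_iterations"])
        soa = float(data["soa"])
        stim = data["stimulus_ids"]
        trial_ids = data["trial_ids"]
        attended = data["attended"]
        n_per = K * J
        if stim.shape != trial_ids.shape or stim.size != attended.size * n_per:
            raise FormatError(f"{path}: field 'stimulus_ids' inconsistent with metadata")
        epochs = EpochSet(
            data["epochs"],
            sampling_rate=float(data["sampling_rate"]),
            window=tuple(data["window"]),
            stimulus_ids=stim,
            trial_ids=trial_ids,
            channel_names=[str(c) for c in data["channel_names"]],
        )
        trials = []
        for t, att in enumerate(attended):
            pres = stim[trial_ids == t]
            try:
                seq = StimulusSequence(
                    trial_index=t, presentations=pres,
                    n_stimuli=K, n_iterations=J, soa=soa,
                )
            except ValueError as err:
                raise FormatError(
                    f"{path}: trial {t} presentations invalid ({err})"
                ) from err
            trials.append(Trial(sequence=seq, attended=int(att)))
        return SyntheticSession(
            epochs=epochs,
            block_ids=data["block_ids"],
            trials=trials,
            seed=int(meta.get("seed", -1)),
            difference_amplitude=float(meta.get("difference_amplitude", np.nan)),
            n_stimuli=K,
            n_iterations=J,
        )


def save_pool(path: Union[str, Path], pool: ClassifierPool) -> None:
    """Checkpoint a classifier pool (weights, precisions, likelihoods)."""
    np.savez(
        path,
        format_version=np.array(SESSION_FORMAT_VERSION),
        W=pool.W,
        lam=pool.lam,
        beta=pool.beta,
        log_likelihoods=pool.log_likelihoods,
        expected_mse=pool.expected_mse,
        mu=np.array([pool.mu_target, pool.mu_nontarget]),
        beta_cap=np.array(pool.beta_cap),
        selection=np.array(pool.selection),
        loglik_mode=np.array(pool.loglik_mode),
    )


def load_pool(path: Union[str, Path]) -> ClassifierPool:
    try:
        data = np.load(path, allow_pickle=False)
    except (OSError, ValueError, zipfile.BadZipFile) as err:
        raise FormatError(f"{path}: not a readable NPZ file ({err})") from err
    with data:
        for f in ("W", "lam", "beta", "mu"):
            if f not in data:
                raise FormatError(f"{path}: missing field {f!r}")
        pool = ClassifierPool(
            data["W"], data["lam"], data["beta"],
            mu_target=float(data["mu"][0]), mu_nontarget=float(data["mu"][1]),
            beta_cap=float(data["beta_cap"]),
            selection=str(data["selection"]),
            loglik_mode=str(data["loglik_mode"]),
        )
        pool.log_likelihoods = data["log_likelihoods"]
        pool.expected_mse = data["expected_mse"]
        return pool


def save_lda(path: Union[str, Path], results) -> None:
    """Checkpoint a fitted shrinkage-LDA baseline."""
    np.savez(
        path,
        format_version=np.array(SESSION_FORMAT_VERSION),
        weights=results.weights,
        bias=np.array(results.bias),
        shrinkage=np.array(results.shrinkage),
        mean_target=results.mean_target,
        mean_nontarget=results.mean_nontarget,
    )


def load_lda(path: Union[str, Path]):
    from .supervised import ShrinkageLDAResults

    try:
        data = np.load(path, allow_pickle=False)
    except (OSError, ValueError, zipfile.BadZipFile) as err:
        raise FormatError(f"{path}: not a readable NPZ file ({err})") from err
    with data:
        for f in ("weights", "bias", "shrinkage"):
            if f not in data:
                raise FormatError(f"{path}: missing field {f!r}")
        return ShrinkageLDAResults(
            weights=data["weights"],
            bias=float(data["bias"]),
            shrinkage=float(data["shrinkage"]),
            mean_target=data["mean_target"],
            mean_nontarget=data["mean_nontarget"],
            covariance=None,
            model=None,
        )


def features_to_csv(path: Union[str, Path], features: FeatureMatrix,
                    labels: np.ndarray | None = None) -> None:
    """CSV export: one row per epoch — trial, stimulus, label (if known), features."""
    cols = {"trial": features.trial_ids, "stimulus": features.stimulus_ids}
    if labels is not None:
        cols["label"] = np.asarray(labels).astype(int)
    df = pd.DataFrame(cols)
    feat = pd.DataFrame(
        features.X, columns=[f"f{i}" for i in range(features.dim)]
    )
    pd.concat([df, feat], axis=1).to_csv(path, index=False)
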