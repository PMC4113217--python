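"""Metrics and experiment harnesses.

Covers the study's analyses on synthetic sessions: trial-wise selection and
two-step symbol accuracy, the warm-up statistic (time-to-control = first
trial of the first run of three consecutive correct selections), signed
scaled AUC (ssAUC) channel/time discriminability maps, the block-alternation
protocol (supervised classifier fixed after calibration, unsupervised pool
re-initialized before every unsupervised block), and the extended-session
simulation (blocks concatenated, pool initialized once, 10-trial sub-block
paired t-tests across simulated subjects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .paradigm import DEFAULT_GRID, SymbolGrid, decode_symbol
from .pipeline import raw_features, supervised_training_set, unsupervised_features
from .preprocessing import EpochSet, acausal_bandpass, baseline_correct
from .preprocessing import DEFAULT_INTERVALS_MS, interval_sample_slices
from .supervised import ShrinkageLDA
from .synthetic import (
    NoiseModel,
    SyntheticSession,
    default_template,
    generate_session,
)
from .unsupervised import UnsupervisedSpeller

__all__ = [
    "BlockRecord",
    "RunRecord",
    "BOTH_FAILED_SENTINEL",
    "selection_accuracy",
    "symbol_accuracy",
    "spell_string",
    "time_to_control",
    "mannwhitney_auc",
    "ssauc_map",
    "run_block_protocol",
    "run_extended_simulation",
    "subblock_correct_counts",
    "subblock_ttests",
    "simulate_subject_session",
    "DEFAULT_AMPLITUDE_RANGE",
]

#: gray symbol shown when both selections of a symbol failed
BOTH_FAILED_SENTINEL = "°"

#: between-subject variability of the class-difference amplitude used when a
#: harness simulates a cohort ("subjects" = independent generator seeds)
DEFAULT_AMPLITUDE_RANGE = (0.25, 0.45)


@dataclass
class BlockRecord:
    """Per-block decoding outcome of one protocol run."""

    block: int
    method: str  # "supervised" | "unsupervised"
    truth: np.ndarray
    online: np.ndarray
    posthoc: Optional[np.ndarray] = None
    trajectory: list[np.ndarray] = field(default_factory=list)
    reset: bool = False  # pool randomly re-initialized before this block

    def __post_init__(self):
        if len(self.online) != len(self.truth):
            raise ValueError("prediction/truth length mismatch")
        if self.trajectory and [len(t) for t in self.trajectory] != list(
            range(1, len(self.truth) + 1)
        ):
            raise ValueError("posthoc trajectory lengths inconsistent with trial count")


@dataclass
class RunRecord:
    """Ordered block records of one simulated session plus timing metadata."""

    blocks: list[BlockRecord]
    seed: int
    protocol: str = "block"

    def method_blocks(self, method: str) -> list[BlockRecord]:
        return [b for b in self.blocks if b.method == method]

    def concat(self, method: str, which: str = "online") -> tuple[np.ndarray, np.ndarray]:
        """(truth, predictions) concatenated over the blocks of one method."""
        bl = self.method_blocks(method)
        truth = np.concatenate([b.truth for b in bl]) if bl else np.empty(0, int)
        if which == "online":
            preds = np.concatenate([b.online for b in bl]) if bl else np.empty(0, int)
        elif which == "posthoc":
            preds = (np.concatenate([b.posthoc for b in bl])
                     if bl and bl[0].posthoc is not None else np.empty(0, int))
        else:
            raise ValueError(which)
        return truth, preds

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-trial view for CSV export."""
        rows = []
        for b in self.blocks:
            for i, (t, o) in enumerate(zip(b.truth, b.online)):
                rows.append(
                    dict(
                        block=b.block, method=b.method, trial=i, truth=int(t),
                        online=int(o),
                        posthoc=(int(b.posthoc[i]) if b.posthoc is not None else None),
                        reset=b.reset,
                    )
                )
        return pd.DataFrame(rows)


def selection_accuracy(truth: np.ndarray, predictions: np.ndarray) -> float:
    """Fraction of trials whose one-out-of-K selection was correct."""
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.size == 0:
        raise ValueError("empty scope")
    if truth.shape != predictions.shape:
        raise ValueError("truth/prediction shape mismatch")
    return float(np.mean(truth == predictions))


def symbol_accuracy(truth: np.ndarray, predictions: np.ndarray) -> float:
    """Fraction of correctly spelled symbols; a symbol needs both of its
    consecutive trials (group, then within-group selection) correct."""
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.size % 2:
        raise ValueError("symbol accuracy needs an even number of trials")
    if truth.size == 0:
        raise ValueError("empty scope")
    ok = (truth == predictions).reshape(-1, 2)
    return float(np.mean(ok.all(axis=1)))


def spell_string(
    truth: np.ndarray,
    predictions: np.ndarray,
    grid: SymbolGrid = DEFAULT_GRID,
) -> tuple[str, str]:
    """(target text, spelled text) of a trial sequence.

    The spelled symbol of a pair is looked up from the predicted selections;
    when both selections failed the sentinel ``°`` is shown instead, matching
    the speller's feedback convention.
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.size % 2:
        raise ValueError("need an even number of trials")
    target, spelled = [], []
    for (t1, t2), (p1, p2) in zip(truth.reshape(-1, 2), predictions.reshape(-1, 2)):
        target.append(decode_symbol(int(t1), int(t2), grid))
        if t1 != p1 and t2 != p2:
            spelled.append(BOTH_FAILED_SENTINEL)
        else:
            spelled.append(decode_symbol(int(p1), int(p2), grid))
    return "".join(target), "".join(spelled)


def time_to_control(correct: np.ndarray) -> Optional[int]:
    """1-based index of the first trial of the first run of >= 3 consecutive
    correct online selections; None if control is never reached."""
    correct = np.asarray(correct, bool)
    for i in range(len(correct) - 2):
        if correct[i] and correct[i + 1] and correct[i + 2]:
            return i + 1
    return None


def mannwhitney_auc(scores_target: np.ndarray, scores_nontarget: np.ndarray) -> float:
    """AUC via the rank-sum formulation with midranks for ties."""
    st = np.asarray(scores_target, float)
    sn = np.asarray(scores_nontarget, float)
    if st.size == 0 or sn.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([st, sn]))
    r_t = ranks[: st.size].sum()
    return float((r_t - st.size * (st.size + 1) / 2) / (st.size * sn.size))


def ssauc_map(
    epochs: EpochSet,
    is_target: np.ndarray,
    *,
    intervals_ms: Sequence[tuple[float, float]] = DEFAULT_INTERVALS_MS,
    bandpass: Optional[tuple[float, float]] = (0.5, 20.0),
) -> np.ndarray:
    """Signed scaled AUC (2*AUC - 1) per channel and time interval.

    The visualization path first applies the acausal forward-backward
    band-pass and re-baselines; pass ``bandpass=None`` to skip.  Values lie
    in [-1, 1]: 0 means no class information (AUC 0.5), +/-1 perfect
    separation.
    """
    is_target = np.asarray(is_target, bool)
    if is_target.all() or not is_target.any():
        raise ValueError("both classes must be present")
    data = epochs
    if bandpass is not None:
        filtered = acausal_bandpass(epochs.epochs, epochs.sampling_rate, bandpass)
        data = EpochSet(filtered, epochs.sampling_rate, epochs.window,
                        stimulus_ids=epochs.stimulus_ids, trial_ids=epochs.trial_ids,
                        channel_names=epochs.channel_names)
        data = baseline_correct(data)
    slices = interval_sample_slices(
        intervals_ms, data.sampling_rate, data.window, data.n_samples
    )
    out = np.empty((data.n_channels, len(slices)))
    for j, s in enumerate(slices):
        means = data.epochs[:, :, s].mean(axis=2)  # (n_epochs, n_channels)
        for ch in range(data.n_channels):
            auc = mannwhitney_auc(means[is_target, ch], means[~is_target, ch])
            out[ch, j] = 2.0 * auc - 1.0
    return out


# ---------------------------------------------------------------------------
# Protocol harnesses
# ---------------------------------------------------------------------------

def _decode_supervised_block(lda, session, block) -> np.ndarray:
    fm, _ = raw_features(session, blocks=[block])
    return lda.predict_trials(fm)


def run_block_protocol(
    session: SyntheticSession,
    seed: int = 0,
    *,
    methods: Optional[Sequence[str]] = None,
    calibration_block: int = 0,
    n_em: int = 5,
    n_pairs: int = 5,
) -> RunRecord:
    """The online study's protocol on one synthetic session.

    Block ``calibration_block`` provides the labeled calibration data for the
    supervised classifier (trained once, fixed thereafter, outlier-rejected).
    The remaining blocks are decoded in order with the given method sequence
    (default: alternating supervised/unsupervised).  The unsupervised pool is
    randomly re-initialized before each unsupervised block; its online
    predictions are fixed, and the posthoc trajectory is recorded after every
    trial.
    """
    eval_blocks = [b for b in range(session.n_blocks) if b != calibration_block]
    if methods is None:
        methods = [("supervised" if i % 2 == 0 else "unsupervised")
                   for i in range(len(eval_blocks))]
    if len(methods) != len(eval_blocks):
        raise ValueError("one method per evaluation block required")

    X_cal, y_cal = supervised_training_set(session, blocks=[calibration_block])
    lda = ShrinkageLDA(X_cal, y_cal).fit()

    rng = np.random.SeedSequence(seed)
    blocks: list[BlockRecord] = []
    for block, method, sub in zip(eval_blocks, methods, rng.spawn(len(eval_blocks))):
        truth = session.attended[session.block_trial_ids(block)]
        if method == "supervised":
            preds = _decode_supervised_block(lda, session, block)
            blocks.append(BlockRecord(block, method, truth, preds))
        elif method == "unsupervised":
            model = UnsupervisedSpeller.from_session(
                session, blocks=[block],
                seed=np.random.default_rng(sub), n_em=n_em, n_pairs=n_pairs,
            )
            res = model.fit(mode="online")
            blocks.append(
                BlockRecord(
                    block, method, truth, res.online_predictions,
                    posthoc=res.posthoc_predictions,
                    trajectory=res.posthoc_trajectory, reset=True,
                )
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    return RunRecord(blocks, seed=seed, protocol="block")


def run_extended_simulation(
    session: SyntheticSession,
    seed: int = 0,
    *,
    calibration_block: int = 0,
    eval_blocks: Optional[Sequence[int]] = None,
    n_em: int = 5,
    n_pairs: int = 5,
) -> RunRecord:
    """Extended-duration simulation: evaluation blocks concatenated in
    chronological order, the unsupervised pool initialized ONCE and never
    reset, posthoc re-classifying all trials at the very end; the fixed
    supervised classifier decodes the same trials for comparison."""
    if eval_blocks is None:
        eval_blocks = [b for b in range(session.n_blocks) if b != calibration_block]
    X_cal, y_cal = supervised_training_set(session, blocks=[calibration_block])
    lda = ShrinkageLDA(X_cal, y_cal).fit()

    model = UnsupervisedSpeller.from_session(
        session, blocks=list(eval_blocks),
        seed=np.random.default_rng(np.random.SeedSequence(seed)),
        n_em=n_em, n_pairs=n_pairs,
    )
    res = model.fit(mode="online")
    truth = model.ground_truth

    sup_preds = np.concatenate(
        [_decode_supervised_block(lda, session, b) for b in eval_blocks]
    )
    blocks = [
        BlockRecord(-1, "supervised", truth, sup_preds),
        BlockRecord(
            -1, "unsupervised", truth, res.online_predictions,
            posthoc=res.posthoc_predictions, trajectory=res.posthoc_trajectory,
            reset=True,
        ),
    ]
    return RunRecord(blocks, seed=seed, protocol="extended")


def subblock_correct_counts(
    truth: np.ndarray, predictions: np.ndarray, subblock_size: int = 10
) -> np.ndarray:
    """Number of correct trials per consecutive sub-block (default 10 trials,
    i.e. 5 symbol selections)."""
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.size % subblock_size:
        raise ValueError("trial count not divisible by the sub-block size")
    ok = (truth == predictions).reshape(-1, subblock_size)
    return ok.sum(axis=1)


def subblock_ttests(
    counts_a: np.ndarray, counts_b: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided paired t-tests per sub-block across simulated subjects.

    ``counts_a``/``counts_b`` are (n_subjects, n_subblocks) correct-trial
    counts of the two methods on matched data.  No multiple-testing
    correction is applied, matching the original reporting convention.
    """
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("need matched (n_subjects, n_subblocks) count arrays")
    t, p = stats.ttest_rel(a, b, axis=0)
    return pd.DataFrame(
        {"subblock": np.arange(a.shape[1]), "t": t, "p": p,
         "significant": p < alpha}
    )


def simulate_subject_session(
    subject: int,
    base_seed: int = 0,
    *,
    n_blocks: int = 7,
    trials_per_block: int = 30,
    amplitude_range: tuple[float, float] = DEFAULT_AMPLITUDE_RANGE,
    noise: Optional[NoiseModel] = None,
) -> SyntheticSession:
    """One simulated subject: an independent generator seed with a
    subject-specific class-difference amplitude drawn uniformly from
    ``amplitude_range`` (reproducing between-subject variability without
    claiming realism)."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(subject,))
    amp_rng = np.random.default_rng(ss.spawn(1)[0])
    amplitude = float(amp_rng.uniform(*amplitude_range))
    session_seed = int(np.random.default_rng(ss).integers(2**31 - 1))
    template = default_template(difference_amplitude=amplitude)
    return generate_session(
        template, noise, n_blocks=n_blocks, trials_per_block=trials_per_block,
        seed=session_seed,
    )
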