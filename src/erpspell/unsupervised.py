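"""Unsupervised EM decoding of the attended stimulus — the package core.

The probabilistic model exploits the paradigm constraint that the user
attends one stimulus c per trial, so fixing c fixes the target/non-target
label of all K*J presentations.  A linear classifier w projects each
(D+1)-dimensional feature vector x to a scalar; the projection is modeled as
Gaussian with class-dependent mean (mu_target for presentations of c,
mu_nontarget otherwise) and shared precision lambda, and w carries a
zero-mean isotropic Gaussian prior with precision beta:

    c_t ~ Uniform(1..K)
    w   ~ N(0, beta^-1 I)
    w'x_{t,j} | c_t ~ N(mu_{s(c_t, j)}, lambda^-1)

EM alternates inference of per-trial posteriors over c (E-step) with
closed-form updates (M-step): w is the posterior-weighted ridge-regression
solution, lambda the inverse expected mean squared projection error, and
beta the inverse average squared weight, capped to prevent collapse onto
w = 0.

Because the likelihood is symmetric under (w, mu) -> (-w, -mu), an
unsupervised run can converge to the label-swapped solution.  The practical
remedy is a pool of sign-flipped classifier pairs (+w0 / -w0): after every
trial each classifier runs a few EM iterations over all stored trials, the
classifier with the highest data log-likelihood makes the prediction, and
within each pair the weaker member is re-initialized to the negation of the
stronger one.  Because the model keeps improving as unlabeled data
accumulates, re-classifying all past trials ("posthoc") revises early
mistakes made during the warm-up period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .preprocessing import FeatureMatrix

__all__ = [
    "DecoderState",
    "ClassifierPool",
    "TrialStore",
    "UnsupervisedSpeller",
    "UnsupervisedSpellerResults",
    "init_pool",
    "infer_attended",
    "e_step",
    "m_step_weights",
    "m_step_lambda",
    "m_step_beta",
    "em_iterations",
    "select_best",
    "reinit_pairs",
    "online_step",
    "posthoc_reanalysis",
]

#: default hyperparameters
N_PAIRS = 5
N_EM = 5
LAMBDA_INIT = 1.0
BETA_INIT = 100.0
BETA_CAP = 200.0
MSE_FLOOR = 1e-10
MU_TARGET = 1.0
MU_NONTARGET = -1.0

LoglikMode = Literal["exact", "legacy-bug-compat"]


def _log_const_factor(mode: LoglikMode) -> float:
    """Per-epoch log-density constant is factor*(log lambda - log 2*pi).

    ``exact`` is the correct Gaussian normalizer (factor 0.5).  The
    ``legacy-bug-compat`` mode halves the constant, reproducing a disclosed
    slip in an earlier implementation of this method, for replication work;
    it rescales the likelihood's lambda-dependence but leaves the posterior
    over c within a trial untouched.
    """
    if mode == "exact":
        return 0.5
    if mode == "legacy-bug-compat":
        return 0.25
    raise ValueError(f"unknown log-likelihood mode {mode!r}")


@dataclass
class DecoderState:
    """One linear decoder: weights plus the Gaussian projection model."""

    w: np.ndarray
    lam: float = LAMBDA_INIT
    beta: float = BETA_INIT
    mu_target: float = MU_TARGET
    mu_nontarget: float = MU_NONTARGET
    log_likelihood: float = -np.inf

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.lam <= 0 or self.beta <= 0:
            raise ValueError("lambda and beta must be positive")
        if self.mu_target == self.mu_nontarget:
            raise ValueError("class projection means must differ")


class TrialStore:
    """Accumulates preprocessed trials (features + stimulus ids) for EM.

    Trials are stored contiguously, each with exactly K*J epochs; the Gram
    matrix X'X is maintained incrementally and its eigendecomposition cached,
    so the per-classifier ridge solves reduce to cheap spectral filtering.
    """

    def __init__(self, dim: int, n_stimuli: int, n_iterations: int):
        self.dim = dim
        self.K = n_stimuli
        self.J = n_iterations
        self._chunks: list[np.ndarray] = []
        self._stim0: list[np.ndarray] = []
        self._X: Optional[np.ndarray] = None
        self._gram = np.zeros((dim, dim))
        self._eig: Optional[tuple[np.ndarray, np.ndarray]] = None

    @property
    def n_trials(self) -> int:
        return len(self._chunks)

    @property
    def n_per_trial(self) -> int:
        return self.K * self.J

    def __len__(self) -> int:
        return self.n_trials * self.n_per_trial

    def append_trial(self, X: np.ndarray, stimulus_ids: np.ndarray) -> None:
        X = np.asarray(X, dtype=float)
        stim = np.asarray(stimulus_ids, dtype=int)
        if X.shape != (self.n_per_trial, self.dim):
            raise ValueError(
                f"trial must be ({self.n_per_trial}, {self.dim}), got {X.shape}"
            )
        if stim.shape != (self.n_per_trial,) or stim.min() < 1 or stim.max() > self.K:
            raise ValueError("stimulus ids must be K*J values in 1..K")
        self._chunks.append(X)
        self._stim0.append(stim - 1)
        self._gram += X.T @ X
        self._X = None
        self._eig = None

    def append_features(self, features: FeatureMatrix) -> None:
        """Append every trial of a FeatureMatrix, in order of appearance."""
        for t in features.trials:
            fm = features.trial_slice(t)
            self.append_trial(fm.X, fm.stimulus_ids)

    @property
    def X(self) -> np.ndarray:
        if self._X is None:
            self._X = (np.concatenate(self._chunks)
                       if self._chunks else np.empty((0, self.dim)))
        return self._X

    @property
    def stim0(self) -> np.ndarray:
        return (np.concatenate(self._stim0)
                if self._stim0 else np.empty(0, dtype=int))

    @property
    def epoch_trial(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_trials), self.n_per_trial)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (eigenvalues, eigenvectors) of X'X."""
        if self._eig is None:
            g, U = np.linalg.eigh(self._gram)
            self._eig = (np.maximum(g, 0.0), U)
        return self._eig


def _per_hypothesis_logliks(
    P: np.ndarray, stim0: np.ndarray, K: int, J: int,
    lam: np.ndarray, mu_t: float, mu_nt: float, const_factor: float,
) -> np.ndarray:
    """Log p(projections of trial t | c) for every trial/hypothesis/classifier.

    ``P`` is (T, K*J, C) projections, ``stim0`` (T, K*J) 0-based stimulus ids.
    Returns (T, K, C).  Uses sufficient statistics only: per-stimulus
    projection sums, total sum and total sum of squares.
    """
    T, n_per, C = P.shape
    onehot = np.eye(K)[stim0]  # (T, K*J, K)
    S = np.einsum("tjk,tjc->tkc", onehot, P)  # per-stimulus projection sums
    Psum = P.sum(axis=1)[:, None, :]  # (T, 1, C)
    SSq = (P * P).sum(axis=1)[:, None, :]
    dot = mu_t * S + mu_nt * (Psum - S)
    sq_mu = J * mu_t**2 + (K - 1) * J * mu_nt**2
    sse = SSq - 2.0 * dot + sq_mu
    lam = np.asarray(lam, dtype=float).reshape(1, 1, -1)
    return -0.5 * lam * sse + n_per * const_factor * (np.log(lam) - np.log(2 * np.pi))


class ClassifierPool:
    """Sign-flipped pairs of decoders sharing one data store.

    Classifier 2i and 2i+1 form pair i; after (re-)initialization their
    weight vectors are exact negations.  All EM arithmetic is vectorized
    across the 2*n_pairs classifiers.
    """

    def __init__(
        self,
        W: np.ndarray,
        lam: np.ndarray,
        beta: np.ndarray,
        *,
        mu_target: float = MU_TARGET,
        mu_nontarget: float = MU_NONTARGET,
        beta_cap: float = BETA_CAP,
        mse_floor: float = MSE_FLOOR,
        selection: Literal["loglik", "mse"] = "loglik",
        loglik_mode: LoglikMode = "exact",
    ):
        self.W = np.asarray(W, dtype=float)  # (dim, C)
        self.lam = np.asarray(lam, dtype=float).copy()
        self.beta = np.asarray(beta, dtype=float).copy()
        self.mu_target = mu_target
        self.mu_nontarget = mu_nontarget
        self.beta_cap = beta_cap
        self.mse_floor = mse_floor
        self.selection = selection
        self.loglik_mode: LoglikMode = loglik_mode
        C = self.W.shape[1]
        self.log_likelihoods = np.full(C, -np.inf)
        self.expected_mse = np.full(C, np.inf)
        self._last_posteriors: Optional[np.ndarray] = None  # (T, K, C)

    # -- construction ---------------------------------------------------
    @classmethod
    def initialize(
        cls,
        dim: int,
        n_pairs: int = N_PAIRS,
        seed: int | np.random.Generator = 0,
        *,
        lambda_init: float = LAMBDA_INIT,
        beta_init: float = BETA_INIT,
        **kwargs,
    ) -> "ClassifierPool":
        """Draw each pair's w0 from the weight prior N(0, beta_init^-1 I);
        members get +w0 and -w0."""
        if dim < 2:
            raise ValueError("dim must be >= 2")
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        W = np.empty((dim, 2 * n_pairs))
        for i in range(n_pairs):
            w0 = rng.standard_normal(dim) / np.sqrt(beta_init)
            W[:, 2 * i] = w0
            W[:, 2 * i + 1] = -w0
        C = 2 * n_pairs
        return cls(W, np.full(C, lambda_init), np.full(C, beta_init), **kwargs)

    # -- views ----------------------------------------------------------
    @property
    def dim(self) -> int:
        return self.W.shape[0]

    @property
    def n_classifiers(self) -> int:
        return self.W.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.n_classifiers // 2

    def state(self, k: int) -> DecoderState:
        return DecoderState(
            w=self.W[:, k].copy(), lam=float(self.lam[k]), beta=float(self.beta[k]),
            mu_target=self.mu_target, mu_nontarget=self.mu_nontarget,
            log_likelihood=float(self.log_likelihoods[k]),
        )

    @property
    def states(self) -> list[DecoderState]:
        return [self.state(k) for k in range(self.n_classifiers)]

    # -- EM -------------------------------------------------------------
    def _e_step(self, P: np.ndarray, store: TrialStore) -> tuple[np.ndarray, np.ndarray]:
        """Posteriors over c per trial and per-classifier data log-likelihood.

        The data log-likelihood marginalizes the K hypotheses per trial with
        the uniform prior (log-sum-exp), summed over all stored trials.
        """
        T = store.n_trials
        P3 = P.reshape(T, store.n_per_trial, -1)
        stim0 = store.stim0.reshape(T, store.n_per_trial)
        ll = _per_hypothesis_logliks(
            P3, stim0, store.K, store.J, self.lam,
            self.mu_target, self.mu_nontarget, _log_const_factor(self.loglik_mode),
        )  # (T, K, C)
        with_prior = ll - np.log(store.K)
        trial_ll = logsumexp(with_prior, axis=1)  # (T, C)
        log_post = with_prior - trial_ll[:, None, :]
        return np.exp(log_post), trial_ll.sum(axis=0)

    def run_em(self, store: TrialStore, n_iter: int = N_EM) -> np.ndarray:
        """n_iter EM rounds over all stored data, vectorized across the pool.

        Returns the (n_iter + 1, C) history of data log-likelihoods: entry 0
        is evaluated under the incoming parameters, entry i under the
        parameters after i EM rounds.  The pool's bookkeeping
        (log-likelihoods, expected MSE, cached posteriors) reflects the final
        parameters on return.
        """
        if store.n_trials < 1:
            raise ValueError("no trials stored")
        X = store.X
        P = X @ self.W  # (N, C)
        history, map_deltas = [], []
        base = pen_new = None  # MAP objective bookkeeping, one step delayed
        for _ in range(n_iter):
            post, ll = self._e_step(P, store)
            history.append(ll)
            if base is not None:
                # F_{i-1}(theta_i) - F_{i-1}(theta_{i-1}) under iteration
                # i-1's beta: the increment EM theory guarantees >= 0
                map_deltas.append((ll - pen_new) - base)
            beta_used = self.beta.copy()
            base = ll - 0.5 * beta_used * (self.W**2).sum(axis=0)
            q = post[store.epoch_trial, store.stim0, :]  # P(epoch is target)
            ybar = q * self.mu_target + (1.0 - q) * self.mu_nontarget
            g, U = store.eig()
            B = U.T @ (X.T @ ybar)  # (dim, C) in the eigenbasis
            self.W = U @ (B / (g[:, None] + (self.beta / self.lam)[None, :]))
            P = X @ self.W
            pen_new = 0.5 * beta_used * (self.W**2).sum(axis=0)
            mse = (q * (P - self.mu_target) ** 2
                   + (1.0 - q) * (P - self.mu_nontarget) ** 2).mean(axis=0)
            self.expected_mse = mse
            self.lam = 1.0 / np.maximum(mse, self.mse_floor)
            self.beta = _beta_update(self.W, self.beta_cap)
        post, ll = self._e_step(P, store)
        history.append(ll)
        if base is not None:
            map_deltas.append((ll - pen_new) - base)
        self.log_likelihoods = ll
        self._last_posteriors = post
        # per-step increments of the penalized (MAP) objective — the quantity
        # this prior-regularized EM is guaranteed to ascend (see methods note);
        # step i compares iterations i and i+1 under the beta of iteration i.
        self.last_map_deltas = (np.asarray(map_deltas)
                                if map_deltas else np.empty((0, self.n_classifiers)))
        return np.asarray(history)

    # -- selection and pairing ------------------------------------------
    def best_index(self) -> int:
        """Best classifier: maximal data log-likelihood (or minimal expected
        MSE under the alternative criterion); ties resolve to the lowest
        index, i.e. lowest pair then first member."""
        if self.selection == "mse":
            return int(np.argmin(self.expected_mse))
        return int(np.argmax(self.log_likelihoods))

    def reinit_pairs(self) -> None:
        """Within each pair keep the higher-likelihood member and re-initialize
        the other with the negated weights (lambda/beta copied from the kept
        member, its likelihood marked stale)."""
        for i in range(self.n_pairs):
            a, b = 2 * i, 2 * i + 1
            keep, drop = (a, b) if self.log_likelihoods[a] >= self.log_likelihoods[b] else (b, a)
            self.W[:, drop] = -self.W[:, keep]
            self.lam[drop] = self.lam[keep]
            self.beta[drop] = self.beta[keep]
            self.log_likelihoods[drop] = -np.inf
            self.expected_mse[drop] = np.inf

    def predict_trials(self, store: TrialStore, classifier: Optional[int] = None) -> np.ndarray:
        """1-based attended-stimulus prediction for every stored trial.

        Uses the cached posteriors when the store is unchanged since the last
        EM run, otherwise re-runs inference.  Argmax ties resolve to the
        lowest stimulus id.
        """
        k = self.best_index() if classifier is None else classifier
        if (self._last_posteriors is None
                or self._last_posteriors.shape[0] != store.n_trials):
            post, _ = self._e_step(store.X @ self.W, store)
        else:
            post = self._last_posteriors
        return post[:, :, k].argmax(axis=1) + 1


def _beta_update(W: np.ndarray, cap: float) -> np.ndarray:
    """beta = dim / sum(w^2), capped; an all-zero w maps to the cap."""
    W = np.atleast_2d(W.T).T  # promote (dim,) to (dim, 1)
    ss = (W**2).sum(axis=0)
    out = np.empty_like(ss)
    zero = ss == 0
    if zero.any():
        warnings.warn("all-zero weight vector: beta set to the cap")
    out[zero] = cap
    out[~zero] = np.minimum(W.shape[0] / ss[~zero], cap)
    return out


# ---------------------------------------------------------------------------
# Functional operations (single-classifier granularity, shared formulas)
# ---------------------------------------------------------------------------

def init_pool(
    dim: int, n_pairs: int = N_PAIRS, seed: int | np.random.Generator = 0, **kwargs
) -> ClassifierPool:
    """Initialize ``n_pairs`` sign-flipped classifier pairs (see
    :meth:`ClassifierPool.initialize`)."""
    return ClassifierPool.initialize(dim, n_pairs, seed, **kwargs)


def _as_trial_arrays(trial_features, stimulus_ids=None):
    if isinstance(trial_features, FeatureMatrix):
        return trial_features.X, trial_features.stimulus_ids
    if stimulus_ids is None:
        raise ValueError("stimulus_ids required when passing a bare array")
    return np.asarray(trial_features, float), np.asarray(stimulus_ids, int)


def infer_attended(
    state: DecoderState,
    trial_features,
    stimulus_ids: Optional[np.ndarray] = None,
    *,
    n_stimuli: Optional[int] = None,
    loglik_mode: LoglikMode = "exact",
) -> np.ndarray:
    """Posterior over the K attended-stimulus hypotheses for one trial.

    For hypothesis c the log-likelihood sums log N(w'x | mu_{s(c, j)},
    lambda^-1) over the trial's epochs; the posterior applies the uniform
    prior and normalizes in log-space.
    """
    X, stim = _as_trial_arrays(trial_features, stimulus_ids)
    if X.shape[0] == 0:
        raise ValueError("empty trial")
    K = n_stimuli if n_stimuli is not None else int(stim.max())
    counts = np.bincount(stim - 1, minlength=K)
    if len(set(counts)) != 1:
        raise ValueError("trial must contain K*J epochs, J per stimulus")
    J = int(counts[0])
    P = (X @ state.w).reshape(1, -1, 1)
    ll = _per_hypothesis_logliks(
        P, (stim - 1).reshape(1, -1), K, J, np.array([state.lam]),
        state.mu_target, state.mu_nontarget, _log_const_factor(loglik_mode),
    )[0, :, 0]
    log_post = ll - logsumexp(ll)
    return np.exp(log_post)


def e_step(state: DecoderState, features: FeatureMatrix, **kwargs) -> list[np.ndarray]:
    """Posterior over c for every trial of a FeatureMatrix (trials independent)."""
    return [
        infer_attended(state, features.trial_slice(t), **kwargs)
        for t in features.trials
    ]


def m_step_weights(
    X: np.ndarray,
    stimulus_ids: np.ndarray,
    trial_ids: np.ndarray,
    posteriors: Sequence[np.ndarray],
    lam: float,
    beta: float,
    *,
    mu_target: float = MU_TARGET,
    mu_nontarget: float = MU_NONTARGET,
) -> np.ndarray:
    """Posterior-weighted ridge solution w = (X'X + (beta/lambda) I)^-1 X' ybar.

    Each epoch's regression target ybar is its posterior-expected class mean:
    with q the probability (under the epoch's trial posterior) that its
    stimulus is the attended one, ybar = q*mu_target + (1-q)*mu_nontarget.
    Equivalently, a sum of all hard-label ridge classifiers weighted by the
    probability that their labels are correct.
    """
    X = np.asarray(X, float)
    stim0 = np.asarray(stimulus_ids, int) - 1
    trial_ids = np.asarray(trial_ids, int)
    order = {t: i for i, t in enumerate(dict.fromkeys(trial_ids))}
    q = np.array(
        [posteriors[order[t]][s] for t, s in zip(trial_ids, stim0)]
    )
    ybar = q * mu_target + (1.0 - q) * mu_nontarget
    A = X.T @ X + (beta / lam) * np.eye(X.shape[1])
    try:
        from scipy.linalg import cho_factor, cho_solve
        return cho_solve(cho_factor(A), X.T @ ybar)
    except np.linalg.LinAlgError as err:  # pragma: no cover - beta>0 prevents this
        raise np.linalg.LinAlgError(f"singular ridge system: {err}")


def m_step_lambda(
    X: np.ndarray,
    stimulus_ids: np.ndarray,
    trial_ids: np.ndarray,
    posteriors: Sequence[np.ndarray],
    w: np.ndarray,
    *,
    mu_target: float = MU_TARGET,
    mu_nontarget: float = MU_NONTARGET,
    floor: float = MSE_FLOOR,
) -> float:
    """lambda = 1 / max(expected MSE, floor): the inverse expected squared
    distance between projections and their (posterior-weighted) class means."""
    X = np.asarray(X, float)
    stim0 = np.asarray(stimulus_ids, int) - 1
    trial_ids = np.asarray(trial_ids, int)
    order = {t: i for i, t in enumerate(dict.fromkeys(trial_ids))}
    q = np.array([posteriors[order[t]][s] for t, s in zip(trial_ids, stim0)])
    p = X @ np.asarray(w, float)
    mse = (q * (p - mu_target) ** 2 + (1 - q) * (p - mu_nontarget) ** 2).mean()
    return float(1.0 / max(mse, floor))


def m_step_beta(w: np.ndarray, dim: Optional[int] = None, *, cap: float = BETA_CAP) -> float:
    """beta = min(dim / sum(w_d^2), cap)."""
    w = np.asarray(w, float)
    if dim is not None and dim != w.size:
        raise ValueError("dim inconsistent with w")
    return float(_beta_update(w.reshape(-1, 1), cap)[0])


def em_iterations(
    pool: ClassifierPool, store: TrialStore, n_iter: int = N_EM
) -> np.ndarray:
    """Run ``n_iter`` EM rounds on all stored data; returns the
    (n_iter + 1, n_classifiers) data log-likelihood history."""
    return pool.run_em(store, n_iter)


def select_best(pool: ClassifierPool) -> DecoderState:
    """The classifier with maximal data log-likelihood (documented tie rule:
    lowest pair index, then first member)."""
    if pool.n_classifiers == 0:
        raise ValueError("empty pool")
    return pool.state(pool.best_index())


def reinit_pairs(pool: ClassifierPool) -> ClassifierPool:
    pool.reinit_pairs()
    return pool


def online_step(
    pool: ClassifierPool,
    store: TrialStore,
    trial_features,
    stimulus_ids: Optional[np.ndarray] = None,
    *,
    n_em: int = N_EM,
) -> tuple[int, ClassifierPool]:
    """One online trial: store it, EM over all stored data, predict with the
    best classifier, then re-initialize the pairs.  The returned prediction is
    final — online outputs are never revised (that is what posthoc is for).
    """
    X, stim = _as_trial_arrays(trial_features, stimulus_ids)
    store.append_trial(X, stim)
    pool.run_em(store, n_em)
    pred = int(pool.predict_trials(store)[store.n_trials - 1])
    pool.reinit_pairs()
    return pred, pool


def posthoc_reanalysis(pool: ClassifierPool, store: TrialStore) -> np.ndarray:
    """Re-classify every stored trial with the currently best classifier."""
    if store.n_trials < 1:
        raise ValueError("no trials stored")
    return pool.predict_trials(store)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class UnsupervisedSpeller:
    """Unsupervised EM speller model over a normalized feature matrix.

    Parameters
    ----------
    features : FeatureMatrix
        Per-trial normalized, bias-augmented features of the session/block to
        decode (see :func:`erpspell.preprocessing.normalize_and_bias`).
    ground_truth : array-like, optional
        Attended stimulus per trial (1-based), used only for the diagnostics
        reported by the results object.
    n_pairs, n_em, lambda_init, beta_init, beta_cap
        Pool and EM hyperparameters; defaults are 5 pairs, 5 EM iterations
        per trial, lambda 1, beta 100 capped at 200.
    seed : int
        Seeds the pool's random initialization.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        *,
        ground_truth: Optional[Sequence[int]] = None,
        n_stimuli: int = 6,
        n_iterations: int = 15,
        n_pairs: int = N_PAIRS,
        n_em: int = N_EM,
        seed: int | np.random.Generator = 0,
        lambda_init: float = LAMBDA_INIT,
        beta_init: float = BETA_INIT,
        beta_cap: float = BETA_CAP,
        mu_target: float = MU_TARGET,
        mu_nontarget: float = MU_NONTARGET,
        selection: Literal["loglik", "mse"] = "loglik",
        loglik_mode: LoglikMode = "exact",
    ):
        if not features.has_bias:
            warnings.warn("features lack a bias column; the decoder expects one")
        self.features = features
        self.ground_truth = (None if ground_truth is None
                             else np.asarray(ground_truth, int))
        self.K = n_stimuli
        self.J = n_iterations
        self.n_pairs = n_pairs
        self.n_em = n_em
        self.seed = seed
        self.pool_kwargs = dict(
            lambda_init=lambda_init, beta_init=beta_init, beta_cap=beta_cap,
            mu_target=mu_target, mu_nontarget=mu_nontarget,
            selection=selection, loglik_mode=loglik_mode,
        )

    @classmethod
    def from_session(cls, session, blocks=None, **kwargs):
        """Build the model straight from a synthetic session (runs the
        baseline-correction / feature / normalization chain)."""
        from .pipeline import unsupervised_features

        features, truth = unsupervised_features(session, blocks=blocks)
        kwargs.setdefault("ground_truth", truth)
        kwargs.setdefault("n_stimuli", session.n_stimuli)
        kwargs.setdefault("n_iterations", session.n_iterations)
        return cls(features, **kwargs)

    def fit(self, mode: Literal["online", "batch"] = "online") -> "UnsupervisedSpellerResults":
        """Decode the trials.

        ``online`` replays the causal protocol (one prediction per trial,
        EM + pair re-initialization after each, posthoc trajectory recorded);
        ``batch`` stores everything first and runs one EM pass, equivalent to
        a posthoc-only analysis.
        """
        trials = self.features.trials
        store = TrialStore(self.features.dim, self.K, self.J)
        pool = ClassifierPool.initialize(
            self.features.dim, self.n_pairs, self.seed, **self.pool_kwargs
        )
        online_preds: list[int] = []
        trajectory: list[np.ndarray] = []
        loglik_trace: list[np.ndarray] = []
        if mode == "online":
            for t in trials:
                fm = self.features.trial_slice(t)
                store.append_trial(fm.X, fm.stimulus_ids)
                pool.run_em(store, self.n_em)
                loglik_trace.append(pool.log_likelihoods.copy())
                online_preds.append(int(pool.predict_trials(store)[store.n_trials - 1]))
                trajectory.append(posthoc_reanalysis(pool, store))
                pool.reinit_pairs()
            posthoc = trajectory[-1].copy()
        elif mode == "batch":
            store.append_features(self.features)
            pool.run_em(store, self.n_em)
            posthoc = posthoc_reanalysis(pool, store)
            loglik_trace.append(pool.log_likelihoods.copy())
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return UnsupervisedSpellerResults(
            model=self,
            pool=pool,
            store=store,
            mode=mode,
            online_predictions=np.asarray(online_preds, int),
            posthoc_predictions=np.asarray(posthoc, int),
            posthoc_trajectory=trajectory,
            loglik_trace=np.asarray(loglik_trace),
        )


@dataclass
class UnsupervisedSpellerResults:
    """Decoding results: per-trial predictions, the trained pool, diagnostics."""

    model: UnsupervisedSpeller
    pool: ClassifierPool
    store: TrialStore
    mode: str
    online_predictions: np.ndarray
    posthoc_predictions: np.ndarray
    posthoc_trajectory: list[np.ndarray]
    loglik_trace: np.ndarray

    @property
    def best_state(self) -> DecoderState:
        return select_best(self.pool)

    @property
    def weights(self) -> np.ndarray:
        return self.best_state.w

    def _accuracy(self, preds: np.ndarray) -> Optional[float]:
        truth = self.model.ground_truth
        if truth is None or preds.size == 0:
            return None
        return float(np.mean(preds == truth[: preds.size]))

    @property
    def online_accuracy(self) -> Optional[float]:
        return self._accuracy(self.online_predictions)

    @property
    def posthoc_accuracy(self) -> Optional[float]:
        return self._accuracy(self.posthoc_predictions)

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        """Classify held-out trials with the final best classifier."""
        state = self.best_state
        return np.array(
            [
                int(np.argmax(infer_attended(state, features.trial_slice(t),
                                             n_stimuli=self.model.K))) + 1
                for t in features.trials
            ]
        )

    def summary(self) -> str:
        state = self.best_state
        lines = [
            "Unsupervised ERP speller (EM, sign-flipped classifier pool)",
            "=" * 59,
            f"mode:                 {self.mode}",
            f"trials decoded:       {self.store.n_trials}",
            f"epochs per trial:     {self.store.n_per_trial} "
            f"({self.model.K} stimuli x {self.model.J} iterations)",
            f"feature dimension:    {self.store.dim}",
            f"classifier pairs:     {self.pool.n_pairs} "
            f"(EM iterations/trial: {self.model.n_em})",
            f"best data log-lik:    {state.log_likelihood:.2f}",
            f"lambda (precision):   {state.lam:.4g}",
            f"beta (weight prior):  {state.beta:.4g} (cap {self.pool.beta_cap:g})",
        ]
        if self.online_accuracy is not None:
            lines.append(f"online accuracy:      {self.online_accuracy:.1%}")
        if self.posthoc_accuracy is not None:
            lines.append(f"posthoc accuracy:     {self.posthoc_accuracy:.1%}")
        return "\n".join(lines)
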