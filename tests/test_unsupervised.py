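"""EM decoder: oracles for every update, pool mechanics, online behavior."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from erpspell.pipeline import unsupervised_features
from erpspell.synthetic import default_template, generate_session
from erpspell.unsupervised import (
    ClassifierPool,
    DecoderState,
    TrialStore,
    UnsupervisedSpeller,
    e_step,
    em_iterations,
    infer_attended,
    init_pool,
    m_step_beta,
    m_step_lambda,
    m_step_weights,
    online_step,
    posthoc_reanalysis,
    reinit_pairs,
    select_best,
)
from conftest import tiny_toy_features


class TestInitPool:
    def test_five_pairs_pairwise_negated(self):
        pool = init_pool(373, 5, seed=0)
        assert pool.n_classifiers == 10
        for i in range(5):
            np.testing.assert_array_equal(pool.W[:, 2 * i], -pool.W[:, 2 * i + 1])
        assert (pool.lam == 1.0).all() and (pool.beta == 100.0).all()

    def test_deterministic(self):
        np.testing.assert_array_equal(init_pool(20, 5, 9).W, init_pool(20, 5, 9).W)

    def test_pair_sums_are_zero(self):
        pool = init_pool(50, 3, seed=2)
        for i in range(3):
            np.testing.assert_allclose(
                pool.W[:, 2 * i] + pool.W[:, 2 * i + 1], 0.0
            )

    def test_draw_scale_follows_prior(self):
        pool = init_pool(5000, 5, seed=1, beta_init=100.0)
        assert pool.W.std() == pytest.approx(0.1, rel=0.05)


class TestInferAttended:
    def test_zero_weights_give_uniform_posterior(self, rng):
        X = rng.standard_normal((90, 10))
        stim = np.tile(np.arange(1, 7), 15)
        state = DecoderState(w=np.zeros(10))
        post = infer_attended(state, X, stim)
        np.testing.assert_allclose(post, np.full(6, 1 / 6), atol=1e-12)

    def test_matches_direct_density_enumeration_on_k2_toy(self):
        """Independent oracle: product of scalar Gaussian pdfs per hypothesis."""
        w = np.array([0.7, -0.3])
        lam = 2.5
        X = np.array([[0.4, 1.0], [-0.9, 0.2]])  # K=2, J=1: stimuli 1 then 2
        stim = np.array([1, 2])
        state = DecoderState(w=w, lam=lam)
        post = infer_attended(state, X, stim)

        p = X @ w
        sd = 1 / np.sqrt(lam)
        like = []
        for c in (1, 2):
            mus = np.where(stim == c, 1.0, -1.0)
            like.append(np.prod(norm.pdf(p, loc=mus, scale=sd)))
        expected = np.array(like) / np.sum(like)
        np.testing.assert_allclose(post, expected, atol=1e-10)

    def test_posterior_normalized_for_random_states(self, rng):
        for _ in range(5):
            X = rng.standard_normal((30, 8))
            stim = np.tile(np.arange(1, 7), 5)
            state = DecoderState(w=rng.standard_normal(8), lam=rng.uniform(0.5, 5))
            post = infer_attended(state, X, stim)
            assert post.sum() == pytest.approx(1.0, abs=1e-12)
            assert (post >= 0).all()

    def test_empty_trial_rejected(self):
        state = DecoderState(w=np.zeros(3))
        with pytest.raises(ValueError):
            infer_attended(state, np.empty((0, 3)), np.empty(0, int))


class TestEStep:
    def _features(self, rng, n_trials=3):
        X, stim, trial, att = tiny_toy_features(rng, n_trials=n_trials, K=3, J=2, dim=4)
        from erpspell.preprocessing import FeatureMatrix

        return FeatureMatrix(X, stim, trial)

    def test_single_trial_equals_infer_attended(self, rng):
        fm = self._features(rng, n_trials=1)
        state = DecoderState(w=rng.standard_normal(4))
        [post] = e_step(state, fm)
        np.testing.assert_allclose(post, infer_attended(state, fm.trial_slice(0)))

    def test_invariant_to_trial_reordering(self, rng):
        from erpspell.preprocessing import FeatureMatrix

        fm = self._features(rng)
        state = DecoderState(w=rng.standard_normal(4))
        posts = e_step(state, fm)
        perm = [2, 0, 1]
        reordered = FeatureMatrix(
            np.concatenate([fm.trial_slice(t).X for t in perm]),
            np.concatenate([fm.trial_slice(t).stimulus_ids for t in perm]),
            np.repeat(perm, 6),
        )
        posts2 = e_step(state, reordered)
        for i, t in enumerate(perm):
            np.testing.assert_allclose(posts2[i], posts[t])

    def test_high_precision_limit_gives_one_hot(self):
        # perfectly separable toy: projection +1 for the true target epochs
        X = np.array([[1.0], [-1.0], [-1.0], [1.0]])
        stim = np.array([1, 2, 2, 1])
        state = DecoderState(w=np.array([1.0]), lam=1e6)
        post = infer_attended(state, X, stim)
        np.testing.assert_allclose(post, [1.0, 0.0], atol=1e-12)


class TestMStepWeights:
    def test_one_hot_posteriors_equal_hard_label_ridge(self, rng):
        """Closed-form ridge oracle on a 2-trial K=2 J=2 D=3 toy, tol 1e-8."""
        X, stim, trial, att = tiny_toy_features(rng, n_trials=2, K=2, J=2, dim=3)
        lam, beta = 2.0, 5.0
        posts = [np.eye(2)[a - 1] for a in att]
        w = m_step_weights(X, stim, trial, posts, lam, beta)
        y = np.where(stim == att[trial], 1.0, -1.0)
        w_ridge = np.linalg.solve(X.T @ X + (beta / lam) * np.eye(3), X.T @ y)
        np.testing.assert_allclose(w, w_ridge, atol=1e-8)

    def test_soft_posteriors_equal_weighted_labeling_enumeration(self, rng):
        """Brute force: enumerate all joint labelings, ridge-solve each, and
        average weighted by posterior mass."""
        X, stim, trial, att = tiny_toy_features(rng, n_trials=2, K=2, J=2, dim=3)
        lam, beta = 1.5, 3.0
        posts = [np.array([0.7, 0.3]), np.array([0.2, 0.8])]
        w = m_step_weights(X, stim, trial, posts, lam, beta)

        A_inv = np.linalg.inv(X.T @ X + (beta / lam) * np.eye(3))
        expected = np.zeros(3)
        for c0, c1 in itertools.product((1, 2), repeat=2):
            mass = posts[0][c0 - 1] * posts[1][c1 - 1]
            hypo = np.array([c0, c1])[trial]
            y = np.where(stim == hypo, 1.0, -1.0)
            expected += mass * (A_inv @ (X.T @ y))
        np.testing.assert_allclose(w, expected, atol=1e-8)

    def test_large_beta_shrinks_weights(self, rng):
        X, stim, trial, att = tiny_toy_features(rng, n_trials=2, K=2, J=3, dim=4)
        posts = [np.eye(2)[a - 1] for a in att]
        norms = [
            np.linalg.norm(m_step_weights(X, stim, trial, posts, 1.0, beta))
            for beta in (1.0, 100.0, 10_000.0)
        ]
        assert norms[0] > norms[1] > norms[2]


class TestMStepLambda:
    def test_hand_computed_four_epoch_example(self):
        # 1-D features; w = [1]; projections = x
        X = np.array([[0.5], [-0.5], [2.0], [-2.0]])
        stim = np.array([1, 2, 1, 2])
        trial = np.zeros(4, int)
        posts = [np.array([0.75, 0.25])]
        # per epoch q = posterior of its own stimulus being attended
        # q = [.75, .25, .75, .25]
        # mse terms: q(p-1)^2 + (1-q)(p+1)^2
        expected_mse = np.mean(
            [
                0.75 * 0.25 + 0.25 * 2.25,
                0.25 * 2.25 + 0.75 * 0.25,
                0.75 * 1.0 + 0.25 * 9.0,
                0.25 * 9.0 + 0.75 * 1.0,
            ]
        )
        lam = m_step_lambda(X, stim, trial, posts, np.array([1.0]))
        assert lam == pytest.approx(1.0 / expected_mse, rel=1e-12)

    def test_perfect_fit_hits_floor(self):
        X = np.array([[1.0], [-1.0]])
        stim = np.array([1, 2])
        posts = [np.array([1.0, 0.0])]
        lam = m_step_lambda(X, stim, np.zeros(2, int), posts, np.array([1.0]))
        assert lam == pytest.approx(1e10)

    def test_always_positive(self, rng):
        X, stim, trial, att = tiny_toy_features(rng, n_trials=2, K=2, J=2, dim=3)
        posts = [np.array([0.5, 0.5])] * 2
        assert m_step_lambda(X, stim, trial, posts, rng.standard_normal(3)) > 0


class TestMStepBeta:
    def test_unit_weights(self):
        assert m_step_beta(np.ones(7)) == pytest.approx(1.0)

    def test_two_zero_example(self):
        assert m_step_beta(np.array([2.0, 0.0])) == pytest.approx(0.5)

    def test_tiny_weights_capped_at_200(self):
        assert m_step_beta(np.full(373, 1e-8)) == 200.0

    def test_zero_weights_warn_and_cap(self):
        with pytest.warns(UserWarning):
            assert m_step_beta(np.zeros(5)) == 200.0


def _store_and_pool(seed, n_trials=30, amplitude=None, n_pairs=5):
    t = default_template() if amplitude is None else default_template(
        difference_amplitude=amplitude
    )
    sess = generate_session(t, n_blocks=1, trials_per_block=n_trials, seed=seed)
    fm, truth = unsupervised_features(sess)
    store = TrialStore(fm.dim, 6, 15)
    store.append_features(fm)
    pool = ClassifierPool.initialize(fm.dim, n_pairs, seed=seed + 500)
    return store, pool, fm, truth


class TestEmIterations:
    def test_zero_iterations_leave_state_unchanged(self, rng):
        store, pool, fm, truth = _store_and_pool(0, n_trials=4)
        W0, lam0, beta0 = pool.W.copy(), pool.lam.copy(), pool.beta.copy()
        hist = em_iterations(pool, store, n_iter=0)
        np.testing.assert_array_equal(pool.W, W0)
        np.testing.assert_array_equal(pool.lam, lam0)
        np.testing.assert_array_equal(pool.beta, beta0)
        assert hist.shape == (1, 10)

    def test_map_objective_monotone(self):
        """The EM ascends its penalized (MAP) objective on fixed data."""
        store, pool, fm, truth = _store_and_pool(5, n_trials=10)
        em_iterations(pool, store, n_iter=5)
        assert pool.last_map_deltas.shape == (5, 10)
        assert pool.last_map_deltas.min() >= -1e-9

    def test_training_improves_selection_accuracy(self):
        """Median over seeds: accuracy of the trained best classifier is at
        least that of the best initial classifier."""
        gains = []
        for seed in range(10):
            store, pool, fm, truth = _store_and_pool(seed, n_trials=15)
            before = pool.run_em(store, 0)  # evaluate initial likelihoods only
            acc0 = np.mean(posthoc_reanalysis(pool, store) == truth)
            pool.run_em(store, 5)
            acc1 = np.mean(posthoc_reanalysis(pool, store) == truth)
            gains.append(acc1 - acc0)
        assert np.median(gains) >= 0


class TestSelectBest:
    def test_strictly_best_selected(self):
        pool = init_pool(8, 2, seed=0)
        pool.log_likelihoods = np.array([-5.0, -1.0, -3.0, -4.0])
        assert select_best(pool).log_likelihood == -1.0

    def test_tie_breaks_to_lowest_index(self):
        pool = init_pool(8, 2, seed=0)
        pool.log_likelihoods = np.array([-2.0, -2.0, -2.0, -2.0])
        state = select_best(pool)
        np.testing.assert_array_equal(state.w, pool.W[:, 0])

    def test_selected_classifier_labels_above_chance(self):
        """Likelihood-based selection tracks labeling quality: after an online
        run on decodable data the selected classifier's target/non-target AUC
        beats 0.5 in at least 95% of seeded runs (the likelihood-AUC
        correlation the selection strategy relies on)."""
        from erpspell.evaluation import mannwhitney_auc

        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            sess = generate_session(n_blocks=1, trials_per_block=30, seed=seed)
            model = UnsupervisedSpeller.from_session(sess, seed=seed + 900)
            res = model.fit("online")
            fm = model.features
            scores = fm.X @ res.best_state.w
            is_target = fm.stimulus_ids == model.ground_truth[fm.trial_ids]
            auc = mannwhitney_auc(scores[is_target], scores[~is_target])
            hits += auc > 0.5
        assert hits >= 0.95 * n_runs


class TestReinitPairs:
    def test_pairs_sum_to_zero_and_keep_best(self):
        store, pool, fm, truth = _store_and_pool(2, n_trials=5)
        pool.run_em(store, 2)
        keep = [
            2 * i if pool.log_likelihoods[2 * i] >= pool.log_likelihoods[2 * i + 1]
            else 2 * i + 1
            for i in range(pool.n_pairs)
        ]
        kept_w = pool.W[:, keep].copy()
        reinit_pairs(pool)
        assert pool.n_classifiers == 10
        np.testing.assert_array_equal(pool.W[:, keep], kept_w)
        for i in range(pool.n_pairs):
            np.testing.assert_allclose(
                pool.W[:, 2 * i] + pool.W[:, 2 * i + 1], 0.0, atol=0
            )
            assert pool.lam[2 * i] == pool.lam[2 * i + 1]
            assert pool.beta[2 * i] == pool.beta[2 * i + 1]


class TestOnlineStep:
    def test_store_grows_by_one_trial_per_step(self):
        store, pool, fm, truth = _store_and_pool(1, n_trials=3)
        store2 = TrialStore(fm.dim, 6, 15)
        pool2 = ClassifierPool.initialize(fm.dim, 5, seed=123)
        for i, t in enumerate(fm.trials):
            pred, pool2 = online_step(pool2, store2, fm.trial_slice(t))
            assert store2.n_trials == i + 1
            assert 1 <= pred <= 6

    def test_first_prediction_is_chance_level_without_class_information(self):
        """Right after random initialization the decoder guesses on trials
        carrying no class information: accuracy over many seeded single-trial
        runs stays in the binomial 95% CI of 1/6.  (On decodable trials even
        the very first EM pass can exploit the within-trial structure, so the
        chance property is stated — and tested — at zero class difference.)"""
        n_runs, hits = 300, 0
        template = default_template(difference_amplitude=0.0)
        for seed in range(n_runs):
            sess = generate_session(template, n_blocks=1, trials_per_block=1,
                                    seed=seed)
            fm, truth = unsupervised_features(sess)
            store = TrialStore(fm.dim, 6, 15)
            pool = ClassifierPool.initialize(fm.dim, 5, seed=seed + 10_000)
            pred, _ = online_step(pool, store, fm.trial_slice(0))
            hits += pred == truth[0]
        p = 1 / 6
        half = 1.96 * np.sqrt(p * (1 - p) / n_runs)
        assert abs(hits / n_runs - p) < half + 1e-12


class TestPosthoc:
    def test_single_step_posthoc_matches_online(self):
        store, pool, fm, truth = _store_and_pool(4, n_trials=2)
        store2 = TrialStore(fm.dim, 6, 15)
        pool2 = ClassifierPool.initialize(fm.dim, 5, seed=55)
        pred, pool2 = online_step(pool2, store2, fm.trial_slice(0))
        post = posthoc_reanalysis(pool2, store2)
        assert post.shape == (1,)
        assert post[0] == pred

    def test_output_length_equals_stored_trials(self):
        store, pool, fm, truth = _store_and_pool(6, n_trials=7)
        pool.run_em(store, 2)
        assert posthoc_reanalysis(pool, store).shape == (7,)

    def test_high_snr_posthoc_recovers_warmup_errors(self):
        model_session = generate_session(n_blocks=1, trials_per_block=30, seed=40)
        model = UnsupervisedSpeller.from_session(model_session, seed=41)
        res = model.fit("online")
        assert res.posthoc_accuracy >= res.online_accuracy
        assert res.posthoc_accuracy >= 0.8


class TestSignSymmetry:
    def test_negated_weights_and_swapped_means_give_identical_predictions(self):
        """The symmetry motivating the pair construction: flipping all signs
        and swapping the class means is exactly the same decoder."""
        sess = generate_session(n_blocks=1, trials_per_block=6, seed=31)
        fm, truth = unsupervised_features(sess)

        preds = {}
        for flip in (False, True):
            pool = ClassifierPool.initialize(fm.dim, 3, seed=77)
            if flip:
                pool = ClassifierPool(
                    -pool.W, pool.lam, pool.beta,
                    mu_target=-1.0, mu_nontarget=1.0,
                )
            store = TrialStore(fm.dim, 6, 15)
            out = []
            for t in fm.trials:
                pred, pool = online_step(pool, store, fm.trial_slice(t))
                out.append(pred)
            preds[flip] = out
        assert preds[False] == preds[True]


class TestModelResults:
    def test_batch_mode_matches_manual_em(self):
        sess = generate_session(n_blocks=1, trials_per_block=5, seed=9)
        model = UnsupervisedSpeller.from_session(sess, seed=10)
        res = model.fit("batch")
        store, pool = res.store, res.pool
        assert res.posthoc_predictions.shape == (5,)
        assert res.online_predictions.size == 0
        assert np.isfinite(res.best_state.log_likelihood)

    def test_summary_mentions_key_quantities(self):
        sess = generate_session(n_blocks=1, trials_per_block=4, seed=9)
        res = UnsupervisedSpeller.from_session(sess, seed=1).fit("online")
        text = res.summary()
        assert "classifier pairs" in text and "lambda" in text
        assert "online accuracy" in text

    def test_predict_on_heldout_features(self, two_block_session):
        model = UnsupervisedSpeller.from_session(two_block_session, blocks=[0], seed=2)
        res = model.fit("online")
        heldout, truth = unsupervised_features(two_block_session, blocks=[1])
        preds = res.predict(heldout)
        assert preds.shape == truth.shape
        assert np.mean(preds == truth) > 0.8  # trained model generalizes

    def test_legacy_bug_compat_changes_likelihood_not_posterior(self, rng):
        X = rng.standard_normal((12, 5))
        stim = np.tile(np.arange(1, 7), 2)
        state = DecoderState(w=rng.standard_normal(5), lam=2.0)
        exact = infer_attended(state, X, stim, loglik_mode="exact")
        compat = infer_attended(state, X, stim, loglik_mode="legacy-bug-compat")
        np.testing.assert_allclose(exact, compat, atol=1e-12)
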