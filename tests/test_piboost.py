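"""Boosting core against numerical-argmin, additive-model and AdaBoost oracles."""

import numpy as np
import pytest

from emseg import piboost as pb


def golden_section_argmin(loss, lo=0.0, hi=20.0, tol=1e-10):
    """Independent 1-D minimizer for the beta oracle."""
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    while b - a > tol:
        if loss(c) < loss(d):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    return (a + b) / 2


def _toy_data(rng, n=300, c=3, sep=2.0):
    y = rng.integers(0, c, n)
    X = rng.normal(size=(n, 4))
    X[:, 0] += sep * y
    return X, y


def test_class_code_sums_to_zero():
    code = pb.ClassCode(4)
    np.testing.assert_allclose(code.label_vectors.sum(axis=1), 0.0, atol=1e-12)
    v = code.group_vector((1,))
    assert abs(v.sum()) < 1e-12


def test_three_classes_give_three_separators(rng):
    X, y = _toy_data(rng)
    ens = pb.fit(X, y, pb.BoostConfig(n_iterations=2, tree_depth=2, seed=0))
    assert len(ens.separators) == 3
    for sep in ens.separators:
        assert len(sep.learners) == 2


def test_beta_zero_for_uninformative_learner():
    """Weighted error exactly 1/2 under symmetric margins -> beta = 0."""
    w = np.full(4, 0.25)
    z = np.array([2.0, 2.0, -2.0, -2.0])
    assert pb.optimal_beta(w, z) == 0.0


def test_beta_matches_golden_section_oracle(rng):
    """Fitted beta equals an independent 1-D numerical argmin, 50 cases."""
    for _ in range(50):
        n = int(rng.integers(5, 40))
        w = rng.random(n)
        w /= w.sum()
        # PIBoost-style margins for c = 3 one-vs-rest groups
        mags = rng.choice([1.5, 0.75], size=n)
        z = mags * rng.choice([-1.0, 1.0], size=n, p=[0.35, 0.65])
        got = pb.optimal_beta(w, z)
        want = golden_section_argmin(lambda b: np.dot(w, np.exp(-b * z)))
        want = min(want, pb.BETA_CAP)
        assert abs(got - want) < 1e-6


def test_beta_capped_for_perfect_learner():
    w = np.full(3, 1 / 3)
    z = np.array([1.0, 1.0, 2.0])      # all margins positive: loss decreasing
    assert pb.optimal_beta(w, z) == pb.BETA_CAP


def test_zero_iterations_gives_zero_scores(rng):
    X, y = _toy_data(rng)
    ens = pb.fit(X, y, pb.BoostConfig(n_iterations=0, seed=0))
    f = pb.predict_scores(ens, X)
    np.testing.assert_array_equal(f, 0.0)


def test_scores_sum_to_zero_and_match_manual_accumulation(rng):
    X, y = _toy_data(rng, n=120)
    ens = pb.fit(X, y, pb.BoostConfig(n_iterations=5, tree_depth=3, seed=1))
    Xq = X[:20]
    f = pb.predict_scores(ens, Xq)
    np.testing.assert_allclose(f.sum(axis=1), 0.0, atol=1e-9)
    # independent term-by-term evaluator
    manual = np.zeros_like(f)
    for sep in ens.separators:
        for tree, beta in sep.learners:
            manual += beta * tree.predict(Xq)[:, None] * sep.v[None, :]
    np.testing.assert_allclose(f, manual, atol=1e-12)


def test_predict_class_argmax_and_ties(rng):
    assert pb.predict_class(np.array([[2.0, -1.0, -1.0]]))[0] == 0
    assert pb.predict_class(np.zeros((1, 3)))[0] == 0
    scores = rng.normal(size=(200, 4))
    got = pb.predict_class(scores)
    want = np.array([int(np.argmax(s)) for s in scores])
    np.testing.assert_array_equal(got, want)


def test_posterior_uniform_normalized_and_eq1_identity(rng):
    np.testing.assert_allclose(pb.posterior(np.zeros((1, 3)))[0],
                               [1 / 3, 1 / 3, 1 / 3])
    f = rng.normal(size=(100, 3)) * 5
    p = pb.posterior(f)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    # -log posterior equals logsumexp(f) - f[j]
    from scipy.special import logsumexp

    np.testing.assert_allclose(-np.log(p), logsumexp(f, axis=1)[:, None] - f,
                               atol=1e-9)


def test_training_loss_monotone_with_full_sampling(rng):
    X, y = _toy_data(rng, n=200, sep=1.0)
    ens = pb.fit(X, y, pb.BoostConfig(n_iterations=20, tree_depth=2,
                                      subsample_fraction=1.0, seed=3))
    diffs = np.diff(ens.loss_history)
    assert np.all(diffs <= 1e-12)


def test_border_classifier_two_class_structure(rng):
    n = 200
    X = rng.normal(size=(n, 3))
    y = (X[:, 0] > 0).astype(int)
    ens = pb.fit_border_classifier(X, y, pb.BoostConfig(n_iterations=10,
                                                        tree_depth=2, seed=0,
                                                        subsample_fraction=1.0))
    assert len(ens.separators) == 1          # the binary problem collapses
    f = pb.predict_scores(ens, X)
    np.testing.assert_allclose(f[:, 1], -f[:, 0], atol=1e-12)
    # linearly separable data is solved within 10 iterations
    assert np.all(pb.predict_class(f) == y)


def test_binary_decision_sign_matches_adaboost(rng):
    """With c = 2 the decision function is sign-equivalent to discrete
    AdaBoost run with the same trees and weights."""
    n = 150
    X = rng.normal(size=(n, 3))
    y = ((X[:, 0] + 0.5 * X[:, 1]) > 0).astype(int)
    ens = pb.fit(X, y, pb.BoostConfig(n_iterations=8, tree_depth=1,
                                      subsample_fraction=1.0, seed=4),
                 n_classes=2)
    # independent AdaBoost accumulation over the stored trees
    w = np.full(n, 1.0 / n)
    t = np.where(y == 1, 1.0, -1.0)
    F = np.zeros(n)
    for tree, _ in ens.separators[0].learners:
        h = tree.predict(X)
        eps = np.clip(np.dot(w, h != t), 1e-12, 1 - 1e-12)
        alpha = 0.5 * np.log((1 - eps) / eps)
        F += alpha * h
        w *= np.exp(-alpha * t * h)
        w /= w.sum()
    ours = pb.predict_scores(ens, X)[:, 1]
    nonzero = (np.abs(F) > 1e-9) & (np.abs(ours) > 1e-9)
    assert np.all(np.sign(ours[nonzero]) == np.sign(F[nonzero]))


def test_missing_class_rejected(rng):
    X = rng.normal(size=(50, 3))
    y = np.zeros(50, dtype=int)
    with pytest.raises(ValueError):
        pb.fit(X, y, pb.BoostConfig(n_iterations=1), n_classes=3)


def test_balance_training_set_counts(rng):
    labels = np.array([0] * 1000 + [1] * 60 + [2] * 40)
    kept = pb.balance_training_set(labels, rng)
    assert np.count_nonzero(labels[kept] == 0) == 500
    assert np.count_nonzero(labels[kept] == 1) == 60
    assert np.count_nonzero(labels[kept] == 2) == 40
    # degenerate: no background
    pos_only = np.array([1, 2, 1])
    np.testing.assert_array_equal(
        pb.balance_training_set(pos_only, rng), [0, 1, 2])


def test_balance_background_selection_uniform():
    """Chi-square uniformity of which background voxels survive."""
    from scipy import stats

    labels = np.array([0] * 50 + [1] * 5)
    counts = np.zeros(50)
    for seed in range(1000):
        kept = pb.balance_training_set(labels, np.random.default_rng(seed))
        counts[kept[kept < 50]] += 1
    _, p = stats.chisquare(counts)
    assert p > 1e-3


def test_model_json_round_trip(rng, tmp_path):
    from emseg import stack_io as io

    X, y = _toy_data(rng, n=100)
    ens = pb.fit(X, y, pb.BoostConfig(n_iterations=3, tree_depth=3, seed=2))
    io.save_model_json(ens.to_dict(), tmp_path / "m.json")
    back = pb.BoostEnsemble.from_dict(io.load_model_json(tmp_path / "m.json"))
    np.testing.assert_allclose(pb.predict_scores(back, X),
                               pb.predict_scores(ens, X), atol=1e-12)
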