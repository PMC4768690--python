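"""Discriminant classifier: training, prediction, evaluation, persistence."""

import numpy as np
import pytest

from otolithid import (
    ConfusionMatrix,
    DAModel,
    LabelledFeatures,
    evaluate,
    predict_da,
    split_indices,
    train_da,
)
from otolithid.errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidSplitError,
    UnknownClassError,
)


def _solve_elimination(A, b):
    """Gaussian elimination with partial pivoting — independent of numpy.linalg."""
    A = [row[:] for row in A.tolist()]
    b = list(b.tolist())
    n = len(A)
    for i in range(n):
        p = max(range(i, n), key=lambda r: abs(A[r][i]))
        A[i], A[p] = A[p], A[i]
        b[i], b[p] = b[p], b[i]
        for r in range(i + 1, n):
            f = A[r][i] / A[i][i]
            for c in range(i, n):
                A[r][c] -= f * A[i][c]
            b[r] -= f * b[i]
    x = [0.0] * n
    for i in range(n - 1, -1, -1):
        x[i] = (b[i] - sum(A[i][c] * x[c] for c in range(i + 1, n))) / A[i][i]
    return np.array(x)


def oracle_scores(X, labels, priors, query):
    """Closed-form discriminant scores delta_k(x) = x' S^-1 mu_k
    - 0.5 mu_k' S^-1 mu_k + log pi_k, with S^-1 mu_k found by explicit
    elimination on the pooled (n - K) covariance."""
    classes = list(dict.fromkeys(labels))
    n, d = X.shape
    K = len(classes)
    mus = np.array([X[np.asarray(labels) == c].mean(axis=0) for c in classes])
    S = np.zeros((d, d))
    for c, mu in zip(classes, mus):
        Xc = X[np.asarray(labels) == c] - mu
        S += Xc.T @ Xc
    S /= n - K
    out = np.empty((query.shape[0], K))
    for k, mu in enumerate(mus):
        Smu = _solve_elimination(S, mu)
        out[:, k] = query @ Smu - 0.5 * mu @ Smu + np.log(priors[k])
    return out


def gaussian_training_set(rng, means, n_per_class, cov=None):
    d = means.shape[1]
    cov = np.eye(d) if cov is None else cov
    chol = np.linalg.cholesky(cov)
    X, labels = [], []
    for k, mu in enumerate(means):
        X.append(rng.standard_normal((n_per_class, d)) @ chol.T + mu)
        labels += [f"sp{k}"] * n_per_class
    return LabelledFeatures(X=np.vstack(X), labels=np.array(labels))


class TestTrainPredict:
    def test_two_class_1d_means_and_boundary(self):
        data = LabelledFeatures(
            X=np.array([[0.0], [0.1], [10.0], [10.1]]),
            labels=np.array(["a", "a", "b", "b"]),
        )
        model = train_da(data)
        np.testing.assert_allclose(model.means, [[0.05], [10.05]])
        # the midpoint 5.05 is the decision boundary; tie resolves to class order
        assert predict_da(model, [[5.04]])[0] == "a"
        assert predict_da(model, [[5.06]])[0] == "b"
        assert predict_da(model, [[5.05]])[0] == "a"

    def test_class_mean_wins_under_identity_covariance(self, rng):
        means = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        data = gaussian_training_set(rng, means, 50)
        model = train_da(data)
        preds = predict_da(model, means)
        assert list(preds) == ["sp0", "sp1", "sp2"]

    def test_scores_match_elimination_oracle(self, rng):
        for trial in range(5):
            means = rng.normal(size=(3, 6)) * 2
            data = gaussian_training_set(rng, means, 20)
            query = rng.normal(size=(10, 6))
            model = train_da(data)
            got = model.scores(query)
            priors = np.full(3, 1 / 3)
            want = oracle_scores(data.X, data.labels, priors, query)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)
            assert list(predict_da(model, query)) == [
                data.classes[i] for i in np.argmax(want, axis=1)
            ]

    def test_identical_means_predicts_at_chance(self, rng):
        means = np.tile(rng.normal(size=(1, 4)), (3, 1))
        data = gaussian_training_set(rng, means, 100)
        model = train_da(data)
        test = gaussian_training_set(rng, means, 667)  # ~2000 draws
        preds = predict_da(model, test.X)
        acc = np.mean(preds == test.labels)
        # binomial 99% CI around 1/3 at n = 2001
        se = np.sqrt((1 / 3) * (2 / 3) / len(test.labels))
        assert abs(acc - 1 / 3) < 2.576 * se + 1e-9

    def test_training_order_permutation_invariant(self, rng):
        means = rng.normal(size=(3, 5))
        data = gaussian_training_set(rng, means, 15)
        perm = rng.permutation(len(data.labels))
        shuffled = LabelledFeatures(X=data.X[perm], labels=data.labels[perm])
        m1, m2 = train_da(data), train_da(shuffled)
        # class discovery order may differ; compare per-class
        for c in m1.classes:
            i, j = m1.classes.index(c), m2.classes.index(c)
            np.testing.assert_allclose(m1.means[i], m2.means[j], atol=1e-12)
        np.testing.assert_allclose(m1.pooled_cov, m2.pooled_cov, atol=1e-12)

    def test_affine_equivariance_of_predictions(self, rng):
        means = rng.normal(size=(3, 4)) * 3
        data = gaussian_training_set(rng, means, 30)
        query = rng.normal(size=(40, 4))
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)  # invertible
        mapped = LabelledFeatures(X=data.X @ A.T, labels=data.labels)
        p1 = predict_da(train_da(data), query)
        p2 = predict_da(train_da(mapped), query @ A.T)
        assert list(p1) == list(p2)

    def test_agrees_with_sklearn_lda(self, rng):
        """Independent route: scikit-learn's LDA with uniform priors must
        produce the same predictions (covariance scale conventions differ,
        but the argmax does not under equal priors)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        means = rng.normal(size=(4, 8))
        data = gaussian_training_set(rng, means, 25)
        query = rng.normal(size=(60, 8))
        ours = predict_da(train_da(data), query)
        sk = LinearDiscriminantAnalysis(priors=np.full(4, 0.25)).fit(data.X, data.labels)
        assert list(ours) == list(sk.predict(query))

    def test_parameter_recovery_and_bayes_rate(self, rng):
        """Two 1-D Gaussian classes, means +/- delta/2, unit sd: estimated
        means within 3 SE; held-out accuracy within 2 points of the analytic
        Bayes rate Phi(delta/2)."""
        from scipy.stats import norm

        delta = 2.0
        means = np.array([[-delta / 2], [delta / 2]])
        data = gaussian_training_set(rng, means, 500)
        model = train_da(data)
        se = 1.0 / np.sqrt(500)
        assert abs(model.means[0, 0] + delta / 2) < 3 * se
        assert abs(model.means[1, 0] - delta / 2) < 3 * se
        test = gaussian_training_set(rng, means, 2000)
        acc = np.mean(predict_da(model, test.X) == test.labels)
        bayes = norm.cdf(delta / 2)
        assert abs(acc - bayes) < 0.02

    def test_insufficient_data_errors(self):
        with pytest.raises(InsufficientDataError):
            train_da(LabelledFeatures(X=np.zeros((3, 2)), labels=np.array(["a"] * 3)))
        with pytest.raises(InsufficientDataError):
            train_da(
                LabelledFeatures(
                    X=np.random.default_rng(0).random((3, 2)),
                    labels=np.array(["a", "a", "b"]),
                )
            )

    def test_dimension_mismatch_rejected(self, rng):
        data = gaussian_training_set(rng, rng.normal(size=(2, 3)), 10)
        model = train_da(data)
        with pytest.raises(InvalidInputError):
            predict_da(model, np.zeros((1, 5)))

    def test_ridge_recorded_when_triggered(self, rng):
        # rank-deficient features: duplicated column
        base = rng.normal(size=(40, 2))
        X = np.hstack([base, base[:, :1]])
        data = LabelledFeatures(X=X, labels=np.array(["a", "b"] * 20))
        model = train_da(data, ridge=1e-6)
        assert model.ridge > 0
        from otolithid.errors import SingularCovarianceError

        with pytest.raises(SingularCovarianceError):
            train_da(data, ridge=0.0)


class TestEvaluate:
    def test_perfect_predictions_give_diagonal(self, rng):
        means = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        data = gaussian_training_set(rng, means, 20)
        model = train_da(data)
        result = evaluate(model, data)
        assert np.array_equal(np.diag(np.diag(result.confusion.counts)), result.confusion.counts)
        assert result.accuracy == 1.0
        assert result.accuracy_percent == 100

    def test_row_sums_equal_per_class_test_counts(self, rng):
        means = rng.normal(size=(3, 4))
        data = gaussian_training_set(rng, means, 30)
        model = train_da(data)
        test = gaussian_training_set(rng, means, 17)
        result = evaluate(model, test)
        np.testing.assert_array_equal(result.confusion.counts.sum(axis=1), [17, 17, 17])

    def test_unseen_test_label_rejected(self, rng):
        data = gaussian_training_set(rng, rng.normal(size=(2, 3)), 10)
        model = train_da(data)
        bad = LabelledFeatures(X=np.zeros((1, 3)), labels=np.array(["mystery"]))
        with pytest.raises(UnknownClassError):
            evaluate(model, bad)

    def test_model_json_round_trip(self, rng, tmp_path):
        data = gaussian_training_set(rng, rng.normal(size=(3, 4)), 15)
        model = train_da(data)
        model.save(tmp_path / "model.json")
        loaded = DAModel.load(tmp_path / "model.json")
        query = rng.normal(size=(20, 4))
        np.testing.assert_allclose(model.scores(query), loaded.scores(query), rtol=1e-12)
        assert loaded.classes == [str(c) for c in model.classes]


class TestConfusionMatrixArithmetic:
    def test_published_style_matrix_accuracy(self):
        cm = ConfusionMatrix(
            counts=np.array([[10, 0, 0], [0, 10, 0], [0, 1, 9]]),
            classes=["A", "B", "C"],
        )
        assert cm.accuracy == pytest.approx(29 / 30)
        assert cm.accuracy_percent == 97
        assert cm.per_class_accuracy()["C"] == pytest.approx(0.9)

    def test_rejects_negative_or_nonsquare(self):
        with pytest.raises(InvalidInputError):
            ConfusionMatrix(counts=np.array([[1, -1], [0, 2]]), classes=["a", "b"])
        with pytest.raises(InvalidInputError):
            ConfusionMatrix(counts=np.zeros((2, 3), dtype=int), classes=["a", "b"])


class TestSplitIndices:
    def test_fixed_split_disjoint_and_deterministic(self):
        tr, te = split_indices(30, 18, 10)
        assert tr == list(range(18)) and te == list(range(18, 28))
        tr2, te2 = split_indices(30, 18, 10, seed=7)
        assert not set(tr2) & set(te2)
        assert (tr2, te2) == split_indices(30, 18, 10, seed=7)

    def test_overflow_rejected(self):
        with pytest.raises(InvalidSplitError):
            split_indices(20, 18, 10)
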