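import numpy as np
import pandas as pd
import pytest

from pefrisk.classifier import (
    Hyperparams,
    OversamplingError,
    evaluate_split,
    extract_features,
    fine_tune_target,
    fit_lr_head,
    predict_risk,
    smote_oversample,
    train_source_model,
    TLClassifier,
)
from pefrisk.nn import MLP

FAST = Hyperparams(epochs=30, patience=10, source_folds=3, target_folds=3, ft_epochs=15)


def _logistic_data(rng, n, w, intercept=0.0):
    X = rng.normal(0, 1, (n, len(w)))
    p = 1 / (1 + np.exp(-(intercept + X @ w)))
    return X, (rng.random(n) < p).astype(int)


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(0, 1, (40, 3))
        y = np.repeat([0, 1], 20)
        Xa, ya, syn = smote_oversample(X, y)
        np.testing.assert_array_equal(Xa, X)
        np.testing.assert_array_equal(ya, y)
        assert not syn.any()

    def test_convexity_in_one_dimension(self, rng):
        X = np.array([[0.0], [1.0]] + [[5.0]] * 10)
        y = np.array([1, 1] + [0] * 10)
        Xa, ya, syn = smote_oversample(X, y, k_neighbors=1, seed=3)
        assert ((Xa[syn] >= 0.0) & (Xa[syn] <= 1.0)).all()

    def test_balances_to_parity(self, rng):
        X = rng.normal(0, 1, (100, 4))
        y = np.array([0] * 80 + [1] * 20)
        Xa, ya, syn = smote_oversample(X, y, seed=0)
        assert (ya == 1).sum() == (ya == 0).sum() == 80
        # originals preserved verbatim
        np.testing.assert_array_equal(Xa[:100], X)
        assert syn.sum() == 60

    def test_tiny_minority_rejected(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = np.array([0] * 9 + [1])
        with pytest.raises(OversamplingError):
            smote_oversample(X, y)


class TestSourceModel:
    def test_separable_data_high_accuracy(self, rng):
        X = rng.normal(0, 1, (400, 4))
        y = (X[:, 0] > 0).astype(int)
        ids = np.repeat(["A", "B"], 200)
        src = train_source_model(X, y, ids, hyperparams=FAST, seed=0)
        acc = np.mean((src.model.predict_proba(src.scaler.transform(X)) >= 0.5) == y)
        assert acc >= 0.95

    def test_seeded_determinism(self, rng):
        X, y = _logistic_data(rng, 200, [1.0, -1.0])
        ids = np.repeat(["A", "B"], 100)
        a = train_source_model(X, y, ids, hyperparams=FAST, seed=5)
        b = train_source_model(X, y, ids, hyperparams=FAST, seed=5)
        for wa, wb in zip(a.model.W, b.model.W):
            np.testing.assert_array_equal(wa, wb)

    def test_target_exclusion_enforced(self, rng):
        X, y = _logistic_data(rng, 100, [1.0])
        ids = np.repeat(["A", "B"], 50)
        with pytest.raises(ValueError, match="present in pooled"):
            train_source_model(X, y, ids, excluded_patient="A", hyperparams=FAST)

    def test_single_patient_or_class_rejected(self, rng):
        X, y = _logistic_data(rng, 100, [1.0])
        with pytest.raises(ValueError, match="2 patients"):
            train_source_model(X, y, ["A"] * 100, hyperparams=FAST)
        with pytest.raises(ValueError, match="single-class"):
            train_source_model(X, np.zeros(100), np.repeat(["A", "B"], 50), hyperparams=FAST)


@pytest.fixture(scope="module")
def source_fixture():
    rng = np.random.default_rng(42)
    w = np.array([1.5, -1.0, 0.8])
    Xs, ys = [], []
    for i, shift in enumerate((-0.3, 0.0, 0.3)):
        X, y = _logistic_data(rng, 250, w, intercept=shift)
        Xs.append(X)
        ys.append(y)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    ids = np.repeat(["A", "B", "C"], 250)
    src = train_source_model(X, y, ids, hyperparams=FAST, seed=1)
    return src, w


class TestFineTune:
    def test_zero_epochs_is_identity(self, source_fixture, rng):
        src, w = source_fixture
        X, y = _logistic_data(rng, 80, w)
        hp = Hyperparams(ft_epochs=0)
        tgt = fine_tune_target(src, src.scaler.transform(X), y, hyperparams=hp)
        for wt, ws in zip(tgt.model.W, src.model.W):
            np.testing.assert_array_equal(wt, ws)

    def test_fine_tuning_beats_source_on_shifted_target(self, source_fixture):
        """Paired comparison over 20 seeded target draws."""
        from pefrisk.nn import _bce

        src, w = source_fixture
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            X, y = _logistic_data(r, 160, w, intercept=1.2)  # shifted base risk
            if len(np.unique(y)) < 2:
                continue
            Xs = src.scaler.transform(X)
            tr, va = np.arange(0, 120), np.arange(120, 160)
            tgt = fine_tune_target(
                src, Xs[tr], y[tr], hyperparams=FAST, seed=seed
            )
            loss_src = _bce(src.model.predict_proba(Xs[va]), y[va])
            loss_tgt = _bce(tgt.model.predict_proba(Xs[va]), y[va])
            wins += loss_tgt <= loss_src
        assert wins >= 16  # >= 80% of repeats

    def test_shuffled_labels_give_chance_accuracy(self, source_fixture):
        src, w = source_fixture
        r = np.random.default_rng(9)
        X, y = _logistic_data(r, 400, w)
        y_perm = r.permutation(y)
        Xs = src.scaler.transform(X)
        tgt = fine_tune_target(src, Xs[:200], y_perm[:200], hyperparams=FAST, seed=9)
        acc = np.mean((tgt.model.predict_proba(Xs[200:]) >= 0.5) == y_perm[200:])
        assert abs(acc - 0.5) <= 0.1

    def test_single_class_instructs_smote(self, source_fixture):
        src, _ = source_fixture
        with pytest.raises(OversamplingError, match="SMOTE"):
            fine_tune_target(src, np.zeros((10, 3)), np.zeros(10), hyperparams=FAST)


class TestFeatureExtraction:
    def test_width_nonnegativity_determinism(self, source_fixture, rng):
        src, w = source_fixture
        X, y = _logistic_data(rng, 30, w)
        Xs = src.scaler.transform(X)
        tgt = fine_tune_target(src, Xs, y, hyperparams=Hyperparams(ft_epochs=0))
        feats = extract_features(tgt, Xs)
        assert feats.shape == (30, 8)  # last hidden layer width
        assert (feats >= 0).all()  # ReLU activations
        np.testing.assert_array_equal(
            extract_features(tgt, np.vstack([Xs[:1], Xs[:1]]))[0],
            extract_features(tgt, np.vstack([Xs[:1], Xs[:1]]))[1],
        )

    def test_dimension_mismatch_rejected(self, source_fixture):
        src, _ = source_fixture
        tgt = fine_tune_target(src, np.zeros((5, 3)), np.array([0, 1, 0, 1, 0]),
                               hyperparams=Hyperparams(ft_epochs=0))
        with pytest.raises(ValueError, match="width"):
            extract_features(tgt, np.zeros((5, 7)))


class TestLRHead:
    def test_separable_features_perfect_heldout(self, rng):
        f_tr = np.concatenate([rng.uniform(-2, -0.5, 50), rng.uniform(0.5, 2, 50)])[:, None]
        y_tr = np.repeat([0, 1], 50)
        head = fit_lr_head(f_tr, y_tr)
        f_te = np.array([[-1.2], [-0.7], [0.9], [1.7]])
        assert np.array_equal(head.predict(f_te), [0, 0, 1, 1])

    def test_tie_probability_is_positive_class(self, rng):
        head = fit_lr_head(rng.normal(0, 1, (20, 1)), np.tile([0, 1], 10))
        head.lr.intercept_ = np.array([0.0])
        head.lr.coef_ = np.array([[0.0]])
        # p is exactly 0.5 everywhere; the rule p >= 0.5 outputs risk
        assert head.predict_proba(np.array([[3.0]]))[0] == 0.5
        assert head.predict(np.array([[3.0]]))[0] == 1

    def test_one_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_lr_head(rng.normal(0, 1, (10, 2)), np.ones(10))

    def test_matches_irls_oracle(self, rng):
        """Coefficients agree with a hand-rolled Newton/IRLS optimiser."""
        X = rng.normal(0, 1, (20, 2))
        y = (rng.random(20) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        head = fit_lr_head(X, y)
        # IRLS on the unpenalised log-likelihood
        Xd = np.column_stack([np.ones(20), X])
        theta = np.zeros(3)
        for _ in range(100):
            p = 1 / (1 + np.exp(-Xd @ theta))
            W = p * (1 - p)
            grad = Xd.T @ (y - p)
            H = Xd.T @ (Xd * W[:, None])
            step = np.linalg.solve(H, grad)
            theta += step
            if np.max(np.abs(step)) < 1e-12:
                break
        assert np.max(np.abs(head.coefficients - theta)) < 1e-6


class TestEvaluateSplit:
    @staticmethod
    def _rows(rng, n=100, p_risk=0.3):
        X = rng.normal(0, 1, (n, 3))
        z = 1.2 * X[:, 0] - 0.8 * X[:, 1] + rng.normal(0, 0.8, n)
        thresh = np.quantile(z, p_risk)
        return pd.DataFrame(
            {"f0": X[:, 0], "f1": X[:, 1], "f2": X[:, 2], "label": (z < thresh).astype(int)}
        )

    def test_stratified_split_arithmetic(self, rng):
        rows = self._rows(rng, 100)
        rep, info, _ = evaluate_split(rows, "lr", seed=0, feature_cols=["f0", "f1", "f2"])
        assert len(info.test_index) == 20
        y = rows["label"].to_numpy()
        full_rate = y.mean()
        test_rate = y[info.test_index].mean()
        assert abs(test_rate - full_rate) <= 1 / 20 + 1e-9

    def test_no_leakage_disjoint_indices(self, rng):
        rows = self._rows(rng, 120)
        _, info, _ = evaluate_split(rows, "lr", seed=1, feature_cols=["f0", "f1", "f2"])
        assert set(info.train_index).isdisjoint(info.test_index)
        assert len(info.train_index) + len(info.test_index) == len(rows)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluate_split(self._rows(rng, 30), "lr", feature_cols=["f0", "f1", "f2"])

    def test_tl_identity_limit(self, rng):
        """With 0 fine-tune epochs TL+LR equals LR on source activations."""
        rows = self._rows(rng, 150)
        pooled = self._rows(rng, 400)
        src = train_source_model(
            pooled[["f0", "f1", "f2"]].to_numpy(),
            pooled["label"].to_numpy(),
            np.repeat(["A", "B"], 200),
            hyperparams=FAST,
            seed=3,
        )
        hp0 = Hyperparams(ft_epochs=0)
        rep, info, clf = evaluate_split(
            rows, "tl+lr", seed=3, source=src, hyperparams=hp0,
            feature_cols=["f0", "f1", "f2"],
        )
        # manual source-features LR on the same split
        from sklearn.model_selection import train_test_split

        X = rows[["f0", "f1", "f2"]].to_numpy()
        y = rows["label"].to_numpy()
        idx = np.arange(len(rows))
        tr, te = train_test_split(idx, test_size=0.2, stratify=y, random_state=3, shuffle=True)
        F_tr = src.model.hidden_activations(src.scaler.transform(X[tr]))
        head = fit_lr_head(F_tr, y[tr], C=1.0, class_weight="balanced")
        p_manual = head.predict_proba(src.model.hidden_activations(src.scaler.transform(X[te])))
        _, p_clf = clf.predict(X[te])
        np.testing.assert_allclose(p_clf, p_manual, rtol=0, atol=1e-12)

    def test_probabilities_valid(self, rng):
        rows = self._rows(rng, 100)
        pooled = self._rows(rng, 300)
        src = train_source_model(
            pooled[["f0", "f1", "f2"]].to_numpy(), pooled["label"].to_numpy(),
            np.repeat(["A", "B", "C"], 100), hyperparams=FAST, seed=2,
        )
        _, _, clf = evaluate_split(
            rows, "tl+lr", seed=2, source=src, hyperparams=FAST,
            feature_cols=["f0", "f1", "f2"],
        )
        cls, p = predict_risk(clf, rows[["f0", "f1", "f2"]].to_numpy()[0])
        assert cls in (0, 1)
        assert 0 < p < 1
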