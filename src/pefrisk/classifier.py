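"""Transfer-learning classification of next-day asthma risk (TL + LR).

Pipeline: a fully connected *source* network is trained on the pooled
labelled days of every cohort patient except the target; the network is
then fine-tuned on the target patient's own training days (*target* model);
finally the target network's last-hidden-layer activations feed a logistic
regression head that outputs the risk probability.  Class imbalance (risk
days are a ~20% minority) is handled with SMOTE inside training folds only;
test data are never oversampled or otherwise touched before evaluation.

The plain logistic-regression baseline trained on the target patient's raw
standardized features is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .exposure import FEATURE_COLUMNS
from .metrics import MetricsReport, compute_metrics, confusion_from_predictions, roc_auc
from .nn import MLP, TrainHistory

__all__ = [
    "Hyperparams",
    "SourceModel",
    "TargetModel",
    "LRHead",
    "TLClassifier",
    "OversamplingError",
    "smote_oversample",
    "train_source_model",
    "fine_tune_target",
    "extract_features",
    "fit_lr_head",
    "predict_risk",
    "evaluate_split",
    "SplitInfo",
]


class OversamplingError(ValueError):
    pass


@dataclass(frozen=True)
class Hyperparams:
    """Training knobs for the source/target networks and the protocol."""

    hidden: Tuple[int, ...] = (16, 8)
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    patience: int = 20
    source_folds: int = 10
    target_folds: int = 5
    ft_lr_scale: float = 0.1  # fine-tuning learning rate = ft_lr_scale * lr
    ft_epochs: int = 40
    freeze_first_layer: bool = False
    smote_k: int = 5


@dataclass
class SourceModel:
    """Population network trained on pooled data excluding the target."""

    model: MLP
    scaler: StandardScaler
    excluded_patient: Optional[str]
    cv_val_losses: List[float] = field(default_factory=list)
    histories: List[TrainHistory] = field(default_factory=list)
    trained_on_patients: Tuple[str, ...] = ()


@dataclass
class TargetModel:
    """Patient-specific fine-tuned copy of a source network."""

    model: MLP
    source: SourceModel
    cv_val_f1: List[float] = field(default_factory=list)
    histories: List[TrainHistory] = field(default_factory=list)


@dataclass
class LRHead:
    """Logistic-regression head on last-hidden-layer activations."""

    lr: LogisticRegression
    threshold: float = 0.5

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([self.lr.intercept_, self.lr.coef_.ravel()])

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.lr.predict_proba(features)[:, 1]

    def predict(self, features: np.ndarray) -> np.ndarray:
        # ties at the threshold go to the positive (risk) class
        return (self.predict_proba(features) >= self.threshold).astype(int)


@dataclass
class TLClassifier:
    """Full predict path: standardize -> target network -> LR head."""

    source: SourceModel
    target: TargetModel
    head: LRHead

    def predict(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        Xs = self.source.scaler.transform(np.asarray(X, dtype=float))
        feats = self.target.model.hidden_activations(Xs)
        p = self.head.predict_proba(feats)
        return self.head.predict(feats), p


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority interpolation (SMOTE).

    Each synthetic point is x + u·(x_nn − x) for a random minority point x,
    one of its k nearest minority neighbours x_nn (Euclidean) and
    u ~ Uniform(0, 1).  Original rows are returned unchanged and first;
    the third return value flags synthetic rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    counts = {c: int(np.sum(y == c)) for c in np.unique(y)}
    if len(counts) != 2:
        raise OversamplingError("SMOTE needs exactly two classes present")
    minority = min(counts, key=counts.get)
    n_min, n_maj = counts[minority], max(counts.values())
    n_new = n_maj - n_min
    if n_new == 0:
        return X, y, np.zeros(len(y), dtype=bool)
    if n_min < 2:
        raise OversamplingError("minority class needs >= 2 samples for SMOTE")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    k = min(k_neighbors, n_min - 1)
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # col 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, n_new)
    pick = rng.integers(1, k + 1, n_new)
    u = rng.uniform(0.0, 1.0, n_new)
    Xnew = Xm[base] + u[:, None] * (Xm[idx[base, pick]] - Xm[base])
    X_aug = np.vstack([X, Xnew])
    y_aug = np.concatenate([y, np.full(n_new, minority)])
    synthetic = np.concatenate([np.zeros(len(y), bool), np.ones(n_new, bool)])
    return X_aug, y_aug, synthetic


def train_source_model(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: Sequence[str],
    *,
    excluded_patient: Optional[str] = None,
    hyperparams: Hyperparams = Hyperparams(),
    seed: int = 0,
    apply_smote: bool = True,
) -> SourceModel:
    """Train the population network with k-fold cross-validation.

    One network per fold is trained (SMOTE and standardization fit inside
    the training folds only; early stopping monitors the held-out fold) and
    the fold model with the lowest validation loss is retained.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    ids = np.asarray(patient_ids)
    uniq = set(ids.tolist())
    if excluded_patient is not None and excluded_patient in uniq:
        raise ValueError(f"target patient {excluded_patient!r} present in pooled data")
    if len(uniq) < 2:
        raise ValueError("pooled source data must span >= 2 patients")
    if len(np.unique(y)) < 2:
        raise ValueError("pooled labels are single-class; cannot train the source model")

    hp = hyperparams
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    folds = min(hp.source_folds, int(np.min(np.bincount(y))))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best = None
    losses: List[float] = []
    histories: List[TrainHistory] = []
    for f, (tr, va) in enumerate(skf.split(Xs, y)):
        Xt, yt = Xs[tr], y[tr]
        if apply_smote:
            Xt, yt, _ = smote_oversample(Xt, yt, hp.smote_k, seed=seed + f)
        model = MLP(X.shape[1], hp.hidden, seed=seed, lr=hp.lr)
        hist = model.fit(
            Xt,
            yt,
            epochs=hp.epochs,
            batch_size=hp.batch_size,
            X_val=Xs[va],
            y_val=y[va],
            patience=hp.patience,
            seed=seed + f,
        )
        val = min(hist.val_loss) if hist.val_loss else np.inf
        losses.append(float(val))
        histories.append(hist)
        if best is None or val < best[0]:
            best = (val, model)
    return SourceModel(
        model=best[1],
        scaler=scaler,
        excluded_patient=excluded_patient,
        cv_val_losses=losses,
        histories=histories,
        trained_on_patients=tuple(sorted(uniq)),
    )


def _f1_at_half(y_true: np.ndarray, p: np.ndarray) -> float:
    rep = compute_metrics(confusion_from_predictions(y_true, (p >= 0.5).astype(int)))
    return rep.f1 if rep.f1 is not None else 0.0


def fine_tune_target(
    source: SourceModel,
    X_std: np.ndarray,
    y: np.ndarray,
    *,
    hyperparams: Hyperparams = Hyperparams(),
    seed: int = 0,
    apply_smote: bool = True,
) -> TargetModel:
    """Fine-tune the source network on one patient's training data.

    ``X_std`` must already be standardized with the source scaler.  All
    layers train at ``ft_lr_scale`` times the source learning rate (or the
    first layer stays frozen under ``freeze_first_layer``).  k-fold CV
    trains one copy per fold — oversampling is applied to the k−1 training
    folds only, so early stopping and fold selection see the patient's real
    class distribution — and the best fold model by validation F1 (ties:
    lower validation loss) is kept.  With ``ft_epochs == 0`` the target is
    an exact copy of the source.
    """
    X_std = np.asarray(X_std, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if len(y) == 0:
        raise ValueError("target training data is empty")
    hp = hyperparams
    if hp.ft_epochs == 0:
        return TargetModel(model=source.model.copy(), source=source)
    if len(np.unique(y)) < 2:
        raise OversamplingError(
            "target training labels are single-class; oversampling (SMOTE) "
            "requires both classes and none is present to synthesise from"
        )
    folds = min(hp.target_folds, int(np.min(np.bincount(y))))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    frozen = (0,) if hp.freeze_first_layer else ()
    best = None
    f1s: List[float] = []
    histories: List[TrainHistory] = []
    for f, (tr, va) in enumerate(skf.split(X_std, y)):
        Xf, yf = X_std[tr], y[tr]
        if apply_smote:
            Xf, yf, _ = smote_oversample(Xf, yf, hp.smote_k, seed=seed + f)
        model = source.model.copy()
        hist = model.fit(
            Xf,
            yf,
            epochs=hp.ft_epochs,
            batch_size=hp.batch_size,
            X_val=X_std[va],
            y_val=y[va],
            patience=hp.patience,
            lr=hp.lr * hp.ft_lr_scale,
            seed=seed + f,
            freeze_layers=frozen,
            balanced_val=True,
        )
        p_va = model.predict_proba(X_std[va])
        f1 = _f1_at_half(y[va], p_va)
        val = min(hist.val_loss) if hist.val_loss else np.inf
        f1s.append(f1)
        histories.append(hist)
        key = (-f1, val)  # maximise F1, break ties on loss
        if best is None or key < best[0]:
            best = (key, model)
    return TargetModel(model=best[1], source=source, cv_val_f1=f1s, histories=histories)


def extract_features(target: TargetModel, X_std: np.ndarray) -> np.ndarray:
    """Last-hidden-layer activations of the target network."""
    X_std = np.asarray(X_std, dtype=float)
    if X_std.ndim != 2 or X_std.shape[1] != target.model.sizes[0]:
        raise ValueError(
            f"expected standardized input of width {target.model.sizes[0]}, "
            f"got shape {X_std.shape}"
        )
    return target.model.hidden_activations(X_std)


def fit_lr_head(
    features: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    *,
    C: float = np.inf,
    class_weight: Optional[str] = None,
) -> LRHead:
    """Logistic regression on network features.

    Plain (unpenalised, unweighted) by default; the TL pipeline fits it with
    ``C=1`` and ``class_weight="balanced"`` — an 8-parameter head refit on
    ~10² patient rows needs shrinkage, and class weighting places the
    decision boundary as balanced training would without manufacturing
    synthetic points in activation space.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("LR head needs both classes in its training labels")
    lr = LogisticRegression(
        C=C, solver="lbfgs", max_iter=5000, tol=1e-10, class_weight=class_weight
    )
    lr.fit(np.asarray(features, dtype=float), labels)
    return LRHead(lr=lr, threshold=threshold)


def predict_risk(clf: TLClassifier, x: np.ndarray) -> Tuple[int, float]:
    """(class, probability) for one feature row; p >= 0.5 is risk."""
    cls, p = clf.predict(np.atleast_2d(x))
    return int(cls[0]), float(p[0])


@dataclass
class SplitInfo:
    """Provenance of an 80/20 evaluation, for leakage assertions."""

    train_index: np.ndarray
    test_index: np.ndarray
    n_train_after_smote: int
    pipeline: str


def evaluate_split(
    rows: pd.DataFrame,
    pipeline: str,
    seed: int = 0,
    *,
    source: Optional[SourceModel] = None,
    hyperparams: Hyperparams = Hyperparams(),
    feature_cols: Sequence[str] = tuple(FEATURE_COLUMNS),
    label_col: str = "label",
    min_rows: int = 50,
    split: str = "stratified",
) -> Tuple[MetricsReport, SplitInfo, Optional[TLClassifier]]:
    """Evaluate one patient's model under the 80/20 protocol.

    Stratified random 80/20 split by default (``split="chronological"``
    holds out the final 20% of days instead, respecting the time-series
    structure); standardization and SMOTE are fit on the 80% training part
    only; metrics are computed once on the untouched 20%.  ``pipeline`` is
    ``"lr"`` (stand-alone logistic regression on raw standardized features)
    or ``"tl+lr"`` (requires a ``source`` model trained on pooled data
    excluding this patient).
    """
    if len(rows) < min_rows:
        raise ValueError(f"need >= {min_rows} labeled rows, got {len(rows)}")
    X = rows[list(feature_cols)].to_numpy(dtype=float)
    y = rows[label_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class; cannot evaluate a classifier")
    idx = np.arange(len(rows))
    if split == "stratified":
        tr_idx, te_idx = train_test_split(
            idx, test_size=0.2, stratify=y, random_state=seed, shuffle=True
        )
    elif split == "chronological":
        cut = int(round(0.8 * len(idx)))
        tr_idx, te_idx = idx[:cut], idx[cut:]
        if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[te_idx])) < 2:
            raise ValueError("chronological split leaves a single-class partition")
    else:
        raise ValueError(f"unknown split {split!r}")
    X_tr, y_tr = X[tr_idx], y[tr_idx]
    X_te, y_te = X[te_idx], y[te_idx]

    clf_out: Optional[TLClassifier] = None
    if pipeline == "lr":
        scaler = StandardScaler().fit(X_tr)
        Xs_tr, ys_tr, _ = smote_oversample(
            scaler.transform(X_tr), y_tr, hyperparams.smote_k, seed=seed
        )
        lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
        lr.fit(Xs_tr, ys_tr)
        p_te = lr.predict_proba(scaler.transform(X_te))[:, 1]
        n_after = len(ys_tr)
    elif pipeline == "tl+lr":
        if source is None:
            raise ValueError("tl+lr pipeline requires a trained source model")
        Xs_tr = source.scaler.transform(X_tr)
        # inner CV oversamples its own training folds; the head is fit on
        # the real training activations with class weighting — interpolating
        # synthetic points in input space and mapping them through the
        # nonlinear network would misplace the minority class in activation
        # space and bias the head against the risk class
        target = fine_tune_target(source, Xs_tr, y_tr, hyperparams=hyperparams, seed=seed)
        F_tr = extract_features(target, Xs_tr)
        head = fit_lr_head(F_tr, y_tr, C=1.0, class_weight="balanced")
        clf_out = TLClassifier(source=source, target=target, head=head)
        _, p_te = clf_out.predict(X_te)
        n_after = len(y_tr)
    else:
        raise ValueError(f"unknown pipeline {pipeline!r}")

    pred = (p_te >= 0.5).astype(int)
    report = compute_metrics(confusion_from_predictions(y_te, pred))
    report.roc_auc = roc_auc(p_te, y_te)
    info = SplitInfo(
        train_index=tr_idx, test_index=te_idx, n_train_after_smote=n_after, pipeline=pipeline
    )
    return report, info, clf_out
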