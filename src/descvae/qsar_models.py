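"""Downstream property models under tenfold cross-validation.

Three model families operate on molecular embeddings (or fingerprint
baselines): ordinary linear regression (logistic regression for
classification), a multilayer perceptron, and a 1D residual network
that treats the d-dimensional embedding as a length-d single-channel
sequence.  Folds are a seeded partition, stratified by class for
classification; every molecule's prediction comes from the fold where
it was held out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.neural_network import MLPClassifier, MLPRegressor
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from . import nn
from .chem_data import MoleculeDataset, TaskType

__all__ = [
    "ModelSpec",
    "CVResult",
    "run_cv",
    "make_folds",
    "metric_r2",
    "metric_rmse",
    "metric_accuracy_f1",
    "build_baseline_fingerprint",
]


@dataclass
class ModelSpec:
    """family: 'linear' | 'mlp' | 'resnet1d'; hyperparameters are
    family-specific and all have CPU-friendly defaults."""

    family: str = "linear"
    task_type: TaskType = TaskType.REGRESSION
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.family = self.family.lower()
        if self.family not in ("linear", "mlp", "resnet1d"):
            raise ValueError(f"unknown model family {self.family!r}")
        self.task_type = TaskType(self.task_type)


@dataclass
class CVResult:
    fold_assignment: np.ndarray
    predictions: np.ndarray
    per_fold_metrics: list[dict[str, float]]
    aggregate: dict[str, tuple[float, float]]
    spec: ModelSpec | None = None

    @property
    def n_folds(self) -> int:
        return len(self.per_fold_metrics)


# ---- metrics -----------------------------------------------------------

def metric_r2(y: np.ndarray, pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if y.shape != pred.shape or y.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant y: R^2 undefined")
    ss_res = float(np.sum((y - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def metric_rmse(y: np.ndarray, pred: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if y.shape != pred.shape or y.size < 1:
        raise ValueError("need two aligned non-empty vectors")
    return float(np.sqrt(np.mean((y - pred) ** 2)))


def metric_accuracy_f1(y: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """Accuracy and positive-class F1 (0 when precision+recall = 0)."""
    y = np.asarray(y)
    pred = np.asarray(pred)
    if y.shape != pred.shape:
        raise ValueError("length mismatch")
    for v in (y, pred):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be binary")
    acc = float(np.mean(y == pred))
    tp = float(np.sum((pred == 1) & (y == 1)))
    fp = float(np.sum((pred == 1) & (y == 0)))
    fn = float(np.sum((pred == 0) & (y == 1)))
    if tp == 0:
        return acc, 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return acc, 2 * precision * recall / (precision + recall)


# ---- folds -------------------------------------------------------------

def make_folds(n: int, n_folds: int, seed: int,
               y: np.ndarray | None = None, stratify: bool = False) -> np.ndarray:
    """Seeded fold assignment, sizes differing by at most one.

    With ``stratify``, each class is shuffled and dealt round-robin so
    folds have near-equal class balance.
    """
    if n < n_folds:
        raise ValueError(f"n={n} < n_folds={n_folds}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratify and y is not None:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            assignment[idx] = np.arange(len(idx)) % n_folds
    else:
        order = rng.permutation(n)
        sizes = np.full(n_folds, n // n_folds)
        sizes[: n % n_folds] += 1
        fold_ids = np.repeat(np.arange(n_folds), sizes)
        assignment[order] = fold_ids
    return assignment


# ---- the 1D residual network ------------------------------------------

class _ResNet1D:
    """Stem conv -> B pre-activation residual blocks -> global average
    pooling -> linear head, over the embedding read as a 1-channel
    sequence."""

    def __init__(self, d: int, n_blocks: int, channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        self.stem = nn.Conv1D(1, channels, kernel, rng, activation="relu")
        self.blocks = [
            (nn.Conv1D(channels, channels, kernel, rng, activation="relu"),
             nn.Conv1D(channels, channels, kernel, rng))
            for _ in range(n_blocks)
        ]
        self.head = nn.Dense(channels, 1, rng)

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = [self.stem]
        for a, b in self.blocks:
            out += [a, b]
        out.append(self.head)
        return out

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = self.stem.forward(X[:, :, None])
        for a, b in self.blocks:
            h = h + b.forward(a.forward(h))
        self._T = h.shape[1]
        pooled = h.mean(axis=1)
        return self.head.forward(pooled)[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        dpooled = self.head.backward(dout[:, None])
        dh = np.repeat(dpooled[:, None, :], self._T, axis=1) / self._T
        for a, b in reversed(self.blocks):
            dh = dh + a.backward(b.backward(dh))
        self.stem.backward(dh)


def _fit_predict_resnet(X_tr, y_tr, X_te, task_type: TaskType,
                        hp: dict[str, Any], seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n_blocks = hp.get("n_blocks", 4)
    channels = hp.get("channels", 32)
    kernel = hp.get("kernel", 5)
    epochs = hp.get("epochs", 60)
    batch = hp.get("batch_size", 32)
    lr = hp.get("learning_rate", 1e-3)

    mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
    sd[sd == 0] = 1.0
    X_tr = (X_tr - mu) / sd
    X_te = (X_te - mu) / sd
    y_tr = np.asarray(y_tr, dtype=float)
    if task_type is TaskType.REGRESSION:
        ym, ys = y_tr.mean(), y_tr.std() or 1.0
        y_fit = (y_tr - ym) / ys
    else:
        y_fit = y_tr

    net = _ResNet1D(X_tr.shape[1], n_blocks, channels, kernel, rng)
    opt = nn.Adam(net.layers(), lr=lr)
    n = len(y_fit)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            opt.zero_grad()
            out = net.forward(X_tr[idx])
            if task_type is TaskType.REGRESSION:
                resid = out - y_fit[idx]
                dout = 2.0 * resid / len(idx)
            else:
                p = 1.0 / (1.0 + np.exp(-out))
                dout = (p - y_fit[idx]) / len(idx)
            net.backward(dout)
            opt.step()
    out = net.forward(X_te)
    if task_type is TaskType.REGRESSION:
        return out * ys + ym
    return (out > 0).astype(int)


def _fit_predict(spec: ModelSpec, X_tr, y_tr, X_te, seed: int) -> np.ndarray:
    hp = spec.hyperparameters
    if spec.family == "linear":
        if spec.task_type is TaskType.REGRESSION:
            model = LinearRegression()
            model.fit(X_tr, y_tr)
            return model.predict(X_te)
        model = LogisticRegression(max_iter=hp.get("max_iter", 2000))
        model.fit(X_tr, y_tr.astype(int))
        return model.predict(X_te)
    if spec.family == "mlp":
        kwargs = dict(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (64, 64)),
            max_iter=hp.get("max_iter", 500),
            random_state=seed,
        )
        if spec.task_type is TaskType.REGRESSION:
            model = MLPRegressor(**kwargs)
            model.fit(X_tr, y_tr)
            return model.predict(X_te)
        model = MLPClassifier(**kwargs)
        model.fit(X_tr, y_tr.astype(int))
        return model.predict(X_te)
    return _fit_predict_resnet(X_tr, y_tr, X_te, spec.task_type, hp, seed)


def run_cv(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
           n_folds: int = 10, seed: int = 0) -> CVResult:
    """Tenfold (by default) cross-validation.

    Each fold's model sees only the other folds; the prediction vector
    is assembled from held-out folds so every molecule is predicted by
    a model that never saw its label.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature matrix")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    stratify = spec.task_type is TaskType.CLASSIFICATION
    assignment = make_folds(len(y), n_folds, seed, y=y, stratify=stratify)

    predictions = np.empty(len(y))
    per_fold: list[dict[str, float]] = []
    for f in range(n_folds):
        test = assignment == f
        pred = _fit_predict(spec, X[~test], y[~test], X[test], seed + f)
        predictions[test] = pred
        if spec.task_type is TaskType.REGRESSION:
            per_fold.append({
                "r2": metric_r2(y[test], pred),
                "rmse": metric_rmse(y[test], pred),
            })
        else:
            acc, f1 = metric_accuracy_f1(y[test].astype(int), pred.astype(int))
            per_fold.append({"accuracy": acc, "f1": f1})

    aggregate = {
        m: (float(np.mean([pf[m] for pf in per_fold])),
            float(np.std([pf[m] for pf in per_fold], ddof=1)))
        for m in per_fold[0]
    }
    return CVResult(fold_assignment=assignment, predictions=predictions,
                    per_fold_metrics=per_fold, aggregate=aggregate, spec=spec)


def build_baseline_fingerprint(dataset: MoleculeDataset, n_bits: int = 1024,
                               radius: int = 2) -> np.ndarray:
    """Morgan (ECFP-style, radius 2 = diameter 4) bit fingerprints."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = np.zeros((len(dataset), n_bits), dtype=np.uint8)
    for i, rec in enumerate(dataset.records):
        mol = Chem.MolFromSmiles(rec.canonical_smiles)
        fp = gen.GetFingerprint(mol)
        rows[i, list(fp.GetOnBits())] = 1
    return rows
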