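"""Least-squares SVM with RBF kernel: training, grid search, CV scoring.

A binary machine solves the single linear (KKT) system (Suykens' dual)

    [ 0   y^T          ] [ b     ]   [ 0 ]
    [ y   Omega + I/g  ] [ alpha ] = [ 1 ]

with Omega_ij = y_i * y_j * K(x_i, x_j) and K(x, y) = exp(-||x - y||^2 / s2);
the decision value is f(x) = sum_i alpha_i * y_i * K(x_i, x) + b.
Multiclass classification is one-vs-rest with argmax of decision values.
Hyperparameters (s2, g) = (10^a, 10^b) are chosen by stratified k-fold
cross-validated grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .exceptions import (
    ConfigError,
    DegenerateInputError,
    NumericalError,
    StratificationError,
    ValidationError,
)
from .redundancy import FeatureSubset

__all__ = [
    "LSSVMBinary",
    "LSSVMMulticlass",
    "GridSearchReport",
    "SubsetEvaluation",
    "rbf_kernel",
    "kernel_matrix",
    "train_binary",
    "train_multiclass",
    "default_grid",
    "cross_val_accuracy",
    "grid_search",
    "evaluate_subset",
]


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma2: float) -> float:
    """Gaussian kernel exp(-||x - y||^2 / sigma2)."""
    if sigma2 <= 0:
        raise ConfigError("sigma2 must be > 0")
    d2 = float(np.sum((np.asarray(x, float) - np.asarray(y, float)) ** 2))
    return float(np.exp(-d2 / sigma2))


def kernel_matrix(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    if sigma2 <= 0:
        raise ConfigError("sigma2 must be > 0")
    return np.exp(-cdist(np.asarray(A, float), np.asarray(B, float), "sqeuclidean") / sigma2)


@dataclass
class LSSVMBinary:
    X: np.ndarray
    y: np.ndarray  # labels in {-1, +1}
    sigma2: float
    gamma: float
    alpha: np.ndarray
    b: float

    def decision_values(self, Xnew: np.ndarray) -> np.ndarray:
        K = kernel_matrix(np.asarray(Xnew, float), self.X, self.sigma2)
        return K @ (self.alpha * self.y) + self.b

    def kkt_residual(self) -> float:
        """Infinity norm of the KKT system residual (should be ~0)."""
        K = kernel_matrix(self.X, self.X, self.sigma2)
        omega = np.outer(self.y, self.y) * K
        n = len(self.y)
        top = float(self.y @ self.alpha)
        rows = self.y * self.b + (omega + np.eye(n) / self.gamma) @ self.alpha - 1.0
        return max(abs(top), float(np.max(np.abs(rows))))


def _fit_from_kernel(K: np.ndarray, y: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    n = len(y)
    omega = np.outer(y, y) * K
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = omega + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], np.ones(n)))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        cond = np.linalg.cond(A)
        raise NumericalError(f"singular LSSVM system (cond ~ {cond:.3e})") from None
    return float(sol[0]), sol[1:]


def train_binary(X: np.ndarray, y: np.ndarray, sigma2: float, gamma: float) -> LSSVMBinary:
    """Train one binary machine; labels must be in {-1, +1} with both present."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[0] < 2:
        raise ValidationError("need >= 2 samples with matching labels")
    if not set(np.unique(y)) <= {-1.0, 1.0} or len(np.unique(y)) < 2:
        raise ValidationError("labels must be {-1, +1} with both classes present")
    if gamma <= 0:
        raise ConfigError("gamma must be > 0")
    K = kernel_matrix(X, X, sigma2)
    b, alpha = _fit_from_kernel(K, y, gamma)
    return LSSVMBinary(X=X, y=y, sigma2=sigma2, gamma=gamma, alpha=alpha, b=b)


@dataclass
class LSSVMMulticlass:
    classes: np.ndarray
    machines: list[LSSVMBinary]
    sigma2: float
    gamma: float

    def decision_matrix(self, Xnew: np.ndarray) -> np.ndarray:
        return np.column_stack([m.decision_values(Xnew) for m in self.machines])

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        scores = self.decision_matrix(Xnew)
        return self.classes[np.argmax(scores, axis=1)]  # ties -> smallest class


def train_multiclass(
    X: np.ndarray, labels: np.ndarray, sigma2: float, gamma: float
) -> LSSVMMulticlass:
    """One-vs-rest multiclass LSSVM; predicts by argmax of decision values."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DegenerateInputError("multiclass training needs >= 2 classes")
    machines = []
    for c in classes:
        y = np.where(labels == c, 1.0, -1.0)
        machines.append(train_binary(X, y, sigma2, gamma))
    return LSSVMMulticlass(classes=classes, machines=machines, sigma2=sigma2, gamma=gamma)


def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """Default exponent grid: 24 levels for a (sigma2 = 10^a, from -1 step
    0.25) and 25 levels for b (gamma = 10^b, from -1 step 0.2) = 600 pairs."""
    a = -1.0 + 0.25 * np.arange(24)
    b = -1.0 + 0.2 * np.arange(25)
    return a, b


@dataclass
class GridSearchReport:
    a_values: np.ndarray
    b_values: np.ndarray
    mean_acc: np.ndarray  # (len(a), len(b))
    sd_acc: np.ndarray
    fold_acc: np.ndarray  # (len(a), len(b), folds)
    best_a: float
    best_b: float
    seed: int
    folds: int

    @property
    def best_sigma2(self) -> float:
        return float(10.0**self.best_a)

    @property
    def best_gamma(self) -> float:
        return float(10.0**self.best_b)

    @property
    def n_cells(self) -> int:
        return len(self.a_values) * len(self.b_values)

    @property
    def best_mean_acc(self) -> float:
        i = list(self.a_values).index(self.best_a)
        j = list(self.b_values).index(self.best_b)
        return float(self.mean_acc[i, j])

    @property
    def best_sd_acc(self) -> float:
        i = list(self.a_values).index(self.best_a)
        j = list(self.b_values).index(self.best_b)
        return float(self.sd_acc[i, j])


def _stratified_splits(labels: np.ndarray, folds: int, seed: int):
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class has {counts.min()} samples, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def cross_val_accuracy(
    X: np.ndarray,
    labels: np.ndarray,
    sigma2: float,
    gamma: float,
    folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Per-fold accuracies of a multiclass LSSVM under stratified k-fold CV."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    accs = []
    for tr, va in _stratified_splits(labels, folds, seed):
        model = train_multiclass(X[tr], labels[tr], sigma2, gamma)
        accs.append(float(np.mean(model.predict(X[va]) == labels[va])))
    return np.array(accs)


def grid_search(
    X: np.ndarray,
    labels: np.ndarray,
    a_values: np.ndarray | None = None,
    b_values: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
) -> GridSearchReport:
    """Cross-validated accuracy over the (a, b) exponent grid.

    Best cell maximizes mean CV accuracy; ties resolve to smaller a, then
    smaller b.  Fold assignment is deterministic given ``seed``.
    """
    if a_values is None or b_values is None:
        da, db = default_grid()
        a_values = da if a_values is None else np.asarray(a_values, float)
        b_values = db if b_values is None else np.asarray(b_values, float)
    a_values = np.asarray(a_values, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if folds < 2:
        raise ConfigError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    splits = _stratified_splits(labels, folds, seed)
    classes = np.unique(labels)

    # squared distances are shared across the grid; only the kernel width varies
    fold_data = []
    for tr, va in splits:
        d_tr = cdist(X[tr], X[tr], "sqeuclidean")
        d_va = cdist(X[va], X[tr], "sqeuclidean")
        fold_data.append((tr, va, d_tr, d_va))

    fold_acc = np.zeros((len(a_values), len(b_values), folds))
    for i, a in enumerate(a_values):
        sigma2 = 10.0**a
        for f, (tr, va, d_tr, d_va) in enumerate(fold_data):
            K_tr = np.exp(-d_tr / sigma2)
            K_va = np.exp(-d_va / sigma2)
            for j, b in enumerate(b_values):
                gamma = 10.0**b
                scores = np.empty((len(va), len(classes)))
                for ci, c in enumerate(classes):
                    y = np.where(labels[tr] == c, 1.0, -1.0)
                    bias, alpha = _fit_from_kernel(K_tr, y, gamma)
                    scores[:, ci] = K_va @ (alpha * y) + bias
                pred = classes[np.argmax(scores, axis=1)]
                fold_acc[i, j, f] = float(np.mean(pred == labels[va]))

    mean_acc = fold_acc.mean(axis=2)
    sd_acc = fold_acc.std(axis=2, ddof=1) if folds > 1 else np.zeros_like(mean_acc)
    flat_best = int(np.argmax(mean_acc))  # row-major: first max -> smaller a then b
    bi, bj = np.unravel_index(flat_best, mean_acc.shape)
    return GridSearchReport(
        a_values=a_values,
        b_values=b_values,
        mean_acc=mean_acc,
        sd_acc=sd_acc,
        fold_acc=fold_acc,
        best_a=float(a_values[bi]),
        best_b=float(b_values[bj]),
        seed=seed,
        folds=folds,
    )


@dataclass
class SubsetEvaluation:
    """Train-CV and held-out accuracies of a feature subset."""

    cv_mean: float
    cv_sd: float
    fold_accuracies: np.ndarray
    test_accuracy: float | None
    report: GridSearchReport
    n_features: int


def evaluate_subset(
    train_ds,
    test_ds,
    subset: FeatureSubset,
    a_values: np.ndarray | None = None,
    b_values: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
) -> SubsetEvaluation:
    """Grid-search a model on the subset-projected training set and score it.

    Mixed features are recomputed on each dataset from the subset's stored
    group definitions.  Reports the best cell's CV mean +/- sd and, when a
    test set is given, held-out accuracy of the model refit on all training
    samples at the best hyperparameters.
    """
    Xtr = subset.transform(train_ds)
    report = grid_search(Xtr, train_ds.stage, a_values, b_values, folds=folds, seed=seed)
    test_accuracy = None
    if test_ds is not None:
        Xte = subset.transform(test_ds)
        model = train_multiclass(Xtr, train_ds.stage, report.best_sigma2, report.best_gamma)
        test_accuracy = float(np.mean(model.predict(Xte) == test_ds.stage))
    i = list(report.a_values).index(report.best_a)
    j = list(report.b_values).index(report.best_b)
    return SubsetEvaluation(
        cv_mean=report.best_mean_acc,
        cv_sd=report.best_sd_acc,
        fold_accuracies=report.fold_acc[i, j],
        test_accuracy=test_accuracy,
        report=report,
        n_features=Xtr.shape[1],
    )
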