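"""Multilayer-perceptron fingerprint classifier with a reject option.

The classifier is a feedforward network with a single hidden layer
(three nodes by default), logistic sigmoid activations on both layers,
trained by full-gradient backpropagation on one-hot targets with a
sum-of-squares loss (reported as root-mean-squared error), a momentum
term, and a cap of 50,000 iterations.  Predictions use a confidence
rule with level alpha (default 0.05): a sample is assigned to class c
only when the c-th output activation is at least ``1 - alpha`` and
every other activation is at most ``alpha``; anything else is reported
as UNKNOWN.  In the success percentage UNKNOWN counts as an error.

Model verification is leave-one-out cross-validation: for each sample
the variance filter, the Z-scaling, and the network are refit on the
remaining n-1 samples, and the held-out sample is transformed with the
training-fold parameters before prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .features import FeatureMatrix, apply_z_scale, variance_filter, z_scale

__all__ = ["MLPConfig", "MLPModel", "CVResult", "UNKNOWN",
           "train", "predict_with_confidence", "loocv", "classification_report",
           "loss_and_grad", "fold_seed"]

UNKNOWN = "UNKNOWN"


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class MLPConfig:
    """Hyperparameters of the perceptron.

    Defaults follow the fingerprinting protocol: 3 hidden nodes, at
    most 50,000 training iterations, confidence level 0.05.  Learning
    rate, momentum, initialization range and the stopping tolerance are
    implementation choices exposed here.
    """

    n_hidden: int = 3
    max_epochs: int = 50_000
    learning_rate: float = 0.1
    momentum: float = 0.9
    confidence_level: float = 0.05
    init_scale: float = 0.5
    tol: float = 1e-7          # mean per-epoch RMSE improvement below which training stops
    check_every: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_hidden < 1 or self.max_epochs < 1:
            raise ValueError("n_hidden and max_epochs must be >= 1")
        if not (0.0 < self.confidence_level < 0.5):
            raise ValueError("confidence_level must be in (0, 0.5)")
        if self.learning_rate <= 0 or not (0.0 <= self.momentum < 1.0):
            raise ValueError("invalid learning_rate/momentum")


@dataclass
class MLPModel:
    """Trained weights: input->hidden (W1, b1) and hidden->output (W2, b2)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    classes: list[str]
    config: MLPConfig
    history: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_epochs: int = 0

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.W1.shape[0]:
            raise ValueError(f"expected {self.W1.shape[0]} inputs, got {X.shape[1]}")
        H = _sigmoid(X @ self.W1 + self.b1)
        return _sigmoid(H @ self.W2 + self.b2)


@dataclass
class CVResult:
    """Leave-one-out predictions and the headline success percentage."""

    sample_ids: list[str]
    true_labels: list[str]
    predicted: list[str]               # class label or UNKNOWN
    classes: list[str]
    feature_counts: list[int] = field(default_factory=list)  # per-fold selected features

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_correct(self) -> int:
        return sum(p == t for p, t in zip(self.predicted, self.true_labels))

    @property
    def n_unknown(self) -> int:
        return sum(p == UNKNOWN for p in self.predicted)

    @property
    def success_percentage(self) -> float:
        """% correct; UNKNOWN predictions count as errors."""
        return 100.0 * self.n_correct / self.n if self.n else 0.0

    def confusion(self) -> pd.DataFrame:
        cols = self.classes + [UNKNOWN]
        tab = pd.DataFrame(0, index=self.classes, columns=cols)
        for t, p in zip(self.true_labels, self.predicted):
            tab.loc[t, p] += 1
        return tab


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def loss_and_grad(params: tuple[np.ndarray, ...], X: np.ndarray, T: np.ndarray):
    """Sum-of-squares loss (mean over samples) and its analytic gradient.

    Returns ``(loss, (gW1, gb1, gW2, gb2))``.  Shared by the training
    loop and the finite-difference gradient check.
    """
    W1, b1, W2, b2 = params
    n = X.shape[0]
    H = _sigmoid(X @ W1 + b1)
    O = _sigmoid(H @ W2 + b2)
    E = O - T
    loss = 0.5 * float(np.sum(E * E)) / n
    d2 = (E * O * (1.0 - O)) / n
    gW2 = H.T @ d2
    gb2 = d2.sum(axis=0)
    d1 = (d2 @ W2.T) * H * (1.0 - H)
    gW1 = X.T @ d1
    gb1 = d1.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


@njit(cache=True, fastmath=True)
def _train_loop(X, T, W1, b1, W2, b2, lr, mom, max_epochs, tol, check_every):
    """Compiled batch-gradient-descent loop; same math as loss_and_grad."""
    n = X.shape[0]
    k = T.shape[1]
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)
    history = np.empty(max_epochs)
    last_check = np.inf
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        H = 1.0 / (1.0 + np.exp(-(np.dot(X, W1) + b1.reshape(1, -1))))
        O = 1.0 / (1.0 + np.exp(-(np.dot(H, W2) + b2.reshape(1, -1))))
        E = O - T
        sse = np.sum(E * E)
        if not np.isfinite(sse):
            return history, epoch, False
        rmse = np.sqrt(sse / (n * k))
        history[epoch - 1] = rmse
        d2 = (E * O * (1.0 - O)) / n
        gW2 = np.dot(H.T, d2)
        gb2 = np.sum(d2, axis=0)
        d1 = np.dot(d2, W2.T) * H * (1.0 - H)
        gW1 = np.dot(X.T, d1)
        gb1 = np.sum(d1, axis=0)
        vW1 = mom * vW1 - lr * gW1
        vb1 = mom * vb1 - lr * gb1
        vW2 = mom * vW2 - lr * gW2
        vb2 = mom * vb2 - lr * gb2
        W1 += vW1
        b1 += vb1
        W2 += vW2
        b2 += vb2
        if epoch % check_every == 0:
            if (last_check - rmse) < tol * check_every:
                break
            last_check = rmse
    return history, epoch, True


def train(config: MLPConfig, X: FeatureMatrix | np.ndarray, y=None) -> MLPModel:
    """Backpropagation training on one-hot targets.

    Accepts either a z_scaled :class:`FeatureMatrix` (labels taken from
    it) or a plain array plus `y`.  Deterministic given ``config.seed``.
    Stops at ``max_epochs`` or when the RMSE improvement per epoch,
    averaged over the last ``check_every`` epochs, falls below ``tol``.
    """
    config.validate()
    if isinstance(X, FeatureMatrix):
        if X.scaling_state != "z_scaled":
            raise ValueError("train expects a z_scaled matrix")
        data, labels = X.values, list(X.labels)
    else:
        data, labels = np.asarray(X, float), list(y)
    if np.any(~np.isfinite(data)):
        raise ValueError("missing values in training data")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training needs at least 2 classes")
    idx = {c: j for j, c in enumerate(classes)}
    T = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        T[i, idx[lab]] = 1.0

    rng = np.random.default_rng(config.seed)
    d, h, k = data.shape[1], config.n_hidden, len(classes)
    W1 = rng.uniform(-config.init_scale, config.init_scale, (d, h))
    b1 = rng.uniform(-config.init_scale, config.init_scale, h)
    W2 = rng.uniform(-config.init_scale, config.init_scale, (h, k))
    b2 = rng.uniform(-config.init_scale, config.init_scale, k)
    data = np.ascontiguousarray(data)
    history, epoch, ok = _train_loop(
        data, T, W1, b1, W2, b2, config.learning_rate, config.momentum,
        config.max_epochs, config.tol, config.check_every)
    if not ok:
        raise DivergenceError("training loss diverged; lower the learning rate")
    return MLPModel(W1=W1, b1=b1, W2=W2, b2=b2, classes=classes, config=config,
                    history=history[:epoch].copy(), n_epochs=epoch)


def predict_with_confidence(model: MLPModel, x: np.ndarray,
                            confidence_level: float | None = None) -> str:
    """Confidence-thresholded class assignment.

    With activations ``a`` and level ``alpha``: assign class c iff
    ``a_c >= 1 - alpha`` and every other activation ``<= alpha``;
    otherwise return UNKNOWN.
    """
    alpha = model.config.confidence_level if confidence_level is None else confidence_level
    a = model.forward(np.asarray(x, float).reshape(1, -1))[0]
    accept = a >= 1.0 - alpha
    if accept.sum() != 1:
        return UNKNOWN
    c = int(np.argmax(a))
    others = np.delete(a, c)
    if np.any(others > alpha):
        return UNKNOWN
    return model.classes[c]


def fold_seed(master_seed: int, fold: int) -> int:
    """Deterministic per-fold seed derived from the master seed."""
    return int(np.random.SeedSequence([int(master_seed), int(fold)])
               .generate_state(1)[0] % (2 ** 31))


def loocv(matrix: FeatureMatrix, config: MLPConfig,
          variance_threshold: float = 1.0, global_prep: bool = False) -> CVResult:
    """Leave-one-out cross-validation on a raw-scale feature matrix.

    For every fold the variance filter and Z-scaling are refit on the
    n-1 training samples (``global_prep=True`` instead fits them once on
    the full matrix, the leakage-prone shortcut some legacy software
    applies), the network is trained with a fold-specific seed derived
    from ``config.seed``, and the held-out sample is predicted under the
    confidence rule.
    """
    if matrix.scaling_state != "raw":
        raise ValueError("loocv expects the raw-scale matrix (it scales per fold)")
    n = matrix.n_samples
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    counts = pd.Series(matrix.labels).value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"class(es) {bad} have a single member; a fold would lose them")

    if global_prep:
        filtered_all = variance_filter(matrix, variance_threshold)
        scaled_all = z_scale(filtered_all)

    preds, fcounts = [], []
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        if global_prep:
            train_m = FeatureMatrix(scaled_all.values[keep], list(scaled_all.feature_ids),
                                    [scaled_all.sample_ids[j] for j in range(n) if keep[j]],
                                    [scaled_all.labels[j] for j in range(n) if keep[j]],
                                    "z_scaled")
            x_test = scaled_all.values[i]
        else:
            fold_raw = FeatureMatrix(matrix.values[keep], list(matrix.feature_ids),
                                     [matrix.sample_ids[j] for j in range(n) if keep[j]],
                                     [matrix.labels[j] for j in range(n) if keep[j]],
                                     "raw")
            filtered = variance_filter(fold_raw, variance_threshold)
            train_m = z_scale(filtered)
            col_idx = [matrix.feature_ids.index(f) for f in filtered.feature_ids]
            x_test = apply_z_scale(matrix.values[i, col_idx], train_m.scaler)
        cfg = MLPConfig(**{**config.__dict__, "seed": fold_seed(config.seed, i)})
        model = train(cfg, train_m)
        preds.append(predict_with_confidence(model, x_test))
        fcounts.append(train_m.n_features)
    return CVResult(sample_ids=list(matrix.sample_ids), true_labels=list(matrix.labels),
                    predicted=preds, classes=sorted(set(matrix.labels)),
                    feature_counts=fcounts)


def classification_report(cv: CVResult) -> tuple[str, pd.DataFrame]:
    """Human-readable summary plus the confusion table (with UNKNOWN column)."""
    tab = cv.confusion()
    pct = round(cv.success_percentage)
    lines = [f"LOOCV success: {pct}% ({cv.n_correct}/{cv.n} correct, "
             f"{cv.n_unknown} unknown)"]
    for c in cv.classes:
        n_c = sum(t == c for t in cv.true_labels)
        ok = int(tab.loc[c, c])
        lines.append(f"  {c}: {ok}/{n_c} correct")
    return "\n".join(lines), tab
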