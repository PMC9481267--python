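"""Fold-local feature selection and L1-penalised logistic regression.

Within every cross-validation fold (and only there — nothing from the
held-out subject enters):

1. features are ranked by the one-way ANOVA F statistic between the two
   outcome classes;
2. a small grid of candidate set sizes k in {5, 10, 15, 20, 25} is
   scored by the training-set AUC of an L1 logistic model on the top-k
   features, and the best k wins (ties -> smallest k);
3. the final model is an L1-penalised logistic regression (liblinear,
   C = 1, at most 100 iterations) on fold-standardised features, whose
   zero coefficients act as a second selection stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = (5, 10, 15, 20, 25)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    C: float = 1.0          # inverse L1 penalty strength
    max_iter: int = 100
    tol: float = 1e-4
    random_state: int = 0   # liblinear tie-breaking; fixed for determinism


@dataclass
class SelectionResult:
    k_best: int
    selected: list[str]      # ordered by descending univariate score
    scores: np.ndarray       # score per input feature (input order)
    train_aucs: dict = field(default_factory=dict)  # k -> train AUC


@dataclass
class TrainedModel:
    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    means: np.ndarray   # training-fold standardisation
    sds: np.ndarray
    config: ModelConfig

    @property
    def nonzero_features(self) -> list[str]:
        return [f for f, w in zip(self.feature_names, self.weights) if w != 0.0]


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ModelError("both outcome classes must be present")


def rank_features(X: np.ndarray, y: np.ndarray,
                  names: list[str]) -> tuple[list[str], np.ndarray]:
    """ANOVA-F ranking of features; returns (names in descending score
    order, scores in input order).  Constant features score 0 and sink
    to the bottom; order among equal scores follows the input order."""
    y = np.asarray(y)
    _check_two_classes(y)
    X = np.asarray(X, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features emit RuntimeWarnings
        scores, _ = f_classif(X, y)
    # constant features carry no information (their 0/0 F statistic is
    # implementation-defined); perfectly separating features keep a
    # largest-finite score
    scores = np.nan_to_num(scores, nan=0.0, posinf=np.finfo(float).max)
    scores[X.std(axis=0) == 0] = 0.0
    order = np.argsort(-scores, kind="stable")
    return [names[i] for i in order], scores


def train_l1_logistic(X: np.ndarray, y: np.ndarray, names: list[str],
                      config: ModelConfig = ModelConfig()) -> TrainedModel:
    """Fit L1 logistic regression on z-scored features (training statistics)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise ModelError("need at least 2 training rows")
    _check_two_classes(y)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / sds
    clf = LogisticRegression(
        penalty="l1", C=config.C, solver="liblinear",
        max_iter=config.max_iter, tol=config.tol,
        random_state=config.random_state,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(Z, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        logger.warning("liblinear stopped at max_iter=%d without convergence",
                       config.max_iter)
    return TrainedModel(list(names), clf.coef_.ravel().copy(),
                        float(clf.intercept_[0]), means, sds, config)


def predict_probability(model: TrainedModel, row: np.ndarray) -> float:
    """Injury probability: sigmoid of the standardised linear predictor."""
    row = np.asarray(row, dtype=float)
    if row.shape[-1] != len(model.feature_names):
        raise ModelError(
            f"row has {row.shape[-1]} features, model expects "
            f"{len(model.feature_names)}")
    z = (row - model.means) / model.sds
    eta = float(z @ model.weights + model.intercept)
    return float(1.0 / (1.0 + np.exp(-eta)))


def select_k(X: np.ndarray, y: np.ndarray, names: list[str],
             config: ModelConfig = ModelConfig()) -> SelectionResult:
    """Pick the feature-set size from ``config.k_grid`` maximising the
    training AUC of the L1 model on the top-k ANOVA-ranked features."""
    if not config.k_grid:
        raise ModelError("empty k grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ordered, scores = rank_features(X, y, names)
    n_features = len(names)
    name_to_col = {n: i for i, n in enumerate(names)}

    grid = sorted(set(min(k, n_features) for k in config.k_grid))
    if max(config.k_grid) > n_features:
        logger.info("k grid clamped to %d available features", n_features)

    best_k, best_auc, aucs = None, -np.inf, {}
    for k in grid:
        cols = [name_to_col[n] for n in ordered[:k]]
        m = train_l1_logistic(X[:, cols], y, ordered[:k], config)
        Z = (X[:, cols] - m.means) / m.sds
        p = 1.0 / (1.0 + np.exp(-(Z @ m.weights + m.intercept)))
        auc = roc_auc_score(y, p)
        aucs[k] = float(auc)
        if auc > best_auc:
            best_auc, best_k = auc, k
    return SelectionResult(best_k, ordered[:best_k], scores, aucs)


def fit_fold(
    X_train: np.ndarray, y_train: np.ndarray, names: list[str],
    config: ModelConfig = ModelConfig(), fixed_k: int | None = None,
) -> tuple[TrainedModel, SelectionResult]:
    """Run the whole fold-local pipeline: rank -> (grid-)select -> fit.

    ``fixed_k`` bypasses the k grid and takes the top ``fixed_k`` ranked
    features directly (used by the group-exclusion analysis).
    """
    if fixed_k is not None:
        if fixed_k > len(names):
            raise ModelError(f"budget {fixed_k} exceeds {len(names)} features")
        ordered, scores = rank_features(X_train, y_train, names)
        sel = SelectionResult(fixed_k, ordered[:fixed_k], scores)
    else:
        sel = select_k(X_train, y_train, names, config)
    name_to_col = {n: i for i, n in enumerate(names)}
    cols = [name_to_col[n] for n in sel.selected]
    model = train_l1_logistic(X_train[:, cols], y_train, sel.selected, config)
    return model, sel
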