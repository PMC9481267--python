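"""Leave-one-subject-out evaluation and the two metrics (AUC, Brier).

With one held-out subject per fold, per-fold metrics are meaningless;
both metrics are computed once on the pooled out-of-fold probabilities.
The Brier score BS = (1/N) * sum_i (p_i - y_i)^2 measures calibration
(0 = perfect); the AUC is the probability that a random injured subject
receives a higher predicted risk than a random healthy one (ties count
one half).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .features import LABEL_COLUMN, feature_columns
from .model import ModelConfig, ModelError, fit_fold, predict_probability


class EvaluationError(ValueError):
    pass


def auc_score(labels, probabilities) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties = 1/2)."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.size != p.size:
        raise EvaluationError("labels and probabilities differ in length")
    if len(np.unique(y)) < 2:
        raise EvaluationError("AUC needs both classes")
    return float(roc_auc_score(y, p))


def brier_score(labels, probabilities) -> float:
    """Mean squared difference between predicted probability and outcome."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.size != p.size:
        raise EvaluationError("labels and probabilities differ in length")
    if np.any((p < 0) | (p > 1)):
        raise EvaluationError("probabilities must lie in [0, 1]")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise EvaluationError("labels must be binary 0/1")
    return float(np.mean((p - y) ** 2))


@dataclass
class FoldRecord:
    subject_id: str
    label: int
    probability: float
    k_best: int
    selected: list[str]
    nonzero: list[str]


@dataclass
class LoocvResult:
    """Out-of-fold predictions plus per-fold selection metadata."""

    records: list[FoldRecord]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([r.probability for r in self.records])

    @property
    def auc(self) -> float:
        return auc_score(self.labels, self.probabilities)

    @property
    def brier(self) -> float:
        return brier_score(self.labels, self.probabilities)

    @property
    def mean_k_best(self) -> float:
        return float(np.mean([r.k_best for r in self.records]))

    @property
    def mean_nonzero(self) -> float:
        return float(np.mean([len(r.nonzero) for r in self.records]))

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": [r.subject_id for r in self.records],
            "label": self.labels,
            "probability": self.probabilities,
        })

    def folds_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": [r.subject_id for r in self.records],
            "k_best": [r.k_best for r in self.records],
            "n_selected": [len(r.selected) for r in self.records],
            "n_nonzero": [len(r.nonzero) for r in self.records],
            "selected": [";".join(r.selected) for r in self.records],
            "nonzero": [";".join(r.nonzero) for r in self.records],
        })


def _impute_train_median(X_train: np.ndarray, X_test: np.ndarray,
                         nan_cols: np.ndarray) -> None:
    """In place: fill NaNs with the training-fold column median."""
    for j in np.flatnonzero(nan_cols):
        col = X_train[:, j]
        med = np.nanmedian(col)
        if np.isnan(med):
            med = 0.0
        col[np.isnan(col)] = med
        if np.isnan(X_test[j]):
            X_test[j] = med


def run_loocv(
    table: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    fixed_k: int | None = None,
    columns: list[str] | None = None,
) -> LoocvResult:
    """Leave-one-subject-out evaluation of the fold-local pipeline.

    ``table`` holds one row per subject: feature columns plus the binary
    ``injured`` label.  For each subject, ranking, k-selection,
    standardisation, imputation and fitting all use only the other
    N - 1 rows.  ``columns`` restricts the candidate features (used by
    the group-exclusion analysis); ``fixed_k`` bypasses the k grid.
    """
    names = columns if columns is not None else feature_columns(table)
    y_all = table[LABEL_COLUMN].to_numpy()
    counts = np.bincount(y_all.astype(int), minlength=2)
    if counts.min() < 2:
        raise EvaluationError(
            f"need at least 2 subjects per class, got healthy={counts[0]} "
            f"injured={counts[1]}")

    X_all = table[names].to_numpy(dtype=float)
    subject_ids = [str(s) for s in table.index]
    nan_cols = np.isnan(X_all).any(axis=0)

    records = []
    n = X_all.shape[0]
    idx = {f: j for j, f in enumerate(names)}
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[:] = True
        mask[i] = False
        X_train = X_all[mask].copy()
        X_test = X_all[i].copy()
        if nan_cols.any():
            _impute_train_median(X_train, X_test, nan_cols)
        model, sel = fit_fold(X_train, y_all[mask], names, config, fixed_k=fixed_k)
        p = predict_probability(model, X_test[[idx[f] for f in sel.selected]])
        records.append(FoldRecord(subject_ids[i], int(y_all[i]), p,
                                  sel.k_best, list(sel.selected),
                                  model.nonzero_features))
    return LoocvResult(records)
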