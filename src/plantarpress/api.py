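"""High-level modelling interface.

``OveruseInjuryModel`` wraps the whole estimation procedure the way
statistical modelling packages do: build the model from a subjects x
features table (or straight from a synthetic cohort configuration),
call :meth:`fit`, and read estimates and diagnostics off the returned
``OveruseInjuryResults``.

Example
-------
>>> from plantarpress import CohortConfig, OveruseInjuryModel
>>> model = OveruseInjuryModel.from_cohort(CohortConfig(n_subjects=40, seed=7))
>>> res = model.fit()
>>> print(res.summary())            # doctest: +SKIP
>>> res.auc, res.brier              # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort import CohortConfig, generate_cohort
from .evaluation import LoocvResult, run_loocv
from .features import LABEL_COLUMN, BankConfig, build_feature_table, feature_columns
from .importance import feature_budget, feature_occurrence, group_exclusion_analysis
from .model import ModelConfig
from .preprocessing import preprocess_cohort


class OveruseInjuryModel:
    """Leave-one-subject-out L1-logistic injury-risk model.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per subject; feature columns named
        ``zone|measurement|footwear|feature_id`` plus a binary
        ``injured`` column.
    config : ModelConfig, optional
        Selection grid, penalty and solver settings.
    """

    def __init__(self, table: pd.DataFrame,
                 config: ModelConfig | None = None) -> None:
        if LABEL_COLUMN not in table.columns:
            raise ValueError(f"table must contain a {LABEL_COLUMN!r} column")
        self.table = table
        self.config = config or ModelConfig()

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = LABEL_COLUMN,
                       config: ModelConfig | None = None) -> "OveruseInjuryModel":
        table = df.rename(columns={label_col: LABEL_COLUMN})
        return cls(table, config=config)

    @classmethod
    def from_cohort(
        cls,
        cohort_config: CohortConfig,
        bank: BankConfig | None = None,
        config: ModelConfig | None = None,
        n_bins: int = 256,
        pool_feet: bool = True,
    ) -> "OveruseInjuryModel":
        """Simulate a cohort, preprocess it and extract features in one go."""
        store, profiles, _ = generate_cohort(cohort_config)
        signal_sets, _ = preprocess_cohort(store, n_bins=n_bins,
                                           pool_feet=pool_feet)
        table = build_feature_table(signal_sets, profiles,
                                    bank or BankConfig())
        return cls(table, config=config)

    # -- estimation --------------------------------------------------------

    def fit(self) -> "OveruseInjuryResults":
        """Run leave-one-subject-out cross-validation with fold-local
        feature selection and return the pooled results."""
        loocv = run_loocv(self.table, self.config)
        return OveruseInjuryResults(self, loocv)


class OveruseInjuryResults:
    """Pooled LOOCV results: out-of-fold probabilities, the two metrics,
    per-fold selection diagnostics, and the importance analyses."""

    def __init__(self, model: OveruseInjuryModel, loocv: LoocvResult) -> None:
        self.model = model
        self.loocv = loocv

    # -- headline quantities ----------------------------------------------

    @property
    def auc(self) -> float:
        return self.loocv.auc

    @property
    def brier(self) -> float:
        return self.loocv.brier

    @property
    def nobs(self) -> int:
        return self.loocv.n

    @property
    def predictions(self) -> pd.DataFrame:
        return self.loocv.predictions_frame()

    @property
    def fold_summary(self) -> pd.DataFrame:
        return self.loocv.folds_frame()

    # -- diagnostics -------------------------------------------------------

    def feature_occurrence(self, threshold: float = 0.10) -> pd.DataFrame:
        """Features surviving both selection stages in >= ``threshold``
        of the folds (Table-4-style report)."""
        return feature_occurrence(self.loocv, threshold=threshold)

    def group_importance(self, budget: int | None = None) -> pd.DataFrame:
        """Group-exclusion impact table (Table-3-style report); budget
        defaults to the 10% rule."""
        impact, _ = group_exclusion_analysis(self.model.table,
                                             self.model.config, budget=budget)
        return impact

    def summary(self) -> str:
        y = self.loocv.labels
        occ = self.feature_occurrence(threshold=0.10)
        lines = [
            "Lower-extremity overuse injury risk model (LOOCV)",
            "=" * 58,
            f"Subjects:              {self.nobs}  "
            f"(healthy {int((y == 0).sum())}, injured {int((y == 1).sum())})",
            f"Candidate features:    {len(feature_columns(self.model.table))}",
            f"k grid:                {list(self.model.config.k_grid)}",
            f"L1 penalty C:          {self.model.config.C}",
            f"Pooled AUC:            {self.auc:.3f}",
            f"Pooled Brier score:    {self.brier:.3f}",
            f"Mean selected k/fold:  {self.loocv.mean_k_best:.1f}",
            f"Mean nonzero weights:  {self.loocv.mean_nonzero:.1f}",
            f"10%-rule budget:       {feature_budget(self.nobs)}",
            "-" * 58,
            "Features in >= 10% of folds (selection AND nonzero weight):",
        ]
        if len(occ):
            for r in occ.itertuples():
                lines.append(
                    f"  {r.foot_area:<13} {r.measurement:<14} {r.footwear:<9}"
                    f" {r.feature:<24} {r.occurrence_pct:5.1f}%")
        else:
            lines.append("  (none)")
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_roc(self, ax=None):
        """ROC curve of the pooled out-of-fold probabilities."""
        from sklearn.metrics import roc_curve
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr, tpr, _ = roc_curve(self.loocv.labels, self.loocv.probabilities)
        ax.plot(fpr, tpr, label=f"LOOCV (AUC = {self.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax
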