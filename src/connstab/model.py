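"""statsmodels-style front end: a model built from data, results from fit().

``ConnectomeClassifier`` wraps an :class:`~connstab.connectivity.EdgeTable`
and a :class:`~connstab.selection.PipelineParams`; ``fit()`` runs the
repeated nested cross-validation and returns a
:class:`ConnectomeCVResults` carrying per-fold records, aggregate metrics,
the pooled ROC, the stability report and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .connectivity import EdgeTable
from .evaluate import (
    CVResults,
    PermutationResult,
    aggregate,
    grid_search,
    permutation_test,
    run_repeated_cv,
)
from .report import StabilityReport, build_stability_report
from .selection import PipelineParams

__all__ = ["ConnectomeClassifier", "ConnectomeCVResults"]


class ConnectomeClassifier:
    """Two-group edge-wise classification model.

    Parameters
    ----------
    table : EdgeTable
        Subjects x edges features with 0/1 group labels.
    params : PipelineParams, optional
        Pipeline tunables; keyword overrides are applied on top.

    Examples
    --------
    >>> from connstab import SyntheticSpec, simulate_edge_table
    >>> table = simulate_edge_table(SyntheticSpec(seed=1))
    >>> model = ConnectomeClassifier(table, p0=0.01, repeats=2)
    >>> res = model.fit()
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(self, table: EdgeTable, params: PipelineParams | None = None, **overrides):
        if not isinstance(table, EdgeTable):
            raise TypeError("table must be an EdgeTable")
        self.table = table
        base = params if params is not None else PipelineParams()
        self.params = replace(base, **overrides) if overrides else base

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        n_roi: int | None = None,
        label_col: str = "label",
        subject_col: str = "subject_id",
        params: PipelineParams | None = None,
        **overrides,
    ) -> "ConnectomeClassifier":
        table = EdgeTable.from_dataframe(
            df, n_roi=n_roi, label_col=label_col, subject_col=subject_col
        )
        return cls(table, params=params, **overrides)

    @classmethod
    def from_csv(cls, path, params: PipelineParams | None = None, **overrides):
        return cls(EdgeTable.from_csv(path), params=params, **overrides)

    def fit(self, repeats: int | None = None) -> "ConnectomeCVResults":
        """Run the repeated nested CV and return the results object."""
        params = self.params if repeats is None else replace(self.params, repeats=repeats)
        return ConnectomeCVResults(self, run_repeated_cv(self.table, params))

    def grid_search(self, p0_grid=None, n_grid=None, c_grid=None, seed: int | None = None):
        """Pick (p0, N, c) maximizing shared-split test accuracy; returns
        (best params, full results table) and updates ``self.params``."""
        from .evaluate import default_grids

        d_p0, d_n, d_c = default_grids()
        best, frame = grid_search(
            self.table,
            p0_grid if p0_grid is not None else d_p0,
            n_grid if n_grid is not None else d_n,
            c_grid if c_grid is not None else d_c,
            seed=self.params.seed if seed is None else seed,
            base_params=self.params,
        )
        self.params = best
        return best, frame

    def permutation_test(
        self,
        n_permutations: int | None = None,
        repeats: int | None = None,
        observed: CVResults | None = None,
    ) -> PermutationResult:
        params = self.params if repeats is None else replace(self.params, repeats=repeats)
        return permutation_test(
            self.table, params, n_permutations=n_permutations, observed=observed
        )


class ConnectomeCVResults:
    """Results of a fitted :class:`ConnectomeClassifier`.

    Attributes
    ----------
    cv : CVResults
        Raw per-fold records.
    metrics : DataFrame
        mean ± SD of accuracy / sensitivity / specificity / recall /
        precision across successful test folds.
    pooled_auc : float
        Mann–Whitney AUC of all pooled test-fold decision scores.
    """

    def __init__(self, model: ConnectomeClassifier, cv: CVResults):
        self.model = model
        self.cv = cv
        self.metrics, self.pooled_auc = aggregate(cv)

    @property
    def params(self) -> PipelineParams:
        return self.cv.params

    @property
    def n_folds(self) -> int:
        return self.cv.n_folds

    @property
    def n_failed(self) -> int:
        return self.cv.n_failed

    def outer_occurrence(self) -> np.ndarray:
        return self.cv.outer_occurrence()

    def stability(
        self,
        threshold: float | None = None,
        alpha: float = 0.05,
        method: str = "bonferroni",
    ) -> StabilityReport:
        return build_stability_report(
            self.cv, self.model.table, threshold=threshold, alpha=alpha, method=method
        )

    def roc_curve(self):
        from .classify import roc_auc

        scores, y = self.cv.pooled_scores()
        return roc_auc(scores, y)

    def plot_roc(self, ax=None):
        """Pooled ROC curve across all test folds."""
        import matplotlib.pyplot as plt

        auc, fpr, tpr, _ = self.roc_curve()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"AUC = {auc:.4f}")
        ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax

    def summary(self) -> str:
        p = self.params
        y = self.cv.labels
        head = [
            "Connectome edge classification (repeated nested CV)",
            "=" * 55,
            f"subjects: {self.cv.n_subjects} "
            f"({int(np.sum(y == 1))} patients / {int(np.sum(y == 0))} controls), "
            f"edges: {self.cv.n_edges}",
            f"params: p0={p.p0:g}, N={p.n_occurrence}, c={p.svm_cost:g}, "
            f"{p.repeats}x{p.k_outer}-fold outer CV, {p.k_inner}-fold inner CV-LASSO",
            f"folds evaluated: {self.n_folds} ({self.n_failed} failed)",
            "",
        ]
        body = self.metrics.round(4).to_string()
        tail = [
            "",
            f"pooled AUC: {self.pooled_auc:.4f}",
            f"mean selected features per fold: {_safe_mean_selected(self.cv):.3f}",
        ]
        return "\n".join(head) + body + "\n".join(tail)


def _safe_mean_selected(cv: CVResults) -> float:
    from .report import mean_selected_count

    try:
        return mean_selected_count(cv)
    except ValueError:
        return float("nan")
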