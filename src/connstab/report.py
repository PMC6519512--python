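"""Cross-fold stability accounting and post-hoc group-difference tests.

After repeated cross-validation, each edge's *outer occurrence* counts how
many of the ``repeats x k_outer`` training folds selected it.  Edges whose
occurrence exceeds a threshold (by default half the fold count, matching
the >500-of-1000 convention) are the *stable features*.  Those are then
compared between groups with pooled two-sample t-tests on the full sample
under family-wise error correction (Bonferroni by default, Holm optional),
and summarized with a model-derived importance: the mean absolute
standardized SVM weight across the folds where the edge entered the model.

The post-hoc tests reuse the same sample the cross-validation selected on;
the report prints that circularity caveat rather than pretending the tests
are independent confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .connectivity import EdgeTable, edge_index_to_pair
from .evaluate import CVResults
from .selection import two_sample_t

__all__ = [
    "StabilityReport",
    "count_outer_occurrence",
    "stable_features",
    "group_difference_tests",
    "feature_weight_summary",
    "mean_selected_count",
    "build_stability_report",
]

CIRCULARITY_CAVEAT = (
    "Post-hoc group-difference tests are computed on the full sample that the "
    "cross-validated selection itself used; they characterize the stable "
    "features and are not independent confirmation of a group effect."
)


def count_outer_occurrence(results: CVResults) -> np.ndarray:
    """Per-edge count of training folds whose LASSO feature set contained it."""
    if results.n_folds == 0:
        raise ValueError("empty results")
    return results.outer_occurrence()


def _edge_names(edges: np.ndarray, n_roi: int, roi_names: list[str] | None):
    names = roi_names or [f"ROI_{r + 1:03d}" for r in range(n_roi)]
    out_a, out_b = [], []
    for k in edges:
        i, j = edge_index_to_pair(int(k), n_roi)
        out_a.append(names[i])
        out_b.append(names[j])
    return out_a, out_b


def stable_features(
    occurrence: np.ndarray,
    threshold: float,
    n_roi: int,
    roi_names: list[str] | None = None,
) -> pd.DataFrame:
    """Edges with occurrence strictly above ``threshold``, highest first."""
    occurrence = np.asarray(occurrence, int)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    edges = np.flatnonzero(occurrence > threshold)
    edges = edges[np.argsort(-occurrence[edges], kind="stable")]
    roi_a, roi_b = _edge_names(edges, n_roi, roi_names)
    return pd.DataFrame(
        {
            "edge": edges,
            "roi_a": roi_a,
            "roi_b": roi_b,
            "occurrence": occurrence[edges],
        }
    )


def group_difference_tests(
    table: EdgeTable,
    edges: np.ndarray,
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Pooled two-sided t-tests per edge on the full sample, FWE-corrected.

    Correction spans exactly the tested edges.  Direction is ``HC>PE``
    when the control mean exceeds the patient mean.
    """
    edges = np.asarray(edges, int)
    if edges.size == 0:
        raise ValueError("no edges to test")
    if method not in ("bonferroni", "holm"):
        raise ValueError("method must be 'bonferroni' or 'holm'")
    X = table.values[:, edges]
    y = table.labels
    t, p = two_sample_t(X[y == 0], X[y == 1])
    reject, p_corr, _, _ = multipletests(p, alpha=alpha, method=method)
    mean_diff = X[y == 0].mean(axis=0) - X[y == 1].mean(axis=0)
    return pd.DataFrame(
        {
            "edge": edges,
            "t": t,
            "p": p,
            "p_fwe": p_corr,
            "significant": reject,
            "direction": np.where(mean_diff > 0, "HC>PE", "HC<PE"),
        }
    )


def feature_weight_summary(results: CVResults, edges: np.ndarray) -> pd.Series:
    """Mean |standardized SVM weight| per edge over folds where it was used.

    Edges never entering any model get NaN (absent, not zero).
    """
    edges = np.asarray(edges, int)
    sums = {int(k): [] for k in edges}
    for f in results.successful:
        idx = f.model.feature_indices
        for pos, k in enumerate(idx):
            if int(k) in sums:
                sums[int(k)].append(abs(f.model.weights[pos]))
    return pd.Series(
        {k: float(np.mean(v)) if v else np.nan for k, v in sums.items()},
        name="weight",
    )


def mean_selected_count(results: CVResults) -> float:
    """Average LASSO-feature count per successful training fold."""
    ok = results.successful
    if not ok:
        raise ValueError("no successful folds")
    return float(np.mean([f.selected.size for f in ok]))


@dataclass
class StabilityReport:
    """Stable edges with occurrence, SVM weight and FWE-corrected statistics."""

    table: pd.DataFrame
    occurrence: np.ndarray
    threshold: float
    n_folds: int
    n_failed: int
    mean_selected: float
    alpha: float
    method: str
    caveat: str = CIRCULARITY_CAVEAT

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_markdown(self) -> str:
        lines = [
            "# Stable discriminative edges",
            "",
            f"Folds: {self.n_folds} ({self.n_failed} failed); occurrence "
            f"threshold: > {self.threshold:g}; mean features per training fold: "
            f"{self.mean_selected:.3f}",
            "",
        ]
        for direction in ("HC>PE", "HC<PE"):
            sub = self.table[self.table["direction"] == direction]
            if sub.empty:
                continue
            lines.append(f"**{direction}**")
            lines.append("")
            lines.append("| Edge | Occurrence | Weight | t | p (FWE) | Significant |")
            lines.append("|---|---|---|---|---|---|")
            for _, r in sub.iterrows():
                lines.append(
                    f"| {r.roi_a} -- {r.roi_b} | {int(r.occurrence)} | "
                    f"{r.weight:.4f} | {r.t:.3f} | {r.p_fwe:.4g} | "
                    f"{'yes' if r.significant else 'no'} |"
                )
            lines.append("")
        lines.append(f"> {self.caveat}")
        return "\n".join(lines)


def build_stability_report(
    results: CVResults,
    table: EdgeTable,
    threshold: float | None = None,
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> StabilityReport:
    """Assemble the full stability report from repeated-CV results.

    ``threshold`` defaults to half the total fold count (edges selected in
    more than 50% of training folds are considered stable).
    """
    occurrence = count_outer_occurrence(results)
    if threshold is None:
        threshold = results.n_folds / 2.0
    stable = stable_features(occurrence, threshold, table.n_roi, table.roi_names)
    if len(stable):
        stats_df = group_difference_tests(table, stable["edge"].to_numpy(), alpha, method)
        weights = feature_weight_summary(results, stable["edge"].to_numpy())
        merged = stable.merge(stats_df, on="edge")
        merged["weight"] = merged["edge"].map(weights)
        merged = merged[
            [
                "edge",
                "roi_a",
                "roi_b",
                "occurrence",
                "weight",
                "t",
                "p",
                "p_fwe",
                "significant",
                "direction",
            ]
        ]
    else:
        merged = pd.DataFrame(
            columns=[
                "edge",
                "roi_a",
                "roi_b",
                "occurrence",
                "weight",
                "t",
                "p",
                "p_fwe",
                "significant",
                "direction",
            ]
        )
    return StabilityReport(
        table=merged,
        occurrence=occurrence,
        threshold=float(threshold),
        n_folds=results.n_folds,
        n_failed=results.n_failed,
        mean_selected=mean_selected_count(results),
        alpha=alpha,
        method=method,
    )
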