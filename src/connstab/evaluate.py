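"""Repeated nested cross-validation, grid search and permutation testing.

The outer loop repeats a stratified k-fold split ``repeats`` times with a
fresh randomization each repeat.  Inside every training fold the full
selection chain runs on training subjects only — t-test screen, CV-LASSO
stability selection, occurrence threshold — followed by a linear SVM; the
held-out fold supplies the test metrics.  Metrics aggregate as mean ± SD
across all successful test folds, and decision scores pool into one ROC.

Folds whose selection comes back empty are recorded as failed and excluded
from aggregates (their count is reported).  A master seed deterministically
spawns per-repeat, per-fold and per-permutation child seeds, so identical
seeds give bit-identical results end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .classify import (
    MetricsReport,
    SVMModel,
    confusion_metrics,
    decision_scores,
    roc_auc,
    train_lsvm,
)
from .connectivity import EdgeTable
from .selection import (
    PipelineParams,
    cv_lasso_select,
    select_by_occurrence,
    ttest_screen,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FoldResult",
    "CVResults",
    "PermutationResult",
    "run_repeated_cv",
    "aggregate",
    "accuracy_auc_or_chance",
    "grid_search",
    "permutation_test",
    "permutation_pvalue",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "recall", "precision")


@dataclass
class FoldResult:
    """Everything one (repeat, fold) evaluation produced."""

    repeat_id: int
    fold_id: int
    test_idx: np.ndarray
    screened: np.ndarray | None = None
    inner_occurrence: np.ndarray | None = None  # aligned with ``screened``
    selected: np.ndarray | None = None  # edge indices entering the SVM
    model: SVMModel | None = None
    metrics: MetricsReport | None = None
    scores: np.ndarray | None = None
    y_test: np.ndarray | None = None
    failure: str | None = None

    @property
    def ok(self) -> bool:
        return self.failure is None


@dataclass
class CVResults:
    """All fold results of one repeated-CV run plus dataset bookkeeping."""

    folds: list[FoldResult]
    n_edges: int
    n_subjects: int
    params: PipelineParams
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def successful(self) -> list[FoldResult]:
        return [f for f in self.folds if f.ok]

    @property
    def n_failed(self) -> int:
        return self.n_folds - len(self.successful)

    def metric_frame(self) -> pd.DataFrame:
        rows = [
            {"repeat": f.repeat_id, "fold": f.fold_id, **f.metrics.as_dict()}
            for f in self.successful
        ]
        return pd.DataFrame(rows)

    def pooled_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """Decision scores and labels concatenated over all test folds."""
        ok = self.successful
        if not ok:
            raise ValueError("no successful folds")
        return (
            np.concatenate([f.scores for f in ok]),
            np.concatenate([f.y_test for f in ok]),
        )

    def pooled_auc(self) -> float:
        scores, y = self.pooled_scores()
        return roc_auc(scores, y)[0]

    def outer_occurrence(self) -> np.ndarray:
        """Per-edge count of training folds whose selection contained it."""
        occ = np.zeros(self.n_edges, dtype=int)
        for f in self.folds:
            if f.selected is not None:
                occ[f.selected] += 1
        return occ


@dataclass
class PermutationResult:
    """Null distributions and p-values from group-label permutation."""

    n_permutations: int
    observed_accuracy: float
    observed_auc: float
    null_accuracy: np.ndarray
    null_auc: np.ndarray
    p_accuracy: float
    p_auc: float


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def _outer_splits(y: np.ndarray, k: int, seed: int, stratified: bool):
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros((len(y), 1)), y))


def _evaluate_fold(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    params: PipelineParams,
    inner_seed: int,
    repeat_id: int,
    fold_id: int,
) -> FoldResult:
    out = FoldResult(repeat_id=repeat_id, fold_id=fold_id, test_idx=test)
    Xtr, ytr = X[train], y[train]
    screened, _, _ = ttest_screen(Xtr, ytr, params.p0)
    out.screened = screened
    if screened.size == 0:
        out.failure = "no edges passed the t-test screen"
        return out
    _, occ = cv_lasso_select(
        Xtr[:, screened],
        ytr,
        k_inner=params.k_inner,
        seed=inner_seed,
        n_lambdas=params.n_lambdas,
        lambda_min_ratio=params.lambda_min_ratio,
        k_lambda=params.k_lambda,
    )
    out.inner_occurrence = occ
    selected = screened[select_by_occurrence(occ, params.n_occurrence)]
    out.selected = selected if selected.size else None
    if selected.size == 0:
        out.failure = "empty LASSO feature set"
        return out
    model = train_lsvm(Xtr[:, selected], ytr, cost=params.svm_cost, feature_indices=selected)
    out.model = model
    out.scores = decision_scores(model, X[np.ix_(test, selected)])
    out.y_test = y[test]
    out.metrics = confusion_metrics(out.y_test, (out.scores > 0).astype(int))
    return out


def run_repeated_cv(table: EdgeTable, params: PipelineParams) -> CVResults:
    """Run ``repeats`` independent stratified ``k_outer``-fold evaluations.

    All selection and fitting happen strictly inside each training fold;
    the held-out fold is touched only for scoring.
    """
    X, y = table.values, table.labels
    master = np.random.SeedSequence(params.seed)
    folds: list[FoldResult] = []
    for rep, rep_ss in enumerate(master.spawn(params.repeats)):
        split_seed = _child_seed(rep_ss)
        fold_seeds = [_child_seed(c) for c in rep_ss.spawn(params.k_outer)]
        for fold_id, (train, test) in enumerate(
            _outer_splits(y, params.k_outer, split_seed, params.stratified)
        ):
            folds.append(
                _evaluate_fold(
                    X, y, train, test, params, fold_seeds[fold_id], rep, fold_id
                )
            )
    if any(not f.ok for f in folds):
        logger.info(
            "%d of %d folds failed (empty feature set)",
            sum(not f.ok for f in folds),
            len(folds),
        )
    return CVResults(
        folds=folds,
        n_edges=table.n_edges,
        n_subjects=table.n_subjects,
        params=params,
        labels=y.copy(),
    )


def aggregate(results: CVResults) -> tuple[pd.DataFrame, float]:
    """Mean ± SD of each metric across successful test folds, plus pooled AUC.

    SD uses the n−1 denominator.  Metrics undefined in a fold (e.g. no
    positives held out in an unstratified split) are skipped for that fold.
    """
    frame = results.metric_frame()
    if frame.empty:
        raise ValueError("no successful folds to aggregate")
    means, sds = [], []
    for m in METRIC_NAMES:
        col = frame[m].dropna()
        means.append(col.mean() if len(col) else np.nan)
        sds.append(col.std(ddof=1) if len(col) > 1 else 0.0)
    table = pd.DataFrame({"mean": means, "sd": sds}, index=list(METRIC_NAMES))
    return table, results.pooled_auc()


# ---------------------------------------------------------------------------
# grid search


def grid_search(
    table: EdgeTable,
    p0_grid,
    n_grid,
    c_grid,
    seed: int = 0,
    base_params: PipelineParams | None = None,
) -> tuple[PipelineParams, pd.DataFrame]:
    """Search (p0, N, c) on one shared k-fold split, maximizing test accuracy.

    This follows the study's literal protocol — the triple is chosen where
    the test-fold accuracy of the resulting model peaks, which is
    optimistically biased; for honest generalization estimates wrap this in
    an outer CV.  One ``k_outer`` split (single repeat) is shared across all
    grid points; screening and the CV-LASSO occurrence counts are computed
    once per (fold, p0) and reused across N and c.  Ties resolve to larger
    N, then smaller c, then smaller p0 (parsimony bias).
    """
    base = base_params or PipelineParams()
    p0s = np.unique(np.asarray(p0_grid, float))
    ns = np.unique(np.asarray(n_grid, int))
    cs = np.unique(np.asarray(c_grid, float))
    if p0s.size == 0 or ns.size == 0 or cs.size == 0:
        raise ValueError("grids must be non-empty")
    X, y = table.values, table.labels
    master = np.random.SeedSequence([59, seed])
    splits = _outer_splits(y, base.k_outer, _child_seed(master), base.stratified)
    fold_seeds = [_child_seed(c) for c in master.spawn(len(splits))]

    # stage results per (fold, p0): screened indices and inner occurrence
    occ_cache: list[dict[float, tuple[np.ndarray, np.ndarray]]] = []
    pvals_per_fold = []
    for fold_id, (train, _) in enumerate(splits):
        _, _, p = ttest_screen(X[train], y[train], 1.0)
        pvals_per_fold.append(p)
        cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        for p0 in p0s:
            screened = np.flatnonzero(p < p0)
            if screened.size == 0:
                cache[float(p0)] = (screened, np.empty(0, int))
                continue
            _, occ = cv_lasso_select(
                X[np.ix_(train, screened)],
                y[train],
                k_inner=base.k_inner,
                seed=fold_seeds[fold_id],
                n_lambdas=base.n_lambdas,
                lambda_min_ratio=base.lambda_min_ratio,
                k_lambda=base.k_lambda,
            )
            cache[float(p0)] = (screened, occ)
        occ_cache.append(cache)

    rows = []
    for p0, n_occ in product(p0s, ns):
        if not 1 <= n_occ <= base.k_inner:
            raise ValueError("n_grid values must lie in 1..k_inner")
        fold_features = []
        for fold_id in range(len(splits)):
            screened, occ = occ_cache[fold_id][float(p0)]
            sel = (
                screened[select_by_occurrence(occ, int(n_occ))]
                if screened.size
                else np.empty(0, int)
            )
            fold_features.append(sel)
        for c in cs:
            accs, failed = [], 0
            for (train, test), sel in zip(splits, fold_features):
                if sel.size == 0:
                    failed += 1
                    continue
                model = train_lsvm(X[np.ix_(train, sel)], y[train], cost=float(c))
                pred = (decision_scores(model, X[np.ix_(test, sel)]) > 0).astype(int)
                accs.append(confusion_metrics(y[test], pred).accuracy)
            rows.append(
                {
                    "p0": float(p0),
                    "n_occurrence": int(n_occ),
                    "c": float(c),
                    "accuracy": float(np.mean(accs)) if accs else np.nan,
                    "n_failed": failed,
                }
            )
    frame = pd.DataFrame(rows)
    ranked = frame.dropna(subset=["accuracy"]).sort_values(
        ["accuracy", "n_occurrence", "c", "p0"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    if ranked.empty:
        raise ValueError("every grid point failed (no features selected)")
    best = ranked.iloc[0]
    best_params = replace(
        base,
        p0=float(best["p0"]),
        n_occurrence=int(best["n_occurrence"]),
        svm_cost=float(best["c"]),
    )
    return best_params, frame


def default_grids() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The study's grid: 11 screening thresholds x 10 occurrence counts x 20 costs."""
    p0 = np.r_[0.001, 0.005, 0.01, np.arange(0.025, 0.2001, 0.025)]
    n = np.arange(1, 11)
    c = np.round(np.arange(0.1, 2.001, 0.1), 10)
    return p0, n, c


# ---------------------------------------------------------------------------
# permutation test


def stats_mode(labels: np.ndarray) -> int:
    """Majority class (ties resolve to the patient class, 1)."""
    labels = np.asarray(labels, int)
    return 1 if np.sum(labels == 1) >= np.sum(labels == 0) else 0


def accuracy_auc_or_chance(results: CVResults, labels: np.ndarray) -> tuple[float, float]:
    """Mean accuracy and pooled AUC, falling back to chance when every fold failed.

    A run in which no fold produced a model is a no-information classifier:
    its accuracy is the majority-class rate and its AUC is 1/2.  Using the
    same convention for observed and permuted runs keeps the permutation
    null exchangeable.
    """
    try:
        tab, auc = aggregate(results)
        return float(tab.loc["accuracy", "mean"]), auc
    except ValueError:
        return float(np.mean(labels == stats_mode(labels))), 0.5


def permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """Add-one permutation p-value ``(1 + #{null >= observed}) / (B + 1)``."""
    null = np.asarray(null, float)
    return (1.0 + float(np.sum(null >= observed))) / (null.size + 1.0)


def permutation_test(
    table: EdgeTable,
    params: PipelineParams,
    n_permutations: int | None = None,
    seed: int | None = None,
    observed: CVResults | None = None,
) -> PermutationResult:
    """Group-label permutation test of mean accuracy and pooled AUC.

    The full pipeline re-runs per permutation with the observed parameter
    triple (no per-permutation re-search).  Pass a reduced-``repeats``
    ``params`` to keep B large runs affordable; the observed statistic is
    then computed under the same reduced setting for exchangeability.
    """
    B = n_permutations if n_permutations is not None else params.n_permutations
    if B < 1:
        raise ValueError("need at least one permutation")
    master = np.random.SeedSequence([71, params.seed if seed is None else seed])
    if observed is None:
        observed = run_repeated_cv(table, params)
    obs_acc, obs_auc = accuracy_auc_or_chance(observed, table.labels)

    null_acc = np.empty(B)
    null_auc = np.empty(B)
    rng = np.random.default_rng(_child_seed(master))
    for b, child in enumerate(master.spawn(B)):
        perm = rng.permutation(table.n_subjects)
        perm_table = EdgeTable(
            table.values,
            labels=table.labels[perm],
            n_roi=table.n_roi,
            subject_ids=table.subject_ids,
            roi_names=table.roi_names,
        )
        perm_params = replace(params, seed=_child_seed(child))
        res = run_repeated_cv(perm_table, perm_params)
        null_acc[b], null_auc[b] = accuracy_auc_or_chance(res, perm_table.labels)
    return PermutationResult(
        n_permutations=B,
        observed_accuracy=obs_acc,
        observed_auc=obs_auc,
        null_accuracy=null_acc,
        null_auc=null_auc,
        p_accuracy=permutation_pvalue(obs_acc, null_acc),
        p_auc=permutation_pvalue(obs_auc, null_auc),
    )
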