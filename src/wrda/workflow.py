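"""End-to-end analyses: the two-level ranking workflow and SVM/ROC validation.

Level 1 scores every feature with equal time-point weights and removes
noise via the permutation filter, yielding feature subset 1 (the features
whose time-course divergence is distinguishable from label-shuffled null).
Level 2 rescores subset 1 with explicit weights concentrated on the
biologically typical stages, targeting the features that separate those
stages specifically. Validation trains an SVM on the selected panel under
repeated stratified k-fold cross-validation and reports per-feature ROC
AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_model import TimeCourseDataset
from .permutation import PermutationNull, noise_filter, permute_scores
from .scoring import DEFAULT_EPSILON, ScoreTable, summarize, top_n, wrda
from .weights import explicit_weights, make_weights

__all__ = [
    "WorkflowConfig",
    "TwoLevelResult",
    "ValidationReport",
    "run_two_level",
    "svm_validate",
    "roc_auc",
    "report_tables",
]


@dataclass
class WorkflowConfig:
    """Settings for the two-level analysis.

    ``level2_weights`` is an explicit per-time-point weight vector (zeros
    silence a point entirely); indices refer to the dataset's 0-based time
    points.
    """

    level2_weights: tuple[float, ...] = ()
    top_n: int = 20
    B: int = 200
    noise_quantile: float = 0.95
    epsilon: float = DEFAULT_EPSILON
    seed: int = 0
    svm_folds: int = 5
    svm_repeats: int = 50
    svm_kernel: str = "rbf"


@dataclass
class TwoLevelResult:
    subset1: list[str]
    level1_top: list[str]
    level2_top: list[str]
    level1_scores: ScoreTable
    level2_scores: ScoreTable
    null: PermutationNull


@dataclass
class ValidationReport:
    accuracies: np.ndarray  # one mean CV accuracy per repeat
    mean_accuracy: float
    sd_accuracy: float
    feature_auc: dict[str, float] = field(default_factory=dict)
    roc_points: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def run_two_level(dataset: TimeCourseDataset, config: WorkflowConfig) -> TwoLevelResult:
    """Run the equal-weight + permutation-filter level then the explicit-
    weight rescoring level; both top-n lists come back with the reports."""
    n_tp = dataset.n_time_points
    if len(config.level2_weights) != n_tp:
        raise ValueError(
            f"level2_weights has {len(config.level2_weights)} entries; "
            f"dataset has {n_tp} time points"
        )
    equal = make_weights("equal", length=n_tp)
    summary = summarize(dataset)
    level1 = wrda(summary, equal, config.epsilon)
    null = permute_scores(
        dataset, equal, epsilon=config.epsilon, B=config.B, seed=config.seed
    )
    subset1 = noise_filter(level1, null, config.noise_quantile)
    level1_top = top_n(level1, min(config.top_n, level1.n_features))

    universe = subset1 if subset1 else list(dataset.feature_ids)
    sub = dataset.subset_features(universe)
    omega2 = explicit_weights(config.level2_weights, normalize=False)
    level2 = wrda(summarize(sub), omega2, config.epsilon)
    level2_top = top_n(level2, min(config.top_n, level2.n_features))
    return TwoLevelResult(
        subset1=subset1,
        level1_top=level1_top,
        level2_top=level2_top,
        level1_scores=level1,
        level2_scores=level2,
        null=null,
    )


def svm_validate(
    dataset: TimeCourseDataset,
    feature_ids: list[str],
    labels: np.ndarray | None = None,
    folds: int = 5,
    repeats: int = 50,
    seed: int = 0,
    kernel: str = "rbf",
) -> ValidationReport:
    """Repeated stratified k-fold CV of an SVM on the selected features.

    *labels* defaults to the group labels (C vs M); pass a custom binary
    vector to validate other sample dichotomies. Standardization happens
    inside each training fold to avoid leakage. AUCs use the raw feature
    values against the labels.
    """
    sub = dataset.subset_features(feature_ids)
    y = dataset.group_codes() if labels is None else np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    X = sub.values
    rng = np.random.default_rng(seed)
    accs = np.empty(repeats)
    for r in range(repeats):
        cv = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        model = make_pipeline(StandardScaler(), SVC(kernel=kernel))
        accs[r] = cross_val_score(model, X, y, cv=cv, scoring="accuracy").mean()

    aucs: dict[str, float] = {}
    rocs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for kcol, fid in enumerate(feature_ids):
        auc, points = roc_auc(y, X[:, kcol])
        aucs[fid] = auc
        rocs[fid] = points
    return ValidationReport(
        accuracies=accs,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if repeats > 1 else 0.0,
        feature_auc=aucs,
        roc_points=rocs,
    )


def roc_auc(labels, scores) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """AUC by the midrank (Mann-Whitney) rule, plus ROC curve points.

    Equals the probability that a randomly chosen positive outscores a
    randomly chosen negative, counting ties as one half.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)  # midranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return auc, (fpr, tpr)


def report_tables(
    table: ScoreTable,
    dataset: TimeCourseDataset,
    n: int = 30,
    test: str = "welch",
) -> pd.DataFrame:
    """Top-n report: rank, score, and two-sided C-vs-M p-values at time
    point 0 alone and pooled over all time points (Welch t by default,
    Mann-Whitney by ``test="mannwhitney"``)."""
    if n > table.n_features:
        import warnings

        warnings.warn(
            f"n={n} exceeds the {table.n_features} available features; clipping",
            stacklevel=2,
        )
        n = table.n_features
    ids = top_n(table, n)
    col = {f: k for k, f in enumerate(dataset.feature_ids)}
    is_m = dataset.group_codes() == 1
    at_t0 = dataset.time_point == 0
    rows = []
    score_by_id = dict(zip(table.feature_ids, table.score))
    rank_by_id = dict(zip(table.feature_ids, table.rank))
    for fid in ids:
        x = dataset.values[:, col[fid]]
        rows.append(
            {
                "feature_id": fid,
                "rank": int(rank_by_id[fid]),
                "score": float(score_by_id[fid]),
                "p_t0": _two_group_p(x[at_t0 & is_m], x[at_t0 & ~is_m], test),
                "p_pooled": _two_group_p(x[is_m], x[~is_m], test),
            }
        )
    return pd.DataFrame(rows)


def _two_group_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if test == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError(f"unknown test {test!r}")
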