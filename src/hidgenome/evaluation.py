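"""Precision-recall evaluation and the replicated cross-validation harness.

Performance of the soft multi-class classifier is summarized by one-vs-rest
precision-recall curves per cancer site, their areas (average precision),
and the macro AUC — the unweighted mean of the per-class AUCs.  The null
baseline for class k is its prevalence n_k/N; the macro null baseline is the
mean prevalence, i.e. exactly 1/K.  PR analysis is preferred over ROC here
because one-vs-rest splits of a K-class problem are inherently imbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import MutationCatalog
from .metafeatures import MetaDesign
from .model import HidGenomeModel, fit as fit_model, pairwise_proba, predict_proba
from .projection import assemble_design
from .screening import screen_catalog


@dataclass
class PRCurve:
    """One-vs-rest precision-recall curve over all score thresholds."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auc: float              # average precision (step integration)
    baseline: float         # class prevalence


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> PRCurve:
    """PR curve and average-precision AUC for binary labels.

    Thresholds are the distinct scores in descending order (an implicit +inf
    sentinel gives the empty classification).  AUC is the step-wise average
    precision sum((R_t - R_{t-1}) * P_t), which avoids the optimistic linear
    interpolation trapezoids produce on PR curves.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    P = int(labels.sum())
    if P == 0 or P == len(labels):
        raise ValueError("labels must contain both classes")
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # last index of each distinct score block
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp_d, fp_d = tp[distinct], fp[distinct]
    precision = tp_d / (tp_d + fp_d)
    recall = tp_d / P
    prev_r = np.r_[0.0, recall[:-1]]
    auc = float(((recall - prev_r) * precision).sum())
    return PRCurve(precision=precision, recall=recall,
                   thresholds=s_sorted[distinct], auc=auc,
                   baseline=P / len(labels))


@dataclass
class PRSummary:
    """Per-class and macro precision-recall summaries."""

    classes: list[str]
    curves: dict[str, PRCurve]
    class_aucs: dict[str, float]
    baselines: dict[str, float]
    macro_auc: float
    macro_baseline: float
    macro_precision: np.ndarray = field(default_factory=lambda: np.array([]))
    macro_recall: np.ndarray = field(default_factory=lambda: np.array([]))


PRECISION_GRID = np.linspace(1.0, 0.0, 101)


def _recall_at_precision(curve: PRCurve, grid: np.ndarray) -> np.ndarray:
    """Best recall achievable at precision >= p, step-interpolated."""
    out = np.zeros_like(grid)
    for i, p in enumerate(grid):
        ok = curve.precision >= p
        out[i] = curve.recall[ok].max() if ok.any() else 0.0
    return out


def macro_summary(probs: np.ndarray, labels, classes: list[str]) -> PRSummary:
    """One-vs-rest PR summary for an n x K probability table.

    The macro curve averages per-class recall on a common descending
    precision grid (101 points); the macro AUC is the unweighted mean of the
    per-class average precisions.
    """
    labels = np.asarray(labels)
    curves, aucs, bases = {}, {}, {}
    recalls = []
    for k, c in enumerate(classes):
        y = (labels == c).astype(int)
        if y.sum() == 0:
            raise ValueError(f"class {c!r} has no members in the evaluation set")
        curve = pr_curve(probs[:, k], y)
        curves[c] = curve
        aucs[c] = curve.auc
        bases[c] = curve.baseline
        recalls.append(_recall_at_precision(curve, PRECISION_GRID))
    macro_auc = float(np.mean(list(aucs.values())))
    macro_base = float(np.mean(list(bases.values())))
    return PRSummary(
        classes=list(classes), curves=curves, class_aucs=aucs, baselines=bases,
        macro_auc=macro_auc, macro_baseline=macro_base,
        macro_precision=PRECISION_GRID.copy(),
        macro_recall=np.mean(recalls, axis=0),
    )


def one_vs_one_matrix(probs: np.ndarray, labels, classes: list[str]) -> np.ndarray:
    """K x K ordered one-vs-one PR-AUC matrix.

    Entry (i, j) treats class i as positive and class j as negative on the
    samples of those two classes, scoring with the conditional probability
    p_i/(p_i + p_j).  PR-AUC is not symmetric in the class roles, so the
    matrix is ordered; the diagonal is NaN.
    """
    labels = np.asarray(labels)
    K = len(classes)
    M = np.full((K, K), np.nan)
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            mask = (labels == classes[i]) | (labels == classes[j])
            if (labels == classes[i]).sum() == 0 or (labels == classes[j]).sum() == 0:
                continue
            cond = pairwise_proba(probs[mask], i, j)
            y = (labels[mask] == classes[i]).astype(int)
            keep = ~np.isnan(cond[:, 0])
            M[i, j] = pr_curve(cond[keep, 0], y[keep]).auc
    return M


@dataclass
class CVResult:
    """Replicated stratified cross-validation output."""

    classes: list[str]
    oof_probs: list[np.ndarray]        # one n x K table per replication
    labels: np.ndarray
    summaries: list[PRSummary]
    mean_macro_auc: float
    mean_class_aucs: dict[str, float]
    seeds: list[int]
    fold_assignments: list[np.ndarray]


def _rep_seed(seed: int, rep: int) -> int:
    return int((seed * 1_000_003 + 7919 * rep + 1) % (2**31 - 1))


def run_cv(
    catalog: MutationCatalog,
    meta_design: MetaDesign,
    folds: int = 5,
    reps: int = 10,
    d0: int = 250,
    seed: int = 0,
    inner_folds: int = 3,
    n_lambda: int = 15,
    lambda_min_ratio: float = 1e-2,
    tol: float = 1e-7,
    max_iter: int = 1500,
) -> CVResult:
    """Replicated stratified K-fold CV of the full pipeline.

    Within each training split — and never on test rows — the harness
    re-runs MI screening, recomputes column moments, tunes lambda by inner
    CV, and fits; out-of-fold probabilities are pooled per replication and
    summarized.  The headline number is the mean macro PR-AUC over
    replications.  Deterministic given (seed, reps, folds).
    """
    from sklearn.model_selection import StratifiedKFold

    codes, classes = catalog.label_codes()
    if (codes < 0).any():
        raise ValueError("cross-validation needs a fully labeled catalog")
    counts = np.bincount(codes, minlength=len(classes))
    if counts.min() < folds:
        k = int(np.argmin(counts))
        raise ValueError(f"class {classes[k]!r} smaller than folds={folds}")
    labels_arr = np.asarray([lab for lab in catalog.labels])
    n, K = catalog.n_samples, len(classes)

    oof_list, summaries, seeds_used, assignments = [], [], [], []
    for rep in range(reps):
        rs = _rep_seed(seed, rep)
        seeds_used.append(rs)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        oof = np.zeros((n, K))
        fold_of = np.full(n, -1)
        for f, (itr, ite) in enumerate(skf.split(np.zeros(n), codes)):
            fold_of[ite] = f
            train_mask = np.zeros(n, dtype=bool)
            train_mask[itr] = True
            train_cat = catalog.subset_samples(train_mask)
            screen = screen_catalog(train_cat, d0=d0)
            # screened indices are relative to the (unchanged) variant list
            design = assemble_design(catalog, meta_design, screen,
                                     train_mask=train_mask)
            mdl = fit_model(
                design, catalog.labels, cv_folds=inner_folds, seed=rs + f,
                n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
                tol=tol, max_iter=max_iter,
            )
            probs = predict_proba(mdl, design)
            oof[ite] = probs[ite]
        oof_list.append(oof)
        assignments.append(fold_of)
        summaries.append(macro_summary(oof, labels_arr, classes))

    mean_macro = float(np.mean([s.macro_auc for s in summaries]))
    mean_class = {
        c: float(np.mean([s.class_aucs[c] for s in summaries])) for c in classes
    }
    return CVResult(
        classes=classes, oof_probs=oof_list, labels=labels_arr,
        summaries=summaries, mean_macro_auc=mean_macro,
        mean_class_aucs=mean_class, seeds=seeds_used,
        fold_assignments=assignments,
    )
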