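"""Cross-validation protocol, metric panel and between-model comparison.

The split follows the published protocol: each subject's segments are
randomly divided into five near-equal parts and fold k tests on the union
of part k over subjects.  Note this places segments of every subject in
both train and test sets (the protocol behind the published numbers); a
subject-wise split is available for honest generalization estimates.

Classification metrics are the confusion-matrix panel at threshold 0.5 plus
AUROC computed from the rank statistic (the Mann-Whitney U normalization).
Fold-wise model comparison uses the exact two-sided Mann-Whitney U test
with Bonferroni-Holm control over the stated comparison family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError
from .preprocess import SegmentDataset

logger = logging.getLogger(__name__)

CLASSIFICATION_METRICS = (
    "accuracy", "f1", "sensitivity", "specificity", "ppv", "npv", "auroc",
)


@dataclass
class FoldSplit:
    """Per-fold test indices; folds partition all retained segments."""

    test_indices: list[np.ndarray]
    n_total: int

    @property
    def k(self) -> int:
        return len(self.test_indices)

    def train_indices(self, fold: int) -> np.ndarray:
        mask = np.ones(self.n_total, dtype=bool)
        mask[self.test_indices[fold]] = False
        return np.nonzero(mask)[0]


def make_within_subject_folds(
    subject_ids: np.ndarray,
    k: int = 5,
    rng: np.random.Generator | None = None,
    on_small_subject: str = "drop",
    contiguous: bool = False,
) -> FoldSplit:
    """Randomly split each subject's segments into k near-equal parts.

    Subjects with fewer than k segments are dropped with a warning (or
    raise, with ``on_small_subject="error"``).  ``contiguous=True`` uses
    consecutive time blocks instead of random assignment.
    """
    rng = rng or np.random.default_rng(0)
    subject_ids = np.asarray(subject_ids)
    tests: list[list[int]] = [[] for _ in range(k)]
    for sid in pd.unique(subject_ids):
        idx = np.nonzero(subject_ids == sid)[0]
        if idx.size < k:
            if on_small_subject == "error":
                raise InvalidArgumentError(
                    f"subject {sid} has {idx.size} < {k} segments"
                )
            logger.warning("dropping subject %s with %d < %d segments", sid, idx.size, k)
            continue
        if not contiguous:
            idx = rng.permutation(idx)
        parts = np.array_split(idx, k)
        order = rng.permutation(k)  # rotate which subjects' large parts align
        for f in range(k):
            tests[f].extend(parts[order[f]].tolist())
    return FoldSplit(
        test_indices=[np.sort(np.asarray(t, dtype=int)) for t in tests],
        n_total=subject_ids.size,
    )


def make_subject_wise_folds(
    subject_ids: np.ndarray,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> FoldSplit:
    """Whole-subject k-fold split: all segments of a subject share a fold.

    This is *not* the published protocol (which splits within subjects); it
    estimates generalization to unseen subjects.
    """
    rng = rng or np.random.default_rng(0)
    subject_ids = np.asarray(subject_ids)
    subjects = pd.unique(subject_ids)
    if subjects.size < k:
        raise InvalidArgumentError(f"need >= {k} subjects for {k} folds")
    parts = np.array_split(rng.permutation(subjects), k)
    tests = [
        np.sort(np.nonzero(np.isin(subject_ids, part))[0]) for part in parts
    ]
    return FoldSplit(test_indices=tests, n_total=subject_ids.size)


def auroc_rank(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """AUROC via the rank statistic (equals the normalized Mann-Whitney U)."""
    y_true = np.asarray(y_true, dtype=float)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError("AUROC undefined with a single class")
    ranks = stats.rankdata(y_score)
    u = np.sum(ranks[y_true == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_metrics(
    y_true: np.ndarray, y_score: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Confusion-matrix panel at the given probability threshold, plus AUROC."""
    y_true = np.asarray(y_true, dtype=float)
    y_score = np.asarray(y_score, dtype=float)
    y_pred = (y_score >= threshold).astype(float)
    tp = float(np.sum((y_pred == 1) & (y_true == 1)))
    tn = float(np.sum((y_pred == 0) & (y_true == 0)))
    fp = float(np.sum((y_pred == 1) & (y_true == 0)))
    fn = float(np.sum((y_pred == 0) & (y_true == 1)))

    def safe(num, den):
        return num / den if den > 0 else np.nan

    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    ppv = safe(tp, tp + fp)
    npv = safe(tn, tn + fn)
    return {
        "accuracy": (tp + tn) / y_true.size,
        "f1": safe(2 * tp, 2 * tp + fp + fn),
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "auroc": auroc_rank(y_true, y_score),
    }


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """R2 (1 - SS_res/SS_tot), MAE and RMSE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise InvalidArgumentError("R2 undefined for constant y_true")
    res = y_true - y_pred
    return {
        "r2": 1.0 - float(np.sum(res**2)) / ss_tot,
        "mae": float(np.mean(np.abs(res))),
        "rmse": float(np.sqrt(np.mean(res**2))),
    }


@dataclass
class ComparisonResult:
    u: float
    p: float
    significant: bool
    alpha_step: float


def compare_fold_metrics(
    metrics_a: np.ndarray,
    metrics_b: np.ndarray,
    n_comparisons: int = 2,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Exact two-sided Mann-Whitney U on fold-wise metric vectors, judged at
    the first Bonferroni-Holm step of the stated comparison family."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.size != b.size:
        raise InvalidArgumentError("fold vectors must have equal length")
    if a.size < 3:
        raise InvalidArgumentError("need at least 3 folds to compare")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    step = alpha / n_comparisons
    return ComparisonResult(
        u=float(res.statistic), p=float(res.pvalue),
        significant=bool(res.pvalue < step), alpha_step=step,
    )


def holm_adjust(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni-Holm adjusted p-values for a comparison family."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), alpha=alpha, method="holm")[1]


# ---------------------------------------------------------------------------
# cross-validated task evaluation
# ---------------------------------------------------------------------------


def evaluate_task(
    dataset: SegmentDataset,
    encoder_state,
    task: str,
    k: int = 5,
    random_state: int = 0,
    epochs: int = 40,
    lr: float = 0.001,
    batch_size: int = 128,
    features: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the k-fold within-subject protocol for one affect task.

    Returns a tidy frame with one row per (fold, level) where level is
    ``segment`` or ``subject`` (subject scores are mean segment
    predictions).
    """
    from .affect import (
        CLASSIFY_TASK,
        TASK_LABEL_FIELD,
        aggregate_subject,
        build_affect_model,
        predict,
        train_affect,
    )
    from .ssl import encode_segments

    rng = np.random.default_rng(random_state)
    if features is None:
        features = encode_segments(encoder_state, dataset.X)
    y = dataset.label_array(TASK_LABEL_FIELD[task])
    folds = make_within_subject_folds(dataset.subject_ids, k=k, rng=rng)
    rows = []
    for f in range(folds.k):
        tr, te = folds.train_indices(f), folds.test_indices[f]
        sub = SegmentDataset(
            X=dataset.X[tr], subject_ids=dataset.subject_ids[tr],
            source_role=dataset.source_role, labels=dataset.labels,
        )
        model = build_affect_model(encoder_state, task, random_state=random_state + f)
        train_affect(
            model, sub, lr=lr, batch_size=batch_size, epochs=epochs,
            random_state=random_state + f, features=features[tr],
        )
        pred = predict(model, dataset.X[te], features=features[te])
        if task == CLASSIFY_TASK:
            seg_metrics = classification_metrics(y[te], pred)
            subj_scores = aggregate_subject(pred, dataset.subject_ids[te])
            subj_truth = aggregate_subject(y[te], dataset.subject_ids[te])
            subj_metrics = classification_metrics(
                subj_truth.to_numpy(), subj_scores.to_numpy()
            )
        else:
            seg_metrics = regression_metrics(y[te], pred)
            subj_scores = aggregate_subject(pred, dataset.subject_ids[te])
            subj_truth = aggregate_subject(y[te], dataset.subject_ids[te])
            subj_metrics = regression_metrics(
                subj_truth.to_numpy(), subj_scores.to_numpy()
            )
        rows.append({"fold": f, "level": "segment", "task": task, **seg_metrics})
        rows.append({"fold": f, "level": "subject", "task": task, **subj_metrics})
    return pd.DataFrame(rows)


def summarize_panel(fold_frame: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd over folds, per level and metric (table-shaped report)."""
    value_cols = [
        c for c in fold_frame.columns if c not in ("fold", "level", "task", "source")
    ]
    keys = [c for c in ("source", "task", "level") if c in fold_frame.columns]
    agg = fold_frame.groupby(keys)[value_cols].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
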