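"""Evaluation of the diagnosis pipeline.

Cross-validation (2/4/10-fold and leave-one-subject-out), repeated-run
summaries, stratified 60/15/25 hold-out, label-shuffling permutation
significance, ROC/AUC of the fused membership score, prevalence-adjusted
positive/negative predictive values, and correlation of area scores
with behavioral (ADOS-like) severity.

All schemes re-fit the per-area classifier ensemble on training folds
only, including the significant-area screen, so no test labels leak
into area selection.  Every source of randomness derives from a single
root seed through a spawned seed sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from rsdiag.diagnosis_fusion import ASD
from rsdiag.pipeline import FeatureDataset, fit_cohort_classifier, score_cohort

__all__ = [
    "EvalMetrics",
    "PrevalenceReport",
    "run_cv",
    "repeat_cv",
    "holdout_split",
    "permutation_test",
    "roc_auc",
    "predictive_values",
    "behavioral_correlation",
]

SCHEMES = {"2-fold": 2, "4-fold": 4, "10-fold": 10}

#: Reference prevalences: general US population and high-risk siblings.
DEFAULT_PREVALENCES = (1.0 / 68.0, 0.187)


@dataclass
class EvalMetrics:
    """Out-of-fold diagnosis metrics for one evaluation scheme."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    scheme: str
    n_repeats: int = 1
    per_repeat_accuracy: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 or np.isnan(v)):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class PrevalenceReport:
    """PPV/NPV of a test with known sensitivity/specificity at a prevalence."""

    prevalence: float
    ppv: float
    npv: float
    sensitivity: float
    specificity: float


def _metrics_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, fused: np.ndarray, scheme: str
) -> EvalMetrics:
    pos, neg = y_true == 1, y_true == 0
    sens = float(np.mean(y_pred[pos] == 1)) if pos.any() else np.nan
    spec = float(np.mean(y_pred[neg] == 0)) if neg.any() else np.nan
    acc = float(np.mean(y_pred == y_true))
    auc = roc_auc(fused, y_true) if pos.any() and neg.any() else np.nan
    return EvalMetrics(
        accuracy=acc, sensitivity=sens, specificity=spec, auc=auc, scheme=scheme
    )


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _stratified_folds(
    y: np.ndarray, n_splits: int, seed: int, max_attempts: int = 10
):
    """Stratified folds whose every training part contains both classes."""
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
    raise ValueError(
        f"could not build {n_splits} stratified folds with both classes "
        f"in every training part after {max_attempts} attempts"
    )


def run_cv(
    dataset: FeatureDataset,
    scheme: str = "LOSO",
    seed: int = 0,
    **fit_kwargs,
) -> EvalMetrics:
    """Cross-validated global diagnosis metrics.

    ``scheme`` is one of 2-fold / 4-fold / 10-fold / LOSO.  Each fold
    trains the full ensemble (including area selection) on the training
    part and diagnoses the held-out subjects; accuracy, sensitivity and
    specificity aggregate the pooled out-of-fold diagnoses, AUC the
    pooled fused membership scores.
    """
    y = dataset.binary_labels()
    n = len(y)
    if scheme == "LOSO":
        folds = [
            (np.delete(np.arange(n), i), np.array([i])) for i in range(n)
        ]
    elif scheme in SCHEMES:
        folds = _stratified_folds(y, SCHEMES[scheme], seed)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use {list(SCHEMES)} or 'LOSO'")
    ss = np.random.SeedSequence(seed)
    fold_seeds = [_child_seed(s) for s in ss.spawn(len(folds))]
    y_pred = np.zeros(n, dtype=int)
    fused = np.zeros(n)
    for (tr, te), fseed in zip(folds, fold_seeds):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("training fold contains a single class")
        clf = fit_cohort_classifier(dataset.subset(tr), seed=fseed, **fit_kwargs)
        _, fold_fused, fold_labels = score_cohort(clf, dataset.subset(te))
        fused[te] = fold_fused
        y_pred[te] = [1 if lab == ASD else 0 for lab in fold_labels]
    return _metrics_from_predictions(y, y_pred, fused, scheme)


def repeat_cv(
    dataset: FeatureDataset,
    scheme: str = "4-fold",
    n_repeats: int = 100,
    seed: int = 0,
    **fit_kwargs,
) -> dict:
    """Accuracy summary over independently re-folded repetitions.

    Returns {"min", "max", "mean", "sd"} of accuracy plus the per-repeat
    list; repeats use distinct seeds spawned from the root seed.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    ss = np.random.SeedSequence(seed)
    accs = [
        run_cv(dataset, scheme, seed=_child_seed(child), **fit_kwargs).accuracy
        for child in ss.spawn(n_repeats)
    ]
    accs = np.asarray(accs)
    return {
        "scheme": scheme,
        "n_repeats": n_repeats,
        "min": float(accs.min()),
        "max": float(accs.max()),
        "mean": float(accs.mean()),
        "sd": float(accs.std(ddof=1)),
        "per_repeat_accuracy": accs.tolist(),
    }


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = np.asarray(fractions, dtype=float) * n
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    for i in np.argsort(-remainder)[: n - sizes.sum()]:
        sizes[i] += 1
    return sizes.tolist()


def holdout_split(
    dataset: FeatureDataset,
    fractions: tuple[float, float, float] = (0.60, 0.15, 0.25),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test partition (default 60/15/25).

    Partition sizes come from largest-remainder rounding of the
    fractions; the three index arrays are disjoint and cover all
    subjects.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    y = dataset.binary_labels()
    n = len(y)
    n_train, n_val, n_test = _largest_remainder(n, fractions)
    if min(n_train, n_val, n_test) == 0:
        raise ValueError(
            f"partition sizes {n_train}/{n_val}/{n_test} include an empty partition"
        )
    idx = np.arange(n)
    rest, test = train_test_split(
        idx, test_size=n_test, stratify=y, random_state=seed
    )
    train, val = train_test_split(
        rest, test_size=n_val, stratify=y[rest], random_state=seed
    )
    return np.sort(train), np.sort(val), np.sort(test)


def _scheme_accuracy(
    dataset: FeatureDataset, scheme: str, seed: int, **fit_kwargs
) -> float:
    """Accuracy of the pipeline under one evaluation scheme."""
    if scheme == "holdout":
        tr_idx, val_idx, te_idx = holdout_split(dataset, seed=seed)
        clf = fit_cohort_classifier(
            dataset.subset(np.concatenate([tr_idx, val_idx])), seed=seed, **fit_kwargs
        )
        test = dataset.subset(te_idx)
        _, _, labels = score_cohort(clf, test)
        pred = np.array([1 if lab == ASD else 0 for lab in labels])
        return float(np.mean(pred == test.binary_labels()))
    return run_cv(dataset, scheme, seed=seed, **fit_kwargs).accuracy


def permutation_test(
    dataset: FeatureDataset,
    n_shuffles: int = 99,
    seed: int = 0,
    scheme: str = "4-fold",
    **fit_kwargs,
) -> dict:
    """Label-shuffling significance of the classifier's accuracy.

    The observed accuracy comes from the chosen evaluation scheme
    (default 4-fold cross-validation).  Each shuffle randomly permutes
    the labels the classifiers train on — simulating a completely
    uninformative dataset — and the same evaluation is repeated.  The
    p-value uses the add-one convention
    p = (1 + #{shuffled acc >= observed acc}) / (1 + n_shuffles),
    so with 99 shuffles the attainable minimum is 0.01.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    ss = np.random.SeedSequence(seed)
    fit_ss, shuffle_ss = ss.spawn(2)
    fit_seed = _child_seed(fit_ss)
    observed = _scheme_accuracy(dataset, scheme, fit_seed, **fit_kwargs)
    rng = np.random.default_rng(_child_seed(shuffle_ss))
    exceed = 0
    shuffled_accs = []
    for _ in range(n_shuffles):
        permuted = FeatureDataset(
            features=dataset.features,
            labels=rng.permutation(dataset.labels),
            area_ids=list(dataset.area_ids),
            subject_ids=list(dataset.subject_ids),
        )
        acc = _scheme_accuracy(permuted, scheme, fit_seed, **fit_kwargs)
        shuffled_accs.append(acc)
        if acc >= observed - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_shuffles)
    return {
        "p_value": p,
        "observed_accuracy": observed,
        "shuffled_accuracies": shuffled_accs,
        "n_shuffles": n_shuffles,
        "scheme": scheme,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve of membership scores.

    Equals the probability that a random ASD subject outscores a random
    TD subject, ties counted half.
    """
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        y = np.array([1 if str(v) == ASD else 0 for v in y])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for ROC analysis")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def predictive_values(
    sens: float, spec: float, prevalence: float
) -> PrevalenceReport:
    """Prevalence-adjusted predictive values of a diagnostic test.

    PPV = sens*prev / (sens*prev + (1-spec)(1-prev));
    NPV = spec(1-prev) / ((1-sens)prev + spec(1-prev)).
    """
    for name, v in (("sens", sens), ("spec", spec)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    ppv_den = sens * prevalence + (1.0 - spec) * (1.0 - prevalence)
    npv_den = (1.0 - sens) * prevalence + spec * (1.0 - prevalence)
    if ppv_den == 0 or npv_den == 0:
        raise ZeroDivisionError(
            "predictive value undefined: no positive (or negative) calls occur "
            f"at sens={sens}, spec={spec}, prevalence={prevalence}"
        )
    return PrevalenceReport(
        prevalence=prevalence,
        ppv=sens * prevalence / ppv_den,
        npv=spec * (1.0 - prevalence) / npv_den,
        sensitivity=sens,
        specificity=spec,
    )


def behavioral_correlation(
    area_scores: np.ndarray,
    behavioral_scores: np.ndarray,
    area_ids: list[int] | None = None,
) -> dict[int, tuple[float, float]]:
    """Pearson correlation of each area's membership score with behavior.

    ``area_scores`` is (n_subjects, n_areas); subjects with missing
    (NaN) behavioral scores are dropped.  Returns {area_id: (r, p)};
    zero-variance areas get (nan, nan) with a warning.
    """
    scores = np.atleast_2d(np.asarray(area_scores, dtype=float))
    behav = np.asarray(behavioral_scores, dtype=float)
    keep = np.isfinite(behav)
    if keep.sum() < 3:
        raise ValueError("need at least 3 subjects with behavioral scores")
    scores, behav = scores[keep], behav[keep]
    ids = area_ids or list(range(1, scores.shape[1] + 1))
    out: dict[int, tuple[float, float]] = {}
    for j, aid in enumerate(ids):
        col = scores[:, j]
        if col.std() == 0 or behav.std() == 0:
            warnings.warn(
                f"zero variance for area {aid}: correlation undefined", stacklevel=2
            )
            out[aid] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(col, behav)
        out[aid] = (float(r), float(p))
    return out
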