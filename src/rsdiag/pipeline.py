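"""End-to-end cohort pipeline: phantom volumes to per-area feature sets
and the fitted per-area classifier ensemble.

This module glues the stages together in the pipeline's canonical order: temporal
concatenation -> group PICA -> dual regression -> atlas matching ->
per-area PSD features -> per-area sparse autoencoder + probabilistic
SVM -> significant-area screening -> winner-takes-all fusion.  The
evaluation schemes (cross-validation, hold-out, permutation testing)
re-fit only the classifier ensemble per fold; the decomposition and
feature extraction are subject-wise and label-free, so they are
computed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rsdiag import atlas as atlas_mod
from rsdiag import decomposition as dec
from rsdiag import spectral_features as sf
from rsdiag.area_classifiers import (
    DEFAULT_BOX_CONSTRAINT,
    DEFAULT_KERNEL_SCALE,
    AreaSVM,
    SAEHyperParams,
    SparseAutoencoder,
    membership_score,
    train_area_svm,
    train_sae,
)
from rsdiag.diagnosis_fusion import (
    ASD,
    area_performance,
    global_diagnosis,
    select_significant_areas,
)
from rsdiag.phantom import PhantomSpec, simulate_cohort

__all__ = [
    "FeatureDataset",
    "CohortClassifier",
    "generic_metadata",
    "features_from_truth",
    "derive_features",
    "phantom_dataset",
    "fit_cohort_classifier",
    "score_cohort",
]


@dataclass
class FeatureDataset:
    """Per-subject, per-area PSD features with labels.

    ``features`` is (n_subjects, n_areas, n_bins); ``labels`` holds
    "ASD"/"TD"; ``behavioral`` is per-subject (NaN where absent).
    """

    features: np.ndarray
    labels: np.ndarray
    area_ids: list[int]
    subject_ids: list[str] = field(default_factory=list)
    behavioral: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 3:
            raise ValueError("features must be (n_subjects, n_areas, n_bins)")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("one label per subject required")
        if len(self.area_ids) != self.features.shape[1]:
            raise ValueError("area_ids must match the feature area axis")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(len(self.labels))]

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    def subset(self, idx) -> "FeatureDataset":
        idx = np.asarray(idx)
        return FeatureDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            area_ids=list(self.area_ids),
            subject_ids=[self.subject_ids[i] for i in idx],
            behavioral=None if self.behavioral is None else self.behavioral[idx],
        )

    def binary_labels(self) -> np.ndarray:
        return np.array([1 if lab == ASD else 0 for lab in self.labels])


def generic_metadata(n_areas: int) -> pd.DataFrame:
    """Metadata table for a phantom atlas of arbitrary size.

    Real 34-area runs use the reference table; phantoms at other sizes
    get synthetic names with sub-atlases assigned round-robin.
    """
    if n_areas == 34:
        return atlas_mod.default_metadata()
    subs = atlas_mod.SUB_ATLASES
    return pd.DataFrame(
        {
            "id": range(1, n_areas + 1),
            "sub_atlas": [subs[i % len(subs)] for i in range(n_areas)],
            "component": [f"P{i:02d}" for i in range(1, n_areas + 1)],
            "anatomical_area": [f"phantom area {i}" for i in range(1, n_areas + 1)],
        }
    )


def features_from_truth(
    truth, spec: PhantomSpec, n_bins: int = sf.DEFAULT_N_BINS
) -> FeatureDataset:
    """PSD features computed directly from the generating time courses.

    Bypasses decomposition; used for classifier-stage tests where the
    decomposition would only add estimation noise.
    """
    grid = sf.common_grid([spec.tr_seconds], n_bins=n_bins)
    n_sub, n_areas, _ = truth.source_timecourses.shape
    feats = np.zeros((n_sub, n_areas, n_bins))
    for s in range(n_sub):
        for a in range(n_areas):
            feats[s, a] = sf.compute_psd(
                truth.source_timecourses[s, a], spec.tr_seconds, grid=grid
            ).power
    return FeatureDataset(
        features=feats,
        labels=np.array(truth.labels),
        area_ids=list(range(1, n_areas + 1)),
        behavioral=truth.behavioral_score,
    )


def derive_features(
    volumes: list[np.ndarray],
    label_volume: np.ndarray,
    labels: list[str],
    tr_seconds: float,
    model_order: int | None = None,
    group_subset: list[int] | None = None,
    n_bins: int = sf.DEFAULT_N_BINS,
    seed: int = 0,
    behavioral: np.ndarray | None = None,
    smooth_fwhm_mm: float = 0.0,
):
    """Run decomposition + matching + feature extraction on a cohort.

    Returns (FeatureDataset, PICAModel, ComponentAssignment, registry).
    ``group_subset`` selects the subjects entering the group PICA
    (default: all); dual regression and features cover every subject.
    """
    registry = atlas_mod.build_registry(
        label_volume, generic_metadata(int(label_volume.max()))
    )
    if model_order is None:
        model_order = len(registry)
    if smooth_fwhm_mm > 0:
        volumes = [dec.smooth_gaussian(v, smooth_fwhm_mm) for v in volumes]
    data = dec.temporal_concat(volumes, group_subset)
    model = dec.fit_group_pica(data, model_order=model_order, seed=seed)
    assignment = atlas_mod.match_components(model.sources, registry)
    grid = sf.common_grid([tr_seconds], n_bins=n_bins)
    feats = []
    for vol in volumes:
        sub = dec.dual_regression(model.sources, vol)
        vecs = sf.extract_features(
            sub, assignment, registry, grid=grid, tr_seconds=tr_seconds
        )
        feats.append(sf.features_to_matrix(vecs))
    dataset = FeatureDataset(
        features=np.stack(feats),
        labels=np.array(labels),
        area_ids=registry.ids,
        behavioral=behavioral,
    )
    return dataset, model, assignment, registry


def phantom_dataset(
    spec: PhantomSpec,
    via_decomposition: bool = True,
    n_bins: int = sf.DEFAULT_N_BINS,
):
    """Simulate a cohort and produce its feature dataset.

    ``via_decomposition=True`` runs the full pipeline (concatenation,
    group PICA, dual regression, atlas matching); ``False`` shortcuts to
    PSDs of the generating time courses.
    """
    volumes, truth = simulate_cohort(spec)
    if not via_decomposition:
        return features_from_truth(truth, spec, n_bins=n_bins), truth
    dataset, *_ = derive_features(
        volumes,
        truth.label_volume,
        truth.labels,
        spec.tr_seconds,
        n_bins=n_bins,
        seed=spec.seed,
        behavioral=truth.behavioral_score,
    )
    return dataset, truth


@dataclass
class CohortClassifier:
    """Fitted per-area SAE + SVM ensemble with frozen area selection."""

    area_ids: list[int]
    saes: dict[int, SparseAutoencoder]
    svms: dict[int, AreaSVM]
    scalers: dict[int, tuple[np.ndarray, np.ndarray]]
    selected_areas: set[int]
    kernel_scale: float = DEFAULT_KERNEL_SCALE
    box_constraint: float = DEFAULT_BOX_CONSTRAINT


def _standardize(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (x - mean) / sd


def _fit_area(
    x: np.ndarray,
    y: np.ndarray,
    hyper: SAEHyperParams,
    kernel_scale: float,
    box_constraint: float,
    seed: int,
    sae_max_iter: int,
):
    """Standardise, encode and classify one area's feature block."""
    mean, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    xs = _standardize(x, mean, sd)
    sae = train_sae(xs, hyper, seed=seed, max_iter=sae_max_iter)
    svm = train_area_svm(
        sae.encode(xs), y, kernel_scale=kernel_scale, box_constraint=box_constraint
    )
    return sae, svm, (mean, sd)


def _oof_area_scores(
    dataset: FeatureDataset,
    y: np.ndarray,
    hyper: SAEHyperParams,
    kernel_scale: float,
    box_constraint: float,
    seed: int,
    sae_max_iter: int,
    n_folds: int,
) -> np.ndarray:
    """Out-of-fold membership scores per area via internal stratified CV."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros((dataset.n_subjects, len(dataset.area_ids)))
    for tr, te in skf.split(np.zeros(len(y)), y):
        for j in range(len(dataset.area_ids)):
            sae, svm, (mean, sd) = _fit_area(
                dataset.features[tr, j, :], y[tr], hyper,
                kernel_scale, box_constraint, seed, sae_max_iter,
            )
            xs_te = _standardize(dataset.features[te, j, :], mean, sd)
            scores[te, j] = membership_score(svm, sae.encode(xs_te))
    return scores


def fit_cohort_classifier(
    dataset: FeatureDataset,
    sae_hyper: SAEHyperParams | None = None,
    kernel_scale: float = DEFAULT_KERNEL_SCALE,
    box_constraint: float = DEFAULT_BOX_CONSTRAINT,
    seed: int = 0,
    sae_max_iter: int = 150,
    selection_threshold: float = 0.65,
    selection_cv: int | None = 4,
) -> CohortClassifier:
    """Train one sparse autoencoder + SVM per area on a labelled training set.

    Area features are standardised per bin (training statistics), the
    autoencoder is trained on the standardised PSDs, the SVM on the
    encoded features.  The significant-area screen (sensitivity and
    specificity > threshold) is computed on training data only and
    frozen into the returned classifier; by default each area's
    sensitivity/specificity come from internal ``selection_cv``-fold
    out-of-fold scores within the training set, which keeps the screen
    honest about areas the flexible kernel classifier merely memorises
    (``selection_cv=None`` scores the training set directly).
    """
    sae_hyper = sae_hyper or SAEHyperParams(hidden_size=8)
    y = dataset.binary_labels()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    saes, svms, scalers = {}, {}, {}
    train_scores = np.zeros((dataset.n_subjects, len(dataset.area_ids)))
    ss = np.random.SeedSequence(seed)
    area_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(dataset.area_ids))]
    for j, aid in enumerate(dataset.area_ids):
        sae, svm, scaler = _fit_area(
            dataset.features[:, j, :], y, sae_hyper,
            kernel_scale, box_constraint, area_seeds[j], sae_max_iter,
        )
        saes[aid], svms[aid], scalers[aid] = sae, svm, scaler
        xs = _standardize(dataset.features[:, j, :], *scaler)
        train_scores[:, j] = membership_score(svm, sae.encode(xs))
    min_class = int(min(np.sum(y == 1), np.sum(y == 0)))
    if selection_cv is not None and min_class >= selection_cv:
        selection_scores = _oof_area_scores(
            dataset, y, sae_hyper, kernel_scale, box_constraint,
            seed, sae_max_iter, selection_cv,
        )
    else:
        selection_scores = train_scores
    perfs = area_performance(selection_scores, y, area_ids=list(dataset.area_ids))
    selected = select_significant_areas(perfs, threshold=selection_threshold)
    return CohortClassifier(
        area_ids=list(dataset.area_ids),
        saes=saes,
        svms=svms,
        scalers=scalers,
        selected_areas=selected,
        kernel_scale=kernel_scale,
        box_constraint=box_constraint,
    )


def score_cohort(
    clf: CohortClassifier, dataset: FeatureDataset
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Score every subject of a dataset with a fitted ensemble.

    Returns (area score matrix (n_subjects, n_areas), fused mean score
    over the selected areas, global labels).
    """
    n = dataset.n_subjects
    scores = np.zeros((n, len(clf.area_ids)))
    for j, aid in enumerate(clf.area_ids):
        mean, sd = clf.scalers[aid]
        xs = _standardize(dataset.features[:, j, :], mean, sd)
        scores[:, j] = membership_score(clf.svms[aid], clf.saes[aid].encode(xs))
    fused = np.zeros(n)
    labels = []
    for i in range(n):
        area_scores = dict(zip(clf.area_ids, scores[i]))
        label, m = global_diagnosis(area_scores, clf.selected_areas)
        fused[i] = m
        labels.append(label)
    return scores, fused, labels
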