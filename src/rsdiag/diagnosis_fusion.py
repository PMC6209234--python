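"""Area screening, winner-takes-all fusion and the personalized report.

Each atlas area's stand-alone classifier is assessed by its sensitivity
and specificity on labelled training data; areas clearing an empirical
threshold of 0.65 on both are the "significant" areas.  A subject's
global diagnosis averages the membership scores of the significant
areas: the class with the larger average wins (winner takes all), with
an exact 0.5 tie resolved conservatively to TD.  The personalized
report presents the raw per-area membership scores with an equal-width
blue-to-red colour binning: blue = least, red = most autism-class
membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AreaPerformance",
    "PersonalizedReport",
    "area_performance",
    "select_significant_areas",
    "global_diagnosis",
    "personalized_report",
]

SIGNIFICANCE_THRESHOLD = 0.65
SCORE_THRESHOLD = 0.5
ASD, TD = "ASD", "TD"


@dataclass(frozen=True)
class AreaPerformance:
    """Stand-alone diagnostic performance of one atlas area."""

    area_id: int
    sensitivity: float
    specificity: float


@dataclass
class PersonalizedReport:
    """Per-subject area membership scores with colour bins and global label."""

    subject_id: str
    area_ids: list[int]
    scores: np.ndarray
    color_bins: np.ndarray
    global_label: str
    n_bins: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "area_id": self.area_ids,
                "membership_score": self.scores,
                "color_bin": self.color_bins,
                "global_label": self.global_label,
            }
        )


def area_performance(
    scores: dict[int, np.ndarray] | np.ndarray,
    labels: np.ndarray,
    threshold: float = SCORE_THRESHOLD,
    area_ids: list[int] | None = None,
) -> list[AreaPerformance]:
    """Sensitivity and specificity of each area's stand-alone diagnosis.

    ``scores`` maps area id to per-subject membership scores (or is an
    (n_subjects, n_areas) array); ``labels`` holds "ASD"/"TD" (or 1/0).
    A subject is called ASD by an area when its score >= threshold;
    sensitivity = TP/(TP+FN) on ASD subjects, specificity = TN/(TN+FP)
    on TD subjects.
    """
    y = _binary_labels(labels)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present to compute sensitivity/specificity")
    if isinstance(scores, np.ndarray):
        ids = area_ids or list(range(1, scores.shape[1] + 1))
        scores = {aid: scores[:, j] for j, aid in enumerate(ids)}
    out = []
    for aid in sorted(scores):
        s = np.asarray(scores[aid], dtype=float)
        called_asd = s >= threshold
        sens = float(np.mean(called_asd[y == 1]))
        spec = float(np.mean(~called_asd[y == 0]))
        out.append(AreaPerformance(area_id=aid, sensitivity=sens, specificity=spec))
    return out


def _binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        return np.array([1 if str(v) == ASD else 0 for v in arr])
    return arr.astype(int)


def select_significant_areas(
    performances: list[AreaPerformance],
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> set[int]:
    """Areas with BOTH sensitivity and specificity strictly above the threshold.

    An empty selection falls back to all areas with a warning so the
    fusion stage always has input.
    """
    selected = {
        p.area_id
        for p in performances
        if p.sensitivity > threshold and p.specificity > threshold
    }
    if not selected:
        warnings.warn(
            f"no area clears sensitivity and specificity > {threshold}; "
            "falling back to all areas",
            stacklevel=2,
        )
        selected = {p.area_id for p in performances}
    return selected


def global_diagnosis(
    area_scores: dict[int, float], selected_areas: set[int]
) -> tuple[str, float]:
    """Winner-takes-all fusion of one subject's selected-area scores.

    Averages the membership scores of the significant areas; the class
    with the larger average wins (ASD iff mean > 0.5; an exact tie goes
    to TD).  Returns (label, mean score).
    """
    if not selected_areas:
        raise ValueError("selected_areas must be nonempty")
    missing = set(selected_areas) - set(area_scores)
    if missing:
        raise KeyError(f"missing scores for selected areas {sorted(missing)}")
    m = float(np.mean([area_scores[a] for a in sorted(selected_areas)]))
    return (ASD if m > 0.5 else TD), m


def personalized_report(
    subject_scores: dict[int, float],
    fusion_result: str | tuple[str, float],
    subject_id: str = "subject",
    n_bins: int = 8,
) -> PersonalizedReport:
    """Colour-coded per-area report for one subject.

    Scores (already in [0, 1]) are binned into ``n_bins`` equal-width
    half-open bins over [0, 1] (last bin closed), bin 0 = coldest blue =
    least autism-class membership, the top bin = hottest red = most.
    """
    ids = sorted(subject_scores)
    scores = np.array([subject_scores[a] for a in ids], dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("membership scores must lie in [0, 1]")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    bins = np.minimum((scores * n_bins).astype(int), n_bins - 1)
    label = fusion_result if isinstance(fusion_result, str) else fusion_result[0]
    return PersonalizedReport(
        subject_id=subject_id,
        area_ids=ids,
        scores=scores,
        color_bins=bins,
        global_label=label,
        n_bins=n_bins,
    )
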