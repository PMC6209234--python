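"""Power-spectral-density features of per-area BOLD time courses.

PSDs are the classifier's input representation: they describe the
low-frequency BOLD oscillations of each matched atlas area and are
invariant to circular time shifts, so the same activation occurring at
different latencies in different subjects yields the same feature
vector.  The default estimator is the full-length periodogram with mean
removal, which keeps the shift invariance exact; Welch averaging is
available as an option for variance reduction.  Features from cohorts
with mixed repetition times are interpolated onto a common frequency
grid spanning 0 to the smallest Nyquist frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "PSDVector",
    "compute_psd",
    "common_grid",
    "extract_features",
    "features_to_matrix",
]

DEFAULT_N_BINS = 32


@dataclass
class PSDVector:
    """One area's power spectrum on a frequency grid.

    ``power`` has units (signal units)^2 / Hz; the grid never extends
    beyond the series' Nyquist frequency 1/(2 TR).
    """

    area_id: int
    frequencies: np.ndarray
    power: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.frequencies[0] < 0:
            raise ValueError("frequencies must be non-negative")
        nyq = 1.0 / (2.0 * self.tr_seconds)
        if self.frequencies[-1] > nyq + 1e-9:
            raise ValueError(
                f"max frequency {self.frequencies[-1]:.4g} exceeds Nyquist {nyq:.4g}"
            )
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def compute_psd(
    timecourse: np.ndarray,
    tr_seconds: float,
    grid: np.ndarray | None = None,
    area_id: int = 0,
    estimator: str = "periodogram",
    nperseg: int | None = None,
) -> PSDVector:
    """Estimate the one-sided PSD of a time course.

    With ``estimator="periodogram"`` the full-length, mean-removed
    periodogram is used (exactly circular-shift invariant; total power
    sum * df equals the series variance).  ``estimator="welch"`` gives
    Hann-windowed segment averaging.  If ``grid`` is supplied the
    spectrum is linearly interpolated onto it; the grid must stay at or
    below the series' Nyquist frequency.  A constant series yields an
    all-zero spectrum with a warning.
    """
    x = np.asarray(timecourse, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("timecourse must be 1D with at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("timecourse contains non-finite values")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    fs = 1.0 / tr_seconds
    if np.ptp(x) == 0:
        warnings.warn("constant time course: returning a zero spectrum", stacklevel=2)
        freqs = np.fft.rfftfreq(x.size, d=tr_seconds)
        power = np.zeros_like(freqs)
    elif estimator == "periodogram":
        freqs, power = signal.periodogram(
            x, fs=fs, window="boxcar", detrend="constant", scaling="density"
        )
    elif estimator == "welch":
        freqs, power = signal.welch(
            x, fs=fs, nperseg=nperseg or min(x.size, 64), detrend="constant"
        )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        if grid[-1] > fs / 2 + 1e-9:
            raise ValueError("requested grid extends above the series' Nyquist")
        power = np.interp(grid, freqs, power)
        freqs = grid
    return PSDVector(
        area_id=area_id, frequencies=freqs, power=power, tr_seconds=tr_seconds
    )


def common_grid(
    tr_values: list[float], n_bins: int = DEFAULT_N_BINS, f_min: float = 0.0
) -> np.ndarray:
    """Shared frequency grid for a cohort with possibly mixed TRs.

    Spans [f_min, min Nyquist] with ``n_bins`` points so subjects
    acquired at different repetition times land on comparable features.
    """
    if not tr_values:
        raise ValueError("need at least one TR value")
    nyq = min(1.0 / (2.0 * tr) for tr in tr_values)
    return np.linspace(f_min, nyq, n_bins)


def extract_features(
    subject_decomposition,
    assignment,
    registry,
    grid: np.ndarray | None = None,
    tr_seconds: float = 2.0,
    estimator: str = "periodogram",
) -> list[PSDVector]:
    """One PSD feature vector per atlas area for one subject.

    Each area's matched decomposition time course (per the component
    assignment) is converted to a PSD on the pipeline's common grid.
    """
    if grid is None:
        grid = common_grid([tr_seconds])
    features = []
    for comp in registry.components:
        if comp.id not in assignment.map_index:
            raise KeyError(f"no matched map for atlas area {comp.id} ({comp.name})")
        m = assignment.map_index[comp.id]
        if m is None or m >= subject_decomposition.timecourses.shape[0]:
            raise KeyError(
                f"matched map {m} for area {comp.id} not present in decomposition"
            )
        features.append(
            compute_psd(
                subject_decomposition.timecourses[m],
                tr_seconds=tr_seconds,
                grid=grid,
                area_id=comp.id,
                estimator=estimator,
            )
        )
    return features


def features_to_matrix(features: list[PSDVector]) -> np.ndarray:
    """Stack per-area PSDs into an (n_areas, n_bins) array ordered by area id."""
    feats = sorted(features, key=lambda f: f.area_id)
    return np.vstack([f.power for f in feats])
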