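"""Synthetic BOLD cohort generator.

The phantom emulates the generative structure the decomposition stage
assumes: every voxel's time series is a linear mixture of spatial source
maps and band-limited source time courses plus i.i.d. Gaussian noise,

    x_i(t) = sum_a  M[a, i] * s_a(t) + eta_i(t),   eta ~ N(0, sigma^2).

Each spatial source is a smooth positive blob supported on one label of
a phantom atlas volume, so atlas matching and per-area recovery can be
tested against known ground truth.  Group differences are injected as a
multiplicative in-band spectral-power shift in designated "affected"
areas of ASD subjects — the effect lives in the PSD feature space the
classifier consumes, not in the signal mean.  Behavioral scores for ASD
subjects depend linearly (positive slope) on each subject's injected
effect magnitude, so sign recovery of score/behavior correlations is
testable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_label_volume",
    "simulate_timecourse",
    "simulate_cohort",
    "save_cohort",
]

#: Default BOLD low-frequency band (Hz) carrying resting-state power.
DEFAULT_BAND = (0.01, 0.08)

#: Baseline in-band power of each source time course (signal units^2).
BASE_POWER = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic resting-state cohort.

    Attributes
    ----------
    grid_shape:
        Voxel grid (nx, ny, nz).
    n_timepoints:
        Frames per subject.
    tr_seconds:
        Repetition time (seconds per frame).
    n_areas:
        Number of atlas areas / spatial sources (default 34).
    affected_areas:
        1-based ids of areas whose ASD in-band power is shifted.
    effect_size:
        Relative in-band power shift: an affected area's power in an ASD
        subject is ``(1 + effect_size * gain)`` times the TD baseline,
        where ``gain`` is a per-subject severity draw.  ``0`` makes the
        two groups exchangeable by construction.
    noise_sigma:
        Standard deviation of the additive voxel noise.
    n_asd, n_td:
        Group sizes; subjects are ordered ASD first, then TD.
    seed:
        Root seed; the whole cohort is a pure function of the spec.
    band_hz:
        Frequency band of the source time courses.
    behavioral_intercept, behavioral_slope, behavioral_noise_sd:
        ADOS-like score model for ASD subjects:
        ``a + b * (summed injected effect) + N(0, sd^2)`` with b > 0.
    """

    grid_shape: tuple[int, int, int] = (30, 30, 20)
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    n_areas: int = 34
    affected_areas: frozenset[int] = field(default_factory=frozenset)
    effect_size: float = 0.0
    noise_sigma: float = 0.5
    n_asd: int = 20
    n_td: int = 20
    seed: int = 0
    band_hz: tuple[float, float] = DEFAULT_BAND
    behavioral_intercept: float = 8.0
    behavioral_slope: float = 1.0
    behavioral_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.n_timepoints <= 0:
            raise ValueError("n_timepoints must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_areas <= 0:
            raise ValueError("n_areas must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_asd < 0 or self.n_td < 0:
            raise ValueError("group sizes must be non-negative")
        object.__setattr__(self, "affected_areas", frozenset(self.affected_areas))
        bad = set(self.affected_areas) - set(range(1, self.n_areas + 1))
        if bad:
            raise ValueError(f"affected_areas {sorted(bad)} outside 1..{self.n_areas}")
        if self.behavioral_slope < 0:
            raise ValueError("behavioral_slope must be non-negative")

    @property
    def n_subjects(self) -> int:
        return self.n_asd + self.n_td

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["affected_areas"] = sorted(self.affected_areas)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GroundTruth:
    """Generating quantities of a simulated cohort.

    ``source_maps`` is (n_areas, n_voxels) over the flattened grid;
    ``source_timecourses`` is (n_subjects, n_areas, n_timepoints);
    ``labels`` holds "ASD"/"TD" per subject (ASD first);
    ``behavioral_score`` is per-subject, NaN for TD subjects;
    ``injected_effect`` is each subject's summed injected effect
    magnitude (0 for TD).
    """

    label_volume: np.ndarray
    source_maps: np.ndarray
    source_timecourses: np.ndarray
    labels: list[str]
    behavioral_score: np.ndarray
    injected_effect: np.ndarray


def make_label_volume(
    grid_shape: Sequence[int], n_areas: int, seed: int
) -> np.ndarray:
    """Place ``n_areas`` disjoint, contiguous spherical blobs on a grid.

    The grid is partitioned into a lattice of cells, one candidate cell
    per area; each area becomes a ball centred in its cell (with a small
    seeded jitter), guaranteeing disjointness and contiguity.  Returns an
    integer volume with 0 background and labels ``1..n_areas``.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if n_areas <= 0:
        raise ValueError("n_areas must be positive")
    # Cells of at least 3 voxels a side so every ball (radius >= 1) fits.
    min_cell = 3
    divs = np.maximum(np.asarray(grid_shape) // min_cell, 1)
    n_cells = int(np.prod(divs))
    if n_cells < n_areas:
        raise ValueError(
            f"grid {grid_shape} too small for {n_areas} areas "
            f"(only {n_cells} placement cells of {min_cell}^3 voxels)"
        )
    rng = np.random.default_rng(seed)
    cell_ids = rng.permutation(n_cells)[:n_areas]
    vol = np.zeros(grid_shape, dtype=np.int32)
    ii, jj, kk = np.indices(grid_shape)
    for area, cid in enumerate(cell_ids, start=1):
        cidx = np.unravel_index(cid, tuple(divs))
        lo = [int(c * g // d) for c, g, d in zip(cidx, grid_shape, divs)]
        hi = [int((c + 1) * g // d) for c, g, d in zip(cidx, grid_shape, divs)]
        size = np.array(hi) - np.array(lo)
        radius = max(size.min() / 2.0 - 0.5, 1.0)
        centre = np.array(lo) + size / 2.0
        jitter = rng.uniform(-0.25, 0.25, size=3) * size
        centre = np.clip(centre + jitter, np.array(lo) + radius, np.array(hi) - radius)
        dist2 = (
            (ii - centre[0]) ** 2 + (jj - centre[1]) ** 2 + (kk - centre[2]) ** 2
        )
        ball = dist2 <= radius**2
        if not ball.any():  # degenerate cell: fall back to the centre voxel
            ball = dist2 == dist2.min()
        vol[ball & (vol == 0)] = area
    counts = np.bincount(vol.ravel(), minlength=n_areas + 1)
    if (counts[1:] == 0).any():
        missing = np.nonzero(counts[1:] == 0)[0] + 1
        raise ValueError(f"failed to place areas {missing.tolist()} on grid {grid_shape}")
    return vol


def simulate_timecourse(
    band_low_hz: float,
    band_high_hz: float,
    power: float,
    n_timepoints: int,
    tr_seconds: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Zero-mean series with total power ``power`` inside the band.

    Built as a random-phase sum of Fourier modes whose bin frequencies
    fall in [band_low, band_high], then rescaled so the series variance
    (= total periodogram power) equals ``power`` exactly.
    """
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 <= band_low_hz < band_high_hz):
        raise ValueError("need 0 <= band_low < band_high")
    if band_high_hz > nyquist + 1e-12:
        raise ValueError(
            f"band_high {band_high_hz} Hz above Nyquist {nyquist:.4g} Hz for TR {tr_seconds}s"
        )
    if power < 0:
        raise ValueError("power must be non-negative")
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    in_band = (freqs >= band_low_hz - 1e-12) & (freqs <= band_high_hz + 1e-12)
    in_band[0] = False  # never put power in DC
    if not in_band.any():
        raise ValueError("no Fourier bin inside the requested band; lengthen the series")
    spectrum = np.zeros(len(freqs), dtype=complex)
    n_modes = int(in_band.sum())
    amp = rng.uniform(0.5, 1.0, size=n_modes)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
    spectrum[in_band] = amp * np.exp(1j * phase)
    series = np.fft.irfft(spectrum, n=n_timepoints)
    series -= series.mean()
    if power == 0:
        return np.zeros(n_timepoints)
    var = series.var()
    if var == 0:  # pragma: no cover - cannot happen with nonzero amplitudes
        raise RuntimeError("degenerate zero-variance draw")
    return series * np.sqrt(power / var)


def _source_maps(label_volume: np.ndarray, n_areas: int) -> np.ndarray:
    """Smooth positive blob weights, one map per atlas label.

    Weight decays with distance from the blob's centroid and is zero
    outside the label, so each map's support matches its atlas area.
    """
    flat_labels = label_volume.ravel()
    maps = np.zeros((n_areas, flat_labels.size))
    coords = np.column_stack([c.ravel() for c in np.indices(label_volume.shape)])
    for area in range(1, n_areas + 1):
        inside = flat_labels == area
        pts = coords[inside]
        centre = pts.mean(axis=0)
        d2 = ((pts - centre) ** 2).sum(axis=1)
        scale = max(d2.max(), 1.0)
        maps[area - 1, inside] = np.exp(-d2 / scale)
    return maps


def simulate_cohort(spec: PhantomSpec) -> tuple[list[np.ndarray], GroundTruth]:
    """Simulate a labelled cohort of 4D BOLD phantoms.

    Returns a list of (nx, ny, nz, n_timepoints) float arrays (ASD
    subjects first, then TD) and the :class:`GroundTruth` that generated
    them.  Identical specs produce bit-identical outputs.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_labels, ss_subjects = root.spawn(2)
    label_volume = make_label_volume(
        spec.grid_shape, spec.n_areas, int(ss_labels.generate_state(1)[0] % (2**31))
    )
    maps = _source_maps(label_volume, spec.n_areas)
    n_vox = maps.shape[1]
    affected = sorted(spec.affected_areas)
    labels = ["ASD"] * spec.n_asd + ["TD"] * spec.n_td

    volumes: list[np.ndarray] = []
    timecourses = np.zeros((spec.n_subjects, spec.n_areas, spec.n_timepoints))
    behavioral = np.full(spec.n_subjects, np.nan)
    injected = np.zeros(spec.n_subjects)
    for s, sub_ss in enumerate(ss_subjects.spawn(spec.n_subjects)):
        rng = np.random.default_rng(sub_ss)
        is_asd = labels[s] == "ASD"
        gain = rng.uniform(0.5, 1.5) if is_asd else 0.0
        for a in range(1, spec.n_areas + 1):
            power = BASE_POWER
            if is_asd and a in spec.affected_areas:
                power *= 1.0 + spec.effect_size * gain
            timecourses[s, a - 1] = simulate_timecourse(
                spec.band_hz[0],
                spec.band_hz[1],
                power,
                spec.n_timepoints,
                spec.tr_seconds,
                rng,
            )
        data = timecourses[s].T @ maps  # (time, voxels)
        if spec.noise_sigma > 0:
            data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
        volumes.append(
            np.ascontiguousarray(
                data.T.reshape(spec.grid_shape + (spec.n_timepoints,))
            )
        )
        if is_asd:
            injected[s] = spec.effect_size * gain * max(len(affected), 1)
            behavioral[s] = (
                spec.behavioral_intercept
                + spec.behavioral_slope * injected[s]
                + rng.normal(0.0, spec.behavioral_noise_sd)
            )
    truth = GroundTruth(
        label_volume=label_volume,
        source_maps=maps,
        source_timecourses=timecourses,
        labels=labels,
        behavioral_score=behavioral,
        injected_effect=injected,
    )
    assert maps.shape == (spec.n_areas, n_vox)
    return volumes, truth


def save_cohort(
    volumes: list[np.ndarray],
    truth: GroundTruth,
    spec: PhantomSpec,
    out_dir,
) -> None:
    """Write a cohort to disk: NIfTI volumes + labels, TSV truth, JSON spec."""
    import pandas as pd

    from rsdiag import io_cli

    out_dir.mkdir(parents=True, exist_ok=True)
    io_cli.write_nifti(out_dir / "atlas_labels.nii", truth.label_volume.astype(np.int16))
    for s, vol in enumerate(volumes):
        io_cli.write_nifti(
            out_dir / f"sub-{s:03d}_bold.nii", vol, tr_seconds=spec.tr_seconds
        )
    pd.DataFrame(
        {
            "subject": [f"sub-{s:03d}" for s in range(len(volumes))],
            "group": truth.labels,
            "behavioral_score": truth.behavioral_score,
            "injected_effect": truth.injected_effect,
        }
    ).to_csv(out_dir / "participants.tsv", sep="\t", index=False)
    (out_dir / "phantom_spec.json").write_text(spec.to_json())
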