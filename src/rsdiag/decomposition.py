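"""Group probabilistic ICA, dual regression and group-difference testing.

The decomposition treats each voxel's BOLD series as a noisy linear
mixture of spatial sources,

    x_i = A s_i + eta_i,    eta_i ~ N(0, sigma^2 I),

and estimates the unmixing operator W with an explicit isotropic noise
term: PCA reduction of the temporally concatenated data to the model
order, probabilistic whitening using eigenvalues shrunk by the noise
floor, a negentropy-maximising fixed-point ICA rotation, and an outer
loop that re-estimates sigma^2 from the mixture residuals until it
stabilises.  Subject-specific time courses and maps are then obtained
with two-stage dual regression against the group spatial maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.decomposition import FastICA

__all__ = [
    "PICAModel",
    "SubjectDecomposition",
    "temporal_concat",
    "fit_group_pica",
    "dual_regression",
    "group_difference_test",
    "smooth_gaussian",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PICAModel:
    """Fitted group decomposition.

    ``mixing`` is (total timepoints, K); ``sources`` is (K, n_voxels);
    ``unmixing`` maps a (timepoints, n_voxels) data matrix to source
    space; ``noise_variance`` is the isotropic residual variance.
    """

    mixing: np.ndarray
    sources: np.ndarray
    unmixing: np.ndarray
    noise_variance: float
    model_order: int
    converged: bool = True
    n_iterations: int = 0

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Apply the unmixing operator: (timepoints, n_voxels) -> (K, n_voxels)."""
        x = data - data.mean(axis=1, keepdims=True)
        return self.unmixing @ x


@dataclass
class SubjectDecomposition:
    """Subject-specific time courses (K, T) and spatial maps (K, n_voxels)."""

    timecourses: np.ndarray
    maps: np.ndarray

    @property
    def model_order(self) -> int:
        return self.timecourses.shape[0]


def temporal_concat(
    subject_volumes: list[np.ndarray], subset: list[int] | None = None
) -> np.ndarray:
    """Row-stack variance-normalised subjects into a (time, voxels) matrix.

    Each subject's 4D volume is flattened to (timepoints, voxels), each
    voxel series is demeaned and scaled to unit variance (constant
    voxels are left at zero), and the subjects in ``subset`` (default:
    all, in order) are stacked along the time axis.
    """
    if subset is None:
        subset = list(range(len(subject_volumes)))
    if len(subset) == 0:
        raise ValueError("subject subset is empty")
    grid = subject_volumes[subset[0]].shape[:3]
    rows = []
    for s in subset:
        vol = subject_volumes[s]
        if vol.shape[:3] != grid:
            raise ValueError(
                f"subject {s} grid {vol.shape[:3]} does not match {grid}"
            )
        data = vol.reshape(-1, vol.shape[3]).T.astype(float)  # (T, V)
        data = data - data.mean(axis=0, keepdims=True)
        sd = data.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        rows.append(data / sd)
    return np.vstack(rows)


def _probabilistic_whiten(
    data: np.ndarray, model_order: int, sigma2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA-reduce (time, voxels) data and whiten with noise-shrunk eigenvalues.

    Returns (whitened data (K, V), whitening matrix (K, T), eigenvalues).
    """
    t_dim, n_vox = data.shape
    cov = (data @ data.T) / n_vox
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    lead = eigvals[:model_order]
    scale = np.sqrt(np.maximum(lead - sigma2, 1e-12))
    whiten = (eigvecs[:, :model_order] / scale).T  # (K, T)
    return whiten @ data, whiten, eigvals


def fit_group_pica(
    data: np.ndarray,
    model_order: int = 34,
    max_iter: int = 20,
    tol: float = 1e-4,
    seed: int = 0,
    ica_max_iter: int = 500,
    ica_tol: float = 1e-5,
) -> PICAModel:
    """Fit the noisy-ICA decomposition to concatenated group data.

    ``data`` is (total timepoints, n_voxels).  The isotropic noise
    variance is initialised from the mean of the eigenvalues discarded
    by the PCA reduction and refined by re-estimating it from the
    residuals of the current mixture fit; the ICA rotation is recomputed
    at each outer iteration.  The fit is deterministic given ``seed``.
    """
    data = np.asarray(data, dtype=float)
    t_dim, n_vox = data.shape
    if model_order > min(t_dim, n_vox):
        raise ValueError(
            f"model_order {model_order} exceeds data rank bound {min(t_dim, n_vox)}"
        )
    x = data - data.mean(axis=1, keepdims=True)  # remove mean image per timepoint

    # Noise floor initialised from the discarded PCA subspace.
    _, _, eigvals = _probabilistic_whiten(x, model_order, 0.0)
    discarded = eigvals[model_order:]
    sigma2 = float(discarded.mean()) if discarded.size else 0.0

    sources = mixing = unmixing = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z, whiten, _ = _probabilistic_whiten(x, model_order, sigma2)
        ica = FastICA(
            n_components=model_order,
            whiten=False,
            fun="logcosh",
            max_iter=ica_max_iter,
            tol=ica_tol,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # FastICA convergence handled below
            sources = ica.fit_transform(z.T).T  # (K, V)
        # Fix source scale (unit variance per spatial map) and sign
        # (positive skewness: blob-like activations point upward).
        sd = sources.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        centred = sources - sources.mean(axis=1, keepdims=True)
        skew_sign = np.sign(np.mean((centred / sd) ** 3, axis=1, keepdims=True))
        skew_sign[skew_sign == 0] = 1.0
        sources = sources * skew_sign / sd
        unmixing = (ica.components_ * skew_sign / sd) @ whiten  # (K, T): s = W x
        mixing, *_ = np.linalg.lstsq(sources.T, x.T, rcond=None)
        mixing = mixing.T  # (T, K)
        resid = x - mixing @ sources
        sigma2_new = float(np.mean(resid**2))
        if abs(sigma2_new - sigma2) < tol * max(sigma2, 1e-12):
            sigma2 = sigma2_new
            converged = True
            break
        sigma2 = sigma2_new
    if not converged:
        warnings.warn(
            f"noise-variance loop did not converge in {max_iter} iterations "
            f"(last sigma^2 = {sigma2:.4g})",
            stacklevel=2,
        )
    return PICAModel(
        mixing=mixing,
        sources=sources,
        unmixing=unmixing,
        noise_variance=sigma2,
        model_order=model_order,
        converged=converged,
        n_iterations=it,
    )


def _name_collinear(design: np.ndarray) -> list[int]:
    """Indices of design columns implicated in a rank deficiency."""
    _, s, vt = np.linalg.svd(design, full_matrices=False)
    null = vt[s < s.max() * 1e-10]
    if null.size == 0:
        return []
    weight = np.abs(null).max(axis=0)
    return sorted(np.nonzero(weight > 0.1 * weight.max())[0].tolist())


def dual_regression(
    group_sources: np.ndarray, subject_volume: np.ndarray
) -> SubjectDecomposition:
    """Two-stage least squares against the group spatial maps.

    Stage 1 regresses every timepoint's voxel vector on the K group maps
    to obtain K subject time courses; stage 2 regresses every voxel's
    series on those time courses to obtain K subject spatial maps.
    """
    sources = np.atleast_2d(np.asarray(group_sources, dtype=float))
    k, n_vox = sources.shape
    if subject_volume.ndim == 4:
        data = subject_volume.reshape(-1, subject_volume.shape[3]).T.astype(float)
    else:
        data = np.asarray(subject_volume, dtype=float)  # already (T, V)
    if data.shape[1] != n_vox:
        raise ValueError(
            f"subject has {data.shape[1]} voxels, group maps have {n_vox}"
        )
    design1 = sources.T  # (V, K)
    if np.linalg.matrix_rank(design1) < k:
        raise np.linalg.LinAlgError(
            "group spatial maps are collinear; components "
            f"{_name_collinear(design1)} are linearly dependent"
        )
    timecourses, *_ = np.linalg.lstsq(design1, data.T, rcond=None)  # (K, T)
    design2 = timecourses.T  # (T, K)
    if np.linalg.matrix_rank(design2) < k:
        raise np.linalg.LinAlgError(
            "stage-1 time courses are collinear; components "
            f"{_name_collinear(design2)} are linearly dependent"
        )
    maps, *_ = np.linalg.lstsq(design2, data, rcond=None)  # (K, V)
    return SubjectDecomposition(timecourses=timecourses, maps=maps)


def group_difference_test(
    subject_maps: np.ndarray,
    labels: list[str],
    n_permutations: int = 999,
    alpha: float = 0.05,
    masks: list[np.ndarray] | None = None,
    seed: int = 0,
) -> dict:
    """Permutation test of per-component group differences, Bonferroni-corrected.

    ``subject_maps`` is (n_subjects, K, n_voxels).  Each subject map is
    summarised as its mean value within the component's mask (default:
    all voxels); the statistic is the ASD-minus-TD difference of group
    means.  Two-sided permutation p-values use the add-one convention
    p = (1 + #{|perm| >= |obs|}) / (1 + n_permutations); a component is
    significant when p <= alpha / K.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    maps = np.asarray(subject_maps, dtype=float)
    n_sub, k, _ = maps.shape
    labels = list(labels)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    counts = {g: labels.count(g) for g in groups}
    if min(counts.values()) < 2:
        raise ValueError("need at least 2 subjects per group")
    if masks is None:
        summaries = maps.mean(axis=2)  # (n_sub, K)
    else:
        if len(masks) != k:
            raise ValueError("one mask per component required")
        summaries = np.column_stack(
            [maps[:, c, np.asarray(masks[c])].mean(axis=1) for c in range(k)]
        )
    is_a = np.array([lab == groups[0] for lab in labels])

    def stat(members: np.ndarray) -> np.ndarray:
        return summaries[members].mean(axis=0) - summaries[~members].mean(axis=0)

    observed = stat(is_a)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(k, dtype=int)
    for _ in range(n_permutations):
        exceed += np.abs(stat(rng.permutation(is_a))) >= np.abs(observed) - 1e-15
    pvals = (1.0 + exceed) / (1.0 + n_permutations)
    threshold = alpha / k
    return {
        "statistic": observed,
        "p_values": pvals,
        "bonferroni_alpha": threshold,
        "significant": pvals <= threshold,
    }


def smooth_gaussian(
    volume: np.ndarray,
    fwhm_mm: float = 2.0,
    voxel_size_mm: float | tuple[float, float, float] = 1.0,
) -> np.ndarray:
    """Spatial Gaussian smoothing of a 3D or 4D volume.

    sigma (voxels) = FWHM / (2 sqrt(2 ln 2)) / voxel size, per axis;
    fwhm = 0 is the identity.  For 4D input each frame is smoothed
    independently (no temporal blurring).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return np.array(volume, dtype=float, copy=True)
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma = fwhm_mm * FWHM_TO_SIGMA / vox
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 3:
        return ndimage.gaussian_filter(vol, sigma=sigma, mode="nearest")
    if vol.ndim == 4:
        return ndimage.gaussian_filter(
            vol, sigma=(*sigma, 0.0), mode="nearest"
        )
    raise ValueError("volume must be 3D or 4D")
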