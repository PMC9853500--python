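"""Feature-matrix construction for the fingerprint classifier.

Per-sample peak lists are tabulated into a samples x m/z-bins matrix of
relative intensities (absent peak -> 0).  The database is then cleaned
by the variance filter — only bins whose sample variance (n-1
denominator) of relative intensity exceeds 1 strictly are kept — and
standardized per column (Z-scaling).  Behavioral outcome columns
(``PTD`` = mean plantar-test latency in s, ``VFD`` = von Frey 50%
threshold in g) can be fused in after the spectral variance filter and
are Z-scaled together with the spectral bins.  PCA scores on the scaled
matrix are exported for cluster inspection; the classifier itself
consumes the scaled intensities (a flag allows PCA-score inputs
instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .behavior import BehaviorRecord
from .preprocess import PeakList

__all__ = ["FeatureMatrix", "PCAResult", "EmptyMatrixError",
           "bin_peaks", "map_to_bins", "variance_filter", "z_scale",
           "apply_z_scale", "fuse_behavior", "pca_scores"]

BEHAVIOR_TAGS = ("PTD", "VFD")


class EmptyMatrixError(ValueError):
    """Filtering removed every feature."""


@dataclass
class FeatureMatrix:
    """Samples x features table with provenance.

    ``feature_ids`` are m/z bin centers formatted as ``mz_<Da>`` plus
    optional behavioral tags; ``scaling_state`` is ``"raw"`` or
    ``"z_scaled"``; after scaling the per-column (mean, sd) used is kept
    in ``scaler`` so held-out samples can be transformed with training
    parameters.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    labels: list[str]
    scaling_state: str = "raw"
    bin_centers: np.ndarray | None = None     # Da, spectral columns only
    scaler: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, d = self.values.shape
        if len(self.feature_ids) != d:
            raise ValueError("feature_ids length mismatch")
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length mismatch")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing or nonfinite values in feature matrix")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def spectral_mask(self) -> np.ndarray:
        return np.array([fid.startswith("mz_") for fid in self.feature_ids])


@dataclass
class PCAResult:
    loadings: np.ndarray            # features x k, orthonormal columns
    scores: np.ndarray              # samples x k
    explained_variance_ratio: np.ndarray


def bin_peaks(peaklists: list[PeakList], labels: dict[str, str],
              tolerance: float = 3.0) -> FeatureMatrix:
    """Cluster peaks across samples into shared m/z bins.

    All peaks are pooled and split into clusters wherever the gap
    between m/z-adjacent peaks exceeds `tolerance`; each cluster becomes
    a feature with center = mean member m/z.  A sample absent from a bin
    contributes intensity 0; a sample with several peaks in one bin
    contributes their maximum.
    """
    if len(peaklists) < 2:
        raise ValueError("binning needs at least 2 samples")
    sample_ids = [p.sample_id for p in peaklists]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_ids in peak lists")
    pooled, inten, samp = [], [], []
    for k, p in enumerate(peaklists):
        pooled.append(p.mz)
        inten.append(p.intensity)
        samp.append(np.full(len(p), k))
    pooled = np.concatenate(pooled)
    inten = np.concatenate(inten)
    samp = np.concatenate(samp)
    if len(pooled) == 0:
        raise EmptyMatrixError("no peaks in any sample")
    order = np.argsort(pooled, kind="stable")
    pooled, inten, samp = pooled[order], inten[order], samp[order]
    breaks = np.nonzero(np.diff(pooled) > tolerance)[0] + 1
    groups = np.split(np.arange(len(pooled)), breaks)
    centers = np.array([float(np.mean(pooled[g])) for g in groups])
    values = np.zeros((len(peaklists), len(groups)))
    for j, g in enumerate(groups):
        np.maximum.at(values[:, j], samp[g], inten[g])
    fids = [f"mz_{c:.1f}" for c in centers]
    labs = [labels[s] for s in sample_ids]
    return FeatureMatrix(values, fids, sample_ids, labs, "raw", bin_centers=centers)


def map_to_bins(peaklist: PeakList, bin_centers: np.ndarray,
                tolerance: float = 3.0) -> np.ndarray:
    """Project one (held-out) peak list onto existing bin centers.

    Each peak is assigned to the nearest center within `tolerance`;
    unmatched peaks are dropped, empty bins get 0.
    """
    vec = np.zeros(len(bin_centers))
    if len(peaklist) == 0 or len(bin_centers) == 0:
        return vec
    centers = np.asarray(bin_centers)
    j = np.clip(np.searchsorted(centers, peaklist.mz), 1, len(centers) - 1)
    left = np.abs(centers[j - 1] - peaklist.mz) <= np.abs(centers[j] - peaklist.mz)
    j = np.where(left, j - 1, j)
    ok = np.abs(centers[j] - peaklist.mz) <= tolerance
    np.maximum.at(vec, j[ok], peaklist.intensity[ok])
    return vec


def variance_filter(matrix: FeatureMatrix, threshold: float = 1.0) -> FeatureMatrix:
    """Keep exactly the spectral columns with sample variance > threshold.

    Strict inequality: a column at exactly the threshold is removed.
    Applied on the raw relative-intensity scale, before Z-scaling, to
    spectral columns; behavioral columns (if already fused) pass
    through untouched.
    """
    if matrix.scaling_state != "raw":
        raise ValueError("variance filter must run on the raw matrix, before Z-scaling")
    var = np.var(matrix.values, axis=0, ddof=1)
    spectral = matrix.spectral_mask()
    keep = var > threshold
    keep[~spectral] = True
    if not np.any(keep & spectral):
        raise EmptyMatrixError(
            f"variance filter (s^2 > {threshold}) removed every feature; "
            "review the threshold or the intensity scale")
    centers = None
    if matrix.bin_centers is not None:
        centers = matrix.bin_centers[keep[spectral]]
    return FeatureMatrix(matrix.values[:, keep],
                         [f for f, k in zip(matrix.feature_ids, keep) if k],
                         list(matrix.sample_ids), list(matrix.labels),
                         "raw", bin_centers=centers)


def z_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Standardize every column to mean 0, sample variance 1 (n-1).

    The per-column parameters are stored on the result so held-out
    samples can be transformed with the training-fold statistics.
    """
    if matrix.scaling_state != "raw":
        raise ValueError("matrix is already z_scaled")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = [matrix.feature_ids[i] for i in np.nonzero(sd <= 0)[0]]
        raise ValueError(f"zero-variance column(s) {bad}; filter before scaling")
    vals = (matrix.values - mean) / sd
    return FeatureMatrix(vals, list(matrix.feature_ids), list(matrix.sample_ids),
                         list(matrix.labels), "z_scaled",
                         bin_centers=matrix.bin_centers, scaler=(mean, sd))


def apply_z_scale(x: np.ndarray, scaler: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Transform a held-out feature vector with stored training parameters."""
    mean, sd = scaler
    return (np.asarray(x, float) - mean) / sd


def fuse_behavior(matrix: FeatureMatrix, behavior: list[BehaviorRecord],
                  include: set[str] = frozenset()) -> FeatureMatrix:
    """Append behavioral outcome columns (order: PTD then VFD).

    ``PTD`` adds the derived mean withdrawal latency, ``VFD`` the
    derived 50% threshold.  Fused columns are raw-scale here and get
    Z-scaled with the spectral ones.
    """
    include = set(include)
    unknown = include - set(BEHAVIOR_TAGS)
    if unknown:
        raise ValueError(f"unknown behavioral tags {sorted(unknown)}")
    if not include:
        return matrix
    if matrix.scaling_state != "raw":
        raise ValueError("fuse behavioral columns before Z-scaling")
    recs = {r.sample_id: r for r in behavior}
    missing = [s for s in matrix.sample_ids if s not in recs]
    if missing:
        raise ValueError(f"missing behavioral record(s) for sample(s) {missing}")
    cols, fids = [], []
    for tag in BEHAVIOR_TAGS:       # documented order: PTD then VFD
        if tag not in include:
            continue
        attr = "derived_latency_mean" if tag == "PTD" else "derived_threshold_50"
        vals = []
        for s in matrix.sample_ids:
            v = getattr(recs[s], attr)
            if v is None:
                raise ValueError(f"behavioral record for {s} lacks {tag}")
            vals.append(float(v))
        cols.append(vals)
        fids.append(tag)
    values = np.column_stack([matrix.values] + [np.asarray(c) for c in cols])
    return FeatureMatrix(values, list(matrix.feature_ids) + fids,
                         list(matrix.sample_ids), list(matrix.labels),
                         "raw", bin_centers=matrix.bin_centers)


def pca_scores(matrix: FeatureMatrix, k: int = 3) -> PCAResult:
    """Principal-component scores of the scaled matrix.

    Components are the eigenvectors of the column covariance; the sign
    of each component is fixed by making its largest-magnitude loading
    positive, so results are deterministic.
    """
    if matrix.scaling_state != "z_scaled":
        raise ValueError("PCA expects a z_scaled matrix")
    n, d = matrix.values.shape
    if not (1 <= k <= min(n - 1, d)):
        raise ValueError(f"k={k} out of range for {n} samples x {d} features")
    pca = _SKPCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(matrix.values)
    loadings = pca.components_.T.copy()          # features x k
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(loadings=loadings, scores=scores,
                     explained_variance_ratio=pca.explained_variance_ratio_.copy())
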