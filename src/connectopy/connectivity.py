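"""Connectivity fingerprints from timeseries.

The fingerprint of an ROI vertex is the vector of Fisher-z correlations
between its timeseries and a set of reference timeseries: the rest of the
brain, rotated into principal-component scores by a lossless PCA (retaining
T-1 components, i.e. 100% of the variance), or the other ROI vertices
themselves for the within-ROI variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .simulate import Timeseries, noise_substitute

__all__ = [
    "Fingerprints",
    "lossless_pca",
    "compute_fingerprints",
    "within_roi_fingerprints",
    "build_connectivity",
    "SOURCE_MODES",
]

SOURCE_MODES = ("all", "cortex", "subcortex", "noise", "within_roi")

#: Correlations are clipped to +/- (1 - _R_CLIP_EPS) before atanh so the
#: Fisher transform stays finite even for duplicated rows.
_R_CLIP_EPS = 1e-7


@dataclass
class Fingerprints:
    """N_roi x D matrix of Fisher-z correlations (the connectivity space)."""

    values: np.ndarray
    source_mode: str = "all"
    pca_applied: bool = True
    split_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("fingerprints contain non-finite values")
        if self.source_mode not in SOURCE_MODES:
            raise ValueError(f"unknown source_mode: {self.source_mode!r}")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_dimensions(self) -> int:
        return self.values.shape[1]


def lossless_pca(source_ts: np.ndarray) -> np.ndarray:
    """Rotate an M x T source matrix into (T-1) x T component-score timeseries.

    Timepoints are the observations and the M rows the feature axes.  With
    M > T, mean-centering leaves exactly T-1 dimensions of variance, so
    retaining T-1 components keeps 100% of the variance: the operation is a
    rotation of the T samples within the feature space, preserving all
    pairwise distances between timepoints.
    """
    source_ts = np.asarray(source_ts, dtype=float)
    m, t = source_ts.shape
    if m <= t:
        raise ValueError(
            f"lossless PCA expects more features than timepoints (got M={m}, "
            f"T={t}); with M <= T omit the PCA, as in the within-ROI analysis"
        )
    pca = PCA(n_components=t - 1, svd_solver="full")
    scores = pca.fit_transform(source_ts.T)  # T x (T-1)
    return scores.T


def _row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``a`` with every row of ``b``."""
    for name, x in (("ROI", a), ("source", b)):
        sd = x.std(axis=1)
        if np.any(sd == 0):
            bad = int(np.argmin(sd))
            raise ValueError(f"{name} row {bad} has zero variance")
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return az @ bz.T / a.shape[1]


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped below 1 so the transform is always finite."""
    return np.arctanh(np.clip(r, -1 + _R_CLIP_EPS, 1 - _R_CLIP_EPS))


def compute_fingerprints(
    roi_ts: np.ndarray,
    source_ts: np.ndarray,
    *,
    fisher: bool = True,
    source_mode: str = "all",
    pca_applied: bool = True,
    split_id: str | None = None,
) -> Fingerprints:
    """Correlate each ROI row with each source row; Fisher-transform."""
    roi_ts = np.asarray(roi_ts, dtype=float)
    source_ts = np.asarray(source_ts, dtype=float)
    if roi_ts.shape[0] < 3:
        raise ValueError("need at least 3 ROI vertices")
    if roi_ts.shape[1] != source_ts.shape[1]:
        raise ValueError("ROI and source timeseries must share the time axis")
    r = _row_correlations(roi_ts, source_ts)
    values = fisher_z(r) if fisher else r
    return Fingerprints(values, source_mode, pca_applied, split_id)


def within_roi_fingerprints(
    roi_ts: np.ndarray,
    *,
    apply_pca: bool = False,
    split_id: str | None = None,
) -> Fingerprints:
    """Fingerprints from the ROI's own timeseries.

    Without PCA: the N x N Fisher-z correlation matrix with the diagonal set
    to zero (each vertex is trivially connected to itself and the perfect
    correlation would break the Fisher transform).  With PCA: each ROI row is
    correlated with the principal-component scores of the ROI rows
    themselves, retaining min(N, T) - 1 components.
    """
    roi_ts = np.asarray(roi_ts, dtype=float)
    n, t = roi_ts.shape
    if n < 3:
        raise ValueError("need at least 3 ROI vertices")
    if apply_pca:
        n_comp = min(n, t) - 1
        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(roi_ts.T).T  # n_comp x T
        return compute_fingerprints(
            roi_ts, scores, source_mode="within_roi", pca_applied=True,
            split_id=split_id,
        )
    fp = compute_fingerprints(
        roi_ts, roi_ts, source_mode="within_roi", pca_applied=False,
        split_id=split_id,
    )
    np.fill_diagonal(fp.values, 0.0)
    return fp


def build_connectivity(
    roi_ts: Timeseries | np.ndarray,
    sources: dict[str, Timeseries | np.ndarray] | None,
    mode: str = "all",
    seed: int = 0,
    *,
    within_roi_pca: bool = False,
    split_id: str | None = None,
) -> Fingerprints:
    """Build fingerprints for one of the five connectivity-source variants.

    mode='all' stacks cortex + subcortex sources, compresses them with the
    lossless PCA and correlates; 'cortex'/'subcortex' use that block alone;
    'noise' substitutes moment-matched Gaussian noise for the stacked
    sources before the same path; 'within_roi' ignores the sources entirely.
    """
    if mode not in SOURCE_MODES:
        raise ValueError(f"unknown source mode: {mode!r}")
    roi = roi_ts.data if isinstance(roi_ts, Timeseries) else np.asarray(roi_ts)
    if mode == "within_roi":
        return within_roi_fingerprints(
            roi, apply_pca=within_roi_pca, split_id=split_id
        )

    needed = {"all": ("cortex", "subcortex"), "noise": ("cortex", "subcortex")}.get(
        mode, (mode,)
    )
    if sources is None or any(k not in sources for k in needed):
        raise ValueError(f"mode {mode!r} requires source blocks {needed}")

    def _arr(key):
        block = sources[key]
        return block.data if isinstance(block, Timeseries) else np.asarray(block)

    stacked = np.vstack([_arr(k) for k in needed])
    if mode == "noise":
        stacked = noise_substitute(Timeseries(stacked), seed=seed).data
    components = lossless_pca(stacked)
    return compute_fingerprints(
        roi, components, source_mode=mode, pca_applied=True, split_id=split_id
    )
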