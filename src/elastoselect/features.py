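"""Color-histogram features and PCA dimension reduction.

Each kept frame is summarized by a joint 8×8×8 RGB histogram (512 bins):
channel value v falls in bin ``v // 32`` and the flat bin index is
``64*bR + 8*bG + bB``.  Counts are normalized by the pixel count so every
histogram sums to 1; the feature therefore describes the frame's color
distribution independent of resolution and spatial layout, which is exactly
the invariance wanted for elastographic pattern matching.

PCA is fitted on training-set histograms only; validation/test histograms
are transformed with the frozen model.  The retained dimension is the
smallest one whose cumulative explained-variance ratio reaches
``variance_target`` (default 0.99) — a data-driven quantity rather than a
fixed constant.  Component signs are fixed (largest-magnitude entry of each
component is positive) so serialized models are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from elastoselect.video_io import Frame, ROIMask

N_BINS = 512


@dataclass
class HistogramFeature:
    """Normalized 512-bin color histogram of one frame."""

    values: np.ndarray
    frame_index: int
    lesion_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_BINS,):
            raise ValueError(f"histogram must have {N_BINS} bins, got {v.shape}")
        if not np.isclose(v.sum(), 1.0, atol=1e-9):
            raise ValueError("histogram must sum to 1")
        self.values = v


@dataclass
class ReducedFeature:
    """PCA-projected feature vector for one frame."""

    values: np.ndarray
    frame_index: int
    lesion_id: str


@dataclass
class PCAModel:
    """Frozen PCA transform: mean, orthonormal components, variance ratios."""

    mean: np.ndarray
    components: np.ndarray  # d × 512, orthonormal rows
    explained_variance_ratio: np.ndarray
    d: int
    variance_target: float

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.d), atol=1e-8):
            raise ValueError("PCA components are not orthonormal")

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            mean=self.mean,
            components=self.components,
            evr=self.explained_variance_ratio,
            d=self.d,
            variance_target=self.variance_target,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        with np.load(path) as z:
            return cls(
                mean=z["mean"],
                components=z["components"],
                explained_variance_ratio=z["evr"],
                d=int(z["d"]),
                variance_target=float(z["variance_target"]),
            )


def color_histogram(
    frame: Frame | np.ndarray,
    roi: ROIMask | None = None,
    frame_index: int | None = None,
    lesion_id: str = "",
) -> HistogramFeature:
    """Joint 8×8×8 RGB histogram of a frame, normalized to sum 1.

    By default the whole frame is histogrammed (selection runs before any
    ROI is available); pass ``roi`` to restrict to a mask.
    """
    if isinstance(frame, Frame):
        px = frame.pixels
        if frame_index is None:
            frame_index = frame.index
    else:
        px = np.asarray(frame, dtype=np.uint8)
        if frame_index is None:
            frame_index = -1
    if roi is not None:
        if roi.mask.shape != px.shape[:2]:
            raise ValueError("ROI mask size does not match frame")
        px = px[roi.mask]
    flat = px.reshape(-1, 3).astype(np.uint16)
    codes = (flat[:, 0] >> 5) * 64 + (flat[:, 1] >> 5) * 8 + (flat[:, 2] >> 5)
    counts = np.bincount(codes, minlength=N_BINS).astype(float)
    return HistogramFeature(values=counts / counts.sum(), frame_index=frame_index, lesion_id=lesion_id)


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    return np.stack([f.values for f in features]).astype(float)


def fit_pca(features, variance_target: float = 0.99) -> PCAModel:
    """Fit PCA on training histograms, retaining the smallest dimension whose
    cumulative explained-variance ratio reaches ``variance_target``."""
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must lie in (0, 1]")
    X = _as_matrix(features)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    total_var = pca.explained_variance_.sum()
    if total_var <= 0:
        raise ValueError("zero-variance input: no principal components exist")
    cum = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    # strip numerically-zero trailing components (rank deficiency)
    d = min(d, int(np.sum(pca.explained_variance_ > total_var * 1e-12)))
    components = pca.components_[:d].copy()
    for row in components:  # deterministic sign: largest-|entry| positive
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    return PCAModel(
        mean=pca.mean_,
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_[:d],
        d=d,
        variance_target=variance_target,
    )


def transform(model: PCAModel, feature: HistogramFeature | np.ndarray) -> ReducedFeature:
    """Project one histogram into the reduced space: components · (x − mean)."""
    if isinstance(feature, HistogramFeature):
        x, idx, lid = feature.values, feature.frame_index, feature.lesion_id
    else:
        x, idx, lid = np.asarray(feature, dtype=float), -1, ""
    if x.shape != model.mean.shape:
        raise ValueError("feature dimension does not match PCA model")
    return ReducedFeature(values=model.components @ (x - model.mean), frame_index=idx, lesion_id=lid)


def transform_matrix(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Vectorized :func:`transform` for an (n, 512) matrix."""
    X = np.asarray(X, dtype=float)
    return (X - model.mean) @ model.components.T
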