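"""Pattern clustering and representative-frame selection.

The selection principle mirrors how an experienced reader works: the color
pattern that recurs most across a recording is the one worth reporting.
k-means clustering over reduced histogram features discovers those recurring
patterns (cluster centers) on the training set; at prediction time each test
frame is allocated to its nearest pattern, the pattern owning the most frames
of a lesion becomes the *representative pattern*, and the three frames
closest to its center are the representative images.

Because a finite training set rarely covers every acquisition condition, an
*update-and-predict* (run-twice) strategy is applied at test time: test
frames are first assigned with the trained centers, the centers are then
refreshed by Lloyd iterations over the pooled training+test features
(initialized at the trained centers — no labels are consumed), and the test
frames are assigned a second time with the refreshed centers.  This narrows
the train/test distribution gap without leaking supervision.

All tie-breaks are deterministic: nearest-center ties go to the lower
pattern id; representative-pattern ties go to the smaller mean distance,
then the lower pattern id; frame-distance ties go to the lower frame index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from elastoselect.features import ReducedFeature


@dataclass
class ClusterModel:
    """K pattern centers in the reduced feature space."""

    centers: np.ndarray  # K × d
    seed: int
    n_init: int
    trained_on: int

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[0] < 1:
            raise ValueError("centers must be a K×d matrix with K >= 1")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("cluster centers must be finite")

    @property
    def k(self) -> int:
        return self.centers.shape[0]


@dataclass
class Selection:
    """Representative pattern and up to 3 chosen frames for one lesion."""

    lesion_id: str
    representative_pattern: int
    frame_indices: list[int]
    distances: list[float]
    short: bool = False

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.distances, self.distances[1:])):
            raise ValueError("selection distances must be non-decreasing")


@dataclass(frozen=True)
class SelectorConfig:
    """Hyper-parameters of the selection model.

    K: number of representative patterns (candidates 32, 64, 128).
    run_twice: whether to apply the update-and-predict strategy.
    pool_training: update step runs Lloyd on training+test features (default)
        rather than test features alone.
    """

    k: int = 64
    run_twice: bool = True
    n_representatives: int = 3
    seed: int = 0
    n_init: int = 10
    pool_training: bool = True


def _feature_frame(features) -> pd.DataFrame:
    """Normalize a feature collection to a DataFrame with an X matrix attached."""
    if isinstance(features, pd.DataFrame):
        df = features.reset_index(drop=True)
        X = np.stack(df["values"].to_numpy()) if len(df) else np.zeros((0, 0))
        return df.assign(_row=np.arange(len(df))), X
    feats = list(features)
    df = pd.DataFrame(
        {
            "lesion_id": [f.lesion_id for f in feats],
            "frame_index": [f.frame_index for f in feats],
            "values": [np.asarray(f.values, dtype=float) for f in feats],
        }
    )
    return df.assign(_row=np.arange(len(df))), np.stack(df["values"].to_numpy())


def as_feature_frame(features: list[ReducedFeature]) -> pd.DataFrame:
    """Public helper: list of reduced features → tidy DataFrame."""
    df, _ = _feature_frame(features)
    return df.drop(columns="_row")


def train_kmeans(features, k: int, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """Lloyd k-means with k-means++ seeding, best of ``n_init`` restarts.

    Deterministic given ``seed``; requires at least ``k`` samples.
    """
    _, X = _feature_frame(features)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} samples, got {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    km.fit(X)
    return ClusterModel(centers=km.cluster_centers_, seed=seed, n_init=n_init, trained_on=X.shape[0])


def assign(model: ClusterModel, features) -> pd.DataFrame:
    """Allocate each frame to its nearest center (Euclidean).

    Returns a PatternAssignment table with columns lesion_id, frame_index,
    pattern_id, distance.  Distance ties go to the lower pattern id.
    """
    df, X = _feature_frame(features)
    if X.shape[1] != model.centers.shape[1]:
        raise ValueError("feature dimension does not match cluster model")
    D = cdist(X, model.centers)
    pattern = D.argmin(axis=1)  # argmin takes the first (lowest id) on ties
    return pd.DataFrame(
        {
            "lesion_id": df["lesion_id"],
            "frame_index": df["frame_index"],
            "pattern_id": pattern,
            "distance": D[np.arange(len(df)), pattern],
        }
    )


def select_representatives(assignment: pd.DataFrame, n_representatives: int = 3) -> Selection:
    """Pick the majority pattern of one lesion and its nearest frames.

    The representative pattern is the one owning most frames; ties break by
    smaller mean distance to center, then lower pattern id.  Up to
    ``n_representatives`` member frames are returned sorted by (distance,
    frame_index); a pattern owning fewer frames yields a short selection.
    """
    if len(assignment) == 0:
        raise ValueError("empty assignment")
    lesions = assignment["lesion_id"].unique()
    if len(lesions) != 1:
        raise ValueError("select_representatives expects a single lesion's assignment")
    stats = (
        assignment.groupby("pattern_id")["distance"]
        .agg(count="size", mean_dist="mean")
        .reset_index()
        .sort_values(["count", "mean_dist", "pattern_id"], ascending=[False, True, True])
    )
    best = int(stats.iloc[0]["pattern_id"])
    members = (
        assignment[assignment["pattern_id"] == best]
        .sort_values(["distance", "frame_index"])
        .head(n_representatives)
    )
    return Selection(
        lesion_id=str(lesions[0]),
        representative_pattern=best,
        frame_indices=[int(i) for i in members["frame_index"]],
        distances=[float(d) for d in members["distance"]],
        short=len(members) < n_representatives,
    )


def lloyd_update(
    X: np.ndarray,
    init_centers: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> np.ndarray:
    """Lloyd iterations from given centers until center movement <= tol.

    Empty clusters are re-seeded to the point farthest from its assigned
    center.  Within-cluster sum of squares is asserted non-increasing at
    every iteration.
    """
    centers = np.array(init_centers, dtype=float, copy=True)
    prev_wcss = np.inf
    for _ in range(max_iter):
        D = cdist(X, centers)
        labels = D.argmin(axis=1)
        wcss = float((D[np.arange(len(X)), labels] ** 2).sum())
        assert wcss <= prev_wcss + 1e-9 * max(1.0, prev_wcss), "Lloyd WCSS increased"
        prev_wcss = wcss
        new_centers = centers.copy()
        for k in range(centers.shape[0]):
            members = labels == k
            if members.any():
                new_centers[k] = X[members].mean(axis=0)
            else:
                farthest = int(D[np.arange(len(X)), labels].argmax())
                new_centers[k] = X[farthest]
        movement = float(np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max())
        centers = new_centers
        if movement <= tol:
            break
    return centers


def update_and_predict(
    model: ClusterModel,
    training_features,
    test_features,
    pool_training: bool = True,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> tuple[ClusterModel, pd.DataFrame]:
    """Run-twice strategy: assign, refresh centers, assign again.

    Run 1 assigns test features with the trained centers (its result is used
    only to seed the update, which here is equivalent to starting Lloyd at
    the trained centers).  The update runs Lloyd to convergence on the
    pooled training+test features (or test alone when ``pool_training`` is
    false), initialized at the trained centers.  Run 2 re-assigns test
    features with the refreshed centers.  No label information is used.
    """
    _, X_test = _feature_frame(test_features)
    if pool_training:
        _, X_train = _feature_frame(training_features)
        X = np.vstack([X_train, X_test])
    else:
        X = X_test
    centers = lloyd_update(X, model.centers, tol=tol, max_iter=max_iter)
    updated = replace(model, centers=centers)
    return updated, assign(updated, test_features)


def tune_hyperparameters(
    train_features,
    validation_bundle,
    k_grid: tuple[int, ...] = (32, 64, 128),
    seed: int = 0,
    n_init: int = 10,
) -> SelectorConfig:
    """Grid search over K × run-twice, scored on the validation set.

    ``validation_bundle`` must provide ``features`` (the validation frames'
    reduced features) and a ``score(selections: dict[str, Selection]) ->
    float`` callback (e.g. diagnostic accuracy of a quantitative metric on
    the selected images).  Ties break toward smaller K, then run-twice off.
    """
    val_features = validation_bundle.features
    df_val, _ = _feature_frame(val_features)
    if len(df_val) == 0:
        raise ValueError("empty validation set")
    results = []
    for k, run_twice in product(k_grid, (False, True)):
        model = train_kmeans(train_features, k=k, seed=seed, n_init=n_init)
        if run_twice:
            _, assignment = update_and_predict(model, train_features, val_features)
        else:
            assignment = assign(model, val_features)
        selections = {
            lesion: select_representatives(grp)
            for lesion, grp in assignment.groupby("lesion_id")
        }
        score = float(validation_bundle.score(selections))
        results.append((score, k, run_twice))
    results.sort(key=lambda r: (-r[0], r[1], r[2]))
    _, best_k, best_twice = results[0]
    return SelectorConfig(k=best_k, run_twice=best_twice, seed=seed, n_init=n_init)


@dataclass
class ValidationBundle:
    """Features plus a scoring callback for hyper-parameter tuning."""

    features: object
    score: object  # callable: dict[lesion_id, Selection] -> float
    labels: dict = field(default_factory=dict)


__all__ = [
    "ClusterModel",
    "Selection",
    "SelectorConfig",
    "ValidationBundle",
    "as_feature_frame",
    "assign",
    "lloyd_update",
    "select_representatives",
    "train_kmeans",
    "tune_hyperparameters",
    "update_and_predict",
]
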