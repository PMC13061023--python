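"""Postural state space: coordinate matrices, PCA, dispersion, similarity.

Each frame's landmark coordinates are flattened into a posture vector
(optionally egocentrically normalized), pooled frames are embedded by PCA,
and the embedding supports the two summary statistics of stereotypy:
trial-to-centroid dispersion over takeoff-aligned time, and the
time-by-time Euclidean similarity matrix whose block structure exposes
stable postural epochs.  Exact dynamic-programming changepoint detection
recovers the block boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.base import BaseEstimator, TransformerMixin

from .records import TrialRecording

DEFAULT_BIN_MS = 2.0
DEFAULT_VARIANCE_TARGET = 0.90
DEFAULT_MAX_COMPONENTS = 5


@dataclass
class PostureMatrix:
    """Flattened (T, 2L) posture features for one trial."""

    features: np.ndarray
    normalization: str
    trial_id: str
    relative_time_ms: np.ndarray | None = None
    excluded_frames: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]


def build_posture_matrix(
    trial: TrialRecording, normalization: str = "centroid"
) -> PostureMatrix:
    """Flatten a cleaned trial into per-frame posture vectors.

    ``centroid`` subtracts each frame's landmark centroid; ``centroid+rotation``
    additionally rotates the hip->shoulder axis onto +x; ``none`` keeps raw
    coordinates.  Frames with any remaining gap are excluded and reported.
    """
    if normalization not in ("centroid", "centroid+rotation", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    pos = trial.positions
    good = ~np.isnan(pos).any(axis=(1, 2))
    excluded = np.flatnonzero(~good)
    p = pos[good]
    if normalization != "none":
        p = p - p.mean(axis=1, keepdims=True)
        if normalization == "centroid+rotation":
            hip = trial.landmark_index("hip")
            shoulder = trial.landmark_index("shoulder")
            axis = p[:, shoulder, :] - p[:, hip, :]
            theta = np.arctan2(axis[:, 1], axis[:, 0])
            c, s = np.cos(-theta), np.sin(-theta)
            rot = np.stack([np.stack([c, -s], -1), np.stack([s, c], -1)], -2)
            p = np.einsum("tij,tlj->tli", rot, p)
    rel = trial.relative_time_ms
    return PostureMatrix(
        features=p.reshape(p.shape[0], -1),
        normalization=normalization,
        trial_id=trial.trial_id,
        relative_time_ms=None if rel is None else rel[good],
        excluded_frames=excluded,
    )


class PosturePCA(BaseEstimator, TransformerMixin):
    """PCA of pooled posture matrices (SVD of the column-centered pool).

    ``n_components`` may be an integer, or None to retain the smallest
    dimension whose cumulative explained variance reaches
    ``variance_target`` (capped at ``max_components``).

    Attributes (after fit): ``mean_``, ``components_`` (k x 2L orthonormal
    rows), ``explained_variance_``, ``explained_variance_ratio_``, ``k_``.
    """

    def __init__(
        self,
        n_components: int | None = None,
        variance_target: float = DEFAULT_VARIANCE_TARGET,
        max_components: int = DEFAULT_MAX_COMPONENTS,
    ):
        self.n_components = n_components
        self.variance_target = variance_target
        self.max_components = max_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        full = PCA(svd_solver="full").fit(X)
        total_var = full.explained_variance_.sum()
        rank = int(np.sum(full.explained_variance_ > 1e-12 * max(total_var, 1e-300)))
        rank = max(rank, 1)
        if self.n_components is not None:
            k = min(self.n_components, rank)
            if k < self.n_components:
                import warnings

                warnings.warn(
                    f"data rank {rank} < requested n_components "
                    f"{self.n_components}; reduced",
                    stacklevel=2,
                )
        else:
            cum = np.cumsum(full.explained_variance_ratio_)
            k = int(np.searchsorted(cum, self.variance_target) + 1)
            k = min(k, self.max_components, rank)
        self.mean_ = full.mean_
        self.components_ = full.components_[:k]
        self.explained_variance_ = full.explained_variance_[:k]
        self.explained_variance_ratio_ = full.explained_variance_ratio_[:k]
        self.full_explained_variance_ratio_ = full.explained_variance_ratio_
        self.k_ = k
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean_.size:
            raise ValueError(
                f"feature count {X.shape[-1]} != fitted {self.mean_.size}"
            )
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores) -> np.ndarray:
        return np.asarray(scores) @ self.components_ + self.mean_


@dataclass
class PostureEmbedding:
    """PCA scores per frame of one trial."""

    scores: np.ndarray
    relative_time_ms: np.ndarray
    trial_id: str

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def fit_pca(
    matrices: list[PostureMatrix],
    k: int | None = None,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
) -> PosturePCA:
    pooled = np.vstack([m.features for m in matrices])
    return PosturePCA(n_components=k, variance_target=variance_target).fit(pooled)


def embed(matrix: PostureMatrix, model: PosturePCA) -> PostureEmbedding:
    if matrix.relative_time_ms is None:
        raise ValueError("posture matrix lacks a takeoff-aligned time axis")
    return PostureEmbedding(
        scores=model.transform(matrix.features),
        relative_time_ms=matrix.relative_time_ms,
        trial_id=matrix.trial_id,
    )


# ---------------------------------------------------------------------------
# binning helpers


def _bin_edges(embeddings: list[PostureEmbedding], bin_ms: float) -> np.ndarray:
    lo = min(e.relative_time_ms[0] for e in embeddings)
    hi = max(e.relative_time_ms[-1] for e in embeddings)
    start = np.floor(lo / bin_ms) * bin_ms
    n_bins = int(np.floor((hi - start) / bin_ms)) + 1
    return start + np.arange(n_bins + 1) * bin_ms


def _bin_means(e: PostureEmbedding, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean score; second array flags populated bins."""
    idx = np.digitize(e.relative_time_ms, edges) - 1
    nbins = edges.size - 1
    k = e.k
    sums = np.zeros((nbins, k))
    counts = np.zeros(nbins)
    valid = (idx >= 0) & (idx < nbins)
    np.add.at(sums, idx[valid], e.scores[valid])
    np.add.at(counts, idx[valid], 1)
    with np.errstate(invalid="ignore"):
        means = sums / counts[:, None]
    return means, counts > 0


@dataclass
class DispersionProfile:
    """Trial-to-centroid distance per takeoff-aligned time bin."""

    time_bins_ms: np.ndarray
    distances: np.ndarray  # (n_trials, n_bins), NaN where a trial misses a bin
    median: np.ndarray
    iqr: np.ndarray

    def window_median(self, lo_ms: float, hi_ms: float) -> float:
        m = (self.time_bins_ms >= lo_ms) & (self.time_bins_ms < hi_ms)
        return float(np.nanmedian(self.distances[:, m]))


def dispersion_profile(
    embeddings: list[PostureEmbedding], bin_ms: float = DEFAULT_BIN_MS
) -> DispersionProfile:
    """Distance of each trial's posture to the across-trial centroid per bin.

    Bins covered by fewer than two trials are dropped.
    """
    if len(embeddings) < 2:
        raise ValueError("dispersion requires at least two trials")
    edges = _bin_edges(embeddings, bin_ms)
    per_trial = [_bin_means(e, edges) for e in embeddings]
    k = embeddings[0].k
    n_bins = edges.size - 1
    stack = np.full((len(embeddings), n_bins, k), np.nan)
    for i, (means, present) in enumerate(per_trial):
        stack[i, present] = means[present]
    coverage = (~np.isnan(stack[:, :, 0])).sum(axis=0)
    keep = coverage >= 2
    stack = stack[:, keep]
    centers = (edges[:-1] + 0.5 * bin_ms)[keep]
    centroid = np.nanmean(stack, axis=0)
    dist = np.linalg.norm(stack - centroid[None], axis=2)
    q1, q3 = np.nanpercentile(dist, [25, 75], axis=0)
    return DispersionProfile(
        time_bins_ms=centers,
        distances=dist,
        median=np.nanmedian(dist, axis=0),
        iqr=q3 - q1,
    )


@dataclass
class SimilarityMatrix:
    """Time-by-time Euclidean distance matrix of trial-averaged postures."""

    distance: np.ndarray
    time_bins_ms: np.ndarray


def similarity_matrix(
    embeddings: list[PostureEmbedding],
    bin_ms: float = DEFAULT_BIN_MS,
    per_trial: bool = False,
) -> SimilarityMatrix:
    """All-pairs distances between per-bin postures.

    Default: average the embedding across trials per bin, then take
    pairwise distances (one matrix).  ``per_trial=True`` instead computes
    one matrix per trial and averages the matrices.
    """
    edges = _bin_edges(embeddings, bin_ms)
    binned = [_bin_means(e, edges) for e in embeddings]
    present = np.stack([p for _, p in binned])
    if per_trial:
        keep = present.all(axis=0)
        mats = []
        for means, _ in binned:
            m = means[keep]
            mats.append(np.linalg.norm(m[:, None] - m[None, :], axis=2))
        dist = np.mean(mats, axis=0)
    else:
        counts = present.sum(axis=0)
        keep = counts >= 1
        stack = np.stack([m for m, _ in binned])
        mean_scores = np.nanmean(stack[:, keep], axis=0)
        dist = np.linalg.norm(mean_scores[:, None] - mean_scores[None, :], axis=2)
    centers = (edges[:-1] + 0.5 * bin_ms)[keep]
    return SimilarityMatrix(distance=dist, time_bins_ms=centers)


# ---------------------------------------------------------------------------
# changepoint detection on the similarity matrix


def _within_cost_table(d: np.ndarray) -> np.ndarray:
    """cost[i, j] = sum of pairwise distances within bins [i, j)."""
    t = d.shape[0]
    # 2-D prefix sums of the full matrix
    ps = np.zeros((t + 1, t + 1))
    ps[1:, 1:] = d.cumsum(0).cumsum(1)
    cost = np.zeros((t + 1, t + 1))
    for i in range(t + 1):
        for j in range(i, t + 1):
            block = ps[j, j] - ps[i, j] - ps[j, i] + ps[i, i]
            cost[i, j] = block / 2.0  # each unordered pair counted once
    return cost


def detect_segments(
    sim: SimilarityMatrix,
    n_segments: int | None = 4,
    penalty: float | None = None,
) -> list[int]:
    """Optimal contiguous segmentation of the similarity matrix.

    Exact dynamic programming minimizing the total within-segment sum of
    pairwise distances, for a fixed number of segments (default 4) or, if
    ``penalty`` is given, with a linear cost per extra segment.  Returns
    the interior boundary bin indices (a segmentation into s segments has
    s - 1 boundaries).
    """
    d = sim.distance
    t = d.shape[0]
    cost = _within_cost_table(d)
    if penalty is not None:
        best = np.full(t + 1, np.inf)
        arg = np.zeros(t + 1, dtype=int)
        best[0] = -penalty
        for j in range(1, t + 1):
            cand = best[:j] + cost[:j, j] + penalty
            arg[j] = int(np.argmin(cand))
            best[j] = cand[arg[j]]
        bounds = []
        j = t
        while j > 0:
            i = arg[j]
            if i > 0:
                bounds.append(i)
            j = i
        return sorted(bounds)
    if n_segments is None:
        raise ValueError("either n_segments or penalty must be given")
    if not 1 <= n_segments <= t:
        raise ValueError(f"n_segments {n_segments} infeasible for {t} bins")
    # dp[s, j]: best cost of splitting [0, j) into s segments
    dp = np.full((n_segments + 1, t + 1), np.inf)
    back = np.zeros((n_segments + 1, t + 1), dtype=int)
    dp[0, 0] = 0.0
    for s in range(1, n_segments + 1):
        for j in range(s, t + 1):
            cand = dp[s - 1, :j] + cost[:j, j]
            back[s, j] = int(np.argmin(cand))
            dp[s, j] = cand[back[s, j]]
    bounds = []
    j = t
    for s in range(n_segments, 0, -1):
        i = back[s, j]
        if i > 0:
            bounds.append(i)
        j = i
    return sorted(bounds)


def segmentation_cost(sim: SimilarityMatrix, boundaries: list[int]) -> float:
    """Total within-segment pairwise distance of a given segmentation."""
    d = sim.distance
    t = d.shape[0]
    edges = [0, *sorted(boundaries), t]
    total = 0.0
    for i, j in zip(edges[:-1], edges[1:]):
        block = d[i:j, i:j]
        total += block.sum() / 2.0
    return total
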