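"""Postural clustering and autoregressive hidden Markov dynamics.

Two complementary views of modular organization:

* **configuration modes** — frames pooled across trials are clustered on a
  symmetric k-nearest-neighbor graph in embedding space by
  modularity-maximizing community detection (Leiden) at low resolution,
  and summarized as temporal occupancy;
* **movement states** — an AR-HMM over the embedding dynamics: the hidden
  state switches the linear dynamics ``x_t = A_k x_{t-1..t-p} + b_k + e``,
  ``e ~ N(0, Sigma_k)``, fitted by expectation-maximization with scaled
  forward-backward recursions, per-state weighted least squares, and a
  sticky self-transition pseudo-count.

The EM, forward-backward, and Viterbi routines are implemented here in
full; tests check them against exhaustive enumeration on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .errors import FitError
from .posture import PostureEmbedding

DEFAULT_KNN = 15
DEFAULT_RESOLUTION = 0.1
DEFAULT_MIN_OCCUPANCY = 0.02


# ---------------------------------------------------------------------------
# configuration-mode clustering


class PostureClusterer(BaseEstimator, ClusterMixin):
    """kNN-graph community detection over pooled posture embeddings.

    A symmetric unit-weight k-nearest-neighbor graph (Euclidean) is
    partitioned by the Leiden algorithm with the RB-configuration quality
    function at resolution ``resolution``; clusters occupying less than
    ``min_occupancy_frac`` of frames are merged into the nearest retained
    cluster by centroid distance.  When the pool exceeds
    ``max_fit_frames``, the partition is stabilized by consensus over
    ``n_consensus`` seeded random subsamples (temporally adjacent frames
    are strongly correlated, so a subsample carries the same structure):
    the modal cluster count across subsamples is retained, the
    best-quality partition among modal draws wins, and the remaining
    frames are assigned to the nearest cluster centroid.  Deterministic
    given ``random_state``.
    """

    def __init__(
        self,
        knn_k: int = DEFAULT_KNN,
        resolution: float = DEFAULT_RESOLUTION,
        min_occupancy_frac: float = DEFAULT_MIN_OCCUPANCY,
        max_fit_frames: int = 1000,
        n_consensus: int = 7,
        random_state: int = 0,
    ):
        self.knn_k = knn_k
        self.resolution = resolution
        self.min_occupancy_frac = min_occupancy_frac
        self.max_fit_frames = max_fit_frames
        self.n_consensus = n_consensus
        self.random_state = random_state

    def _partition_once(self, xf: np.ndarray, seed: int):
        """(labels, quality) of one Leiden run with small-cluster merging."""
        nn = NearestNeighbors(n_neighbors=self.knn_k + 1).fit(xf)
        _, idx = nn.kneighbors(xf)
        src = np.repeat(np.arange(len(xf)), self.knn_k)
        dst = idx[:, 1:].ravel()
        edges = {(min(a, b), max(a, b)) for a, b in zip(src, dst)}
        graph = ig.Graph(n=len(xf), edges=sorted(edges))
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=self.resolution,
            seed=int(seed),
            n_iterations=2,
        )
        labels = self._merge_small(xf, np.asarray(part.membership))
        return labels, part.quality()

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n <= self.knn_k:
            raise ValueError(f"need > knn_k={self.knn_k} frames, got {n}")
        if np.allclose(X, X[0]):
            self.labels_ = np.zeros(n, dtype=int)
            self.n_clusters_ = 1
            return self
        rng = np.random.default_rng(self.random_state)
        if self.max_fit_frames and n > self.max_fit_frames:
            draws = []
            for _ in range(max(1, self.n_consensus)):
                fit_idx = np.sort(
                    rng.choice(n, size=self.max_fit_frames, replace=False)
                )
                seed = int(rng.integers(0, 2 ** 31 - 1))
                labels, quality = self._partition_once(X[fit_idx], seed)
                draws.append((fit_idx, labels, quality))
            counts = [int(lab.max()) + 1 for _, lab, _ in draws]
            vals, freq = np.unique(counts, return_counts=True)
            modal_k = int(vals[np.argmax(freq)])
            self.consensus_counts_ = counts
            candidates = [d for d, c in zip(draws, counts) if c == modal_k]
            fit_idx, fit_labels, _ = max(candidates, key=lambda d: d[2])
        else:
            fit_idx = np.arange(n)
            fit_labels, _ = self._partition_once(X, int(self.random_state))
            self.consensus_counts_ = [int(fit_labels.max()) + 1]
        xf = X[fit_idx]
        k = int(fit_labels.max()) + 1
        centroids = np.stack([xf[fit_labels == c].mean(axis=0) for c in range(k)])
        if len(fit_idx) < n:
            d = np.linalg.norm(X[:, None, :] - centroids[None, :, :], axis=2)
            labels = np.argmin(d, axis=1)
            labels[fit_idx] = fit_labels
        else:
            labels = fit_labels
        self.cluster_centers_ = centroids
        self.fit_indices_ = fit_idx
        self.labels_ = labels
        self.n_clusters_ = k
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def _merge_small(self, X: np.ndarray, labels: np.ndarray) -> np.ndarray:
        n = labels.size
        while True:
            ids, counts = np.unique(labels, return_counts=True)
            fracs = counts / n
            small = ids[fracs < self.min_occupancy_frac]
            if small.size == 0 or ids.size == 1:
                break
            centroids = {i: X[labels == i].mean(axis=0) for i in ids}
            # merge the smallest cluster first
            victim = small[np.argmin(counts[np.isin(ids, small)])]
            others = [i for i in ids if i != victim]
            dists = [np.linalg.norm(centroids[victim] - centroids[o]) for o in others]
            labels = labels.copy()
            labels[labels == victim] = others[int(np.argmin(dists))]
        # dense relabeling by descending size
        ids, counts = np.unique(labels, return_counts=True)
        order = ids[np.argsort(-counts)]
        remap = {old: new for new, old in enumerate(order)}
        return np.array([remap[v] for v in labels], dtype=int)


def cluster_postures(
    scores: np.ndarray,
    knn_k: int = DEFAULT_KNN,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
    min_occupancy_frac: float = DEFAULT_MIN_OCCUPANCY,
) -> PostureClusterer:
    return PostureClusterer(
        knn_k=knn_k, resolution=resolution,
        min_occupancy_frac=min_occupancy_frac, random_state=seed,
    ).fit(scores)


@dataclass
class OccupancyMap:
    """Fraction of frames per cluster per takeoff-aligned time bin."""

    time_bins_ms: np.ndarray
    occupancy: np.ndarray  # (n_clusters, n_bins), columns sum to 1

    def modal_cluster(self, lo_ms: float, hi_ms: float) -> int:
        m = (self.time_bins_ms >= lo_ms) & (self.time_bins_ms < hi_ms)
        return int(np.argmax(self.occupancy[:, m].sum(axis=1)))


def occupancy_over_time(
    labels: np.ndarray, relative_times_ms: np.ndarray, bin_ms: float = 2.0
) -> OccupancyMap:
    labels = np.asarray(labels)
    t = np.asarray(relative_times_ms, dtype=float)
    if labels.size != t.size:
        raise ValueError("labels and times differ in length")
    n_clusters = int(labels.max()) + 1
    start = np.floor(t.min() / bin_ms) * bin_ms
    edges = np.arange(start, t.max() + bin_ms, bin_ms)
    idx = np.clip(np.digitize(t, edges) - 1, 0, edges.size - 2)
    counts = np.zeros((n_clusters, edges.size - 1))
    np.add.at(counts, (labels, idx), 1)
    present = counts.sum(axis=0) > 0
    occ = counts[:, present] / counts.sum(axis=0)[present]
    centers = (edges[:-1] + 0.5 * bin_ms)[present]
    return OccupancyMap(time_bins_ms=centers, occupancy=occ)


# ---------------------------------------------------------------------------
# AR-HMM


@dataclass
class ARHMMPosterior:
    """Per-trial posterior: gamma (T-p, K), expected transitions, loglik."""

    gamma: np.ndarray
    xi_sum: np.ndarray
    log_likelihood: float
    relative_time_ms: np.ndarray | None = None


def _design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design: targets x[p:], regressors [x_{t-1} .. x_{t-p}, 1]."""
    t, d = x.shape
    cols = [x[p - lag - 1 : t - lag - 1] for lag in range(p)]
    phi = np.concatenate(cols + [np.ones((t - p, 1))], axis=1)
    return x[p:], phi


class ARHMM(BaseEstimator):
    """Gaussian autoregressive hidden Markov model, fitted by EM.

    Parameters
    ----------
    n_states : number of dynamical states K
    ar_order : autoregressive lag p
    sticky_kappa : pseudo-count added to the transition-matrix diagonal,
        encouraging dwell-and-switch state sequences
    ridge : added to residual covariances (and regression normal
        equations) for numerical stability
    n_restarts, max_iter, tol, random_state : EM schedule

    Attributes (after fit)
    ----------------------
    coefs_ : (K, D, D*p) per-state dynamics matrices
    intercepts_ : (K, D)
    covars_ : (K, D, D) symmetric positive-definite
    transmat_ : (K, K) row-stochastic
    startprob_ : (K,)
    log_likelihood_, history_ (per-iteration loglik of the winning restart)
    """

    def __init__(
        self,
        n_states: int = 6,
        ar_order: int = 1,
        n_restarts: int = 5,
        max_iter: int = 100,
        tol: float = 1e-6,
        sticky_kappa: float = 10.0,
        ridge: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_states = n_states
        self.ar_order = ar_order
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.sticky_kappa = sticky_kappa
        self.ridge = ridge
        self.random_state = random_state

    # -- emission log-densities -----------------------------------------
    def _log_emissions(self, y: np.ndarray, phi: np.ndarray) -> np.ndarray:
        n, d = y.shape
        k = self.n_states
        out = np.empty((n, k))
        for j in range(k):
            w = np.concatenate([self.coefs_[j], self.intercepts_[j][:, None]], axis=1)
            resid = y - phi @ w.T
            chol, lower = cho_factor(self.covars_[j], lower=True)
            solved = cho_solve((chol, lower), resid.T)
            maha = (resid.T * solved).sum(axis=0)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            out[:, j] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
        return out

    # -- forward-backward ------------------------------------------------
    def _forward_backward(self, logb: np.ndarray) -> ARHMMPosterior:
        n, k = logb.shape
        b = np.exp(logb - logb.max(axis=1, keepdims=True))
        alpha = np.empty((n, k))
        c = np.empty(n)
        alpha[0] = self.startprob_ * b[0]
        c[0] = alpha[0].sum()
        alpha[0] /= c[0]
        for t in range(1, n):
            alpha[t] = (alpha[t - 1] @ self.transmat_) * b[t]
            c[t] = alpha[t].sum()
            if c[t] <= 0 or not np.isfinite(c[t]):
                raise FloatingPointError("forward pass underflow")
            alpha[t] /= c[t]
        beta = np.ones((n, k))
        xi_sum = np.zeros((k, k))
        for t in range(n - 2, -1, -1):
            nxt = b[t + 1] * beta[t + 1]
            xi = (alpha[t][:, None] * self.transmat_) * nxt[None, :]
            xi_sum += xi / xi.sum()
            beta[t] = (self.transmat_ @ nxt) / c[t + 1]
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        loglik = float(np.log(c).sum() + logb.max(axis=1).sum())
        return ARHMMPosterior(gamma=gamma, xi_sum=xi_sum, log_likelihood=loglik)

    # -- M-step ----------------------------------------------------------
    def _m_step(self, data, posteriors) -> None:
        k = self.n_states
        d = data[0][0].shape[1]
        q = data[0][1].shape[1]
        for j in range(k):
            g = np.zeros((q, q))
            h = np.zeros((q, d))
            tot = 0.0
            for (y, phi), post in zip(data, posteriors):
                w = post.gamma[:, j]
                pw = phi * w[:, None]
                g += pw.T @ phi
                h += pw.T @ y
                tot += w.sum()
            g += self.ridge * np.eye(q)
            wmat = np.linalg.solve(g, h).T  # (D, q)
            self.coefs_[j] = wmat[:, :-1]
            self.intercepts_[j] = wmat[:, -1]
            s = np.zeros((d, d))
            for (y, phi), post in zip(data, posteriors):
                resid = y - phi @ wmat.T
                s += (resid * post.gamma[:, j][:, None]).T @ resid
            self.covars_[j] = s / max(tot, 1e-12) + self.ridge * np.eye(d)
        trans = sum(p.xi_sum for p in posteriors)
        trans = trans + self.sticky_kappa * np.eye(k) + 1e-12
        self.transmat_ = trans / trans.sum(axis=1, keepdims=True)
        start = sum(p.gamma[0] for p in posteriors) + 1e-12
        self.startprob_ = start / start.sum()

    def _init_params(self, data, rng: np.random.Generator) -> None:
        k = self.n_states
        d = data[0][0].shape[1]
        q = data[0][1].shape[1]
        self.coefs_ = np.zeros((k, d, q - 1))
        self.intercepts_ = np.zeros((k, d))
        self.covars_ = np.stack([np.eye(d)] * k)
        self.transmat_ = np.full((k, k), 1.0 / k)
        self.startprob_ = np.full(k, 1.0 / k)
        # random responsibilities -> M-step
        posts = []
        for y, phi in data:
            g = rng.dirichlet(np.ones(k), size=y.shape[0])
            posts.append(
                ARHMMPosterior(gamma=g, xi_sum=np.full((k, k), 1.0 / k), log_likelihood=-np.inf)
            )
        self._m_step(data, posts)

    # -- public API -------------------------------------------------------
    def fit(self, sequences: list[np.ndarray], y=None):
        seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
        seqs = [s[:, None] if s.ndim == 1 else s for s in seqs]
        p = self.ar_order
        for s in seqs:
            if s.shape[0] <= p + 1:
                raise ValueError("each sequence must be longer than ar_order + 1")
        data = [_design(s, p) for s in seqs]
        root = np.random.default_rng(self.random_state)
        best = None
        failures = 0
        for _ in range(max(1, self.n_restarts)):
            rng = np.random.default_rng(root.integers(0, 2 ** 31 - 1))
            try:
                result = self._run_em(data, rng)
            except (FloatingPointError, np.linalg.LinAlgError):
                failures += 1
                continue
            if best is None or result["loglik"] > best["loglik"]:
                best = result
        if best is None:
            raise FitError(f"all {self.n_restarts} EM restarts failed")
        self.n_failed_restarts_ = failures
        for name in ("coefs_", "intercepts_", "covars_", "transmat_", "startprob_"):
            setattr(self, name, best[name])
        self.log_likelihood_ = best["loglik"]
        self.history_ = best["history"]
        self.n_iter_ = len(best["history"])
        return self

    def _run_em(self, data, rng) -> dict:
        self._init_params(data, rng)
        history = []
        prev = -np.inf
        for _ in range(self.max_iter):
            posts = [self._forward_backward(self._log_emissions(y, phi))
                     for y, phi in data]
            loglik = sum(p.log_likelihood for p in posts)
            if not np.isfinite(loglik):
                raise FloatingPointError("non-finite likelihood")
            history.append(loglik)
            self._m_step(data, posts)
            if abs(loglik - prev) < self.tol * max(1.0, abs(loglik)):
                break
            prev = loglik
        return {
            "loglik": history[-1],
            "history": history,
            "coefs_": self.coefs_.copy(),
            "intercepts_": self.intercepts_.copy(),
            "covars_": self.covars_.copy(),
            "transmat_": self.transmat_.copy(),
            "startprob_": self.startprob_.copy(),
        }

    def posterior(self, sequence: np.ndarray,
                  relative_time_ms: np.ndarray | None = None) -> ARHMMPosterior:
        x = np.atleast_2d(np.asarray(sequence, dtype=float))
        y, phi = _design(x, self.ar_order)
        post = self._forward_backward(self._log_emissions(y, phi))
        if relative_time_ms is not None:
            post.relative_time_ms = np.asarray(relative_time_ms)[self.ar_order:]
        return post

    def score(self, sequence: np.ndarray) -> float:
        return self.posterior(sequence).log_likelihood

    def predict(self, sequence: np.ndarray) -> np.ndarray:
        """Viterbi path (log-space recursion) over the modeled frames."""
        x = np.atleast_2d(np.asarray(sequence, dtype=float))
        if x.shape[0] <= self.ar_order:
            raise ValueError("sequence not longer than ar_order")
        y, phi = _design(x, self.ar_order)
        logb = self._log_emissions(y, phi)
        n, k = logb.shape
        log_a = np.log(self.transmat_ + 1e-300)
        delta = np.log(self.startprob_ + 1e-300) + logb[0]
        back = np.zeros((n, k), dtype=int)
        for t in range(1, n):
            cand = delta[:, None] + log_a
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(k)] + logb[t]
        path = np.empty(n, dtype=int)
        path[-1] = int(np.argmax(delta))
        for t in range(n - 2, -1, -1):
            path[t] = back[t + 1, path[t + 1]]
        return path

    def sample(self, n_frames: int, seed: int = 0,
               x_init: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Sample (observations, states) from the fitted/assigned model."""
        rng = np.random.default_rng(seed)
        k = self.n_states
        p = self.ar_order
        d = self.intercepts_.shape[1]
        x = np.zeros((n_frames, d))
        if x_init is not None:
            x[:p] = x_init
        else:
            x[:p] = rng.standard_normal((p, d))
        z = np.empty(n_frames, dtype=int)
        z[:p] = -1
        state = rng.choice(k, p=self.startprob_)
        chols = [np.linalg.cholesky(self.covars_[j]) for j in range(k)]
        for t in range(p, n_frames):
            if t > p:
                state = rng.choice(k, p=self.transmat_[state])
            z[t] = state
            phi = np.concatenate([x[t - lag - 1] for lag in range(p)])
            mean = self.coefs_[state] @ phi + self.intercepts_[state]
            x[t] = mean + chols[state] @ rng.standard_normal(d)
        return x, z


def fit_arhmm(
    embeddings: list[PostureEmbedding] | list[np.ndarray],
    n_states: int = 6,
    ar_order: int = 1,
    n_restarts: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
    sticky_kappa: float = 10.0,
    seed: int = 0,
) -> tuple[ARHMM, list[ARHMMPosterior]]:
    seqs, times = [], []
    for e in embeddings:
        if isinstance(e, PostureEmbedding):
            seqs.append(e.scores)
            times.append(e.relative_time_ms)
        else:
            seqs.append(np.asarray(e))
            times.append(None)
    model = ARHMM(
        n_states=n_states, ar_order=ar_order, n_restarts=n_restarts,
        max_iter=max_iter, tol=tol, sticky_kappa=sticky_kappa,
        random_state=seed,
    ).fit(seqs)
    posts = [model.posterior(s, t) for s, t in zip(seqs, times)]
    return model, posts


def viterbi(model: ARHMM, sequence: np.ndarray) -> np.ndarray:
    return model.predict(sequence)


def state_probability_profile(
    posteriors: list[ARHMMPosterior], bin_ms: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """(time_bins_ms, states x bins mean posterior); columns sum to 1."""
    if any(p.relative_time_ms is None for p in posteriors):
        raise ValueError("posteriors need relative_time_ms for profiling")
    lo = min(p.relative_time_ms[0] for p in posteriors)
    hi = max(p.relative_time_ms[-1] for p in posteriors)
    edges = np.arange(np.floor(lo / bin_ms) * bin_ms, hi + bin_ms, bin_ms)
    k = posteriors[0].gamma.shape[1]
    sums = np.zeros((k, edges.size - 1))
    counts = np.zeros(edges.size - 1)
    for p in posteriors:
        idx = np.clip(np.digitize(p.relative_time_ms, edges) - 1, 0, edges.size - 2)
        np.add.at(sums.T, idx, p.gamma)
        np.add.at(counts, idx, 1)
    present = counts > 0
    profile = sums[:, present] / counts[present]
    centers = (edges[:-1] + 0.5 * bin_ms)[present]
    return centers, profile


def modal_state_partition(
    model: ARHMM, embeddings: list[PostureEmbedding], bin_ms: float = 2.0
) -> np.ndarray:
    """Modal (argmax mean-posterior) state per time bin."""
    posts = [model.posterior(e.scores, e.relative_time_ms) for e in embeddings]
    _, profile = state_probability_profile(posts, bin_ms)
    return np.argmax(profile, axis=0)


def robustness_scan(
    embeddings: list[PostureEmbedding],
    k_grid: tuple[int, ...] = (4, 5, 6),
    p_grid: tuple[int, ...] = (1,),
    seeds: tuple[int, ...] = (0,),
    bin_ms: float = 2.0,
    **fit_kwargs,
) -> dict:
    """Fit across (K, p, seed) and report agreement of binned modal states.

    Individual fit failures are recorded and the scan continues.
    """
    if not k_grid or not p_grid or not seeds:
        raise ValueError("grids must be non-empty")
    settings, partitions, failures = [], [], []
    for k in k_grid:
        for p in p_grid:
            for s in seeds:
                try:
                    model, _ = fit_arhmm(
                        embeddings, n_states=k, ar_order=p, seed=s, **fit_kwargs
                    )
                    partitions.append(modal_state_partition(model, embeddings, bin_ms))
                    settings.append((k, p, s))
                except (FitError, ValueError) as err:
                    failures.append(((k, p, s), str(err)))
    n = len(partitions)
    ari = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = min(partitions[i].size, partitions[j].size)
            ari[i, j] = ari[j, i] = adjusted_rand_score(
                partitions[i][:m], partitions[j][:m]
            )
    mean_ari = float(ari[np.triu_indices(n, 1)].mean()) if n > 1 else 1.0
    return {
        "settings": settings, "partitions": partitions,
        "ari_matrix": ari, "mean_pairwise_ari": mean_ari,
        "failures": failures,
    }
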