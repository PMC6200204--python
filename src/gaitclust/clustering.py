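"""Multi-restart k-means and squared-Euclidean silhouettes.

Lloyd's algorithm with randomly allocated seeds in the data space (initial
centroids drawn uniformly inside the data bounding box; Forgy seeding from
data rows is available as an option), 50 random restarts per k with
minimum-SSE selection, repeated independently R times (default 10) over
k = 2..5 to form a cluster ensemble whose allocation stability is analyzed
downstream.

Silhouette values follow s(i) = (b(i) - a(i)) / max{a(i), b(i)} with a(i)
and b(i) computed from *squared* Euclidean distances: a(i) is the mean
squared distance from i to the other members of its own cluster, b(i) the
smallest mean squared distance from i to any other cluster. Members of
singleton clusters get s(i) = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KMeansResult",
    "SilhouetteResult",
    "ClusterEnsemble",
    "kmeans_single",
    "kmeans_restarts",
    "silhouette",
    "run_ensemble",
]

DEFAULT_K_RANGE = (2, 3, 4, 5)
DEFAULT_N_RESTARTS = 50
DEFAULT_REPETITIONS = 10

#: Lloyd convergence: centroid shift tolerance and iteration cap.
CENTROID_TOL = 1e-8
MAX_ITER = 300


@dataclass
class KMeansResult:
    k: int
    labels: np.ndarray  # cluster index per row, 1..k
    centroids: np.ndarray  # k x n_features
    sse: float
    n_iter: int
    restart_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


@dataclass
class SilhouetteResult:
    s_values: np.ndarray
    a_values: np.ndarray
    b_values: np.ndarray

    @property
    def mean_s(self) -> float:
        return float(np.mean(self.s_values))

    @property
    def sd_s(self) -> float:
        return float(np.std(self.s_values, ddof=0))


@dataclass
class ClusterEnsemble:
    """Per-(repetition, k) clustering outcomes with the seeds used."""

    k_range: tuple[int, ...]
    n_repetitions: int
    rng_seeds: list[int]
    results: dict[tuple[int, int], KMeansResult] = field(default_factory=dict)
    silhouettes: dict[tuple[int, int], SilhouetteResult] = field(default_factory=dict)

    def labels_matrix(self, k: int) -> np.ndarray:
        """R x n matrix of labels for a given k, repetitions as rows."""
        return np.vstack([self.results[(r, k)].labels
                          for r in range(self.n_repetitions)])

    def s_matrix(self, k: int) -> np.ndarray:
        """R x n matrix of per-participant silhouette values."""
        return np.vstack([self.silhouettes[(r, k)].s_values
                          for r in range(self.n_repetitions)])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k_range": list(self.k_range),
            "n_repetitions": self.n_repetitions,
            "rng_seeds": self.rng_seeds,
            "results": {
                f"{r}:{k}": {
                    "labels": res.labels.tolist(),
                    "sse": res.sse,
                    "n_iter": res.n_iter,
                    "restart_index": res.restart_index,
                    "centroids": res.centroids.tolist(),
                    "s_values": self.silhouettes[(r, k)].s_values.tolist(),
                    "a_values": self.silhouettes[(r, k)].a_values.tolist(),
                    "b_values": self.silhouettes[(r, k)].b_values.tolist(),
                }
                for (r, k), res in self.results.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterEnsemble":
        payload = json.loads(Path(path).read_text())
        ens = cls(
            k_range=tuple(payload["k_range"]),
            n_repetitions=payload["n_repetitions"],
            rng_seeds=list(payload["rng_seeds"]),
        )
        for key, d in payload["results"].items():
            r, k = (int(x) for x in key.split(":"))
            ens.results[(r, k)] = KMeansResult(
                k=k, labels=np.array(d["labels"]), centroids=np.array(d["centroids"]),
                sse=d["sse"], n_iter=d["n_iter"], restart_index=d["restart_index"],
            )
            ens.silhouettes[(r, k)] = SilhouetteResult(
                np.array(d["s_values"]), np.array(d["a_values"]), np.array(d["b_values"]),
            )
        return ens


def _sse(X: np.ndarray, centroids: np.ndarray, labels0: np.ndarray) -> float:
    return float(np.sum((X - centroids[labels0]) ** 2))


def kmeans_single(X: np.ndarray, k: int, rng: np.random.Generator,
                  restart_index: int = 0, init: str = "uniform") -> KMeansResult:
    """One Lloyd run from k randomly allocated seeds.

    ``init='uniform'`` draws initial centroids uniformly inside the data
    bounding box (random seeds in the data space); ``init='data'`` draws k
    distinct data rows (Forgy). Converges when assignments are stable or
    the maximum centroid shift drops below tolerance; an emptied cluster is
    re-seeded with the point farthest from its assigned centroid so k stays
    fixed.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if init == "uniform":
        lo, hi = X.min(axis=0), X.max(axis=0)
        centroids = rng.uniform(lo, hi, size=(k, X.shape[1]))
    elif init == "data":
        centroids = X[rng.choice(n, size=k, replace=False)].copy()
    else:
        raise ValueError(f"init must be 'uniform' or 'data', got {init!r}")
    labels0 = np.full(n, -1)
    for it in range(1, MAX_ITER + 1):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        new_labels = np.argmin(d2, axis=1)
        new_centroids = centroids.copy()
        for c in range(k):
            members = new_labels == c
            if members.any():
                new_centroids[c] = X[members].mean(axis=0)
            else:
                # re-seed with the point farthest from its assigned centroid
                farthest = int(np.argmax(d2[np.arange(n), new_labels]))
                new_centroids[c] = X[farthest]
                new_labels[farthest] = c
        shift = float(np.max(np.abs(new_centroids - centroids)))
        converged = np.array_equal(new_labels, labels0) or shift < CENTROID_TOL
        centroids, labels0 = new_centroids, new_labels
        if converged:
            break
    # final E-step so the reported SSE matches the reported assignments
    d2 = cdist(X, centroids, metric="sqeuclidean")
    labels0 = np.argmin(d2, axis=1)
    return KMeansResult(k=k, labels=labels0 + 1, centroids=centroids,
                        sse=_sse(X, centroids, labels0), n_iter=it,
                        restart_index=restart_index)


def kmeans_restarts(X: np.ndarray, k: int, n_restarts: int = DEFAULT_N_RESTARTS,
                    rng: np.random.Generator | None = None,
                    init: str = "uniform") -> KMeansResult:
    """Best-of-``n_restarts`` k-means by minimum SSE (ties: lowest restart)."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    best: KMeansResult | None = None
    for r in range(n_restarts):
        res = kmeans_single(X, k, rng, restart_index=r, init=init)
        if best is None or res.sse < best.sse:
            best = res
    assert best is not None
    return best


def silhouette(X: np.ndarray, labels: Sequence[int] | np.ndarray) -> SilhouetteResult:
    """Silhouette values from squared Euclidean distances.

    s(i) = (b(i) - a(i)) / max{a(i), b(i)}; singleton-cluster members get
    s(i) = 0 (a(i) undefined, reported as 0).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = X.shape[0]
    d2 = cdist(X, X, metric="sqeuclidean")
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = int(own.sum())
        means_other = [d2[i, labels == c].mean() for c in uniq if c != labels[i]]
        b[i] = min(means_other)
        if n_own == 1:
            a[i] = 0.0
            s[i] = 0.0
            continue
        a[i] = d2[i, own].sum() / (n_own - 1)  # excludes the zero self-distance
        s[i] = (b[i] - a[i]) / max(a[i], b[i])
    return SilhouetteResult(s, a, b)


def run_ensemble(
    X: np.ndarray,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    n_restarts: int = DEFAULT_N_RESTARTS,
    n_repetitions: int = DEFAULT_REPETITIONS,
    master_seed: int = 0,
    init: str = "uniform",
) -> ClusterEnsemble:
    """R independent repetitions of best-of-restarts k-means per k.

    Per-repetition seeds are spawned deterministically from ``master_seed``
    and recorded for replay; silhouettes are computed for each repetition's
    chosen restart.
    """
    X = np.asarray(X, dtype=float)
    k_range = tuple(sorted(int(k) for k in k_range))
    n = X.shape[0]
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range {k_range} must lie within [2, n-1] = [2, {n - 1}]")
    seed_seq = np.random.SeedSequence(master_seed)
    rep_seeds = [int(child.generate_state(1)[0] % (2 ** 31)) for child in
                 seed_seq.spawn(n_repetitions)]
    ens = ClusterEnsemble(k_range=k_range, n_repetitions=n_repetitions,
                          rng_seeds=rep_seeds)
    for r, seed in enumerate(rep_seeds):
        rng = np.random.default_rng(seed)
        for k in k_range:
            res = kmeans_restarts(X, k, n_restarts=n_restarts, rng=rng, init=init)
            ens.results[(r, k)] = res
            ens.silhouettes[(r, k)] = silhouette(X, res.labels)
    return ens
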