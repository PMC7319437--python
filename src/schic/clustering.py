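"""Cluster assignment from embeddings or neighbor graphs.

Two clusterers: best-of-n Lloyd k-means with k-means++ seeding, and spectral
clustering on the symmetric normalized Laplacian of a k-nearest-neighbor
graph.  Labels are always relabeled canonically (first-occurrence order) so
the output is order-deterministic regardless of internal label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import pairwise_distances

from .core import SchicError
from .dimred import EmbeddingMatrix, KNNGraph, exact_knn, internal_knn_k

__all__ = ["ClusterAssignment", "kmeans_cluster", "spectral_cluster"]


@dataclass
class ClusterAssignment:
    """Cell -> cluster label mapping plus the parameters that produced it."""

    cell_ids: list[str]
    labels: np.ndarray
    K: int
    method: str
    seed: int | None = None
    inertia: float | None = None
    inertia_trajectory: np.ndarray | None = None
    eigengap: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.cell_ids):
            raise SchicError("labels and cell_ids length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "label": self.labels})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, method: str = "loaded") -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t")
        labels = df["label"].to_numpy(np.int64)
        return cls(list(df["cell_id"].astype(str)), labels,
                   K=int(labels.max()) + 1 if len(labels) else 0, method=method)


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters in first-occurrence order (0, 1, 2, ...)."""
    labels = np.asarray(labels)
    mapping, out = {}, np.empty_like(labels)
    for i, l in enumerate(labels):
        if l not in mapping:
            mapping[l] = len(mapping)
        out[i] = mapping[l]
    return out


def _as_features(data) -> tuple[list[str], np.ndarray]:
    if isinstance(data, KNNGraph):
        # cluster the samples x samples weight rows directly
        return data.cell_ids, np.asarray(data.weights, np.float64)
    if isinstance(data, EmbeddingMatrix):
        return data.cell_ids, data.dense()
    raise SchicError(f"cannot cluster a {type(data).__name__}")


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int,
           tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Lloyd run; returns (labels, final centers, inertia trajectory)."""
    K = centers.shape[0]
    trajectory = []
    labels = None
    for _ in range(max_iter):
        D2 = pairwise_distances(X, centers, metric="sqeuclidean")
        labels = np.argmin(D2, axis=1)
        inertia = float(D2[np.arange(len(X)), labels].sum())
        trajectory.append(inertia)
        new_centers = centers.copy()
        for k in range(K):
            members = labels == k
            if members.any():
                new_centers[k] = X[members].mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                new_centers[k] = X[np.argmax(D2[np.arange(len(X)), labels])]
        shift = float(np.linalg.norm(new_centers - centers))
        centers = new_centers
        if shift <= tol:
            break
    # final assignment against the converged centers
    D2 = pairwise_distances(X, centers, metric="sqeuclidean")
    labels = np.argmin(D2, axis=1)
    trajectory.append(float(D2[np.arange(len(X)), labels].sum()))
    return labels, centers, np.asarray(trajectory)


def kmeans_cluster(data: EmbeddingMatrix | KNNGraph, K: int,
                   seed: int | None = 0, n_init: int = 10,
                   max_iter: int = 300, tol: float = 1e-6
                   ) -> ClusterAssignment:
    """Best-of-``n_init`` Lloyd k-means with k-means++ seeding.

    Deterministic given the seed; reports the best run's inertia and its
    per-iteration inertia trajectory (which is non-increasing).
    """
    cell_ids, X = _as_features(data)
    n = len(cell_ids)
    if K > n:
        raise SchicError(f"K={K} exceeds n_cells={n}")
    rng = np.random.RandomState(seed)
    best = None
    for _ in range(n_init):
        centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=rng)
        labels, _, traj = _lloyd(X, centers, max_iter, tol)
        if best is None or traj[-1] < best[2][-1]:
            best = (labels, None, traj)
    labels, _, traj = best
    return ClusterAssignment(cell_ids, canonicalize_labels(labels), K,
                             "kmeans", seed=seed, inertia=float(traj[-1]),
                             inertia_trajectory=traj,
                             params={"n_init": n_init, "max_iter": max_iter,
                                     "tol": tol})


def spectral_cluster(data: KNNGraph | EmbeddingMatrix, K: int,
                     seed: int | None = 0) -> ClusterAssignment:
    """Normalized spectral clustering.

    Builds L = I - D^(-1/2) W D^(-1/2), takes the eigenvectors of the K
    smallest eigenvalues (signs fixed largest-|entry|-positive), unit-
    normalizes the rows and runs seeded k-means on them.  A graph with
    exactly K connected components is recovered exactly for any seed.
    """
    if isinstance(data, EmbeddingMatrix):
        data = exact_knn(data, internal_knn_k(data.n_cells))
    if not isinstance(data, KNNGraph):
        raise SchicError(f"cannot spectral-cluster a {type(data).__name__}")
    W = np.asarray(data.weights, np.float64)
    n = W.shape[0]
    if K > n:
        raise SchicError(f"K={K} exceeds n_cells={n}")
    deg = W.sum(axis=1)
    isolated = np.flatnonzero(deg == 0)
    if len(isolated):
        names = [data.cell_ids[i] for i in isolated]
        raise SchicError(f"graph has isolated cells {names}; cannot "
                         f"normalize the Laplacian")
    dinv = 1.0 / np.sqrt(deg)
    L = np.eye(n) - dinv[:, None] * W * dinv[None, :]
    L = (L + L.T) / 2  # exact symmetry for eigh
    evals, evecs = scipy.linalg.eigh(L, subset_by_index=(0, K - 1))
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0),
                         np.arange(K)])
    flip[flip == 0] = 1.0
    Y = evecs * flip
    norms = np.linalg.norm(Y, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    Y = Y / norms
    emb = EmbeddingMatrix(data.cell_ids, Y, "spectral-rows")
    inner = kmeans_cluster(emb, K, seed=seed)
    full = scipy.linalg.eigh(L, eigvals_only=True,
                             subset_by_index=(0, min(K, n - 1)))
    return ClusterAssignment(data.cell_ids, inner.labels, K, "spectral",
                             seed=seed, eigengap=np.asarray(full),
                             params={"k": data.k, "metric": data.metric})
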