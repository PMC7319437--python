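"""Dimension reduction for single-cell Hi-C: embeddings and neighbor graphs.

Five schemes turn a container of per-cell contact matrices into something a
clustering algorithm can digest:

* ``raw`` — each cell as its flattened upper-triangle pixel vector
  (cells x ~bins^2/2 features, kept sparse);
* ``pca`` — principal components of the raw matrix;
* ``knn`` — exact k-nearest-neighbor graph on Euclidean distances
  (cells x cells);
* ``minhash`` — approximate k-nearest-neighbor graph on Jaccard similarity
  of non-zero pixel sets, estimated with MinHash locality-sensitive hashing;
* ``svl`` — short-range vs long-range contact ratio per chromosome
  (cells x chromosomes);
* ``compartments`` — per-cell A/B compartment track: the leading
  eigenvector of the observed/expected Pearson correlation matrix per
  chromosome, concatenated to a cells x bins matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import pairwise_distances

from .core import CellMatrix, SCoolContainer, SchicError
from .io_scool import pool_to_bulk

__all__ = ["EmbeddingMatrix", "KNNGraph", "flatten_cells", "pca_reduce",
           "exact_knn", "minhash_knn", "exact_jaccard", "svl_features",
           "obs_exp", "compartment_features", "SVL_SENTINEL"]

SVL_SENTINEL = 1e12  # stands in for short/long when a cell has no long-range contacts

# prime modulus for the universal hash family; must exceed the feature universe
_MINHASH_PRIME = 2_147_483_647  # 2^31 - 1


@dataclass
class EmbeddingMatrix:
    """Cells x features matrix produced by one reduction method."""

    cell_ids: list[str]
    features: np.ndarray | sp.spmatrix
    method: str  # raw | pca | svl | compartments
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.features):
            return np.asarray(self.features.todense())
        return np.asarray(self.features)


@dataclass
class KNNGraph:
    """Symmetric non-negative neighbor graph over cells (zero diagonal)."""

    cell_ids: list[str]
    weights: np.ndarray
    k: int
    metric: str  # euclidean | jaccard_estimate
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def _triu_index(b1: np.ndarray, b2: np.ndarray, n_bins: int) -> np.ndarray:
    """Flat index of (i, j), i <= j, in row-major upper-triangle order."""
    return b1 * n_bins - b1 * (b1 - 1) // 2 + (b2 - b1)


def flatten_cells(container: SCoolContainer) -> EmbeddingMatrix:
    """Raw embedding: one row per cell, one column per upper-triangle pixel.

    The feature space has n_bins(n_bins+1)/2 columns — order bins^2 — and is
    stored sparsely.
    """
    if container.n_cells == 0:
        raise SchicError("empty container")
    nb = container.binning.n_bins
    n_feat = nb * (nb + 1) // 2
    rows, cols, vals = [], [], []
    for r, cell in enumerate(container.cells):
        idx = _triu_index(cell.bin1_id, cell.bin2_id, nb)
        rows.append(np.full(len(idx), r))
        cols.append(idx)
        vals.append(np.asarray(cell.count, np.float64))
    feats = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(container.n_cells, n_feat))
    return EmbeddingMatrix(container.cell_ids, feats, "raw",
                           {"n_bins": nb, "n_features": n_feat})


def pca_reduce(embedding: EmbeddingMatrix,
               n_components: int | None = None) -> EmbeddingMatrix:
    """Project cells onto the top principal components of the mean-centered
    raw matrix.

    Deterministic: component signs are fixed so the largest-magnitude
    loading of each component is positive.  Default ``n_components`` is
    n_bins, capped at min(n_cells, n_features).
    """
    X = embedding.dense()
    n_cells, n_feat = X.shape
    cap = min(n_cells, n_feat)
    if n_components is None:
        n_components = min(embedding.params.get("n_bins", cap), cap)
    if n_components <= 0:
        raise SchicError(f"n_components must be positive, got {n_components}")
    if n_components > cap:
        raise SchicError(f"n_components={n_components} exceeds "
                         f"min(n_cells, n_features)={cap}")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    flip = np.sign(Vt[np.arange(len(Vt)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = U * S * flip
    return EmbeddingMatrix(embedding.cell_ids, scores, "pca",
                           {"n_components": n_components,
                            "explained_variance": (S ** 2) / max(n_cells - 1, 1)})


def _topk_graph(sim_or_dist: np.ndarray, k: int, weights: np.ndarray,
                largest: bool) -> np.ndarray:
    """Symmetric graph keeping each row's top-k partners (ties by index)."""
    n = sim_or_dist.shape[0]
    out = np.zeros((n, n))
    order_key = -sim_or_dist if largest else sim_or_dist
    for i in range(n):
        key = order_key[i].copy()
        key[i] = np.inf  # exclude self
        nbrs = np.argsort(key, kind="stable")[:k]
        out[i, nbrs] = weights[i, nbrs]
    out = np.maximum(out, out.T)
    np.fill_diagonal(out, 0.0)
    return out


def exact_knn(embedding: EmbeddingMatrix, k: int) -> KNNGraph:
    """Exact k-nearest-neighbor graph on Euclidean distances.

    Edge weight 1/(1 + dist); each row's k nearest (ties broken by cell
    index) are kept, then the graph is symmetrized by element-wise max.
    """
    n = embedding.n_cells
    if k >= n:
        raise SchicError(f"k={k} must be < n_cells={n}")
    X = embedding.dense()
    D = pairwise_distances(X, metric="euclidean")
    W = _topk_graph(D, k, 1.0 / (1.0 + D), largest=False)
    return KNNGraph(embedding.cell_ids, W, k, "euclidean")


def _nonzero_sets(container: SCoolContainer) -> tuple[list[np.ndarray], int]:
    nb = container.binning.n_bins
    universe = nb * (nb + 1) // 2
    sets = []
    for cell in container.cells:
        nz = np.asarray(cell.count) != 0
        idx = _triu_index(cell.bin1_id[nz], cell.bin2_id[nz], nb)
        if len(idx) == 0:
            raise SchicError(f"cell {cell.cell_id!r} has no non-zero pixels; "
                             f"run QC first")
        sets.append(np.sort(idx))
    return sets, universe


def exact_jaccard(container: SCoolContainer) -> np.ndarray:
    """Exact pairwise Jaccard similarity of non-zero pixel sets.

    The brute-force counterpart of the MinHash estimate, used for
    validation and as an alternative exact route.
    """
    sets, _ = _nonzero_sets(container)
    n = len(sets)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(np.intersect1d(sets[i], sets[j], assume_unique=True))
            union = len(sets[i]) + len(sets[j]) - inter
            J[i, j] = J[j, i] = inter / union if union else 0.0
    return J


def _mix64(x: np.ndarray) -> np.ndarray:
    """Fixed bijective 64-bit scrambler (splitmix64 finalizer).

    Plain affine hashes (a x + b) mod p are not min-wise independent on
    structured inputs: translated sets such as {1,2,3} and {2,3,4} collide
    with visibly biased probability.  Scrambling the element values first
    destroys that arithmetic structure, making the per-slot collision
    probability match the Jaccard similarity.
    """
    z = x.astype(np.uint64)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return (z % np.uint64(_MINHASH_PRIME)).astype(np.int64)


def minhash_signatures(sets: list[np.ndarray], num_hashes: int,
                       seed, universe: int) -> np.ndarray:
    """MinHash signature matrix (cells x num_hashes).

    Hash family h_i(x) = (a_i mix(x) + b_i) mod p with p prime > universe
    and mix a fixed 64-bit scrambler; (a_i, b_i) drawn from a seeded RNG.
    The probability that two cells collide in one slot equals their Jaccard
    similarity.
    """
    if universe >= _MINHASH_PRIME:
        raise SchicError("feature universe exceeds the hash modulus")
    rng = np.random.default_rng(seed)
    a = rng.integers(1, _MINHASH_PRIME, size=num_hashes, dtype=np.int64)
    b = rng.integers(0, _MINHASH_PRIME, size=num_hashes, dtype=np.int64)
    sigs = np.empty((len(sets), num_hashes), dtype=np.int64)
    for r, x in enumerate(sets):
        mixed = _mix64(x)
        sigs[r] = ((a[:, None] * mixed[None, :] + b[:, None])
                   % _MINHASH_PRIME).min(axis=1)
    return sigs


def minhash_knn(container: SCoolContainer, k: int, num_hashes: int = 800,
                seed: int | None = 0) -> KNNGraph:
    """Approximate k-nearest-neighbor graph via MinHash LSH.

    Each cell is the set of its non-zero upper-triangle pixel indices
    (count magnitudes ignored); estimated Jaccard similarity is the fraction
    of matching signature slots.  The graph keeps each cell's top-k
    estimated similarities (ties by index), symmetrized by max; weights are
    the estimates, hence in [0, 1].
    """
    n = container.n_cells
    if k >= n:
        raise SchicError(f"k={k} must be < n_cells={n}")
    sets, universe = _nonzero_sets(container)
    sigs = minhash_signatures(sets, num_hashes, seed, universe)
    sim = (sigs[:, None, :] == sigs[None, :, :]).mean(axis=2)
    W = _topk_graph(sim, k, sim, largest=True)
    return KNNGraph(container.cell_ids, W, k, "jaccard_estimate",
                    {"num_hashes": num_hashes, "seed": seed})


def svl_features(container: SCoolContainer,
                 distance_threshold: int = 2_000_000) -> EmbeddingMatrix:
    """Short-range over long-range contact ratio per chromosome.

    Per cell and chromosome: short = counts at genomic distance in
    (0, threshold], long = counts beyond threshold; the feature is
    short/long.  The main diagonal is excluded.  Cells with no long-range
    contacts on a chromosome get the sentinel value (flagged in params);
    chromosomes too short to have any long-range pixel are flagged
    degenerate.
    """
    binning = container.binning
    bs = binning.bin_size
    if distance_threshold < bs:
        raise SchicError("distance_threshold must be >= bin_size")
    thr_bins = distance_threshold // bs
    chrom_of = binning.bin_chrom_index()
    degenerate = [name for name, nb in zip(binning.chrom_names,
                                           binning.bins_per_chrom)
                  if (nb - 1) * bs <= distance_threshold]
    if degenerate:
        warnings.warn(f"chromosomes with no possible long-range pixel: "
                      f"{degenerate}", stacklevel=2)
    feats = np.zeros((container.n_cells, binning.n_chroms))
    sentinel_cells = []
    for r, cell in enumerate(container.cells):
        d = cell.bin2_id - cell.bin1_id
        intra = chrom_of[cell.bin1_id] == chrom_of[cell.bin2_id]
        cnt = np.asarray(cell.count, np.float64)
        for ci in range(binning.n_chroms):
            on = intra & (chrom_of[cell.bin1_id] == ci)
            short = cnt[on & (d > 0) & (d <= thr_bins)].sum()
            long_ = cnt[on & (d > thr_bins)].sum()
            if long_ == 0:
                feats[r, ci] = SVL_SENTINEL
                sentinel_cells.append((cell.cell_id, binning.chrom_names[ci]))
            else:
                feats[r, ci] = short / long_
    return EmbeddingMatrix(container.cell_ids, feats, "svl",
                           {"distance_threshold": distance_threshold,
                            "sentinel": SVL_SENTINEL,
                            "sentinel_cells": sentinel_cells,
                            "degenerate_chroms": degenerate})


def obs_exp(matrix: CellMatrix, chromosome: str, binning) -> np.ndarray:
    """Observed/expected intra-chromosomal matrix.

    expected(d) is the mean observed count over *all* pixels at bin
    distance d, zeros included; entries where expected is 0 are set to 0.
    """
    lo, hi = binning.chrom_bin_range(chromosome)
    n = hi - lo
    on = ((matrix.bin1_id >= lo) & (matrix.bin1_id < hi)
          & (matrix.bin2_id >= lo) & (matrix.bin2_id < hi))
    A = np.zeros((n, n))
    i = matrix.bin1_id[on] - lo
    j = matrix.bin2_id[on] - lo
    A[i, j] = matrix.count[on]
    A[j, i] = matrix.count[on]
    out = np.zeros_like(A)
    for d in range(n):
        diag = np.diagonal(A, offset=d)
        exp = diag.mean()
        if exp > 0:
            vals = diag / exp
            idx = np.arange(n - d)
            out[idx, idx + d] = vals
            out[idx + d, idx] = vals
    return out


def _compartment_track(matrix: CellMatrix, chromosome: str,
                       binning) -> tuple[np.ndarray, bool]:
    """First eigenvector of the obs/exp Pearson correlation matrix.

    Zero-variance columns are masked to 0; returns (track, ok); ok is False
    when fewer than 3 bins are unmasked (track then all zero).
    """
    oe = obs_exp(matrix, chromosome, binning)
    n = oe.shape[0]
    var = oe.var(axis=0)
    unmasked = var > 0
    if unmasked.sum() < 3:
        return np.zeros(n), False
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(oe, rowvar=False)
    C[~np.isfinite(C)] = 0.0
    C[~unmasked, :] = 0.0
    C[:, ~unmasked] = 0.0
    evals, evecs = np.linalg.eigh(C)
    v = evecs[:, -1]  # largest eigenvalue
    v = v.copy()
    v[~unmasked] = 0.0
    # deterministic default orientation: largest-|entry| positive
    peak = np.argmax(np.abs(v))
    if v[peak] < 0:
        v = -v
    return v, True


def compartment_features(container: SCoolContainer,
                         reference: CellMatrix | None = None
                         ) -> EmbeddingMatrix:
    """Per-cell A/B compartment tracks, concatenated across chromosomes.

    For each cell and chromosome the track is the leading eigenvector of
    the Pearson correlation matrix of the observed/expected matrix, with
    its sign oriented so the dot product with the reference track (the same
    procedure applied to the pooled bulk matrix, or a user-supplied
    reference) is non-negative.
    """
    binning = container.binning
    if reference is None:
        reference = pool_to_bulk(container)
    ref_tracks = {}
    flagged = []
    for chrom in binning.chrom_names:
        ref_tracks[chrom], ok = _compartment_track(reference, chrom, binning)
        if not ok:
            flagged.append(("reference", chrom))
    feats = np.zeros((container.n_cells, binning.n_bins))
    for r, cell in enumerate(container.cells):
        pieces = []
        for chrom in binning.chrom_names:
            v, ok = _compartment_track(cell, chrom, binning)
            if not ok:
                flagged.append((cell.cell_id, chrom))
            elif float(v @ ref_tracks[chrom]) < 0:
                v = -v
            pieces.append(v)
        feats[r] = np.concatenate(pieces)
    return EmbeddingMatrix(container.cell_ids, feats, "compartments",
                           {"flagged": flagged})


def internal_knn_k(n_cells: int) -> int:
    """Default neighbor count when an embedding must become a graph."""
    return min(max(10, math.ceil(math.log2(max(n_cells, 2)))), n_cells - 1)
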