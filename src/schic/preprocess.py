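"""Normalization, matrix balancing and matrix-shape adjustments.

Three normalization modes make cells of different sequencing depth
comparable: scaling every cell to the depth of the shallowest one, scaling a
matrix to the value range [0, 1], or multiplying by a user-given factor.
Balancing removes per-bin biases by finding a diagonal scaling under which
all (unmasked) row sums agree: iterative correction (ICE) equalizes row sums
by repeated division, Knight–Ruiz (KR) balancing makes the matrix doubly
stochastic.  Bin merging coarsens the resolution; chromosome adjustment
restricts the container to a chromosome subset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .core import CellMatrix, GenomeBinning, SCoolContainer, SchicError

__all__ = ["BalancingResult", "normalize_smallest", "normalize_range01",
           "normalize_scale", "ice_correct", "kr_correct", "merge_bins",
           "adjust_chromosomes"]


# ---------------------------------------------------------------- normalization

def normalize_smallest(container: SCoolContainer) -> SCoolContainer:
    """Scale every cell to the read depth of the shallowest cell.

    Each cell is multiplied by (min total / own total), so all totals agree
    afterwards.  Idempotent.
    """
    if container.n_cells == 0:
        raise SchicError("normalize_smallest requires at least one cell")
    totals = container.totals()
    if np.any(totals <= 0):
        bad = [c.cell_id for c, t in zip(container.cells, totals) if t <= 0]
        raise SchicError(f"cells with zero total reads {bad}: run QC first")
    target = totals.min()
    cells = [replace(c, count=np.asarray(c.count, dtype=np.float64) * (target / t),
                     value_kind="normalized")
             for c, t in zip(container.cells, totals)]
    return container.with_cells(cells, f"normalize_smallest: target={target:g}")


def normalize_range01(matrix: CellMatrix) -> CellMatrix:
    """Divide every pixel by the matrix maximum, mapping values into [0, 1]."""
    if matrix.n_pixels == 0 or matrix.count.max() <= 0:
        raise SchicError(f"cell {matrix.cell_id!r}: all-zero matrix")
    if matrix.count.min() < 0:
        raise SchicError(f"cell {matrix.cell_id!r}: negative values")
    return replace(matrix,
                   count=np.asarray(matrix.count, np.float64) / matrix.count.max(),
                   value_kind="normalized")


def normalize_scale(matrix: CellMatrix, factor: float) -> CellMatrix:
    """Multiply every pixel by a user-defined positive scaling factor."""
    if factor <= 0:
        raise SchicError(f"scaling factor must be > 0, got {factor}")
    return replace(matrix, count=np.asarray(matrix.count, np.float64) * factor,
                   value_kind="normalized")


# ------------------------------------------------------------------- balancing

@dataclass
class BalancingResult:
    """Outcome of a matrix-balancing run.

    ``matrix`` holds the corrected values (raw / (bias_i * bias_j)); ``bias``
    is the per-bin factor, NaN at masked bins; ``mask`` flags bins whose full
    row is zero and which were excluded from balancing.
    """

    matrix: CellMatrix
    bias: np.ndarray
    mask: np.ndarray
    iterations: int
    converged: bool


def _dense_symmetric(matrix: CellMatrix, n_bins: int) -> np.ndarray:
    return np.asarray(matrix.to_csr(n_bins, symmetric=True).todense())


def _finish(matrix, n_bins, A_full, bias_full, mask, iterations, converged):
    with np.errstate(invalid="ignore"):
        denom = np.outer(bias_full, bias_full)
    corrected = np.where(np.isnan(denom), 0.0, A_full / np.where(
        np.isnan(denom) | (denom == 0), 1.0, denom))
    cell = CellMatrix.from_symmetric(matrix.cell_id, sp.coo_matrix(corrected),
                                     value_kind="corrected")
    return BalancingResult(cell, bias_full, mask, iterations, converged)


def ice_correct(matrix: CellMatrix, n_bins: int, max_iter: int = 1000,
                tol: float = 1e-5, mask_zero_bins: bool = True
                ) -> BalancingResult:
    """Iterative correction: repeatedly divide rows/columns by their
    (mean-normalized) row sums until the coefficient of variation of the
    unmasked row sums falls below ``tol``.

    The bias vector is renormalized to geometric mean 1 over unmasked bins.
    Non-convergence within ``max_iter`` returns ``converged=False``.
    """
    A_full = _dense_symmetric(matrix, n_bins)
    rowsum = A_full.sum(axis=1)
    mask = (rowsum == 0) if mask_zero_bins else np.zeros(n_bins, bool)
    idx = np.flatnonzero(~mask)
    if len(idx) == 0:
        raise SchicError("cannot balance an all-zero matrix")
    W = A_full[np.ix_(idx, idx)].copy()
    b = np.ones(len(idx))
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        s = W.sum(axis=1)
        if np.any(s == 0):
            raise SchicError("row became zero during iteration; mask zero bins")
        cv = s.std() / s.mean()
        if cv < tol:
            converged = True
            break
        d = s / s.mean()
        W /= np.outer(d, d)
        b *= d
    # geometric-mean-1 gauge for the bias
    b /= np.exp(np.mean(np.log(b)))
    bias_full = np.full(n_bins, np.nan)
    bias_full[idx] = b
    return _finish(matrix, n_bins, A_full, bias_full, mask, iterations, converged)


def kr_correct(matrix: CellMatrix, n_bins: int, tol: float = 1e-6,
               max_iter: int = 100_000) -> BalancingResult:
    """Knight–Ruiz-style balancing: find a diagonal scaling making the
    corrected matrix doubly stochastic (every unmasked row sums to 1).

    Solved by the damped symmetric fixed point y <- sqrt(y / (A y)), where
    the corrected matrix is diag(y) A diag(y); requires the unmasked support
    to be irreducible (connected).
    """
    A_full = _dense_symmetric(matrix, n_bins)
    rowsum = A_full.sum(axis=1)
    mask = rowsum == 0
    idx = np.flatnonzero(~mask)
    if len(idx) == 0:
        raise SchicError("cannot balance an all-zero matrix")
    W = A_full[np.ix_(idx, idx)]
    y = 1.0 / np.sqrt(W.sum(axis=1))
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        Ay = W @ y
        resid = np.max(np.abs(y * Ay - 1.0))
        if resid < tol:
            converged = True
            break
        y = np.sqrt(y / Ay)
    if not converged:
        # diagnose: a disconnected support can still balance (each component
        # independently); failure to converge means the support lacks total
        # support, so name the components to help locate the defect
        n_comp, labels = connected_components(sp.csr_matrix(W != 0),
                                              directed=False)
        comp0 = [int(idx[i]) for i in np.flatnonzero(labels == labels[0])]
        raise SchicError(
            f"matrix is not balanceable: no convergence in {max_iter} "
            f"iterations (residual {resid:.3g}; support has {n_comp} "
            f"connected component(s), first: {comp0})")
    bias_full = np.full(n_bins, np.nan)
    bias_full[idx] = 1.0 / y  # corrected = raw / (bias_i bias_j)
    return _finish(matrix, n_bins, A_full, bias_full, mask, iterations, converged)


# ------------------------------------------------------------- shape adjustment

def merge_bins(container: SCoolContainer, n: int) -> SCoolContainer:
    """Merge runs of ``n`` consecutive bins within each chromosome.

    The resolution becomes ``n * bin_size``; counts are summed, so per-cell
    totals are conserved exactly.  The last run of a chromosome may cover
    fewer than ``n`` bins.
    """
    if int(n) != n or n < 1:
        raise SchicError(f"merge factor must be an integer >= 1, got {n}")
    n = int(n)
    if n == 1:
        return container
    old = container.binning
    new = GenomeBinning(old.chrom_names, old.chrom_lengths, old.bin_size * n)
    # old global bin id -> new global bin id
    chrom_of = old.bin_chrom_index()
    local = np.arange(old.n_bins) - old.chrom_offsets[chrom_of]
    bin_map = new.chrom_offsets[chrom_of] + local // n
    cells = []
    for c in container.cells:
        b1 = bin_map[c.bin1_id]
        b2 = bin_map[c.bin2_id]
        key = b1 * new.n_bins + b2
        uniq, inv = np.unique(key, return_inverse=True)
        summed = np.bincount(inv, weights=np.asarray(c.count, np.float64),
                             minlength=len(uniq))
        if c.value_kind == "raw-count":
            summed = summed.astype(np.int64)
        cells.append(CellMatrix(c.cell_id, uniq // new.n_bins,
                                uniq % new.n_bins, summed, c.value_kind))
    out = SCoolContainer(new, cells,
                         container.provenance + [f"merge_bins: n={n}"])
    out.validate()
    return out


def adjust_chromosomes(container: SCoolContainer,
                       keep: list[str] | None = None,
                       remove: list[str] | None = None) -> SCoolContainer:
    """Restrict the container to a chromosome subset.

    Exactly one of ``keep``/``remove`` must be given; bin ids are re-indexed
    contiguously over the surviving chromosomes (original order preserved).
    """
    if (keep is None) == (remove is None):
        raise SchicError("give exactly one of keep= or remove=")
    old = container.binning
    wanted = set(keep) if keep is not None else set(remove)
    unknown = wanted - set(old.chrom_names)
    if unknown:
        raise SchicError(f"unknown chromosome names: {sorted(unknown)}")
    if keep is not None:
        survive = [c for c in old.chrom_names if c in wanted]
    else:
        survive = [c for c in old.chrom_names if c not in wanted]
    if not survive:
        raise SchicError("no chromosomes left after adjustment")
    new = GenomeBinning(
        tuple(survive),
        tuple(old.chrom_lengths[old.chrom_names.index(c)] for c in survive),
        old.bin_size)
    # old global bin id -> new global bin id (-1 = dropped)
    bin_map = np.full(old.n_bins, -1, dtype=np.int64)
    for c in survive:
        lo, hi = old.chrom_bin_range(c)
        nlo, nhi = new.chrom_bin_range(c)
        bin_map[lo:hi] = np.arange(nlo, nhi)
    cells = []
    for c in container.cells:
        ok = (bin_map[c.bin1_id] >= 0) & (bin_map[c.bin2_id] >= 0)
        cells.append(CellMatrix(c.cell_id, bin_map[c.bin1_id[ok]],
                                bin_map[c.bin2_id[ok]], c.count[ok],
                                c.value_kind))
    out = SCoolContainer(new, cells, container.provenance
                         + [f"adjust_chromosomes: kept {survive}"])
    out.validate()
    return out
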