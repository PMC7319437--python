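"""Cluster summaries: consensus matrices and contact-decay profiles.

A consensus matrix pools all cells of one cluster into a single interaction
matrix; consensus matrices are then normalized to the same read coverage
(the smallest cluster total) so clusters of different size stay comparable.
A decay profile shows, per cell, the distribution of contacts over genomic
distance from the main diagonal out to a maximum distance (50 Mb by
default), with cells grouped by cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .core import CellMatrix, SCoolContainer, SchicError
from .io_scool import pool_to_bulk

__all__ = ["ConsensusSet", "DecayProfile", "build_consensus",
           "decay_profiles", "render_consensus", "render_profiles"]

DEFAULT_MAX_DISTANCE = 50_000_000  # profile extends to 50 Mb off-diagonal


@dataclass
class ConsensusSet:
    """Per-cluster pooled matrices, coverage-normalized across clusters."""

    matrices: dict[int, CellMatrix]
    member_counts: dict[int, int]
    target_total: float
    binning: object = None


@dataclass
class DecayProfile:
    """Cells x distances contact-frequency distributions, cluster-ordered."""

    cell_ids: list[str]
    labels: np.ndarray
    distances: np.ndarray  # genomic distances in bp, 0..max inclusive
    values: np.ndarray     # rows sum to 1 (degenerate zero-count cells flagged)
    degenerate_cells: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values,
                          columns=[str(int(d)) for d in self.distances])
        df.insert(0, "label", self.labels)
        df.insert(0, "cell_id", self.cell_ids)
        return df


def _labels_in_order(assignment: ClusterAssignment,
                     container: SCoolContainer) -> dict[str, int]:
    lookup = dict(zip(assignment.cell_ids, assignment.labels))
    missing = [c for c in container.cell_ids if c not in lookup]
    if missing:
        raise SchicError(f"assignment does not cover cells: {missing}")
    return lookup


def build_consensus(container: SCoolContainer,
                    assignment: ClusterAssignment) -> ConsensusSet:
    """Sum member matrices per cluster, then scale every consensus to the
    smallest cluster total.

    Invariant to cell order within clusters; labels with no members are
    skipped with a warning.
    """
    lookup = _labels_in_order(assignment, container)
    groups: dict[int, list] = {}
    for cell in container.cells:
        groups.setdefault(int(lookup[cell.cell_id]), []).append(cell)
    declared = set(int(l) for l in assignment.labels) | set(range(assignment.K))
    empty = sorted(declared - set(groups))
    if empty:
        warnings.warn(f"clusters with no member cells skipped: {empty}",
                      stacklevel=2)
    summed = {}
    for label in sorted(groups):
        sub = container.with_cells(groups[label])
        m = pool_to_bulk(sub)
        m.cell_id = f"cluster_{label}"
        summed[label] = m
    target = min(m.total_reads for m in summed.values())
    matrices = {}
    for label, m in summed.items():
        scale = target / m.total_reads
        matrices[label] = CellMatrix(
            m.cell_id, m.bin1_id, m.bin2_id,
            np.asarray(m.count, np.float64) * scale, "normalized")
    return ConsensusSet(matrices,
                        {l: len(g) for l, g in groups.items()},
                        float(target), container.binning)


def decay_profiles(container: SCoolContainer,
                   assignment: ClusterAssignment,
                   max_distance: int = DEFAULT_MAX_DISTANCE) -> DecayProfile:
    """Per-cell contact frequency vs genomic distance from the diagonal.

    Distance d runs from 0 to ``max_distance`` inclusive in bin steps; the
    value at d sums counts at bin offset d/bin_size over all chromosomes.
    Each row is normalized to sum 1 (relative frequencies, so coverage
    differences do not dominate); rows are ordered by cluster label, then
    original container order.
    """
    binning = container.binning
    bs = binning.bin_size
    if max_distance < bs:
        raise SchicError("max_distance must be >= bin_size")
    lookup = _labels_in_order(assignment, container)
    n_d = max_distance // bs + 1
    chrom_of = binning.bin_chrom_index()
    order = sorted(range(container.n_cells),
                   key=lambda i: (lookup[container.cell_ids[i]], i))
    cells = [container.cells[i] for i in order]
    values = np.zeros((len(cells), n_d))
    degenerate = []
    for r, cell in enumerate(cells):
        d = cell.bin2_id - cell.bin1_id
        ok = (chrom_of[cell.bin1_id] == chrom_of[cell.bin2_id]) & (d < n_d)
        row = np.bincount(d[ok], weights=np.asarray(cell.count[ok], np.float64),
                          minlength=n_d)
        total = row.sum()
        if total > 0:
            values[r] = row / total
        else:
            degenerate.append(cell.cell_id)
    return DecayProfile(
        [c.cell_id for c in cells],
        np.array([lookup[c.cell_id] for c in cells], dtype=np.int64),
        np.arange(n_d, dtype=np.int64) * bs, values, degenerate)


# ------------------------------------------------------------------ rendering

def _dense(matrix: CellMatrix, n_bins: int) -> np.ndarray:
    return np.asarray(matrix.to_csr(n_bins, symmetric=True).todense())


def render_consensus(cset: ConsensusSet, prefix: str) -> list[str]:
    """Log-scaled heatmap per consensus matrix, plus a pixel table (TSV)
    alongside each image so the numbers are inspectable; returns the paths
    written.  Empty clusters were already skipped at build time."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_bins = cset.binning.n_bins
    paths = []
    for label, m in sorted(cset.matrices.items()):
        tsv = f"{prefix}_cluster{label}.tsv"
        pd.DataFrame({"bin1_id": m.bin1_id, "bin2_id": m.bin2_id,
                      "value": m.count}).to_csv(tsv, sep="\t", index=False)
        png = f"{prefix}_cluster{label}.png"
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(np.log1p(_dense(m, n_bins)), cmap="YlOrRd",
                  interpolation="nearest")
        ax.set_title(f"cluster {label} (n={cset.member_counts[label]})")
        ax.set_xlabel("bin")
        ax.set_ylabel("bin")
        fig.savefig(png, dpi=100)
        plt.close(fig)
        paths.extend([tsv, png])
    return paths


def render_profiles(profile: DecayProfile, path: str) -> list[str]:
    """Cells x distance heatmap with separators between clusters; the
    numeric table is always written alongside (same path, .tsv suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tsv = path.rsplit(".", 1)[0] + ".tsv"
    profile.to_frame().to_csv(tsv, sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(profile.values.T, aspect="auto", cmap="viridis",
              origin="lower", interpolation="nearest")
    boundaries = np.flatnonzero(np.diff(profile.labels)) + 0.5
    for b in boundaries:
        ax.axvline(b, color="white", lw=1)
    ax.set_xlabel("cells (grouped by cluster)")
    ax.set_ylabel("distance from diagonal (bins)")
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return [tsv, path]
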