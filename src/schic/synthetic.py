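"""Seeded generator of scool containers with known cluster structure.

Emulates the two statistical signals that distinguish cell populations in
single-cell Hi-C at coarse resolution: the contact-decay exponent (contact
probability falls off as a power law (1+d)^(-alpha) of bin distance d) and
an A/B-compartment checkerboard (contacts within the same compartment are
enriched, across compartments depleted, by a multiplicative contrast
epsilon, with a per-cluster phase so clusters can differ in compartment
structure).  Reads are placed multinomially over intra-chromosomal pixel
weights, so every cell has an exactly known total and the generator is
bit-reproducible given a seed.

The defaults describe the reference simulation used throughout: a 100 Mb
genome (60 + 40 Mb chromosomes) at 1 Mb resolution, three clusters of 50
cells with decay exponents 0.8 / 1.2 / 1.6 and 50 000 reads per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterAssignment
from .core import CellMatrix, GenomeBinning, SCoolContainer, SchicError

__all__ = ["SimulationSpec", "simulate_cells"]


@dataclass
class SimulationSpec:
    """Parameters of one simulated single-cell Hi-C experiment."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000_000, "chr2": 40_000_000})
    bin_size: int = 1_000_000
    cells_per_cluster: int = 50
    #: one decay exponent per cluster (K = len(decay_exponents))
    decay_exponents: tuple[float, ...] = (0.8, 1.2, 1.6)
    #: reads per cell: fixed count, or ("lognormal", mu, sigma) of the count
    reads_per_cell: int | tuple = 50_000
    #: checkerboard contrast per cluster (0 disables compartments)
    compartment_contrast: tuple[float, ...] | float = 0.0
    compartment_block_size: int = 10_000_000
    #: per-cluster shift of the block grid, in bins; shifting the grid (not
    #: flipping A/B labels, which leaves every pair's same/different status
    #: unchanged) is what makes cluster compartment patterns distinct
    compartment_phase: tuple[int, ...] | int = 0
    seed: int = 0

    @property
    def K(self) -> int:
        return len(self.decay_exponents)

    def _per_cluster(self, value, name) -> tuple:
        if np.isscalar(value):
            return tuple([value] * self.K)
        if len(value) != self.K:
            raise SchicError(f"{name} must have one entry per cluster")
        return tuple(value)

    def validate(self) -> None:
        if self.bin_size < 1 or any(l < 1 for l in self.chrom_lengths.values()):
            raise SchicError("invalid genome geometry")
        if self.cells_per_cluster < 1 or self.K < 1:
            raise SchicError("need at least one cell and one cluster")
        if any(a <= 0 for a in self.decay_exponents):
            raise SchicError("decay exponents must be positive")
        eps = self._per_cluster(self.compartment_contrast, "compartment_contrast")
        if any(e < 0 for e in eps):
            raise SchicError("compartment contrast must be >= 0")
        if isinstance(self.reads_per_cell, tuple):
            kind = self.reads_per_cell[0]
            if kind != "lognormal" or len(self.reads_per_cell) != 3:
                raise SchicError(
                    "reads_per_cell must be an int or ('lognormal', mu, sigma)")
        elif self.reads_per_cell < 0:
            raise SchicError("reads_per_cell must be >= 0")


def _cluster_weights(binning: GenomeBinning, alpha: float, eps: float,
                     block_bins: int, phase: int):
    """Per-chromosome upper-triangle pixel ids and sampling weights."""
    b1_all, b2_all, w_all = [], [], []
    for ci, nb in enumerate(binning.bins_per_chrom):
        off = int(binning.chrom_offsets[ci])
        i, j = np.triu_indices(int(nb))
        w = (1.0 + (j - i)) ** (-alpha)
        if eps > 0:
            side = ((np.arange(nb) + phase) // block_bins) % 2
            same = side[i] == side[j]
            w = w * np.clip(np.where(same, 1.0 + eps, 1.0 - eps), 0.0, None)
        b1_all.append(i + off)
        b2_all.append(j + off)
        w_all.append(w)
    return (np.concatenate(b1_all), np.concatenate(b2_all),
            np.concatenate(w_all))


def simulate_cells(spec: SimulationSpec
                   ) -> tuple[SCoolContainer, ClusterAssignment]:
    """Draw a container of simulated cells plus the ground-truth labels.

    For a cell of cluster kappa, intra-chromosomal pixel (i, j) has sampling
    weight (1+|i-j|)^(-alpha_kappa) * clip(1 +/- epsilon_kappa, 0) — plus for
    same-compartment pairs, minus across — and the cell's reads are placed
    multinomially over those weights.  Deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    binning = GenomeBinning.from_sizes(spec.chrom_lengths, spec.bin_size)
    eps = spec._per_cluster(spec.compartment_contrast, "compartment_contrast")
    phase = spec._per_cluster(spec.compartment_phase, "compartment_phase")
    block_bins = max(1, spec.compartment_block_size // spec.bin_size)
    cells, labels = [], []
    for k, alpha in enumerate(spec.decay_exponents):
        b1, b2, w = _cluster_weights(binning, alpha, eps[k], block_bins,
                                     phase[k])
        p = w / w.sum()
        for c in range(spec.cells_per_cluster):
            if isinstance(spec.reads_per_cell, tuple):
                _, mu, sigma = spec.reads_per_cell
                n_reads = int(round(rng.lognormal(mu, sigma)))
            else:
                n_reads = int(spec.reads_per_cell)
            counts = rng.multinomial(n_reads, p)
            nz = counts > 0
            cells.append(CellMatrix(f"cluster{k}_cell{c:03d}",
                                    b1[nz], b2[nz], counts[nz].astype(np.int64)))
            labels.append(k)
    container = SCoolContainer(binning, cells,
                               [f"simulate_cells: seed={spec.seed} K={spec.K} "
                                f"cells_per_cluster={spec.cells_per_cluster}"])
    container.validate()
    truth = ClusterAssignment([c.cell_id for c in cells],
                              np.array(labels, dtype=np.int64), spec.K,
                              "truth", seed=spec.seed)
    return container, truth
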