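"""Per-cell quality control: read coverage and matrix sparsity.

Cells with too few total reads or too sparse an intra-chromosomal contact
pattern carry little structural information and are removed before
normalization and clustering.  The default coverage threshold keeps cells
with at least 100 000 reads and discards those strictly below it; no default
sparsity threshold is imposed (``min_density=0`` disables the check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SCoolContainer, SchicError

__all__ = ["QCReport", "compute_qc", "filter_cells"]

DEFAULT_MIN_READS = 100_000


@dataclass(frozen=True)
class QCReport:
    """Per-cell QC records plus the thresholds that produced them.

    ``sparsity`` is the fraction of possible intra-chromosomal
    upper-triangle pixels (diagonal included) that are non-zero; only
    intra-chromosomal pixels count, since inter-chromosomal signal in
    single-cell Hi-C at coarse resolution is overwhelmingly noise.
    """

    records: pd.DataFrame  # cell_id, total_reads, sparsity, pass, fail_reason
    min_reads: float
    min_density: float

    def passing_ids(self) -> list[str]:
        return list(self.records.loc[self.records["pass"], "cell_id"])

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _possible_intra_pixels(binning) -> int:
    nb = binning.bins_per_chrom
    return int((nb * (nb + 1) // 2).sum())


def _qc_record(cell, binning, possible: int) -> tuple[float, float]:
    chrom_of = binning.bin_chrom_index()
    intra = chrom_of[cell.bin1_id] == chrom_of[cell.bin2_id]
    nonzero = int(np.count_nonzero(cell.count[intra]))
    sparsity = nonzero / possible if possible else 0.0
    return cell.total_reads, sparsity


def compute_qc(container: SCoolContainer,
               min_reads: float = DEFAULT_MIN_READS,
               min_density: float = 0.0) -> QCReport:
    """Compute per-cell totals and sparsity and flag pass/fail.

    A cell passes iff ``total_reads >= min_reads`` and
    ``sparsity >= min_density``; a cell failing both reports ``low_reads``
    (the coverage check wins).
    """
    if container.n_cells == 0:
        raise SchicError("QC requires at least one cell")
    possible = _possible_intra_pixels(container.binning)
    rows = []
    for cell in container.cells:
        total, sparsity = _qc_record(cell, container.binning, possible)
        if total < min_reads:
            reason = "low_reads"
        elif sparsity < min_density:
            reason = "too_sparse"
        else:
            reason = "none"
        rows.append((cell.cell_id, total, sparsity, reason == "none", reason))
    records = pd.DataFrame(rows, columns=["cell_id", "total_reads",
                                          "sparsity", "pass", "fail_reason"])
    return QCReport(records, float(min_reads), float(min_density))


def filter_cells(container: SCoolContainer,
                 min_reads: float = DEFAULT_MIN_READS,
                 min_density: float = 0.0
                 ) -> tuple[SCoolContainer, QCReport]:
    """Drop cells below the coverage or density thresholds.

    Returns the filtered container (passing cells, original order) and the
    QC report covering every input cell.  Filtering is idempotent and
    monotone in both thresholds.
    """
    report = compute_qc(container, min_reads=min_reads, min_density=min_density)
    keep = set(report.passing_ids())
    kept = [c for c in container.cells if c.cell_id in keep]
    if not kept:
        warnings.warn("QC removed every cell; returning an empty container",
                      stacklevel=2)
    out = container.with_cells(
        kept, f"filter_cells: min_reads={min_reads} min_density={min_density} "
              f"kept {len(kept)}/{container.n_cells}")
    return out, report
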