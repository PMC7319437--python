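"""Core domain types for single-cell Hi-C containers.

A single-cell Hi-C experiment yields one sparse contact matrix per cell, all
sharing a genome-wide binning at a fixed resolution.  The in-memory model
mirrors the on-disk scool layout: one :class:`GenomeBinning` shared by an
ordered collection of :class:`CellMatrix` records inside a
:class:`SCoolContainer`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["GenomeBinning", "CellMatrix", "SCoolContainer", "SchicError",
           "FormatError", "ConsistencyError"]


class SchicError(ValueError):
    """Base class for domain errors."""


class FormatError(SchicError):
    """On-disk layout does not follow the expected schema."""


class ConsistencyError(SchicError):
    """Records that must agree (bin tables, cell ids) do not."""


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-size genomic binning: the coordinate system of every matrix.

    Bins tile each chromosome contiguously from 0 in half-open
    ``[start, end)`` intervals of ``bin_size`` base pairs; the last bin of a
    chromosome may be shorter.  Global bin ids are 0-based and increase in
    (chromosome order, start).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise SchicError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise SchicError("duplicate chromosome names")
        if self.bin_size < 1:
            raise SchicError(f"bin_size must be >= 1, got {self.bin_size}")
        if any(l < 1 for l in self.chrom_lengths):
            raise SchicError("chromosome lengths must be positive")
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths",
                           tuple(int(l) for l in self.chrom_lengths))

    @classmethod
    def from_sizes(cls, chrom_sizes: dict[str, int] | pd.DataFrame,
                   bin_size: int) -> "GenomeBinning":
        """Build from a chromosome-sizes table (name -> length in bp)."""
        if isinstance(chrom_sizes, pd.DataFrame):
            names = tuple(chrom_sizes.iloc[:, 0].astype(str))
            lengths = tuple(int(x) for x in chrom_sizes.iloc[:, 1])
        else:
            names = tuple(chrom_sizes)
            lengths = tuple(int(chrom_sizes[n]) for n in names)
        return cls(names, lengths, int(bin_size))

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    @property
    def bins_per_chrom(self) -> np.ndarray:
        return np.array([-(-l // self.bin_size) for l in self.chrom_lengths],
                        dtype=np.int64)

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Global bin id of the first bin of each chromosome, plus n_bins."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)])

    @property
    def n_bins(self) -> int:
        return int(self.bins_per_chrom.sum())

    @property
    def bins(self) -> pd.DataFrame:
        """Ordered bin table with columns chrom, start, end (half-open)."""
        chroms, starts, ends = [], [], []
        for name, length, nb in zip(self.chrom_names, self.chrom_lengths,
                                    self.bins_per_chrom):
            s = np.arange(nb, dtype=np.int64) * self.bin_size
            e = np.minimum(s + self.bin_size, length)
            chroms.extend([name] * int(nb))
            starts.append(s)
            ends.append(e)
        return pd.DataFrame({
            "chrom": pd.Series(chroms, dtype=str),
            "start": np.concatenate(starts) if starts else np.array([], dtype=np.int64),
            "end": np.concatenate(ends) if ends else np.array([], dtype=np.int64),
        })

    def bin_chrom_index(self) -> np.ndarray:
        """Chromosome index (into chrom_names) of every global bin."""
        return np.repeat(np.arange(self.n_chroms), self.bins_per_chrom)

    def chrom_bin_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global bin id range [lo, hi) of one chromosome."""
        try:
            ci = self.chrom_names.index(chrom)
        except ValueError:
            raise SchicError(f"unknown chromosome {chrom!r}") from None
        off = self.chrom_offsets
        return int(off[ci]), int(off[ci + 1])


@dataclass
class CellMatrix:
    """One cell's sparse upper-triangular contact matrix.

    Pixels are parallel arrays ``(bin1_id, bin2_id, count)`` with
    ``bin1_id <= bin2_id``, sorted by (bin1_id, bin2_id), no duplicates.
    ``value_kind`` is one of ``raw-count``, ``corrected``, ``normalized``.
    """

    cell_id: str
    bin1_id: np.ndarray
    bin2_id: np.ndarray
    count: np.ndarray
    value_kind: str = "raw-count"

    def __post_init__(self):
        self.bin1_id = np.asarray(self.bin1_id, dtype=np.int64)
        self.bin2_id = np.asarray(self.bin2_id, dtype=np.int64)
        kind = np.int64 if self.value_kind == "raw-count" else np.float64
        self.count = np.asarray(self.count, dtype=kind)
        if not (len(self.bin1_id) == len(self.bin2_id) == len(self.count)):
            raise SchicError("pixel arrays must have equal length")

    @classmethod
    def from_pixels(cls, cell_id, pixels, value_kind="raw-count"):
        """Build from an iterable of (bin1_id, bin2_id, count) triplets."""
        arr = np.asarray(list(pixels), dtype=np.float64).reshape(-1, 3)
        m = cls(cell_id, arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64), arr[:, 2], value_kind)
        return m.sorted()

    @property
    def n_pixels(self) -> int:
        return len(self.count)

    @property
    def total_reads(self) -> float:
        # plain sum of stored upper-triangle pixels, not doubled for symmetry
        total = self.count.sum()
        return int(total) if self.value_kind == "raw-count" else float(total)

    def validate(self, n_bins: int) -> None:
        if self.n_pixels == 0:
            return
        if self.bin1_id.min() < 0 or self.bin2_id.max() >= n_bins:
            raise SchicError(f"cell {self.cell_id!r}: bin ids out of range "
                             f"[0, {n_bins})")
        if np.any(self.bin1_id > self.bin2_id):
            raise SchicError(f"cell {self.cell_id!r}: lower-triangle pixel present")
        if np.any(self.count < 0):
            raise SchicError(f"cell {self.cell_id!r}: negative counts")
        key = self.bin1_id * n_bins + self.bin2_id
        if len(np.unique(key)) != len(key):
            raise SchicError(f"cell {self.cell_id!r}: duplicate pixel pair")
        if self.value_kind == "raw-count" and not np.issubdtype(
                self.count.dtype, np.integer):
            raise SchicError(f"cell {self.cell_id!r}: raw counts must be integer")

    def sorted(self) -> "CellMatrix":
        """Copy with pixels in canonical (bin1_id, bin2_id) order."""
        order = np.lexsort((self.bin2_id, self.bin1_id))
        return replace(self, bin1_id=self.bin1_id[order],
                       bin2_id=self.bin2_id[order], count=self.count[order])

    def to_csr(self, n_bins: int, symmetric: bool = True) -> sp.csr_matrix:
        """Dense-shape sparse matrix; symmetric=True mirrors the upper triangle."""
        m = sp.coo_matrix(
            (self.count.astype(np.float64), (self.bin1_id, self.bin2_id)),
            shape=(n_bins, n_bins))
        if symmetric:
            off = self.bin1_id != self.bin2_id
            m = m + sp.coo_matrix(
                (self.count[off].astype(np.float64),
                 (self.bin2_id[off], self.bin1_id[off])),
                shape=(n_bins, n_bins))
        return m.tocsr()

    @classmethod
    def from_symmetric(cls, cell_id: str, mat, value_kind="raw-count"):
        """Build from a symmetric (sparse or dense) matrix, keeping i <= j."""
        coo = sp.coo_matrix(mat)
        keep = coo.row <= coo.col
        m = cls(cell_id, coo.row[keep], coo.col[keep],
                coo.data[keep], value_kind)
        return m.sorted()

    def equal_pixels(self, other: "CellMatrix") -> bool:
        a, b = self.sorted(), other.sorted()
        return (np.array_equal(a.bin1_id, b.bin1_id)
                and np.array_equal(a.bin2_id, b.bin2_id)
                and np.array_equal(a.count, b.count))


@dataclass
class SCoolContainer:
    """A shared binning plus an ordered collection of per-cell matrices."""

    binning: GenomeBinning
    cells: list[CellMatrix] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConsistencyError(f"duplicate cell ids: {dup}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    def validate(self) -> None:
        nb = self.binning.n_bins
        for c in self.cells:
            c.validate(nb)

    def with_cells(self, cells, note: str | None = None) -> "SCoolContainer":
        prov = list(self.provenance) + ([note] if note else [])
        return SCoolContainer(self.binning, list(cells), prov)

    def totals(self) -> np.ndarray:
        return np.array([c.total_reads for c in self.cells], dtype=np.float64)

    def __eq__(self, other):
        if not isinstance(other, SCoolContainer):
            return NotImplemented
        return (self.binning == other.binning
                and self.cell_ids == other.cell_ids
                and all(a.value_kind == b.value_kind and a.equal_pixels(b)
                        for a, b in zip(self.cells, other.cells)))
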