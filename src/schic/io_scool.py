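"""Read, write and merge per-cell contact matrices in the cooler/scool HDF5 layout.

The scool container stores one genome binning (``chroms/{name,length}`` and
``bins/{chrom,start,end}``) at the root, shared by per-cell groups
``cells/<cell_id>`` each holding a ``pixels/{bin1_id,bin2_id,count}`` table and
``indexes/{chrom_offset,bin1_offset}``.  A plain cool file is the same layout
with a single pixel table at the root.  Exactly one resolution per file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import h5py
import numpy as np

from .core import (CellMatrix, ConsistencyError, FormatError, GenomeBinning,
                   SCoolContainer, SchicError)

__all__ = ["read_scool", "write_scool", "read_cool", "write_cool",
           "merge_cells_to_scool", "pool_to_bulk", "info", "ContainerInfo"]

_SCOOL_FORMAT = "HDF5::SCOOL"
_COOL_FORMAT = "HDF5::Cooler"


def _require(group, name: str, path: str):
    if name not in group:
        raise FormatError(f"missing {path!r} in {group.file.filename}")
    return group[name]


def _write_binning(h5: h5py.Group, binning: GenomeBinning) -> None:
    chroms = h5.create_group("chroms")
    chroms.create_dataset("name", data=np.array(binning.chrom_names, dtype="S"))
    chroms.create_dataset("length",
                          data=np.array(binning.chrom_lengths, dtype=np.int64))
    bins = h5.create_group("bins")
    bins.create_dataset("chrom", data=binning.bin_chrom_index().astype(np.int32))
    table = binning.bins
    bins.create_dataset("start", data=table["start"].to_numpy(np.int64))
    bins.create_dataset("end", data=table["end"].to_numpy(np.int64))


def _read_binning(h5: h5py.Group, prefix: str = "") -> GenomeBinning:
    chroms = _require(h5, "chroms", prefix + "chroms")
    names = [n.decode() for n in _require(chroms, "name", prefix + "chroms/name")[:]]
    lengths = _require(chroms, "length", prefix + "chroms/length")[:]
    bin_size = int(h5.attrs["bin-size"])
    binning = GenomeBinning(tuple(names), tuple(int(l) for l in lengths), bin_size)
    # cross-check the stored bin table against the derived one
    bins = _require(h5, "bins", prefix + "bins")
    start = _require(bins, "start", prefix + "bins/start")[:]
    table = binning.bins
    if len(start) != binning.n_bins or not np.array_equal(
            start, table["start"].to_numpy()):
        raise ConsistencyError(
            f"bins table in {h5.file.filename} does not match chroms/bin-size")
    return binning


def _write_pixels(group: h5py.Group, cell: CellMatrix,
                  binning: GenomeBinning) -> None:
    cell = cell.sorted()
    pix = group.create_group("pixels")
    pix.create_dataset("bin1_id", data=cell.bin1_id)
    pix.create_dataset("bin2_id", data=cell.bin2_id)
    pix.create_dataset("count", data=cell.count)
    idx = group.create_group("indexes")
    idx.create_dataset("chrom_offset", data=binning.chrom_offsets.astype(np.int64))
    idx.create_dataset(
        "bin1_offset",
        data=np.searchsorted(cell.bin1_id,
                             np.arange(binning.n_bins + 1)).astype(np.int64))
    group.attrs["value_kind"] = cell.value_kind
    group.attrs["sum"] = cell.total_reads


def _read_pixels(group: h5py.Group, cell_id: str, path: str) -> CellMatrix:
    pix = _require(group, "pixels", path + "/pixels")
    b1 = _require(pix, "bin1_id", path + "/pixels/bin1_id")[:]
    b2 = _require(pix, "bin2_id", path + "/pixels/bin2_id")[:]
    cnt = _require(pix, "count", path + "/pixels/count")[:]
    kind = group.attrs.get("value_kind", "raw-count")
    return CellMatrix(cell_id, b1, b2, cnt, str(kind)).sorted()


def write_scool(container: SCoolContainer, path: str | os.PathLike) -> None:
    """Write a container to the scool HDF5 layout.

    Content is deterministic for identical input: no timestamps, cells stored
    in container order under ``cells/<cell_id>``.
    """
    container.validate()
    with h5py.File(path, "w", track_order=True) as h5:
        h5.attrs["format"] = _SCOOL_FORMAT
        h5.attrs["bin-size"] = container.binning.bin_size
        h5.attrs["nbins"] = container.binning.n_bins
        h5.attrs["nchroms"] = container.binning.n_chroms
        h5.attrs["ncells"] = container.n_cells
        h5.attrs["provenance"] = "\n".join(container.provenance)
        _write_binning(h5, container.binning)
        cells = h5.create_group("cells", track_order=True)
        for cell in container.cells:
            _write_pixels(cells.create_group(cell.cell_id), cell,
                          container.binning)


def read_scool(path: str | os.PathLike) -> SCoolContainer:
    """Read an scool file into memory, normalizing pixel order."""
    with h5py.File(path, "r") as h5:
        binning = _read_binning(h5)
        cells_grp = _require(h5, "cells", "cells")
        cells = []
        for cid in cells_grp:
            grp = cells_grp[cid]
            if "bins" in grp:  # per-cell bins table must agree with the root
                cstart = grp["bins"]["start"][:]
                if not np.array_equal(cstart,
                                      binning.bins["start"].to_numpy()):
                    raise ConsistencyError(
                        f"cell {cid!r} carries a bins table that differs "
                        f"from the root bins table")
            cells.append(_read_pixels(grp, cid, f"cells/{cid}"))
        prov = str(h5.attrs.get("provenance", ""))
    provenance = [l for l in prov.split("\n") if l]
    out = SCoolContainer(binning, cells, provenance)
    out.validate()
    return out


def write_cool(cell: CellMatrix, binning: GenomeBinning,
               path: str | os.PathLike) -> None:
    """Write a single matrix as a cool file."""
    cell.validate(binning.n_bins)
    with h5py.File(path, "w", track_order=True) as h5:
        h5.attrs["format"] = _COOL_FORMAT
        h5.attrs["bin-size"] = binning.bin_size
        h5.attrs["nbins"] = binning.n_bins
        h5.attrs["nchroms"] = binning.n_chroms
        _write_binning(h5, binning)
        _write_pixels(h5, cell, binning)


def read_cool(path: str | os.PathLike) -> tuple[CellMatrix, GenomeBinning]:
    """Read a single-matrix cool file; cell_id is the basename sans extension."""
    cell_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    with h5py.File(path, "r") as h5:
        binning = _read_binning(h5)
        cell = _read_pixels(h5, cell_id, "/")
    cell.validate(binning.n_bins)
    return cell, binning


def merge_cells_to_scool(cell_paths: list[str | os.PathLike]) -> SCoolContainer:
    """Merge individual cool files into one container.

    All files must share an identical binning; cell ids derive from file
    names (basename, extension stripped) and must be unique.
    """
    if not cell_paths:
        raise SchicError("no input files given")
    cells, binning = [], None
    mismatched = []
    for p in cell_paths:
        cell, b = read_cool(p)
        if binning is None:
            binning = b
        elif b != binning:
            mismatched.append(os.fspath(p))
            continue
        cells.append(cell)
    if mismatched:
        raise ConsistencyError(
            f"bin tables differ from first input in: {mismatched}")
    ids = [c.cell_id for c in cells]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise ConsistencyError(f"duplicate cell ids from file names: {dup}")
    return SCoolContainer(binning, cells,
                          [f"merge_cells_to_scool: {len(cells)} files"])


def pool_to_bulk(container: SCoolContainer) -> CellMatrix:
    """Pixel-wise sum of all cells: the pooled bulk Hi-C matrix."""
    if container.n_cells == 0:
        raise SchicError("cannot pool an empty container")
    nb = container.binning.n_bins
    keys = np.concatenate([c.bin1_id * nb + c.bin2_id for c in container.cells])
    vals = np.concatenate([np.asarray(c.count, dtype=np.float64)
                           for c in container.cells])
    uniq, inv = np.unique(keys, return_inverse=True)
    sums = np.bincount(inv, weights=vals, minlength=len(uniq))
    kind = container.cells[0].value_kind
    counts = sums.astype(np.int64) if kind == "raw-count" else sums
    return CellMatrix("bulk", uniq // nb, uniq % nb, counts, kind)


@dataclass(frozen=True)
class ContainerInfo:
    n_cells: int
    n_bins: int
    bin_size: int
    chromosomes: tuple[str, ...]
    min_reads: float | None
    median_reads: float | None
    max_reads: float | None

    def __str__(self):
        lines = [f"cells:        {self.n_cells}",
                 f"bins:         {self.n_bins}",
                 f"bin size:     {self.bin_size}",
                 f"chromosomes:  {', '.join(self.chromosomes)}"]
        if self.min_reads is None:
            lines.append("read totals:  absent (no cells)")
        else:
            lines.append(f"read totals:  min {self.min_reads:g} / "
                         f"median {self.median_reads:g} / max {self.max_reads:g}")
        return "\n".join(lines)


def info(container: SCoolContainer) -> ContainerInfo:
    """Summary record: cell/bin counts, resolution, per-cell read totals."""
    totals = container.totals()
    has = len(totals) > 0
    return ContainerInfo(
        n_cells=container.n_cells,
        n_bins=container.binning.n_bins,
        bin_size=container.binning.bin_size,
        chromosomes=container.binning.chrom_names,
        min_reads=float(totals.min()) if has else None,
        median_reads=float(np.median(totals)) if has else None,
        max_reads=float(totals.max()) if has else None,
    )
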