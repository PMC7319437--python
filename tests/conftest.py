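import numpy as np
import pytest

from schic import CellMatrix, GenomeBinning, SCoolContainer, SimulationSpec, simulate_cells


@pytest.fixture
def toy_binning():
    """One 4 Mb chromosome at 1 Mb resolution: 4 bins, 10 upper-tri pixels."""
    return GenomeBinning(("chr1",), (4_000_000,), 1_000_000)


@pytest.fixture
def two_chrom_binning():
    """chr1: 4 bins, chr2: 2 bins at 1 Mb."""
    return GenomeBinning(("chr1", "chr2"), (4_000_000, 2_000_000), 1_000_000)


def make_cell(cell_id, pixels, value_kind="raw-count"):
    return CellMatrix.from_pixels(cell_id, pixels, value_kind)


def random_container(rng, max_cells=6, max_chroms=3, max_bins_per_chrom=10):
    """Small random-but-valid container for property tests."""
    bin_size = int(rng.integers(5, 20))
    n_chroms = int(rng.integers(1, max_chroms + 1))
    lengths = tuple(int(rng.integers(1, max_bins_per_chrom * bin_size))
                    for _ in range(n_chroms))
    binning = GenomeBinning(tuple(f"chr{i+1}" for i in range(n_chroms)),
                            lengths, bin_size)
    nb = binning.n_bins
    i, j = np.triu_indices(nb)
    cells = []
    for c in range(int(rng.integers(0, max_cells + 1))):
        n_pix = int(rng.integers(0, len(i) + 1))
        pick = rng.choice(len(i), size=n_pix, replace=False)
        counts = rng.integers(1, 100, size=n_pix)
        cells.append(CellMatrix(f"cell{c}", i[pick], j[pick],
                                counts.astype(np.int64)).sorted())
    return SCoolContainer(binning, cells)


@pytest.fixture(scope="session")
def sim_three_clusters():
    """Small 3-cluster simulation shared by downstream tests."""
    spec = SimulationSpec(cells_per_cluster=8, reads_per_cell=20_000,
                          compartment_contrast=0.5, compartment_phase=(0, 5, 3),
                          seed=7)
    return simulate_cells(spec)
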