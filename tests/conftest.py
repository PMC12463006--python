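import numpy as np
import pytest

from xciphase import SimConfig, simulate_matrix
from xciphase.core_matrix import BASE_INDEX, BaseCountMatrix


def matrix_from_reads(cell_reads, positions):
    """Build a BaseCountMatrix from {barcode: {position: {base: n_reads}}}."""
    barcodes = sorted(cell_reads)
    positions = np.asarray(sorted(positions), dtype=np.int64)
    pos_idx = {int(p): j for j, p in enumerate(positions)}
    counts = np.zeros((len(barcodes), len(positions), 4), dtype=np.int64)
    for i, bc in enumerate(barcodes):
        for pos, base_counts in cell_reads[bc].items():
            for base, n in base_counts.items():
                counts[i, pos_idx[pos], BASE_INDEX[base]] += n
    return BaseCountMatrix(barcodes=barcodes, positions=positions, counts=counts)


def matrix_from_calls(call_table, positions, depth=10):
    """Matrix where each cell expresses one base per site with fixed depth.

    ``call_table``: {barcode: {position: base}}.
    """
    reads = {
        bc: {pos: {base: depth} for pos, base in per_cell.items()}
        for bc, per_cell in call_table.items()
    }
    return matrix_from_reads(reads, positions)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, densely covered simulation: phasing should be exact."""
    cfg = SimConfig(n_cells=200, n_sites=300, p_obs=0.3, error_rate=0.0, seed=7)
    return simulate_matrix(cfg)
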