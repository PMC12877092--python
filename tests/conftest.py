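import numpy as np
import pytest
import scipy.sparse as sp

from mbstage import io_core, niche_similarity, synthetic_data


@pytest.fixture
def rook_2x2():
    """2x2 square grid with rook adjacency (4 edges)."""
    return io_core.SpotGrid(
        spots=["s0", "s1", "s2", "s3"],
        array_coords=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
        phys_coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        adjacency={("s0", "s1"), ("s0", "s2"), ("s1", "s3"), ("s2", "s3")},
    )


@pytest.fixture(scope="session")
def hex_grid_r3():
    cfg = synthetic_data.SyntheticConfig(seed=11, grid_radius=3, n_genes=40)
    grid, ab, cm, gt = synthetic_data.generate_tissue_sample(cfg, cfg.timepoints[1])
    niche_similarity.build_adjacency(grid)
    return grid


@pytest.fixture(scope="session")
def sc_dataset():
    """One synthetic single-cell dataset with lognorm layer, shared read-only."""
    cfg = synthetic_data.SyntheticConfig(seed=5, n_genes=120, n_cells=600)
    cm, meta, gt = synthetic_data.generate_single_cell_dataset(cfg)
    io_core.lognormalize(cm)
    return cfg, cm, meta, gt


def make_count_matrix(counts, prefix=("e", "g")):
    counts = np.asarray(counts)
    return io_core.CountMatrix(
        entities=[f"{prefix[0]}{i}" for i in range(counts.shape[0])],
        genes=[f"{prefix[1]}{j}" for j in range(counts.shape[1])],
        counts=sp.csr_matrix(counts),
    )
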