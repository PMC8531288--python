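import pytest

import stemscore as ss
from stemscore.simulate import STAGES


def lean_bulk_cfg(n_genes=200, n_up=20, n_down=0, seed=0):
    """Small gene universe with a minimal cell-type block, for bulk DE tests
    (the default 6-type marker set would dominate a 200-gene universe)."""
    return ss.SimConfig(
        n_genes=n_genes, n_signature_up=n_up, n_signature_down=n_down,
        cell_types=(ss.CellTypeSpec("A", "epithelial", 1.0, n_markers=2),
                    ss.CellTypeSpec("Stem", "epithelial", 0.0, n_markers=2)),
        stem_fraction=0.0, seed=seed)


@pytest.fixture(scope="session")
def small_cfg():
    return ss.SimConfig(n_genes=800,
                        cells_per_stage={s: 60 for s in STAGES},
                        seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(counts, cell table, truth) for a compact staged atlas."""
    return ss.simulate_single_cell(small_cfg)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    counts, _, _ = small_sim
    return ss.lognormalize(counts, allow_zero_cells=True)
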