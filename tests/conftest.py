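import numpy as np
import pytest
from hypothesis import settings

from tracetcr._types import CountMatrix
from tracetcr.preprocess import PreprocessConfig
from tracetcr.synthdata import SimSpec, simulate_dataset
from tracetcr.trainer import SearchSpace, fit_checkpoint

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


def make_counts(counts, genes=None, cells=None, sample="s0"):
    counts = np.asarray(counts)
    n, g = counts.shape
    cells = cells or [f"cell{i}" for i in range(n)]
    genes = genes or [f"G{j:03d}" for j in range(g)]
    return CountMatrix(
        unit_ids=cells,
        gene_ids=genes,
        counts=counts,
        sample_of_unit={c: sample for c in cells},
    )


@pytest.fixture(scope="session")
def default_sim():
    """The generator's default study conditions (strong planted program)."""
    return simulate_dataset(SimSpec(seed=1))


FAST_SPEC = dict(
    seed=5,
    n_genes=300,
    n_clones=120,
    frac_trt=0.05,
    n_up=10,
    n_down=4,
    trt_clone_size_mean=8.0,
)


@pytest.fixture(scope="session")
def fast_sim():
    """A small dataset for pipeline plumbing tests."""
    return simulate_dataset(SimSpec(**FAST_SPEC))


@pytest.fixture(scope="session")
def fast_checkpoint(fast_sim):
    """A small trained checkpoint shared across scoring tests."""
    return fit_checkpoint(
        fast_sim.counts,
        fast_sim.clone_of_cell,
        fast_sim.labels,
        PreprocessConfig(),
        SearchSpace(n_trials=2),
        seed=0,
        k_model=15,
        k_support=60,
    )
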