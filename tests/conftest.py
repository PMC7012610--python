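import numpy as np
import pytest
from hypothesis import settings

from habquant.qc import lognormalize, qc_metrics, scale_regress
from habquant.sim import CellTypeSpec, CountSimConfig, generate_counts

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_type_dataset():
    """Small two-type count matrix with markers, plus QC/norm/scaled views."""
    cfg = CountSimConfig(
        n_genes=300,
        n_cells=400,
        cell_types=[
            CellTypeSpec("A", 0.5, 20, 4.0),
            CellTypeSpec("B", 0.5, 20, 4.0),
        ],
        seed=2,
    )
    counts, truth = generate_counts(cfg)
    metrics = qc_metrics(counts)
    norm = lognormalize(counts)
    scaled = scale_regress(norm, metrics[["nUMI", "percent.mito"]].to_numpy())
    return counts, truth, metrics, norm, scaled


@pytest.fixture
def rng():
    return np.random.default_rng(0)
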