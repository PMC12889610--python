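import numpy as np
import pandas as pd
import pytest

from scplex.quant_io import QuantMatrix
from scplex.synthetic import AcquisitionConfig, GroundTruthConfig, generate_truth


@pytest.fixture(scope="session")
def small_truth_config():
    """Compact cohort for fast simulation-based tests."""
    return GroundTruthConfig(
        n_batches=4,
        n_proteins=300,
        n_cells_per_batch=27,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_truth_config):
    return generate_truth(small_truth_config)


@pytest.fixture()
def tiny_qm():
    """3 features × 4 samples with two missing cells (completeness 10/12)."""
    vals = pd.DataFrame(
        [[1.0, 2.0, np.nan, 4.0], [5.0, 6.0, 7.0, 8.0], [9.0, np.nan, 11.0, 12.0]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return QuantMatrix(values=vals, level="protein", scale="linear")


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def default_acquisition(**kw):
    return AcquisitionConfig(**kw)
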