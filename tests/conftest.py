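import numpy as np
import pytest

from mirtarget import NoiseParams, TruthRecord, simulate_paired_counts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_gaussian_dataset():
    """30-sample dataset with one planted slope of -2 and tiny residual noise."""
    planted = [TruthRecord("mir_0001", "gene_0001", "beta1", -2.0)]
    data, truth = simulate_paired_counts(
        n_samples=30, n_mirna=3, n_mrna=3, planted=planted,
        family="gaussian", noise=NoiseParams(sigma=0.01), seed=7,
    )
    return data, truth
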