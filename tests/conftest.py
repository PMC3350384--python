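import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from anchorcorr import DatasetMetadata, ExpressionDataset, SimulationConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def tiny_dataset():
    """3 features x 4 samples, 2 cancer + 2 normal, log2 scale."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [-0.5, 0.5, -1.5, 2.5]],
        index=["PSME3", "G1", "G2"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionDataset(
        metadata=DatasetMetadata(dataset_id="tiny", tissue="colon", n_samples=4),
        values=values,
        sample_class={"s1": "cancer", "s2": "cancer", "s3": "normal", "s4": "normal"},
        is_log2=True,
    )


@pytest.fixture
def planted_dataset():
    """One simulated dataset with two planted genes, analysis-ready."""
    config = SimulationConfig(
        n_genes=200,
        planted_genes=(("PGPOS", 0.8), ("PGNEG", -0.7)),
        n_samples={"cancer": 40, "disease": 0, "normal": 40},
        output_scale="log2",
        seed=7,
    )
    dataset, truth = simulate_dataset(config, tissue="colon", dataset_id="colon01")
    return dataset, truth
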