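import numpy as np
import pytest

import subnetmarkers as sm


@pytest.fixture
def tiny_dataset() -> sm.ExpressionDataset:
    """3 genes x 4 samples, classes of size 2/2, handmade values."""
    return sm.ExpressionDataset(
        gene_ids=["ga", "gb", "gc"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [0.0, 2.0, 5.0, 5.0],
                [1.0, 1.5, -1.0, -2.0],
                [3.0, 3.0, 3.0, 3.0],
            ]
        ),
        labels=np.array([1, 1, 2, 2]),
    )


@pytest.fixture(scope="session")
def planted_case():
    """The standard planted fixture: 300-node sparse network, three
    6-gene modules with effect size 2 and target correlation 0.5,
    100 + 100 samples, seed 42."""
    return sm.planted_fixture()


@pytest.fixture(scope="session")
def discovered(planted_case):
    """Top-3 markers discovered on the standard fixture at default settings."""
    network, truth, dataset = planted_case
    config = sm.RunConfig(marker_count=3)
    return sm.identify_markers(network, dataset, config)


@pytest.fixture(scope="session")
def planted_llr(planted_case):
    """LLR matrix and per-gene t-scores of the standard fixture."""
    _, _, dataset = planted_case
    params = sm.estimate_params(dataset)
    llr = sm.compute_llr(dataset, params)
    return llr, sm.gene_t_scores(llr, dataset.labels)
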