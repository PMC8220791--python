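import numpy as np
import pytest
from hypothesis import settings

from quantbench import pipeline, simulate
from quantbench.matrix import ExpressionMatrix, ModelGrouping

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


def make_matrix(values, measure="count", scale="linear", gene_ids=None, sample_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    g, s = values.shape
    return ExpressionMatrix(
        gene_ids=gene_ids or [f"g{i + 1}" for i in range(g)],
        sample_ids=sample_ids or [f"s{j + 1}" for j in range(s)],
        values=values,
        measure=measure,
        scale=scale,
    )


@pytest.fixture
def toy_counts():
    """Two genes of length (1000, 2000) with 10 fragments each."""
    return make_matrix([[10.0], [10.0]])


@pytest.fixture(scope="session")
def contaminated_dataset():
    cfg = simulate.default_config()
    samples, annotations, truth = simulate.generate_dataset(cfg, seed=1)
    return samples, ModelGrouping(annotations), truth


@pytest.fixture(scope="session")
def contaminated_report(contaminated_dataset):
    samples, grouping, _truth = contaminated_dataset
    return pipeline.run_comparison(records_by_sample=samples, grouping=grouping)


@pytest.fixture(scope="session")
def clean_dataset():
    cfg = simulate.clean_config()
    samples, annotations, truth = simulate.generate_dataset(cfg, seed=1)
    return samples, ModelGrouping(annotations), truth
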