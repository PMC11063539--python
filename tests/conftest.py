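import numpy as np
import pytest

from icluf import ClusterAssignment, OmicsMatrix, SimilarityMatrix


def make_omics(values, omic_name="omic", sample_ids=None, feature_ids=None):
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    return OmicsMatrix(
        omic_name,
        sample_ids or [f"S{i}" for i in range(n)],
        feature_ids or [f"g{j}" for j in range(f)],
        values,
    )


def make_similarity(values, role="original", omic_name="omic", sample_ids=None):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix(
        sample_ids or [f"S{i}" for i in range(len(values))],
        values,
        role,
        omic_name,
    )


def make_assignment(labels, k=None, sample_ids=None):
    labels = np.asarray(labels, dtype=int)
    return ClusterAssignment(
        sample_ids or [f"S{i}" for i in range(len(labels))],
        labels,
        k if k is not None else int(labels.max()) + 1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def block_affinity():
    """Two planted 5-sample blocks: within-block similarity 0.9, cross 0.01."""
    n = 10
    values = np.full((n, n), 0.01)
    values[:5, :5] = 0.9
    values[5:, 5:] = 0.9
    np.fill_diagonal(values, 1.0)
    return make_similarity(values), np.array([0] * 5 + [1] * 5)
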