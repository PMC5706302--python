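import numpy as np
import pytest

from tumortyper.matrix import (BinaryAlterationMatrix, FeatureDescriptor,
                               LabeledDataset)


def dataset_from_array(X, y, kinds=None, sample_ids=None) -> LabeledDataset:
    """Wrap a plain binary array into a LabeledDataset with generated
    feature descriptors (gene F000, F001, ... / kind SPM by default)."""
    X = np.asarray(X, dtype=np.uint8)
    n, p = X.shape
    if kinds is None:
        kinds = ["SPM"] * p
    features = [FeatureDescriptor(j, f"F{j:03d}", kinds[j]) for j in range(p)]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return LabeledDataset(BinaryAlterationMatrix(sample_ids, features, X),
                          np.asarray(y, dtype=np.int64))


def matrix_from_array(X, kinds=None, sample_ids=None) -> BinaryAlterationMatrix:
    return dataset_from_array(X, np.zeros(len(X)), kinds, sample_ids).matrix


@pytest.fixture
def separable_dataset() -> LabeledDataset:
    """Two classes perfectly separated by feature 0; feature 1 is noise,
    feature 2 is constant zero."""
    X = np.array([
        [1, 0, 0],
        [1, 1, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 0],
        [0, 1, 0],
        [0, 0, 0],
    ])
    y = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    return dataset_from_array(X, y)
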