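import numpy as np
import pandas as pd
import pytest

from forkscan.matrix_io import CONTROL, GENE, METABOLITE, TREATMENT, FeatureMatrix


def make_matrix(values, feature_ids=None, sample_ids=None, kinds=None, conditions=None):
    """Build a FeatureMatrix from a raw array with sensible defaults:
    metabolite features, first half of samples control, second half treatment."""
    arr = np.asarray(values, dtype=float)
    n_feat, n_samp = arr.shape
    feature_ids = feature_ids or [f"m{i:03d}" for i in range(1, n_feat + 1)]
    sample_ids = sample_ids or [f"s{i:03d}" for i in range(1, n_samp + 1)]
    if kinds is None:
        kinds = [METABOLITE] * n_feat
    if conditions is None:
        half = n_samp // 2
        conditions = [CONTROL] * half + [TREATMENT] * (n_samp - half)
    return FeatureMatrix(
        pd.DataFrame(arr, index=feature_ids, columns=sample_ids),
        pd.Series(kinds, index=feature_ids),
        pd.Series(conditions, index=sample_ids),
    )


@pytest.fixture
def toy_matrix():
    return make_matrix([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
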