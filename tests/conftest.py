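import numpy as np
import pandas as pd
import pytest

import chondropipe as cp


def random_multilabel_mask(rng, shape=(10, 10, 6), p_fore=0.15):
    labels = np.zeros(shape, dtype=np.uint8)
    fore = rng.random(shape) < p_fore
    labels[fore] = rng.integers(1, 3, size=int(fore.sum()))
    return cp.MultiLabelMask(labels=labels, spacing=(1.0, 1.0, 1.0))


def random_blob_mask(rng, shape=(14, 14, 8), n_blobs=2):
    """A few roundish blobs with holes punched in, for hull-filling tests."""
    from scipy import ndimage

    labels = np.zeros(shape, dtype=np.uint8)
    for _ in range(n_blobs):
        c = rng.integers(2, np.asarray(shape) - 2)
        r = rng.integers(2, 4)
        grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
        d2 = ((grid - c) ** 2).sum(-1)
        blob = d2 <= r ** 2
        # punch a hole
        hole = d2 <= max(r - 2, 0) ** 2
        lab = int(rng.integers(1, 3))
        labels[blob & ~hole] = lab
    return cp.MultiLabelMask(labels=labels, spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def balanced_cohort():
    """50 EC + 50 ACT phantom cases at defaults (the calibration cohort)."""
    return cp.generate_cohort_records(0, 50, 50, master_seed=7)


@pytest.fixture(scope="session")
def balanced_features(balanced_cohort):
    rows = {c.case_id: cp.extract_all(c.volume, c.gt_mask) for c in balanced_cohort}
    return pd.DataFrame.from_dict(rows, orient="index")


@pytest.fixture(scope="session")
def balanced_labels(balanced_cohort):
    return pd.Series({c.case_id: c.case_class for c in balanced_cohort})


@pytest.fixture(scope="session")
def balanced_ensemble(balanced_features, balanced_labels):
    cfg = cp.SelectionConfig(n_trials=100, master_seed=1)
    return cp.build_ensemble(balanced_features, balanced_labels, cfg)
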