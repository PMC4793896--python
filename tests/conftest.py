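import numpy as np
import pandas as pd
import pytest

from mirnorm.io import (
    REASON_OBSERVED,
    REASON_UNDETERMINED,
    CtMatrix,
    SampleAnnotation,
)
from mirnorm.preprocess import RQMatrix


def make_ct(values, detectors=None, samples=None, platform=""):
    """CtMatrix from a 2-D array; NaN cells become 'undetermined'."""
    arr = np.asarray(values, dtype=float)
    detectors = detectors or [f"miR-{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(arr.shape[1])]
    reason = np.where(np.isfinite(arr), REASON_OBSERVED, REASON_UNDETERMINED)
    return CtMatrix(
        pd.DataFrame(arr, index=detectors, columns=samples),
        pd.DataFrame(reason, index=detectors, columns=samples),
        platform=platform,
    )


def make_rq(values, detectors=None, samples=None, **kw):
    arr = np.asarray(values, dtype=float)
    detectors = detectors or [f"miR-{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(arr.shape[1])]
    return RQMatrix(pd.DataFrame(arr, index=detectors, columns=samples), **kw)


def make_annotation(groups_per_sample, samples=None):
    samples = samples or [f"s{j + 1}" for j in range(len(groups_per_sample))]
    return SampleAnnotation(
        pd.DataFrame({"group": list(groups_per_sample)}, index=pd.Index(samples, name="sample_id"))
    )


@pytest.fixture
def genorm_example():
    """Three detectors: A and B exactly proportional, C constant."""
    return make_rq(
        [[1, 2, 4, 8], [2, 4, 8, 16], [1, 1, 1, 1]], detectors=["A", "B", "C"]
    )


@pytest.fixture
def two_group_annotation():
    return make_annotation(["healthy"] * 4 + ["disease"] * 4, samples=[f"s{j+1}" for j in range(8)])


@pytest.fixture
def random_rq():
    """Factory for random positive complete RQ matrices."""

    def _make(m, n, seed, groups=None):
        rng = np.random.default_rng(seed)
        vals = np.exp2(rng.normal(0, 1, size=(m, n)))
        rq = make_rq(vals, detectors=[f"d{i:02d}" for i in range(m)])
        if groups is None:
            return rq
        labels = [f"g{(j % groups) + 1}" for j in range(n)]
        # contiguous groups keep sizes >= 2 when n >= 2*groups
        labels = sorted(labels)
        ann = make_annotation(labels, samples=rq.sample_ids)
        return rq, ann

    return _make
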