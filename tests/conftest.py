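import numpy as np
import pandas as pd
import pytest

from cvmstage.datamodel import LabeledDataset, LandmarkSet, Subject
from cvmstage.morphometry import extract_features


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_vertebrae():
    """A hand-built 19-point set: flat inferior borders, square C3/C4 bodies.

    C2 border on y=100, C3 body a 40x40 square with border on y=160,
    C4 likewise on y=220.  Known geometry for feature assertions.
    """
    pts = {}
    for i, x in zip(range(1, 6), (10, 20, 30, 40, 50)):
        pts[i] = (x, 100.0)
    for i, x in zip(range(6, 11), (10, 20, 30, 40, 50)):
        pts[i] = (x, 160.0)
    pts[11] = (10.0, 120.0)
    pts[12] = (50.0, 120.0)
    for i, x in zip(range(13, 18), (10, 20, 30, 40, 50)):
        pts[i] = (x, 220.0)
    pts[18] = (10.0, 180.0)
    pts[19] = (50.0, 180.0)
    coords = np.array([pts[i] for i in range(1, 20)], dtype=float)
    return LandmarkSet.from_array("SQ1", coords)


@pytest.fixture
def square_subject():
    return Subject("SQ1", age=12.0, sex="female")


@pytest.fixture
def square_features(square_vertebrae, square_subject):
    return extract_features(square_vertebrae, square_subject)


def make_dataset(n_per_stage=10, provenance="Rater1", seed=0,
                 informative=True, signal_sd=0.3):
    """Small labelled dataset: one informative feature plus one noise."""
    rng = np.random.default_rng(seed)
    stages = np.repeat(np.arange(1, 7), n_per_stage)
    ids = [f"T{i:04d}" for i in range(len(stages))]
    signal = stages + rng.normal(0, signal_sd if informative else 100,
                                 len(stages))
    X = pd.DataFrame({"signal": signal, "noise": rng.normal(size=len(stages))},
                     index=pd.Index(ids, name="subject_id"))
    y = pd.Series(stages, index=X.index, name="stage")
    return LabeledDataset(provenance=provenance, X=X, y=y)
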