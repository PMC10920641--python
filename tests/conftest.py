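import numpy as np
import pandas as pd
import pytest

from dyadsync.motion_energy import RegionOfInterest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_table():
    """Factory for dyad feature tables with a group mean shift of d SDs.

    Features are i.i.d. standard normal (class 0) vs N(d, 1) (class 1);
    age is uniform and independent of everything, mirroring a cohort where
    the diagnostic signal lives purely in the feature means.
    """

    def make(n1=30, n0=30, d=0.0, p=25, seed=0, labels=("ASD", "CC")):
        r = np.random.default_rng(seed)
        X = np.vstack([r.normal(d, 1, (n1, p)), r.normal(0, 1, (n0, p))])
        df = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(p)])
        df["label"] = [labels[0]] * n1 + [labels[1]] * n0
        df["age"] = r.uniform(6, 25, n1 + n0)
        df.index = pd.Index([f"d{i:03d}" for i in range(n1 + n0)], name="dyad_id")
        return df

    return make


@pytest.fixture
def quadrant_rois():
    """Four disjoint ROIs on a 60x80 frame, one per dyad role."""
    return [
        RegionOfInterest("participant_head", 0, 0, 38, 28),
        RegionOfInterest("participant_body", 0, 30, 38, 60),
        RegionOfInterest("administrator_head", 40, 0, 80, 28),
        RegionOfInterest("administrator_body", 40, 30, 80, 60),
    ]
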