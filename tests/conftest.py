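import numpy as np
import pytest

from clasta import LocalizationSet, RegionOfInterest


@pytest.fixture
def unit_roi() -> RegionOfInterest:
    return RegionOfInterest(0.0, 0.0, 1000.0, 1000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_set(xy, roi, channel_id="ch", frame=None) -> LocalizationSet:
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    return LocalizationSet(channel_id=channel_id, x=xy[:, 0], y=xy[:, 1],
                           frame=frame, roi=roi)


@pytest.fixture
def random_pair(unit_roi, rng):
    """200 query + 300 reference points, uniform in a 1x1 um ROI."""
    q = make_set(rng.uniform(0, 1000, (200, 2)), unit_roi, "red")
    r = make_set(rng.uniform(0, 1000, (300, 2)), unit_roi, "blue")
    return q, r
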