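import numpy as np
import pytest

from hydratox.records import DoseGroup, QuantalSeries, RunConfig


@pytest.fixture
def clean_series():
    """A well-behaved dose-response series: p_adj = (0, .2, .8, 1), n = 20."""
    groups = (
        DoseGroup(50, 20, 0),
        DoseGroup(100, 20, 4),
        DoseGroup(200, 20, 16),
        DoseGroup(400, 20, 20),
    )
    return QuantalSeries(groups=groups, axis="dose", label="demo")


@pytest.fixture
def config():
    return RunConfig()


def random_monotone_curve(rng, k=None):
    """Random monotone quantal curve spanning 0..1 on a random log grid."""
    from hydratox.dose_response import SmoothedCurve

    if k is None:
        k = int(rng.integers(3, 9))
    x = np.sort(rng.uniform(0.5, 3.5, size=k))
    while np.any(np.diff(x) < 1e-3):
        x = np.sort(rng.uniform(0.5, 3.5, size=k))
    p = np.sort(rng.uniform(0, 1, size=k))
    p[0], p[-1] = 0.0, 1.0
    n = rng.integers(5, 40, size=k)
    return SmoothedCurve(x=tuple(x), p_raw=tuple(p), p_adj=tuple(p),
                         n=tuple(int(v) for v in n))
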