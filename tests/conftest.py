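import numpy as np
import pytest

from cicerchip.models import ClusterSummary


@pytest.fixture
def three_clusters():
    """Well-behaved three-cluster geometry: AA at +1, AB at 0, BB at -1."""

    def _make(
        mx=(1.0, 0.0, -1.0),
        my=(1.0, 1.0, 1.0),
        sd_x=0.1,
        sd_y=0.1,
        n=(100, 100, 100),
    ):
        labels = ("AA", "AB", "BB")
        return [
            ClusterSummary(
                genotype=g, n=k, mean_x=x, sd_x=sd_x, mean_y=y, sd_y=sd_y
            )
            for g, k, x, y in zip(labels, n, mx, my)
        ]

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20259)
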