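import numpy as np
import pytest
from hypothesis import settings

from sizephenome.datatypes import SizeDistribution

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def simple_dist():
    """Symmetric 3-bin distribution: mean = median = mode = 50."""
    return SizeDistribution(
        strain_id="s", replicate_id="r1",
        volumes_fL=np.array([40.0, 50.0, 60.0]),
        counts=np.array([1.0, 2.0, 1.0]),
    )


def expanded_median(volumes: np.ndarray, counts: np.ndarray) -> float:
    """Brute-force oracle: median of each bin centre repeated count times."""
    expanded = np.repeat(volumes, counts.astype(int))
    return float(np.median(expanded))


def expanded_mean(volumes: np.ndarray, counts: np.ndarray) -> float:
    expanded = np.repeat(volumes, counts.astype(int))
    return float(np.mean(expanded))
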