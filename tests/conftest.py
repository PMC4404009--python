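import numpy as np
import pytest

from ammopareto import PYRAMID_VERTICES, sample_polytope

#: (D, W) triangle of the two-trait analyses
TRIANGLE_DW = np.array([[0.0, 1.0], [0.7, 1.35], [0.0, 4.6]])


@pytest.fixture(scope="session")
def pyramid_data():
    """Corner-informative pyramid sample with 2% trait noise."""
    pts, weights = sample_polytope(
        PYRAMID_VERTICES, 1000, concentration=0.25, noise_sd=0.02, seed=4
    )
    return pts, weights


@pytest.fixture(scope="session")
def triangle_data():
    pts, weights = sample_polytope(
        TRIANGLE_DW, 500, concentration=0.3, noise_sd=0.02, seed=3
    )
    return pts, weights


def match_vertices(fitted: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Per-coordinate absolute errors after optimal vertex matching."""
    from scipy.optimize import linear_sum_assignment

    cost = np.linalg.norm(fitted[:, None, :] - true[None, :, :], axis=2)
    r, c = linear_sum_assignment(cost)
    return np.abs(fitted[r] - true[c])
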