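import numpy as np
import pytest

from albind.synthetic_data import GroundTruth, generate_titration

# Published per-temperature study values used as test inputs:
# T (K) -> (Ksv L/mol, n, Ka L/mol, dG J/mol)
STUDY_TABLE = {
    298.0: (7.85e4, 1.14, 4.09e5, -31.92e3),
    304.0: (7.31e4, 1.06, 1.41e5, -30.17e3),
    310.0: (6.18e4, 1.00, 0.64e5, -28.42e3),
}
STUDY_DELTA_H = -118.75e3  # J/mol
STUDY_DELTA_S = -291.38  # J/mol/K


def ols_oracle(x, y):
    """Closed-form normal equations for a straight-line fit (independent oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    return slope, intercept


@pytest.fixture(scope="session")
def truth():
    return GroundTruth()


@pytest.fixture(scope="session")
def noiseless_bundle(truth):
    return generate_titration(truth)
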