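import numpy as np
import pytest

from bistab import wilhelm_fixture

# Published worked example for the minimal two-species bistable network:
# steady states with their Jacobians, eigenvalues and stability labels.
WILHELM_TABLE = [
    {
        "coords": (0.0, 0.0),
        "jacobian": [[-1.5, 16.0], [0.0, -8.0]],
        "eigenvalues": (-1.5, -8.0),
        "stability": "stable",
    },
    {
        "coords": (2.0, 0.5),
        "jacobian": [[-6.0, 14.0], [4.0, -8.0]],
        "eigenvalues": (0.54, -14.5),
        "stability": "saddle",
    },
    {
        "coords": (6.0, 4.5),
        "jacobian": [[-18.0, 10.0], [12.0, -8.0]],
        "eigenvalues": (-0.95, -25.04),
        "stability": "stable",
    },
]


def printed_tolerance(value: float) -> float:
    """One unit in the last printed decimal place of a tabulated value.

    The published table truncates (e.g. 0.5498 prints as 0.54), so printed
    precision means agreement within one ulp of the printed figure.
    """
    text = repr(float(value))
    decimals = len(text.split(".")[1]) if "." in text else 0
    return 10.0 ** (-decimals)

# Analytic fold locations from the discriminant of the reduced quadratic
# (k2*k3/k1) x^2 - k2 x + k4 = 0 (with the other constants nominal).
WILHELM_FOLDS = {"k1": 6.0, "k2": 0.75, "k3": 4.0 / 3.0, "k4": 2.0}


@pytest.fixture
def wilhelm():
    return wilhelm_fixture()


@pytest.fixture
def nominal(wilhelm):
    return wilhelm.nominal()


def upper_branch_x(k1=8.0, k2=1.0, k3=1.0, k4=1.5):
    """Closed-form x of the upper stable state: larger root of the reduced
    quadratic (k2*k3/k1) x^2 - k2 x + k4 = 0."""
    a, b, c = k2 * k3 / k1, -k2, k4
    disc = b * b - 4 * a * c
    if disc < 0:
        return None
    return (-b + np.sqrt(disc)) / (2 * a)
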