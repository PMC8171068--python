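from fractions import Fraction

import pytest

from superspacer import (RationalQ, SuperspaceModel, make_ninefold_example,
                         make_sevenfold_example, simulate_intensities)

Q37 = RationalQ(Fraction(0), Fraction(0), Fraction(3, 7))
Q49 = RationalQ(Fraction(0), Fraction(0), Fraction(4, 9))


@pytest.fixture(scope="session")
def sevenfold():
    """Sevenfold exemplar supercell (q = 3/7, 4 families) with ground truth."""
    return make_sevenfold_example(seed=1)


@pytest.fixture(scope="session")
def ninefold():
    return make_ninefold_example(seed=1)


@pytest.fixture(scope="session")
def sevenfold_fit(sevenfold):
    model, _truth = sevenfold
    return SuperspaceModel(model, Q37).fit()


@pytest.fixture(scope="session")
def sevenfold_diffraction(sevenfold):
    model, _truth = sevenfold
    return simulate_intensities(model)


@pytest.fixture(scope="session")
def ninefold_diffraction(ninefold):
    model, _truth = ninefold
    return simulate_intensities(model)
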