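import numpy as np
import pytest

from refweight import ReflectionSet, SynthSpec, UnitCell, generate


@pytest.fixture(scope="session")
def cubic_cell() -> UnitCell:
    return UnitCell(10.0, 10.0, 10.0)


@pytest.fixture
def small_rs(cubic_cell) -> ReflectionSet:
    """Five handmade reflections on a cubic cell."""
    return ReflectionSet(
        hkl=np.array([[1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 0, 0], [1, 1, 1]]),
        f_obs_sq=np.array([4.1, 0.9, 2.5, 9.3, -0.2]),
        sigma_f_obs_sq=np.array([0.2, 0.1, 0.3, 0.5, 0.15]),
        f_calc_sq=np.array([4.0, 1.0, 2.4, 9.0, 0.1]),
        cell=cubic_cell,
        wavelength=0.71073,
        n_params=2,
    )


@pytest.fixture(scope="session")
def synth_rs() -> ReflectionSet:
    """A mid-size synthetic set with the default variance inflation."""
    return generate(SynthSpec(n=2000, seed=11))


@pytest.fixture(scope="session")
def synth_rs_statistical() -> ReflectionSet:
    """Synthetic set with no inflation: statistical weights are correct."""
    return generate(SynthSpec(n=5000, seed=3, a_true=0.0, b_true=0.0))
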