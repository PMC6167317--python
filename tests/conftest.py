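import numpy as np
import pytest

from magnetofossil.morphometry import CrystalMeasurement
from magnetofossil.synthetic import (
    CrystalPopulationSpec,
    IrmComponentSpec,
    generate_crystal_population,
)


@pytest.fixture(scope="session")
def uniform_crystal():
    """A single elongated crystal used to build identical-particle chains."""
    return [CrystalMeasurement("uniform", 60.0, 48.0)]


@pytest.fixture(scope="session")
def synthetic_population():
    """A realistic magnetofossil-like population: log-normal lengths,
    slightly elongated on average, a small bullet share."""
    spec = CrystalPopulationSpec(
        n_crystals=500,
        length_logmean=float(np.log(60.0)),
        length_logsd=0.25,
        axial_ratio_mean=0.8,
        axial_ratio_sd=0.08,
        bullet_fraction=0.008,
        seed=3,
    )
    return generate_crystal_population(spec)


@pytest.fixture(scope="session")
def three_component_truth():
    """A 3-component IRM mixture: dominant narrow biogenic-like component
    plus soft and hard detrital-like components."""
    return [
        IrmComponentSpec(0.76, float(np.log10(30.0)), 0.15),
        IrmComponentSpec(0.09, float(np.log10(100.0)), 0.25),
        IrmComponentSpec(0.15, float(np.log10(400.0)), 0.20),
    ]
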