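import numpy as np
import pytest

from lcnpipe.models import SubstitutionModel
from lcnpipe.published import reference_rates
from lcnpipe.simulate import SimulationConfig


@pytest.fixture(scope="session")
def panel_rates() -> np.ndarray:
    """Calibrated rates of the 50-locus reference marker panel."""
    return reference_rates()


@pytest.fixture(scope="session")
def six_taxa_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def hky_model(six_taxa_config) -> SubstitutionModel:
    """The generator's default HKY parameterization, reused for inference."""
    return SubstitutionModel(family="HKY85",
                             freqs=six_taxa_config.model.freqs, kappa=2.0)
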