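import numpy as np
import pytest

from lymphodose.circulation import Compartment, CompartmentModel, build_default_model
from lymphodose.dvh_io import OrganDVH


@pytest.fixture
def default_model():
    return build_default_model(None)


@pytest.fixture
def single_compartment_model():
    """Degenerate one-compartment cycle: every element always in the lungs."""
    return CompartmentModel(
        compartments=(Compartment("lungs", 1.0, "lungs"),),
        topology={"lungs": "lungs"},
        element_volume_ml=53.0,  # 100 elements
    )


@pytest.fixture
def two_bin_cumulative():
    """Cumulative curve 1.0 @0, 0.5 @33, 0.0 @66 (mean 33 GyE)."""
    return OrganDVH(
        "lungs", np.array([0.0, 33.0, 66.0]), np.array([1.0, 0.5, 0.0]), "cumulative"
    )


@pytest.fixture
def uniform_plan_dvh():
    """Uniform 66 GyE plan: all volume at the prescription dose."""
    return OrganDVH("lungs", np.array([0.0, 66.0]), np.array([1.0, 1.0]), "cumulative")
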