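import numpy as np
import pytest

from ssnm.motifs import (
    default_rates,
    extended_neuronal_ssnm,
    mutant_neuronal_ssnm,
    neuronal_ssnm,
    yeast_ssnm,
)
from ssnm.network import NetworkModel, Reaction, Species

CATALOG = {
    "yeast": yeast_ssnm,
    "neuronal": neuronal_ssnm,
    "mutant_neuronal": mutant_neuronal_ssnm,
    "extended_neuronal": extended_neuronal_ssnm,
}


@pytest.fixture(params=sorted(CATALOG))
def catalog_motif(request):
    """Each catalog motif with its default rate set."""
    name = request.param
    return CATALOG[name](), default_rates(name)


@pytest.fixture
def binding_model():
    """Isolated A + B ⇌ C with Kd = 1 μM and unit totals.

    At equilibrium [C] solves C² − 3C + 1 = 0, i.e. [C] = (3 − √5)/2 μM.
    """
    model = NetworkModel(
        name="binding",
        species=[
            Species("A", {"A": 1}),
            Species("B", {"B": 1}),
            Species("C", {"A": 1, "B": 1}, "complex"),
        ],
        reactions=[Reaction("R1", {"A": 1, "B": 1}, {"C": 1}, 1.0, 1.0)],
        initial_concentrations={"A": 1.0, "B": 1.0, "C": 0.0},
        readout_moiety="A",
    )
    return model, {"R1": (1.0, 1.0)}


BINDING_EQ_C = (3 - np.sqrt(5)) / 2  # positive root of C² − 3C + 1
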