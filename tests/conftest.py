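import numpy as np
import pytest

from xcemap import StrainPanel


@pytest.fixture(scope="session")
def classical_panel() -> StrainPanel:
    """The classical inbred panel with known Xce alleles.

    Xce^a carriers against Xce^b carriers (reference C57BL/6J); C57L/J is
    unassigned and stays out of the group logic.
    """
    return StrainPanel(
        {
            "129S1/SvlmJ": "a",
            "A/J": "a",
            "BALB/cByJ": "a",
            "C3H/HeJ": "a",
            "CBA/J": "a",
            "AKR/J": "a",
            "DDK": "b",
            "C57BL/6J": "b",
            "DBA/1J": "b",
            "DBA/2J": "b",
            "C57L/J": "unknown",
        },
        reference_strain="C57BL/6J",
    )


@pytest.fixture(scope="session")
def tiny_panel() -> StrainPanel:
    """3-vs-3 panel for exhaustive SDP enumeration."""
    return StrainPanel(
        {"B6": "b", "D1": "b", "D2": "b", "A1": "a", "A2": "a", "A3": "a"},
        reference_strain="B6",
    )
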