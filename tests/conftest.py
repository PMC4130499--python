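import pytest

import ventcell as vc


@pytest.fixture()
def geometry() -> vc.MembraneGeometry:
    """Default 1 um protocell, half in each fluid."""
    return vc.MembraneGeometry()


@pytest.fixture()
def vent_env() -> vc.Environment:
    """The canonical 7:10 acid/alkaline pair."""
    return vc.Environment(ph_acid=7.0, ph_alk=10.0)
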