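import numpy as np
import pytest

from o18quant import LabelingModel, light_ion
from o18quant.quant import envelope_ratios_for


@pytest.fixture(scope="session")
def fat_ion():
    """The FATNTTLTK glycopeptide (one sequon at Asn4), light form, 2+."""
    return light_ion("FATNTTLTK", charge=2)


@pytest.fixture(scope="session")
def fat_ratios(fat_ion):
    return envelope_ratios_for(fat_ion)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140115)


def perfect_model(ratio: float, purity: float = 1.0) -> LabelingModel:
    """Complete C-terminal and site labeling at a given mixing ratio."""
    return LabelingModel(ratio=ratio, p_cterm=(0.0, 0.0, 1.0), site_efficiency=1.0, purity=purity)
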