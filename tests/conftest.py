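import pytest

from gagnre.catalog import build_ion_catalog, default_enumeration_config, enumerate_compositions
from gagnre.matching import CompositionQuant
from gagnre.structures import REGISTRY


@pytest.fixture(scope="session")
def catalog():
    return build_ion_catalog(enumerate_compositions(default_enumeration_config()))


@pytest.fixture(scope="session")
def records():
    return enumerate_compositions(default_enumeration_config())


def make_quant(structure_name, intensity, sample_id="s1"):
    """CompositionQuant for a registered structure (composition-level)."""
    entry = REGISTRY[structure_name]
    comp = entry.composition
    from gagnre.catalog import _record_id

    return CompositionQuant(
        sample_id=sample_id,
        composition_id=_record_id(comp),
        composition=comp,
        intensity=float(intensity),
        n_features=1,
        rt_apex=entry.rt_min,
    )


@pytest.fixture
def quant_factory():
    return make_quant
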