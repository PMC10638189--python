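"""Mass-engine checks against an independent elemental-formula oracle.

The oracle composes each species' elemental formula from residue formulas and
sums monoisotopic atomic masses via pyteomics, independently of the package's
constants table.
"""

import pytest
from pyteomics.mass import calculate_mass

from gagnre.errors import (
    CompositionMismatchError,
    InvalidCompositionError,
    InvalidIonError,
    UnsupportedFragmentError,
)
from gagnre.masses import (
    CONSTANTS,
    FragmentKind,
    GlycanComposition,
    IonSpecies,
    Residue,
    constants_json,
    fragment_mz,
    ion_mz,
    neutral_mass,
    nre_internal_mass_delta,
)

# residue elemental formulas (free monosaccharide minus one water)
_RESIDUE_FORMULA = {
    "dUA": dict(C=6, H=6, O=5),
    "UA": dict(C=6, H=8, O=6),
    "HexNAc": dict(C=8, H=13, N=1, O=5),
    "HexN": dict(C=6, H=11, N=1, O=4),
}
_H2O = dict(H=2, O=1)
_SO3 = dict(S=1, O=3)
_2AB_NET = dict(C=7, H=8, N=2)   # 2-aminobenzamide - H2O + H2
_DBA = dict(C=8, H=19, N=1)


def _add(*parts):
    out = {}
    for p in parts:
        for el, n in p.items():
            out[el] = out.get(el, 0) + n
    return out


def _scale(f, k):
    return {el: n * k for el, n in f.items()}


def oracle_neutral(comp: GlycanComposition) -> float:
    formula = _add(
        _scale(_RESIDUE_FORMULA["dUA"], comp.n_dUA),
        _scale(_RESIDUE_FORMULA["UA"], comp.n_UA),
        _scale(_RESIDUE_FORMULA["HexNAc"], comp.n_acetyl),
        _scale(_RESIDUE_FORMULA["HexN"], comp.n_hexn - comp.n_acetyl),
        _H2O,
        _scale(_SO3, comp.n_SO3),
        _2AB_NET if comp.labeled_2AB else {},
    )
    return calculate_mass(composition=formula)


def oracle_mz(species: IonSpecies) -> float:
    m = (
        oracle_neutral(species.composition)
        - species.n_SO3_lost * calculate_mass(composition=_SO3)
        + species.n_DBA * calculate_mass(composition=_DBA)
        - species.charge_z * 1.00727646688
    )
    return m / species.charge_z


DP2S1_NRE = GlycanComposition(n_UA=1, n_hexn=1, n_acetyl=1, n_SO3=1)
DP2S1_INT = GlycanComposition(n_dUA=1, n_hexn=1, n_acetyl=1, n_SO3=1)
DP2S2_NRE = GlycanComposition(n_UA=1, n_hexn=1, n_acetyl=1, n_SO3=2)


@pytest.mark.parametrize(
    "comp, expected",
    [
        (DP2S1_NRE, 597.1476),                                       # 2-AB NRE dp2S1
        (DP2S1_INT, 579.1370),                                       # internal counterpart
        (GlycanComposition(n_UA=1, labeled_2AB=False), 194.0427),    # free uronic acid
    ],
)
def test_neutral_mass_examples(comp, expected):
    assert neutral_mass(comp) == pytest.approx(expected, abs=5e-4)
    assert neutral_mass(comp) == pytest.approx(oracle_neutral(comp), abs=1e-4)


@pytest.mark.parametrize(
    "species, expected",
    [
        (IonSpecies(DP2S1_NRE, charge_z=1), 596.1403),
        (IonSpecies(DP2S2_NRE, charge_z=2), 337.5449),
        # dp2S2 after one in-source sulfate loss lands on the dp2S1 parent m/z
        (IonSpecies(DP2S2_NRE, charge_z=1, n_SO3_lost=1), 596.1403),
    ],
)
def test_ion_mz_examples(species, expected):
    assert ion_mz(species) == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize(
    "kind, expected",
    [
        (FragmentKind.C1_UA, 193.0354),
        (FragmentKind.B1_UA, 175.0248),
        (FragmentKind.B1_UA2S, 254.9816),
        (FragmentKind.Y1_HexNAcS_2AB, 420.1082),
    ],
)
def test_fragment_mz_examples(kind, expected):
    assert fragment_mz(kind) == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize(
    "comp",
    [
        DP2S1_NRE,
        DP2S2_NRE,
        GlycanComposition(n_dUA=1, n_hexn=1, n_SO3=3),
        GlycanComposition(n_UA=1, n_hexn=2, n_SO3=2),                 # GlcNH2 trisaccharide
        GlycanComposition(n_hexn=1, n_acetyl=1, n_SO3=1),             # dp1
        GlycanComposition(n_dUA=1, n_hexn=1, n_acetyl=1, n_SO3=2, labeled_2AB=False),
    ],
)
@pytest.mark.parametrize("z", [1, 2])
@pytest.mark.parametrize("n_dba, n_lost", [(0, 0), (1, 0), (0, 1)])
def test_ion_mz_roundtrips_elemental_oracle(comp, z, n_dba, n_lost):
    """m/z from the constants table agrees with atom-by-atom summation to < 1e-4 Th."""
    if n_lost > comp.n_SO3:
        pytest.skip("loss exceeds sulfate count")
    sp = IonSpecies(comp, charge_z=z, n_DBA=n_dba, n_SO3_lost=n_lost)
    assert ion_mz(sp) == pytest.approx(oracle_mz(sp), abs=1e-4)


def test_charge_monotonicity():
    mzs = [ion_mz(IonSpecies(DP2S2_NRE, charge_z=z)) for z in (1, 2, 3)]
    assert mzs[0] > mzs[1] > mzs[2]


def test_residue_water_relation():
    assert Residue.UA.mass - Residue.dUA.mass == pytest.approx(CONSTANTS["H2O"], abs=1e-6)
    assert all(r.mass > 0 for r in Residue)


@pytest.mark.parametrize(
    "nre, internal",
    [
        (DP2S1_NRE, DP2S1_INT),
        (
            GlycanComposition(n_UA=1, n_hexn=1, n_acetyl=1),
            GlycanComposition(n_dUA=1, n_hexn=1, n_acetyl=1),
        ),
        (
            GlycanComposition(n_UA=1, n_hexn=1, n_SO3=3),
            GlycanComposition(n_dUA=1, n_hexn=1, n_SO3=3),
        ),
    ],
)
def test_nre_internal_delta_is_one_water(nre, internal):
    """The saturated/unsaturated mass split is 18.0106 Da for every substitution state."""
    assert nre_internal_mass_delta(nre, internal) == pytest.approx(18.0106, abs=5e-4)


def test_nre_internal_delta_rejects_non_counterparts():
    other = GlycanComposition(n_dUA=1, n_hexn=1, n_acetyl=1, n_SO3=2)
    with pytest.raises(CompositionMismatchError):
        nre_internal_mass_delta(DP2S1_NRE, other)


def test_invalid_inputs_raise():
    with pytest.raises(InvalidCompositionError):
        GlycanComposition(n_UA=-1, n_hexn=1)
    with pytest.raises(InvalidCompositionError):
        GlycanComposition(n_hexn=1, n_acetyl=2)
    with pytest.raises(InvalidIonError):
        IonSpecies(DP2S1_NRE, charge_z=1, n_SO3_lost=2)
    with pytest.raises(InvalidIonError):
        IonSpecies(DP2S1_NRE, charge_z=5)
    with pytest.raises(UnsupportedFragmentError):
        fragment_mz("Z9_bogus")


def test_constants_export_is_valid_json():
    import json

    payload = json.loads(constants_json())
    assert payload["residues"]["UA"] == CONSTANTS["residues"]["UA"]
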