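"""Monoisotopic mass arithmetic for lyase-depolymerized GAG saccharides.

Bacterial lyases (chondroitinases, heparinases) cleave CS/DS and HS chains by
beta-elimination, yielding internal disaccharides whose new non-reducing
terminus is a 4,5-unsaturated uronic acid (dUA) and, from the original chain
terminus, saturated non-reducing-end (NRE) mono- to trisaccharides.  The
saturated species are one water (18.0106 Da) heavier than their unsaturated
internal counterparts, which is what lets MS separate the two pools.

Reducing ends are derivatized with 2-aminobenzamide (2-AB) by reductive
amination (net addition: 2-AB − H2O + H2 = 120.0687 Da).  Ions are observed in
negative mode as [M − zH]z−, optionally carrying di-n-butylamine (DBA, the
ion-pairing agent) as a neutral adduct and/or having lost SO3 in-source.

All constants are monoisotopic and kept in one table (:data:`CONSTANTS`)
exportable as JSON for audit.  N- and O-sulfation are isobaric and counted as
one SO3 tally; positional identity lives in :class:`IsomerAnnotation` only.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace

from .errors import (
    CompositionMismatchError,
    InvalidCompositionError,
    InvalidIonError,
    UnsupportedFragmentError,
)

__all__ = [
    "CONSTANTS",
    "Residue",
    "GlycanComposition",
    "IsomerAnnotation",
    "IonSpecies",
    "FragmentKind",
    "neutral_mass",
    "ion_mz",
    "fragment_mz",
    "nre_internal_mass_delta",
    "constants_json",
]

#: Monoisotopic mass table (Da).  Residue masses are for the glycosidically
#: linked residue, i.e. the free monosaccharide minus one water.
CONSTANTS: dict = {
    "H2O": 18.010565,
    "H2": 2.015650,
    "SO3": 79.956815,
    "proton": 1.007276,
    # 2-aminobenzamide reductive-amination net addition: 2-AB - H2O + H2
    "2AB_net": 120.068748,
    # di-n-butylamine C8H19N, retained as a neutral adduct on the anion
    "DBA": 129.151750,
    "residues": {
        "dUA": 158.021523,   # 4,5-unsaturated uronic acid
        "UA": 176.032088,    # saturated uronic acid (GlcA/IdoA, isobaric)
        "HexNAc": 203.079373,
        "HexN": 161.068808,  # hexosamine with free amine (or N-sulfated, SO3 counted separately)
    },
}


class Residue(enum.Enum):
    """Monosaccharide residue codes with fixed monoisotopic residue masses."""

    dUA = "dUA"
    UA = "UA"
    HexNAc = "HexNAc"
    HexN = "HexN"

    @property
    def mass(self) -> float:
        return CONSTANTS["residues"][self.value]


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Residue/substituent counts defining one dp species.

    ``terminus`` is derived: compositions with one dUA are internal lyase
    products; compositions without dUA are saturated NRE saccharides.
    N- and O-sulfates are pooled in ``n_SO3`` (isobaric at MS1); a free-amine
    hexosamine (GlcNH2) is simply a HexN backbone with neither acetyl nor
    N-sulfate — no extra mass term.
    """

    n_dUA: int = 0
    n_UA: int = 0
    n_hexn: int = 0          # hexosamine backbone units (acetylated or not)
    n_acetyl: int = 0        # how many backbone hexosamines are N-acetylated
    n_SO3: int = 0
    labeled_2AB: bool = True

    def __post_init__(self) -> None:
        counts = (self.n_dUA, self.n_UA, self.n_hexn, self.n_acetyl, self.n_SO3)
        if any(c < 0 for c in counts):
            raise InvalidCompositionError(f"negative counts in {counts}")
        if self.n_acetyl > self.n_hexn:
            raise InvalidCompositionError(
                f"n_acetyl={self.n_acetyl} exceeds hexosamine backbone {self.n_hexn}"
            )
        if self.n_dUA > 1:
            raise InvalidCompositionError("at most one unsaturated uronic acid per fragment")
        if self.dp < 1:
            raise InvalidCompositionError("empty composition (dp = 0)")

    @property
    def dp(self) -> int:
        """Degree of polymerization."""
        return self.n_dUA + self.n_UA + self.n_hexn

    @property
    def terminus(self) -> str:
        """``'internal'`` (carries a dUA) or ``'NRE'`` (saturated)."""
        return "internal" if self.n_dUA == 1 else "NRE"

    @property
    def key(self) -> tuple:
        return (self.n_dUA, self.n_UA, self.n_hexn, self.n_acetyl, self.n_SO3, self.labeled_2AB)

    def shorthand(self) -> str:
        """Field shorthand, e.g. ``dp2S1`` / ``dp3(1Ac,3S)``."""
        base = f"dp{self.dp}S{self.n_SO3}"
        if self.n_hexn > 1 or self.n_acetyl != min(1, self.n_hexn):
            base = f"dp{self.dp}({self.n_acetyl}Ac,{self.n_SO3}S)"
        if not self.labeled_2AB:
            base += "*"  # unlabeled variant
        return base

    def unsaturated_counterpart(self) -> "GlycanComposition":
        """The internal (dUA) composition matching this NRE composition."""
        if self.terminus != "NRE" or self.n_UA < 1:
            raise CompositionMismatchError("composition has no saturated UA to swap")
        return replace(self, n_dUA=1, n_UA=self.n_UA - 1)


@dataclass(frozen=True)
class IsomerAnnotation:
    """Positional/epimeric identity of one composition (isobaric at MS1)."""

    composition: GlycanComposition
    structure_name: str
    epimer: str = "unknown"                   # GlcA | IdoA | unknown
    sulfation_positions: tuple = ()           # e.g. ("2S", "NS", "6S"); len == n_SO3
    evidence: str = "assumed"                 # standard | ms2 | rt_order | assumed

    def __post_init__(self) -> None:
        if len(self.sulfation_positions) != self.composition.n_SO3:
            raise InvalidCompositionError(
                f"{self.structure_name}: {len(self.sulfation_positions)} sulfation positions "
                f"for n_SO3={self.composition.n_SO3}"
            )


def neutral_mass(composition: GlycanComposition) -> float:
    """Neutral monoisotopic mass (Da) of a composition.

    Sum of residue masses plus the reducing-end water, sulfates, and — when
    labeled — the 2-AB reductive-amination net addition.
    """
    c = composition
    m = (
        c.n_dUA * CONSTANTS["residues"]["dUA"]
        + c.n_UA * CONSTANTS["residues"]["UA"]
        + c.n_acetyl * CONSTANTS["residues"]["HexNAc"]
        + (c.n_hexn - c.n_acetyl) * CONSTANTS["residues"]["HexN"]
        + CONSTANTS["H2O"]
        + c.n_SO3 * CONSTANTS["SO3"]
    )
    if c.labeled_2AB:
        m += CONSTANTS["2AB_net"]
    return m


@dataclass(frozen=True)
class IonSpecies:
    """One observable negative-mode ion of a composition.

    The DBA adduct convention: the neutral amine is retained on the
    deprotonated ion, i.e. ``[M + n·DBA − zH]z−``.  ``n_SO3_lost`` counts
    in-source sulfate losses; loss species co-elute with their parent.
    """

    composition: GlycanComposition
    charge_z: int = 1
    n_DBA: int = 0
    n_SO3_lost: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.charge_z <= 4:
            raise InvalidIonError(f"charge {self.charge_z} outside 1..4 (negative mode)")
        if self.n_DBA < 0 or self.n_SO3_lost < 0:
            raise InvalidIonError("negative adduct/loss counts")
        if self.n_SO3_lost > self.composition.n_SO3:
            raise InvalidIonError(
                f"cannot lose {self.n_SO3_lost} sulfates from a composition with "
                f"{self.composition.n_SO3}"
            )

    @property
    def mz(self) -> float:
        return ion_mz(self)

    @property
    def role(self) -> str:
        if self.n_DBA > 0:
            return "adduct"
        if self.n_SO3_lost > 0:
            return "sulfate_loss"
        return "parent"


def ion_mz(species: IonSpecies) -> float:
    """Theoretical m/z of an ion species (Th)."""
    m = (
        neutral_mass(species.composition)
        - species.n_SO3_lost * CONSTANTS["SO3"]
        + species.n_DBA * CONSTANTS["DBA"]
        - species.charge_z * CONSTANTS["proton"]
    )
    return m / species.charge_z


class FragmentKind(enum.Enum):
    """Diagnostic negative-mode MS2 fragments used for isomer assignment."""

    B1_UA = "B1_UA"                      # dehydrated uronic acid
    C1_UA = "C1_UA"                      # intact uronic acid
    B1_UA2S = "B1_UA2S"                  # dehydrated mono-sulfated uronic acid
    Y1_HexNAcS_2AB = "Y1_HexNAcS_2AB"    # sulfated HexNAc retaining the 2-AB label
    Y1_HexNAc_2AB = "Y1_HexNAc_2AB"      # unsulfated HexNAc retaining the 2-AB label


def _fragment_neutrals() -> dict:
    k = CONSTANTS
    ua, hexnac = k["residues"]["UA"], k["residues"]["HexNAc"]
    return {
        FragmentKind.B1_UA: ua,
        FragmentKind.C1_UA: ua + k["H2O"],
        FragmentKind.B1_UA2S: ua + k["SO3"],
        FragmentKind.Y1_HexNAcS_2AB: hexnac + k["H2O"] + k["SO3"] + k["2AB_net"],
        FragmentKind.Y1_HexNAc_2AB: hexnac + k["H2O"] + k["2AB_net"],
    }


def fragment_mz(fragment_kind: FragmentKind, charge_z: int = 1) -> float:
    """Singly deprotonated m/z of a diagnostic fragment."""
    if charge_z != 1:
        raise UnsupportedFragmentError("diagnostic fragments are modeled singly charged only")
    if not isinstance(fragment_kind, FragmentKind):
        try:
            fragment_kind = FragmentKind(fragment_kind)
        except ValueError as exc:
            raise UnsupportedFragmentError(f"unknown fragment kind {fragment_kind!r}") from exc
    neutral = _fragment_neutrals()[fragment_kind]
    return neutral - CONSTANTS["proton"]


def nre_internal_mass_delta(
    composition_nre: GlycanComposition, composition_internal: GlycanComposition
) -> float:
    """Neutral mass difference between an NRE composition and its internal counterpart.

    The two must be identical except for the dUA <-> UA swap; the delta is one
    water, 18.0106 Da, independent of sulfation/acetylation state.
    """
    nre, internal = composition_nre, composition_internal
    if nre.terminus != "NRE" or internal.terminus != "internal":
        raise CompositionMismatchError("expected (NRE, internal) pair")
    if not _are_counterparts(nre, internal):
        raise CompositionMismatchError(f"{nre} and {internal} are not dUA/UA counterparts")
    return neutral_mass(nre) - neutral_mass(internal)


def _are_counterparts(nre: GlycanComposition, internal: GlycanComposition) -> bool:
    return (
        nre.n_UA == internal.n_UA + 1
        and nre.n_dUA == 0
        and internal.n_dUA == 1
        and nre.n_hexn == internal.n_hexn
        and nre.n_acetyl == internal.n_acetyl
        and nre.n_SO3 == internal.n_SO3
        and nre.labeled_2AB == internal.labeled_2AB
    )


def constants_json() -> str:
    """The constants table as JSON, for audit trails."""
    return json.dumps(CONSTANTS, indent=2, sort_keys=True)
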