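"""Registry of named CS/DS and HS saccharide structures.

Each entry maps a field-standard structure name (e.g. ``IdoAGalNAc4S``,
``GlcNH2UAGlcNS(6S)``) to its MS1 composition, its epimeric/positional
identity and a reference retention time on the default ion-pairing nano-LC
gradient.  Structures sharing one composition are MS1-isobaric and are told
apart by MS2 diagnostic ions and/or elution order.

Reference retention times for the mono-sulfated NRE disaccharide isomers
follow the experimentally established elution order
IdoAGalNAc4S < GlcAGalNAc4S < GlcAGalNAc6S (32.15 / 32.66 / 33.83 min);
other times are plausible placeholders on the same gradient, used by the
synthetic-data generator and the RT-based isomer resolver.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnsupportedStructureError
from .masses import GlycanComposition, IsomerAnnotation

__all__ = ["StructureEntry", "REGISTRY", "get_structure", "isomers_of", "annotation_for"]


@dataclass(frozen=True)
class StructureEntry:
    name: str
    composition: GlycanComposition
    epimer: str               # GlcA | IdoA | unknown (dUA internals: unknown)
    sulfation_positions: tuple
    rt_min: float             # reference elution time, default gradient
    evidence: str = "assumed"


def _c(n_dUA=0, n_UA=0, n_hexn=0, n_acetyl=0, n_SO3=0, labeled=True) -> GlycanComposition:
    return GlycanComposition(n_dUA, n_UA, n_hexn, n_acetyl, n_SO3, labeled)


# fmt: off
_ENTRIES = [
    # --- NRE monosaccharides (dp1) ---
    StructureEntry("GalNAc",           _c(n_hexn=1, n_acetyl=1),            "unknown", (),            20.0, "standard"),
    StructureEntry("GalNAc4S",         _c(n_hexn=1, n_acetyl=1, n_SO3=1),   "unknown", ("4S",),       21.5, "ms2"),
    StructureEntry("GalNAc6S",         _c(n_hexn=1, n_acetyl=1, n_SO3=1),   "unknown", ("6S",),       22.6, "ms2"),
    StructureEntry("GlcNH2",           _c(n_hexn=1),                        "unknown", (),            18.8),
    StructureEntry("GlcNS",            _c(n_hexn=1, n_SO3=1),               "unknown", ("NS",),       23.4),
    # --- NRE disaccharides (dp2), CS/DS type (acetylated hexosamine) ---
    StructureEntry("GlcAGalNAc",       _c(n_UA=1, n_hexn=1, n_acetyl=1),            "GlcA", (),             30.1),
    StructureEntry("IdoAGalNAc4S",     _c(n_UA=1, n_hexn=1, n_acetyl=1, n_SO3=1),   "IdoA", ("4S",),        32.15, "ms2"),
    StructureEntry("GlcAGalNAc4S",     _c(n_UA=1, n_hexn=1, n_acetyl=1, n_SO3=1),   "GlcA", ("4S",),        32.66, "ms2"),
    StructureEntry("IdoAGalNAc6S",     _c(n_UA=1, n_hexn=1, n_acetyl=1, n_SO3=1),   "IdoA", ("6S",),        33.06, "rt_order"),
    StructureEntry("GlcAGalNAc6S",     _c(n_UA=1, n_hexn=1, n_acetyl=1, n_SO3=1),   "GlcA", ("6S",),        33.83, "ms2"),
    StructureEntry("IdoA2SGalNAc",     _c(n_UA=1, n_hexn=1, n_acetyl=1, n_SO3=1),   "IdoA", ("2S",),        34.86, "ms2"),
    StructureEntry("IdoA2SGalNAc4S",   _c(n_UA=1, n_hexn=1, n_acetyl=1, n_SO3=2),   "IdoA", ("2S", "4S"),   37.46, "ms2"),
    # --- NRE disaccharides (dp2), HS type (GlcN backbone, N-sulfated) ---
    StructureEntry("GlcAGlcNS",        _c(n_UA=1, n_hexn=1, n_SO3=1),               "GlcA", ("NS",),        30.6),
    StructureEntry("IdoAGlcNS",        _c(n_UA=1, n_hexn=1, n_SO3=1),               "IdoA", ("NS",),        31.1, "ms2"),
    StructureEntry("IdoAGlcNS(6S)",    _c(n_UA=1, n_hexn=1, n_SO3=2),               "IdoA", ("NS", "6S"),   35.5, "ms2"),
    StructureEntry("IdoA2SGlcNS",      _c(n_UA=1, n_hexn=1, n_SO3=2),               "IdoA", ("2S", "NS"),   36.1, "ms2"),
    StructureEntry("IdoA2SGlcNS(6S)",  _c(n_UA=1, n_hexn=1, n_SO3=3),               "IdoA", ("2S", "NS", "6S"), 37.8, "ms2"),
    # --- NRE trisaccharides (dp3), free-amine glucosamine termini ---
    StructureEntry("GlcNH2UAGlcNAc(6S)",    _c(n_UA=1, n_hexn=2, n_acetyl=1, n_SO3=1), "unknown", ("6S",),             38.5, "ms2"),
    StructureEntry("GlcNH2UAGlcNS(6S)",     _c(n_UA=1, n_hexn=2, n_SO3=2),             "unknown", ("NS", "6S"),        39.4, "ms2"),
    StructureEntry("GlcNH2(6S)UAGlcNS(6S)", _c(n_UA=1, n_hexn=2, n_SO3=3),             "unknown", ("6S", "NS", "6S"),  40.2, "ms2"),
    # --- internal disaccharides (dUA terminus, lyase products) ---
    StructureEntry("dUAGalNAc",        _c(n_dUA=1, n_hexn=1, n_acetyl=1),           "unknown", (),          27.9, "standard"),
    StructureEntry("dUAGlcNAc",        _c(n_dUA=1, n_hexn=1, n_acetyl=1),           "unknown", (),          28.4, "standard"),
    StructureEntry("dUAGalNAc4S",      _c(n_dUA=1, n_hexn=1, n_acetyl=1, n_SO3=1),  "unknown", ("4S",),     30.5, "standard"),
    StructureEntry("dUAGalNAc6S",      _c(n_dUA=1, n_hexn=1, n_acetyl=1, n_SO3=1),  "unknown", ("6S",),     31.3, "standard"),
    StructureEntry("dUAGlcNS",         _c(n_dUA=1, n_hexn=1, n_SO3=1),              "unknown", ("NS",),     29.6, "standard"),
    StructureEntry("dUAGalNAc4S6S",    _c(n_dUA=1, n_hexn=1, n_acetyl=1, n_SO3=2),  "unknown", ("4S", "6S"), 36.6, "standard"),
    # unlabeled internal dp2S2: the 2-AB labeling-yield QC species
    StructureEntry("dUAGalNAc4S6S (unlabeled)",
                   _c(n_dUA=1, n_hexn=1, n_acetyl=1, n_SO3=2, labeled=False),       "unknown", ("4S", "6S"), 25.8, "standard"),
]
# fmt: on

REGISTRY: dict[str, StructureEntry] = {e.name: e for e in _ENTRIES}


def get_structure(name: str) -> StructureEntry:
    try:
        return REGISTRY[name]
    except KeyError as exc:
        raise UnsupportedStructureError(f"unknown structure {name!r}") from exc


def isomers_of(composition: GlycanComposition) -> list[StructureEntry]:
    """All registered structures sharing one MS1 composition, by elution order."""
    hits = [e for e in _ENTRIES if e.composition.key == composition.key]
    return sorted(hits, key=lambda e: e.rt_min)


def annotation_for(name: str) -> IsomerAnnotation:
    e = get_structure(name)
    return IsomerAnnotation(
        composition=e.composition,
        structure_name=e.name,
        epimer=e.epimer,
        sulfation_positions=e.sulfation_positions,
        evidence=e.evidence,
    )
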