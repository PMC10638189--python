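"""MS2 diagnostic-ion annotation and isomer-level structure calls.

Negative-mode HCD spectra of 2-AB-labeled GAG saccharides contain a small set
of diagnostic fragments that settle the ambiguities MS1 cannot:

* uronic-acid epimer (GlcA vs IdoA): the intact-UA C ion at m/z 193.04 is
  relatively more intense for GlcA-terminated species, the dehydrated-UA B
  ion at 175.02 for IdoA-terminated ones;
* 2-O-sulfated uronic acid: presence of sulfated UA at 254.98 together with
  the *absence* of sulfated HexNAc-2-AB at 420.11;
* 4S vs 6S positional isomers: the relative abundance of the 420.11 ion
  differs between the two — the direction is instrument/collision-energy
  dependent, so the polarity is a calibrated config parameter, not a
  hard-coded rule;
* free-amine glucosamine (GlcNH2) termini of the MPS IIIc trisaccharides:
  precursor mass requires a non-acetylated, non-N-sulfated hexosamine, and
  fragments retaining the terminus corroborate it.

All rules operate on base-peak-normalized intensities and are invariant
under uniform scaling of the spectrum.  "Absent" means below a
relative-intensity floor (default 1% of base peak).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import UnsupportedStructureError
from .masses import CONSTANTS, FragmentKind, GlycanComposition, fragment_mz, neutral_mass
from .structures import isomers_of

logger = logging.getLogger(__name__)

__all__ = [
    "MS2Spectrum",
    "FragmentAnnotation",
    "IsomerCall",
    "MS2Config",
    "annotate_fragments",
    "call_uronic_epimer",
    "call_2S_uronic",
    "call_sulfation_position",
    "call_glcnh2_terminus",
    "call_structure",
    "calibrate_sulfation_polarity",
    "read_ms2_csv",
    "read_mgf",
]


@dataclass(frozen=True)
class MS2Spectrum:
    precursor_mz: float
    precursor_z: int
    peaks: tuple                 # ((mz, intensity), ...) sorted by mz
    rt: float = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise ValueError("negative fragment intensity")
        object.__setattr__(self, "peaks", pk)

    @property
    def base_peak_intensity(self) -> float:
        return max((i for _, i in self.peaks), default=0.0)


@dataclass(frozen=True)
class FragmentAnnotation:
    peak_index: int
    fragment_kind: FragmentKind
    ppm_error: float
    rel_intensity: float         # normalized to base peak


@dataclass(frozen=True)
class IsomerCall:
    composition_id: str
    structure_name: str
    confidence: str              # standard_matched | diagnostic | tentative
    evidence: tuple = ()


@dataclass(frozen=True)
class MS2Config:
    frag_tol_ppm: float = 20.0           # MS2 acquired at lower resolution than MS1
    absence_floor: float = 0.01          # "lack of an ion" = < 1% of base peak
    epimer_ratio_threshold: float = 1.5  # I(193)/I(175) dead band: (1/r, r) -> unknown
    pos_cutoff: float = 0.40             # rel abundance of 420.11 separating 4S/6S
    pos_dead_band: float = 0.05
    pos_polarity: str = "high_is_4S"     # or "high_is_6S"; calibrate against standards
    # fragments taken as retaining a free-amine glucosamine terminus (B/C ions of HexN)
    glcnh2_fragment_mzs: tuple = (160.0615, 178.0721)


def annotate_fragments(spectrum: MS2Spectrum, frag_tol_ppm: float = 20.0) -> list:
    """Match each diagnostic fragment against the peak list within tolerance.

    When several peaks fall inside the tolerance window the most intense one
    is annotated.
    """
    if not spectrum.peaks:
        warnings.warn("empty MS2 peak list; no fragments annotated")
        return []
    base = spectrum.base_peak_intensity
    annotations = []
    for kind in FragmentKind:
        theo = fragment_mz(kind)
        best = None
        for idx, (mz, inten) in enumerate(spectrum.peaks):
            ppm = 1e6 * (mz - theo) / theo
            if abs(ppm) <= frag_tol_ppm and (best is None or inten > best[2]):
                best = (idx, ppm, inten)
        if best is not None:
            idx, ppm, inten = best
            annotations.append(
                FragmentAnnotation(idx, kind, ppm, inten / base if base else 0.0)
            )
    return annotations


def _rel(annotations: list, kind: FragmentKind) -> float:
    for a in annotations:
        if a.fragment_kind == kind:
            return a.rel_intensity
    return 0.0


def call_uronic_epimer(annotations: list, config: MS2Config = MS2Config()) -> str:
    """GlcA/IdoA call from the 193.04 (intact UA) vs 175.02 (UA - H2O) ratio."""
    i193 = _rel(annotations, FragmentKind.C1_UA)
    i175 = _rel(annotations, FragmentKind.B1_UA)
    if i193 < config.absence_floor and i175 < config.absence_floor:
        return "unknown"
    if i175 == 0.0:
        return "GlcA"
    r = i193 / i175
    if r > config.epimer_ratio_threshold:
        return "GlcA"
    if r < 1.0 / config.epimer_ratio_threshold:
        return "IdoA"
    return "unknown"


def call_2S_uronic(annotations: list, config: MS2Config = MS2Config()) -> bool:
    """True iff sulfated UA (254.98) is present and sulfated HexNAc-2-AB (420.11) absent."""
    ua2s = _rel(annotations, FragmentKind.B1_UA2S) >= config.absence_floor
    hexnacs = _rel(annotations, FragmentKind.Y1_HexNAcS_2AB) >= config.absence_floor
    if ua2s and hexnacs:
        warnings.warn("mixed evidence: both sulfated-UA and sulfated-HexNAc ions present")
        return False
    return ua2s and not hexnacs


def call_sulfation_position(
    annotations: list, composition: GlycanComposition, config: MS2Config = MS2Config()
) -> str:
    """4S/6S call from the relative abundance of the 420.11 ion.

    Applies to mono-sulfated HexNAc-containing dp1/dp2 species.  Returns
    ``unknown`` inside the dead band around the cutoff or when the fragment
    (and hence any evidence) is missing entirely.
    """
    if composition.n_SO3 != 1 or composition.n_acetyl < 1 or composition.dp > 2:
        raise ValueError("4S/6S rule applies to mono-sulfated HexNAc dp1/dp2 species")
    rel = _rel(annotations, FragmentKind.Y1_HexNAcS_2AB)
    if not annotations:
        return "unknown"
    hi, lo = ("4S", "6S") if config.pos_polarity == "high_is_4S" else ("6S", "4S")
    if rel > config.pos_cutoff + config.pos_dead_band:
        return hi
    if rel < config.pos_cutoff - config.pos_dead_band:
        return lo
    return "unknown"


def call_glcnh2_terminus(
    spectrum: MS2Spectrum,
    composition: GlycanComposition,
    config: MS2Config = MS2Config(),
    ms1_tol_ppm: float = 15.0,
) -> tuple:
    """(is_glcnh2, confidence) for dp3 NRE trisaccharides.

    The precursor mass must be consistent with a composition carrying a
    non-acetylated hexosamine (the free-amine candidate); fragment peaks
    retaining the GlcNH2 terminus upgrade the call from ``tentative`` to
    ``diagnostic``.
    """
    if composition.n_acetyl >= composition.n_hexn:
        return False, "tentative"  # every backbone hexosamine acetylated: mass excludes GlcNH2
    theo = (neutral_mass(composition) - spectrum.precursor_z * CONSTANTS["proton"]) / spectrum.precursor_z
    ppm = 1e6 * (spectrum.precursor_mz - theo) / theo
    if abs(ppm) > ms1_tol_ppm:
        return False, "tentative"
    base = spectrum.base_peak_intensity
    for target in config.glcnh2_fragment_mzs:
        for mz, inten in spectrum.peaks:
            if abs(1e6 * (mz - target) / target) <= config.frag_tol_ppm and (
                base and inten / base >= config.absence_floor
            ):
                return True, "diagnostic"
    return True, "tentative"  # mass-only call


def call_structure(
    spectrum: MS2Spectrum,
    composition: GlycanComposition,
    composition_id: str = "",
    config: MS2Config = MS2Config(),
) -> IsomerCall:
    """Combine the rule set into one structure call for a spectrum.

    Covers the mono-/di-sulfated CS-type dp2 NREs (epimer + 2S + 4S/6S logic)
    and the GlcNH2-terminated dp3 species; other compositions get a tentative
    call of their first registered isomer.
    """
    annotations = annotate_fragments(spectrum, config.frag_tol_ppm)
    evidence = []
    candidates = isomers_of(composition)
    if composition.dp == 3 and composition.terminus == "NRE":
        is_nh2, conf = call_glcnh2_terminus(spectrum, composition, config)
        if is_nh2 and candidates:
            evidence.append("glcnh2_terminus")
            return IsomerCall(composition_id, candidates[0].name, conf, tuple(evidence))
        return IsomerCall(composition_id, "unknown", "tentative", tuple(evidence))
    if composition.terminus == "NRE" and composition.dp <= 2 and composition.n_acetyl == 1:
        epimer = call_uronic_epimer(annotations, config) if composition.n_UA else "none"
        if epimer not in ("unknown", "none"):
            evidence.append(f"epimer:{epimer}")
        if composition.n_SO3 >= 2:
            # with >= 2 sulfates both rings may be sulfated, so the strict
            # "420.11 absent" conjunction does not apply; 254.98 alone attests 2S
            is_2s = composition.n_UA > 0 and _rel(
                annotations, FragmentKind.B1_UA2S
            ) >= config.absence_floor
        else:
            is_2s = composition.n_UA > 0 and call_2S_uronic(annotations, config)
        if is_2s:
            evidence.append("ua_2S")
        pos = "unknown"
        if composition.n_SO3 == 1 and not is_2s:
            pos = call_sulfation_position(annotations, composition, config)
            if pos != "unknown":
                evidence.append(f"position:{pos}")
        name = _assemble_cs_name(composition, epimer, is_2s, pos, candidates)
        if name is not None:
            conf = "diagnostic" if evidence else "tentative"
            return IsomerCall(composition_id, name, conf, tuple(evidence))
    # fall back to elution-order prior / first registered isomer
    if candidates:
        return IsomerCall(composition_id, candidates[0].name, "tentative", tuple(evidence))
    raise UnsupportedStructureError(f"no isomer candidates for composition {composition}")


def _assemble_cs_name(composition, epimer, is_2s, pos, candidates) -> str:
    """Pick the registered isomer matching the fired rules, if unambiguous."""

    def matches(entry):
        if epimer not in ("unknown", "none") and entry.epimer != epimer:
            return False
        if is_2s != ("2S" in entry.sulfation_positions):
            return False
        if pos != "unknown" and pos not in entry.sulfation_positions:
            return False
        return True

    hits = [e for e in candidates if matches(e)]
    if len(hits) == 1:
        return hits[0].name
    if hits:
        return hits[0].name  # elution-order prior breaks remaining ties
    return None


def calibrate_sulfation_polarity(labeled_spectra: list, config: MS2Config = MS2Config()) -> MS2Config:
    """Derive the 4S/6S polarity and cutoff from standards of known position.

    ``labeled_spectra`` is a list of ``(MS2Spectrum, '4S' | '6S')`` pairs.
    Returns a new config with ``pos_polarity`` set to whichever class shows
    the higher mean 420.11 relative abundance and ``pos_cutoff`` at the
    midpoint of the class means.
    """
    groups = {"4S": [], "6S": []}
    for spectrum, label in labeled_spectra:
        ann = annotate_fragments(spectrum, config.frag_tol_ppm)
        groups[label].append(_rel(ann, FragmentKind.Y1_HexNAcS_2AB))
    if not groups["4S"] or not groups["6S"]:
        raise ValueError("need at least one spectrum of each positional class")
    m4, m6 = np.mean(groups["4S"]), np.mean(groups["6S"])
    polarity = "high_is_4S" if m4 >= m6 else "high_is_6S"
    cutoff = float((m4 + m6) / 2.0)
    return MS2Config(
        frag_tol_ppm=config.frag_tol_ppm,
        absence_floor=config.absence_floor,
        epimer_ratio_threshold=config.epimer_ratio_threshold,
        pos_cutoff=cutoff,
        pos_dead_band=config.pos_dead_band,
        pos_polarity=polarity,
        glcnh2_fragment_mzs=config.glcnh2_fragment_mzs,
    )


def read_ms2_csv(path) -> list:
    """CSV with columns precursor_mz, precursor_z, fragment_mz, intensity (one spectrum per precursor)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = ["precursor_mz", "precursor_z", "fragment_mz", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"MS2 CSV {path} missing columns {missing}")
    spectra = []
    for (pmz, pz), grp in df.groupby(["precursor_mz", "precursor_z"], sort=True):
        spectra.append(
            MS2Spectrum(float(pmz), int(pz), tuple(zip(grp.fragment_mz, grp.intensity)))
        )
    return spectra


def read_mgf(path) -> list:
    """Read MS2 spectra from an MGF file."""
    from pyteomics import mgf

    spectra = []
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pmz = float(params["pepmass"][0])
            charge = params.get("charge")
            pz = abs(int(charge[0])) if charge else 1
            peaks = tuple(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            spectra.append(
                MS2Spectrum(pmz, pz, peaks, rt=float(params.get("rtinseconds", 0)) / 60.0)
            )
    return spectra
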