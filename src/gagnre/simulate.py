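"""Synthetic MS1 feature tables and MS2 spectra with the statistical
structure of depolymerized urine GAG samples.

The generator emulates the observable layer of the assay: per-phenotype
relative-abundance vectors over named structures, log-normal intensity noise,
Gaussian ppm mass error, charge-state splitting, co-eluting DBA-adduct and
in-source sulfate-loss satellites, incomplete 2-AB labeling of the internal
disulfated disaccharide (the labeling-yield QC pair), and decoy features at
random m/z.  Every non-decoy feature carries exactly one ground-truth
assignment in the emitted truth table.

Phenotype abundance vectors are qualitative transcriptions of the published
per-subtype profiles (which markers are elevated, reduced or absent), not
digitized bar heights; they are editable config, not code.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import _record_id, max_feasible_charge
from .errors import ConfigError, UnsupportedStructureError
from .masses import CONSTANTS, GlycanComposition, IonSpecies, ion_mz
from .matching import MS1Feature
from .ms2 import MS2Spectrum
from .structures import REGISTRY, get_structure

__all__ = [
    "PhenotypeModel",
    "SimConfig",
    "default_phenotype_models",
    "simulate_sample",
    "simulate_cohort",
    "simulate_ms2",
]

NO_CALL = "no call"


@dataclass(frozen=True)
class PhenotypeModel:
    """Expected relative-intensity vectors for one phenotype.

    ``nre_weights``/``internal_weights`` are relative within their class;
    ``nre_total_fraction`` (percent) fixes the NRE share of total identified
    intensity.  ``expected_call`` is the verdict the assay should reach —
    the underlying subtype for samples whose markers remain diagnostic, and
    "no call" for controls and for treated samples whose profile is
    normalized.
    """

    name: str
    nre_weights: dict
    internal_weights: dict
    galnac_ratio: float = None           # if set, GalNAc6S weight := ratio * GalNAc4S weight
    labeling_efficiency: float = 0.91
    nre_total_fraction: float = 10.3     # percent of all identified saccharide intensity
    expected_call: str = NO_CALL

    def __post_init__(self) -> None:
        if not 0.0 < self.labeling_efficiency <= 1.0:
            raise ConfigError("labeling_efficiency must be in (0, 1]")
        if any(w < 0 for w in self.nre_weights.values()):
            raise ConfigError("negative abundance weight")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_replicates: int = 3                # technical triplicates
    ppm_sigma: float = 3.0               # Gaussian m/z error (~5 sigma inside the 15 ppm gate)
    intensity_cv: float = 0.15           # log-normal sigma of intensity noise
    adduct_fraction: float = 0.10        # DBA satellite intensity relative to parent
    sulfate_loss_fraction: float = 0.08  # in-source loss satellite, per sulfated species
    decoy_rate: float = 0.2              # decoys per true feature
    rt_jitter: float = 0.03              # minutes
    rt_run_length: float = 60.0
    base_intensity: float = 1.0e7
    charge_weights: tuple = (0.65, 0.30, 0.04, 0.01)


_CONTROL_NRE = {
    "GlcAGalNAc4S": 30.0,
    "GlcAGalNAc6S": 20.0,
    "GalNAc4S": 20.0,
    "GalNAc6S": 9.0,
    "GalNAc": 8.0,
    "GlcNS": 5.0,
    "GlcAGlcNS": 5.0,
}

_CONTROL_INTERNAL = {
    "dUAGalNAc4S": 40.0,
    "dUAGalNAc6S": 35.0,
    "dUAGalNAc": 10.0,
    "dUAGlcNAc": 5.0,
    "dUAGlcNS": 5.0,
    "dUAGalNAc4S6S": 5.0,
}


def default_phenotype_models() -> tuple:
    """Control plus the studied MPS phenotypes (naive and treated variants)."""

    def nre(extra=None, scale_baseline=1.0, **overrides):
        v = {k: w * scale_baseline for k, w in _CONTROL_NRE.items()}
        v.update(overrides)
        if extra:
            v.update(extra)
        return v

    control = PhenotypeModel(
        "control", dict(_CONTROL_NRE), dict(_CONTROL_INTERNAL), galnac_ratio=0.45
    )
    return (
        control,
        PhenotypeModel(
            "MPS_I_naive",
            nre(extra={"IdoAGalNAc4S": 45.0, "IdoAGlcNS": 20.0,
                       "IdoAGlcNS(6S)": 18.0, "IdoAGalNAc6S": 8.0}),
            dict(_CONTROL_INTERNAL),
            expected_call="MPS_I",
        ),
        PhenotypeModel(
            "MPS_I_treated",
            # markers reduced but still present after HSCT
            nre(extra={"IdoAGalNAc4S": 20.0, "IdoAGlcNS": 10.0, "IdoAGlcNS(6S)": 10.0}),
            dict(_CONTROL_INTERNAL),
            expected_call="MPS_I",
        ),
        PhenotypeModel(
            "MPS_II",
            nre(extra={"IdoA2SGlcNS": 18.0, "IdoA2SGalNAc4S": 20.0,
                       "IdoA2SGlcNS(6S)": 16.0, "IdoA2SGalNAc": 10.0}),
            dict(_CONTROL_INTERNAL),
            expected_call="MPS_II",
        ),
        PhenotypeModel(
            "MPS_IIIc",
            nre(extra={"GlcNH2UAGlcNAc(6S)": 30.0, "GlcNH2UAGlcNS(6S)": 25.0,
                       "GlcNH2(6S)UAGlcNS(6S)": 12.0}),
            # the two dominant internal disaccharides are reduced in this phenotype
            {**_CONTROL_INTERNAL, "dUAGalNAc4S": 25.0, "dUAGalNAc6S": 20.0},
            expected_call="MPS_IIIc",
        ),
        PhenotypeModel(
            "MPS_IVa",
            nre(),
            dict(_CONTROL_INTERNAL),
            galnac_ratio=1.5,
            expected_call="MPS_IVa",
        ),
        PhenotypeModel(
            "MPS_VI_naive",
            # GalNAc4S accumulates (~3x its control share); other termini recede
            nre(scale_baseline=0.48, GalNAc4S=60.0, GalNAc6S=4.5),
            dict(_CONTROL_INTERNAL),
            expected_call="MPS_VI",
        ),
        PhenotypeModel(
            "MPS_VI_treated",
            # almost normalized after treatment: below the diagnostic elevation
            nre(GalNAc4S=26.0),
            dict(_CONTROL_INTERNAL),
            expected_call=NO_CALL,
        ),
    )


def _charge_split(comp: GlycanComposition, config: SimConfig) -> list:
    zmax = max_feasible_charge(comp)
    weights = np.array(config.charge_weights[:zmax])
    weights = weights / weights.sum()
    return [(z + 1, w) for z, w in enumerate(weights)]


def _mz_observed(comp: GlycanComposition, z: int, rng, config: SimConfig,
                 n_dba: int = 0, n_lost: int = 0) -> float:
    theo = ion_mz(IonSpecies(comp, charge_z=z, n_DBA=n_dba, n_SO3_lost=n_lost))
    return theo * (1.0 + rng.normal(0.0, config.ppm_sigma) * 1e-6)


def simulate_sample(
    model: PhenotypeModel, config: SimConfig, replicate: int = 0, rng=None
):
    """One replicate's feature table plus its ground-truth assignment table.

    Returns ``(features, truth)`` where ``truth`` is a DataFrame with one row
    per feature (``structure`` is empty for decoys).
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, zlib.crc32(model.name.encode()), replicate))
    sample_id = f"{model.name}_r{replicate}"

    nre_weights = dict(model.nre_weights)
    if model.galnac_ratio is not None and "GalNAc4S" in nre_weights:
        nre_weights["GalNAc6S"] = model.galnac_ratio * nre_weights["GalNAc4S"]
    for name in list(nre_weights) + list(model.internal_weights):
        if name not in REGISTRY:
            raise ConfigError(f"model {model.name}: structure {name!r} not in registry")

    # scale classes so that NRE / (NRE + internal) matches nre_total_fraction
    nre_sum = sum(nre_weights.values())
    int_sum = sum(model.internal_weights.values())
    f = model.nre_total_fraction / 100.0
    nre_scale = config.base_intensity * f / nre_sum if nre_sum else 0.0
    int_scale = config.base_intensity * (1.0 - f) / int_sum if int_sum else 0.0

    features, truth_rows = [], []

    def emit(comp, structure, role, rt, intensity, z, n_dba=0, n_lost=0):
        if intensity <= 0:
            return
        feat = MS1Feature(
            sample_id=sample_id,
            rt=float(np.clip(rt + rng.normal(0.0, config.rt_jitter), 0.0, config.rt_run_length)),
            mz=_mz_observed(comp, z, rng, config, n_dba, n_lost),
            charge_z=z,
            intensity=float(intensity),
            sn=float(max(3.0, intensity / (0.002 * config.base_intensity))),
        )
        features.append(feat)
        truth_rows.append(
            dict(sample_id=sample_id, structure=structure, composition_id=_record_id(comp),
                 role=role, rt=feat.rt, mz=feat.mz, charge=z, intensity=feat.intensity)
        )

    def emit_structure(name, expected):
        entry = get_structure(name)
        comp = entry.composition
        true_int = expected * rng.lognormal(0.0, config.intensity_cv)
        for z, w in _charge_split(comp, config):
            emit(comp, name, "parent", entry.rt_min, true_int * w, z)
        if config.adduct_fraction > 0:
            emit(comp, name, "adduct", entry.rt_min,
                 true_int * config.adduct_fraction * rng.lognormal(0.0, config.intensity_cv),
                 1, n_dba=1)
        if comp.n_SO3 >= 1 and config.sulfate_loss_fraction > 0:
            emit(comp, name, "sulfate_loss", entry.rt_min,
                 true_int * config.sulfate_loss_fraction * rng.lognormal(0.0, config.intensity_cv),
                 1, n_lost=1)

    for name, w in sorted(nre_weights.items()):
        emit_structure(name, w * nre_scale)
    for name, w in sorted(model.internal_weights.items()):
        expected = w * int_scale
        entry = get_structure(name)
        if entry.composition.terminus == "internal" and entry.composition.n_SO3 == 2 \
                and entry.composition.labeled_2AB:
            # incomplete 2-AB derivatization: the labeled/unlabeled QC pair
            p = model.labeling_efficiency
            emit_structure(name, expected * p)
            unlabeled = name + " (unlabeled)"
            if unlabeled in REGISTRY:
                emit_structure(unlabeled, expected * (1.0 - p))
        else:
            emit_structure(name, expected)

    n_decoys = int(round(config.decoy_rate * len(features)))
    for _ in range(n_decoys):
        mz = rng.uniform(150.0, 900.0)
        feat = MS1Feature(
            sample_id=sample_id,
            rt=float(rng.uniform(5.0, config.rt_run_length - 5.0)),
            mz=float(mz),
            charge_z=int(rng.integers(1, 4)),
            intensity=float(0.0005 * config.base_intensity * rng.lognormal(0.0, 1.0)),
            sn=float(rng.uniform(3.0, 20.0)),
        )
        features.append(feat)
        truth_rows.append(
            dict(sample_id=sample_id, structure="", composition_id="", role="decoy",
                 rt=feat.rt, mz=feat.mz, charge=feat.charge_z, intensity=feat.intensity)
        )
    truth = pd.DataFrame(truth_rows)
    return features, truth


def simulate_cohort(models: tuple, config: SimConfig):
    """All models x replicates.

    Returns ``(tables, manifest)``: ``tables`` maps sample_id to
    ``(features, truth)``; the manifest links each sample to its phenotype
    truth and expected verdict.
    """
    tables = {}
    manifest_rows = []
    for model in models:
        for rep in range(config.n_replicates):
            features, truth = simulate_sample(model, config, replicate=rep)
            sample_id = f"{model.name}_r{rep}"
            tables[sample_id] = (features, truth)
            manifest_rows.append(
                dict(sample_id=sample_id, phenotype=model.name, replicate=rep,
                     expected_call=model.expected_call)
            )
    return tables, pd.DataFrame(manifest_rows)


def features_to_frame(features: list) -> pd.DataFrame:
    """Feature list in the exact CSV dialect the matcher reads."""
    return pd.DataFrame(
        dict(sample_id=[f.sample_id for f in features],
             rt_min=[f.rt for f in features],
             mz=[f.mz for f in features],
             charge=[f.charge_z for f in features],
             intensity=[f.intensity for f in features],
             sn=[f.sn for f in features])
    )


# --- MS2 templates -------------------------------------------------------

_FRAG = dict(C1_UA=193.035377, B1_UA=175.024812, B1_UA2S=254.981627,
             Y1_HexNAcS_2AB=420.108226, Y1_HexNAc_2AB=340.151411,
             C1_HexN=178.072100)


def _ms2_template(name: str) -> list:
    """Diagnostic-fragment template (mz, relative intensity) for a structure."""
    entry = get_structure(name)
    comp, pos, epimer = entry.composition, entry.sulfation_positions, entry.epimer
    peaks = []
    if comp.n_UA > 0:
        if epimer == "GlcA":
            peaks += [(_FRAG["C1_UA"], 100.0), (_FRAG["B1_UA"], 35.0)]
        elif epimer == "IdoA":
            peaks += [(_FRAG["C1_UA"], 30.0), (_FRAG["B1_UA"], 100.0)]
        else:
            peaks += [(_FRAG["C1_UA"], 50.0), (_FRAG["B1_UA"], 50.0)]
        if "2S" in pos:
            peaks.append((_FRAG["B1_UA2S"], 60.0))
    if comp.n_acetyl >= 1:
        hexnac_sulfated = any(p in ("4S", "6S") for p in pos) and not (
            "2S" in pos and comp.n_SO3 == 1
        )
        if hexnac_sulfated:
            # positional polarity: the 4S isomer shows the more intense 420.11
            rel = 80.0 if "4S" in pos else 15.0
            peaks.append((_FRAG["Y1_HexNAcS_2AB"], rel))
            if comp.dp == 1:
                # dp1 precursor *is* the 420.11 ion; HCD yields its sulfate-loss
                # product, against which the surviving precursor is read
                peaks.append((_FRAG["Y1_HexNAc_2AB"], 50.0))
        elif comp.labeled_2AB:
            peaks.append((_FRAG["Y1_HexNAc_2AB"], 40.0))
    if comp.n_hexn > comp.n_acetyl and comp.dp == 3:
        peaks.append((_FRAG["C1_HexN"], 45.0))  # free-amine terminus retained
    if not peaks:
        raise UnsupportedStructureError(f"no MS2 fragment template for {name!r}")
    return peaks


def simulate_ms2(structure: str, config: SimConfig, rng=None, template=None) -> MS2Spectrum:
    """One HCD spectrum of a named structure, with noise peaks.

    ``template`` overrides the built-in fragment template (an empty list
    yields a noise-only spectrum).
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, zlib.crc32(structure.encode())))
    entry = get_structure(structure)
    comp = entry.composition
    precursor_mz = ion_mz(IonSpecies(comp, charge_z=1))
    peaks = list(_ms2_template(structure)) if template is None else list(template)
    if all(abs(mz - precursor_mz) > 0.05 for mz, _ in peaks):
        peaks.append((precursor_mz, 70.0))  # residual precursor
    observed = []
    for mz, rel in peaks:
        jittered = mz * (1.0 + rng.normal(0.0, config.ppm_sigma * 2.0) * 1e-6)
        observed.append((jittered, rel * rng.lognormal(0.0, 0.2)))
    for _ in range(int(rng.integers(3, 8))):  # chemical noise
        observed.append((float(rng.uniform(120.0, precursor_mz)), float(rng.uniform(0.1, 2.0))))
    return MS2Spectrum(
        precursor_mz=precursor_mz, precursor_z=1, peaks=tuple(observed),
        rt=entry.rt_min, sample_id=structure,
    )
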