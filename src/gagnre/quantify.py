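"""Relative-quantification statistics and QC metrics.

All statistics are intensity-ratio based and therefore invariant under global
intensity scaling:

* per-class relative abundance — each composition/structure as a percent of
  the summed intensity of its class (NRE or internal) in the same sample;
* NRE/dp2S1 ratios — each NRE intensity as a percent of the combined
  intensity of the two major internal disaccharides (dUAGalNAc4S +
  dUAGalNAc6S), the internal-reference normalization used for
  between-sample comparison;
* GalNAc6S/GalNAc4S ratio of the two mono-sulfated dp1 NRE isomers
  (elevated in MPS IVa);
* 2-AB labeling yield from the labeled/unlabeled internal disulfated
  disaccharide (dp2S2) QC pair.

Undefined ratios (zero denominator) propagate as explicit ``None`` values,
never as 0 or infinity — a sample where GalNAc6S is undetected has an
undefined ratio, not a zero one.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .structures import REGISTRY, isomers_of

logger = logging.getLogger(__name__)

__all__ = [
    "NREProfile",
    "relative_abundance",
    "nre_to_dp2s1_ratio",
    "galnac6s_4s_ratio",
    "labeling_yield",
    "resolve_isomers",
    "build_profile",
    "replicate_summary",
]

#: the two dominant internal disaccharides used as the normalization reference
DP2S1_REFERENCE_STRUCTURES = ("dUAGalNAc4S", "dUAGalNAc6S")


def _check_nonnegative(quants) -> None:
    for q in quants:
        if q.intensity < 0:
            raise DataError(f"negative intensity for {q.composition_id}")


def _class_of(q) -> str:
    return q.composition.terminus  # 'internal' | 'NRE'


def relative_abundance(quants: list, klass: str) -> dict:
    """Each member as ``100 * I / sum(I)`` within its terminus class."""
    _check_nonnegative(quants)
    members = [q for q in quants if _class_of(q) == klass and q.composition.labeled_2AB]
    total = sum(q.intensity for q in members)
    if total == 0:
        return {}
    return {q.composition_id: 100.0 * q.intensity / total for q in members}


def _reference_intensity(quants: list) -> float:
    ref_keys = {REGISTRY[n].composition.key for n in DP2S1_REFERENCE_STRUCTURES}
    return sum(q.intensity for q in quants if q.composition.key in ref_keys)


def nre_to_dp2s1_ratio(quants: list) -> dict:
    """Each NRE as a percent of the combined dp2S1 internal reference.

    Returns ``None`` per entry when the reference intensity is zero.
    """
    _check_nonnegative(quants)
    ref = _reference_intensity(quants)
    nres = [q for q in quants if _class_of(q) == "NRE" and q.composition.labeled_2AB]
    if ref == 0:
        logger.warning("dp2S1 internal reference absent; NRE/dp2S1 ratios undefined")
        return {q.composition_id: None for q in nres}
    return {q.composition_id: 100.0 * q.intensity / ref for q in nres}


def galnac6s_4s_ratio(isomer_intensities: dict) -> float:
    """I(GalNAc6S)/I(GalNAc4S) from isomer-resolved dp1 intensities.

    ``None`` when the denominator is absent/zero (e.g. GalNAc6S-only samples)
    or when neither isomer was resolved.
    """
    i6 = isomer_intensities.get("GalNAc6S")
    i4 = isomer_intensities.get("GalNAc4S")
    if not i4:
        logger.info("GalNAc4S intensity absent or zero; 6S/4S ratio undefined")
        return None
    return (i6 or 0.0) / i4


def labeling_yield(quants: list) -> float:
    """2-AB labeling efficiency (%) from the internal dp2S2 QC pair.

    ``100 * I(labeled dp2S2) / (I(labeled) + I(unlabeled))``; ``None`` when
    neither form was observed.  A yield of 0% (labeled form absent) is a QC
    failure and is logged as such.
    """

    def is_dp2s2(q, labeled):
        c = q.composition
        return (c.terminus == "internal" and c.dp == 2 and c.n_SO3 == 2
                and c.labeled_2AB is labeled)

    lab = sum(q.intensity for q in quants if is_dp2s2(q, True))
    unlab = sum(q.intensity for q in quants if is_dp2s2(q, False))
    if lab + unlab == 0:
        return None
    pct = 100.0 * lab / (lab + unlab)
    if pct == 0.0:
        logger.warning("labeling-yield QC fail: only unlabeled dp2S2 observed")
    return pct


def resolve_isomers(matches: list, rt_window: float = 0.5) -> dict:
    """Split composition intensities into named isomers by elution time.

    Preferred parent-role matches of compositions with several registered
    isomers are assigned to the nearest reference retention time within
    ``rt_window``; satellites follow their co-eluting isomer.  Features
    outside every isomer window stay unresolved at composition level.

    Returns ``{sample_id: {structure_name: intensity}}``.
    """
    out: dict[str, dict[str, float]] = {}
    for m in matches:
        if not m.preferred:
            continue
        isomers = isomers_of(m.ion.composition)
        if not isomers:
            continue
        if len(isomers) == 1:
            name = isomers[0].name
        else:
            nearest = min(isomers, key=lambda e: abs(e.rt_min - m.feature.rt))
            if abs(nearest.rt_min - m.feature.rt) > rt_window:
                continue  # isomer-unresolved; stays at composition level
            name = nearest.name
        bucket = out.setdefault(m.feature.sample_id, {})
        bucket[name] = bucket.get(name, 0.0) + m.feature.intensity
    return out


@dataclass
class NREProfile:
    """Per-sample relative-abundance vectors and derived ratios.

    Maps are keyed by structure name where isomer-resolved, otherwise by
    composition id (carried in ``unresolved_keys``).  Percentages within
    ``nre_rel`` and ``internal_rel`` each sum to 100 when nonempty.
    """

    sample_id: str
    nre_rel: dict = field(default_factory=dict)
    internal_rel: dict = field(default_factory=dict)
    nre_over_dp2s1: dict = field(default_factory=dict)
    nre_fraction_total: float = None
    galnac6s_4s_ratio: float = None
    labeling_yield: float = None
    unresolved_keys: frozenset = frozenset()
    replicate_stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "nre_rel": self.nre_rel,
            "internal_rel": self.internal_rel,
            "nre_over_dp2s1": self.nre_over_dp2s1,
            "nre_fraction_total": self.nre_fraction_total,
            "galnac6s_4s_ratio": self.galnac6s_4s_ratio,
            "labeling_yield": self.labeling_yield,
            "unresolved_keys": sorted(self.unresolved_keys),
            "replicate_stats": self.replicate_stats,
        }


def _structure_level(quants: list, isomer_intensities: dict, klass: str) -> tuple:
    """Intensities keyed by structure name where resolved, else composition id."""
    values: dict[str, float] = {}
    unresolved = set()
    resolved_total_by_comp: dict[str, float] = {}
    for name, inten in isomer_intensities.items():
        entry = REGISTRY[name]
        if entry.composition.terminus != klass or not entry.composition.labeled_2AB:
            continue
        values[name] = values.get(name, 0.0) + inten
        key = entry.composition.key
        resolved_total_by_comp[key] = resolved_total_by_comp.get(key, 0.0) + inten
    for q in quants:
        if _class_of(q) != klass or not q.composition.labeled_2AB:
            continue
        leftover = q.intensity - resolved_total_by_comp.get(q.composition.key, 0.0)
        if leftover > 1e-9 * max(q.intensity, 1.0):
            values[q.composition_id] = values.get(q.composition_id, 0.0) + leftover
            unresolved.add(q.composition_id)
    return values, unresolved


def build_profile(quants: list, isomer_intensities: dict = None, sample_id: str = None) -> NREProfile:
    """Assemble the full per-sample profile from aggregated intensities."""
    _check_nonnegative(quants)
    isomer_intensities = isomer_intensities or {}
    if sample_id is None:
        sample_id = quants[0].sample_id if quants else "sample"

    nre_vals, nre_unres = _structure_level(quants, isomer_intensities, "NRE")
    int_vals, int_unres = _structure_level(quants, isomer_intensities, "internal")

    def normalize(vals):
        tot = sum(vals.values())
        return {k: 100.0 * v / tot for k, v in vals.items()} if tot > 0 else {}

    total_nre = sum(nre_vals.values())
    total_int = sum(int_vals.values())
    ref = _reference_intensity(quants)
    over = (
        {k: 100.0 * v / ref for k, v in nre_vals.items()}
        if ref > 0
        else {k: None for k in nre_vals}
    )
    return NREProfile(
        sample_id=sample_id,
        nre_rel=normalize(nre_vals),
        internal_rel=normalize(int_vals),
        nre_over_dp2s1=over,
        nre_fraction_total=(
            100.0 * total_nre / (total_nre + total_int) if total_nre + total_int > 0 else None
        ),
        galnac6s_4s_ratio=galnac6s_4s_ratio(isomer_intensities),
        labeling_yield=labeling_yield(quants),
        unresolved_keys=frozenset(nre_unres | int_unres),
    )


def _mean_sd(values: list) -> tuple:
    vals = [v for v in values if v is not None]
    if not vals:
        return None, None
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    return mean, sd


def replicate_summary(profiles: list) -> NREProfile:
    """Mean/SD over technical replicates (union of keys; missing = 0, warned)."""
    if not profiles:
        raise DataError("no replicates to summarize")
    sample_id = profiles[0].sample_id.rsplit("_r", 1)[0]
    stats: dict = {}
    mean_maps: dict = {}
    for attr in ("nre_rel", "internal_rel", "nre_over_dp2s1"):
        keys = sorted({k for p in profiles for k in getattr(p, attr)})
        per_key = {}
        means = {}
        for k in keys:
            vals = []
            for p in profiles:
                v = getattr(p, attr).get(k)
                if k not in getattr(p, attr):
                    warnings.warn(
                        f"replicate {p.sample_id} missing {k} in {attr}; treated as 0"
                    )
                    v = 0.0
                vals.append(v)
            mean, sd = _mean_sd(vals)
            per_key[k] = {"mean": mean, "sd": sd}
            means[k] = mean
        stats[attr] = per_key
        mean_maps[attr] = means
    for attr in ("nre_fraction_total", "galnac6s_4s_ratio", "labeling_yield"):
        mean, sd = _mean_sd([getattr(p, attr) for p in profiles])
        stats[attr] = {"mean": mean, "sd": sd}
        mean_maps[attr] = mean
    return NREProfile(
        sample_id=sample_id,
        nre_rel=mean_maps["nre_rel"],
        internal_rel=mean_maps["internal_rel"],
        nre_over_dp2s1=mean_maps["nre_over_dp2s1"],
        nre_fraction_total=mean_maps["nre_fraction_total"],
        galnac6s_4s_ratio=mean_maps["galnac6s_4s_ratio"],
        labeling_yield=mean_maps["labeling_yield"],
        unresolved_keys=frozenset().union(*(p.unresolved_keys for p in profiles)),
        replicate_stats=stats,
    )
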