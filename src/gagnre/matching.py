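"""MS1 feature -> theoretical ion assignment within a ppm tolerance.

A deconvoluted feature matches a catalog ion iff the relative mass error is
within the tolerance (default 15 ppm) and the charge states agree (features
with undetermined charge, z = 0, may match any catalog charge and are
flagged).  Features matching several candidate ions keep all candidates under
a shared ambiguity group; a deterministic tie-break (smallest |ppm|, then
fewer adducts, then fewer sulfate losses) marks one candidate preferred —
replacing manual inspection with an auditable rule.

Co-elution consolidation then attaches sulfate-loss/adduct satellites to a
parent composition only when a parent-species feature of that composition
elutes within ``rt_tol``; orphan loss candidates fall back to the isobaric
lower-sulfation parent, or are flagged ``loss_only``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import IonCatalog
from .errors import RowValidationError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "MS1Feature",
    "FeatureMatch",
    "CompositionQuant",
    "read_feature_table",
    "match_features",
    "consolidate_coeluting",
    "aggregate_by_composition",
    "unassigned_features",
]

REQUIRED_COLUMNS = ["sample_id", "rt_min", "mz", "charge", "intensity", "sn"]


@dataclass(frozen=True)
class MS1Feature:
    """One deconvoluted LC-MS1 signal."""

    sample_id: str
    rt: float            # minutes
    mz: float            # Th
    charge_z: int = 0    # 0 = undetermined
    intensity: float = 0.0
    sn: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"negative intensity {self.intensity}")


@dataclass
class FeatureMatch:
    feature: MS1Feature
    ion: object                      # CatalogIon
    ppm_error: float
    role: str                        # parent | sulfate_loss | adduct
    ambiguity_group: int = None
    preferred: bool = True
    flags: frozenset = frozenset()


@dataclass
class CompositionQuant:
    sample_id: str
    composition_id: str
    composition: object
    intensity: float
    n_features: int
    rt_apex: float
    flags: frozenset = frozenset()


def read_feature_table(path, dialect: str = None, errors: str = "raise") -> list:
    """Read an MS1 feature table (CSV or TSV) into :class:`MS1Feature` rows.

    Rows failing numeric validation are reported — raised as
    :class:`RowValidationError` listing their 1-based data-row indices, or,
    with ``errors='warn'``, warned about and dropped.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table {path} missing columns: {missing}")
    if df.empty:
        warnings.warn(f"feature table {path} contains a header but no rows")
        return []
    feats, bad_rows = [], []
    numeric = ["rt_min", "mz", "charge", "intensity", "sn"]
    for i, row in df.iterrows():
        try:
            if row[numeric].isna().any():
                raise ValueError("missing numeric value")
            feats.append(
                MS1Feature(
                    sample_id=str(row["sample_id"]),
                    rt=float(row["rt_min"]),
                    mz=float(row["mz"]),
                    charge_z=int(row["charge"]),
                    intensity=float(row["intensity"]),
                    sn=float(row["sn"]),
                )
            )
        except (TypeError, ValueError):
            bad_rows.append(i + 1)  # 1-based data-row index
    if bad_rows:
        msg = f"feature table {path}: {len(bad_rows)} invalid row(s): {bad_rows[:10]}"
        if errors == "raise":
            raise RowValidationError(msg, bad_rows)
        warnings.warn(msg)
    return feats


def _candidate_sort_key(m: FeatureMatch) -> tuple:
    return (abs(m.ppm_error), m.ion.n_dba, m.ion.n_so3_lost, m.ion.key)


def match_features(features: list, catalog: IonCatalog, tol_ppm: float = 15.0) -> list:
    """All (feature, ion) pairs within ``tol_ppm``; deterministic, order-independent."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    mz_arr = catalog.mz_array
    z_arr = catalog.z_array
    matches = []
    group_counter = 0
    # sort features for order-independent output/grouping ids
    ordered = sorted(features, key=lambda f: (f.sample_id, f.mz, f.rt, f.charge_z, f.intensity))
    for feat in ordered:
        half = feat.mz * tol_ppm * 1e-6
        lo = np.searchsorted(mz_arr, feat.mz - half, side="left")
        hi = np.searchsorted(mz_arr, feat.mz + half, side="right")
        cands = []
        for idx in range(lo, hi):
            ion = catalog.entries[idx]
            if feat.charge_z not in (0, z_arr[idx]):
                continue
            ppm = 1e6 * (feat.mz - ion.mz) / ion.mz
            if abs(ppm) > tol_ppm:
                continue
            flags = frozenset({"charge_undetermined"}) if feat.charge_z == 0 else frozenset()
            cands.append(FeatureMatch(feat, ion, ppm, ion.role, flags=flags))
        if not cands:
            continue
        cands.sort(key=_candidate_sort_key)
        if len(cands) > 1:
            group_counter += 1
            for c in cands:
                c.ambiguity_group = group_counter
                c.flags = c.flags | {"ambiguous"}
        for rank, c in enumerate(cands):
            c.preferred = rank == 0
        matches.extend(cands)
    return matches


def consolidate_coeluting(matches: list, rt_tol: float = 0.2) -> list:
    """Resolve satellite (loss/adduct) assignments by RT co-elution evidence.

    A loss/adduct candidate is *supported* when a parent-species match of the
    same composition elutes within ``rt_tol`` in the same sample.  Supported
    satellites outrank bare parent candidates for the same feature (co-elution
    evidence beats parsimony); unsupported satellites lose to any parent
    candidate of an isobaric lower-sulfation composition, and are flagged
    ``loss_only``/``adduct_only`` when no such parent exists.
    """
    # parent elution evidence per (sample, composition)
    parent_rts: dict[tuple, list] = {}
    for m in matches:
        if m.role == "parent":
            parent_rts.setdefault((m.feature.sample_id, m.ion.composition_id), []).append(
                m.feature.rt
            )

    def supported(m: FeatureMatch) -> bool:
        if m.role == "parent":
            return True
        rts = parent_rts.get((m.feature.sample_id, m.ion.composition_id), [])
        return any(abs(m.feature.rt - rt) <= rt_tol for rt in rts)

    by_feature: dict[int, list] = {}
    for m in matches:
        by_feature.setdefault(id(m.feature), []).append(m)

    out = []
    for cands in by_feature.values():
        ranked = sorted(
            cands,
            key=lambda m: (
                # supported satellites first, then parents, then orphans
                0 if (m.role != "parent" and supported(m)) else (1 if m.role == "parent" else 2),
                *_candidate_sort_key(m),
            ),
        )
        for rank, m in enumerate(ranked):
            chosen = rank == 0
            flags = set(m.flags)
            if chosen and m.role != "parent" and not supported(m):
                flags.add("loss_only" if m.role == "sulfate_loss" else "adduct_only")
                logger.info(
                    "orphan %s match %s at rt %.2f (no co-eluting parent within %.2f min)",
                    m.role, m.ion.composition_id, m.feature.rt, rt_tol,
                )
            out.append(replace_match(m, preferred=chosen, flags=frozenset(flags)))
    out.sort(key=lambda m: (m.feature.sample_id, m.feature.mz, m.feature.rt,
                            not m.preferred, m.ion.key))
    return out


def replace_match(m: FeatureMatch, **kw) -> FeatureMatch:
    d = dict(feature=m.feature, ion=m.ion, ppm_error=m.ppm_error, role=m.role,
             ambiguity_group=m.ambiguity_group, preferred=m.preferred, flags=m.flags)
    d.update(kw)
    return FeatureMatch(**d)


def aggregate_by_composition(matches: list) -> list:
    """Sum each feature's intensity once, under its preferred candidate.

    Intensities are combined across charge states, adduct species and
    attached sulfate-loss satellites of one composition.
    """
    groups: dict[tuple, list] = {}
    for m in matches:
        if not m.preferred:
            continue
        groups.setdefault((m.feature.sample_id, m.ion.composition_id), []).append(m)
    quants = []
    for (sample_id, comp_id), ms in sorted(groups.items()):
        intensity = sum(m.feature.intensity for m in ms)
        apex = max(ms, key=lambda m: m.feature.intensity).feature.rt
        flags = set()
        if any("ambiguous" in m.flags for m in ms):
            flags.add("ambiguous")
        roles = {m.role for m in ms}
        if "parent" not in roles:
            flags.add("loss_only" if "sulfate_loss" in roles else "adduct_only")
        quants.append(
            CompositionQuant(
                sample_id=sample_id,
                composition_id=comp_id,
                composition=ms[0].ion.composition,
                intensity=intensity,
                n_features=len(ms),
                rt_apex=apex,
                flags=frozenset(flags),
            )
        )
    return quants


def unassigned_features(features: list, matches: list) -> list:
    """Features with no catalog match (decoys, contaminants, unknowns)."""
    matched_ids = {id(m.feature) for m in matches}
    return [f for f in features if id(f) not in matched_ids]
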