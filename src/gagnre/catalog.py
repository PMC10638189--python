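"""Composition enumeration and the searchable theoretical ion catalog.

The composition database is the set of saccharide compositions considered by
the search: internal (dUA) disaccharides and saturated NRE mono- to
trisaccharides, over configurable sulfation/acetylation/labeling bounds.
Each composition is then expanded into all observable ions — charge states
1− to 4−, DBA adducts, and in-source sulfate-loss satellites — with
theoretical m/z from the mass engine.

Enumeration is a pure function of its config: the same
:class:`EnumerationConfig` always yields the bit-identical record list, so a
supplementary composition table can be transcribed into a config and
reproduced exactly.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CatalogError, ConfigError
from .masses import GlycanComposition, IonSpecies, ion_mz
from .structures import isomers_of

__all__ = [
    "ClassBounds",
    "EnumerationConfig",
    "CompositionRecord",
    "CatalogIon",
    "IonCatalog",
    "default_enumeration_config",
    "enumerate_compositions",
    "build_ion_catalog",
    "export_catalog",
    "import_catalog",
    "export_catalog_sqlite",
]

# backbone composition implied by (terminus, dp): lyase internals start with a
# dUA; NREs are hexosamine (dp1), UA-hexosamine (dp2) or hexosamine-UA-hexosamine (dp3)
_BACKBONES = {
    ("internal", 2): dict(n_dUA=1, n_UA=0, n_hexn=1),
    ("NRE", 1): dict(n_dUA=0, n_UA=0, n_hexn=1),
    ("NRE", 2): dict(n_dUA=0, n_UA=1, n_hexn=1),
    ("NRE", 3): dict(n_dUA=0, n_UA=1, n_hexn=2),
}


@dataclass(frozen=True)
class ClassBounds:
    """Enumeration bounds for one composition class."""

    terminus: str                      # 'internal' | 'NRE'
    dp: int
    max_so3: int
    min_so3: int = 0
    acetyl: tuple = None               # allowed N-acetyl counts; None = 0..n_hexn
    labeled: tuple = (True,)

    def backbone(self) -> dict:
        try:
            return _BACKBONES[(self.terminus, self.dp)]
        except KeyError as exc:
            raise ConfigError(
                f"no backbone defined for terminus={self.terminus!r}, dp={self.dp}"
            ) from exc


@dataclass(frozen=True)
class EnumerationConfig:
    classes: tuple = ()


def default_enumeration_config() -> EnumerationConfig:
    """Bounds covering the classes named for this workflow.

    Internal dp2 with 0-3 sulfates (plus the unlabeled disulfated QC
    species), NRE dp1 with 0-2 sulfates, NRE dp2 with 0-3, and the
    glucosamine-terminated NRE dp3 with 0-4.
    """
    return EnumerationConfig(
        classes=(
            ClassBounds("internal", 2, max_so3=3),
            ClassBounds("internal", 2, max_so3=2, min_so3=2, labeled=(False,)),  # dp2S2 QC
            ClassBounds("NRE", 1, max_so3=2),
            ClassBounds("NRE", 2, max_so3=3),
            ClassBounds("NRE", 3, max_so3=4),
        )
    )


@dataclass(frozen=True)
class CompositionRecord:
    id: str
    composition: GlycanComposition
    isomers: tuple = ()
    gag_class_hint: str = "ambiguous"   # CS/DS | HS | ambiguous
    nre_flag: bool = False


def _record_id(c: GlycanComposition) -> str:
    tag = "nre" if c.terminus == "NRE" else "int"
    lab = "2ab" if c.labeled_2AB else "free"
    return f"{tag}-dp{c.dp}-ac{c.n_acetyl}-s{c.n_SO3}-{lab}"


def _class_hint(c: GlycanComposition, isomers) -> str:
    names = [e.name for e in isomers]
    if names:
        has_hs = any("GlcN" in n for n in names)
        has_cs = any("GalNAc" in n for n in names)
        if has_hs and not has_cs:
            return "HS"
        if has_cs and not has_hs:
            return "CS/DS"
        return "ambiguous"
    if c.n_hexn == 2:
        return "HS"  # glucosamine-terminated trisaccharides
    return "ambiguous"


def enumerate_compositions(config: EnumerationConfig = None) -> list:
    """Expand the config bounds into a sorted, deduplicated record list."""
    config = config or default_enumeration_config()
    seen: dict[tuple, GlycanComposition] = {}
    for cls in config.classes:
        backbone = cls.backbone()
        if cls.min_so3 > cls.max_so3:
            raise ConfigError(f"min_so3 > max_so3 in {cls}")
        acetyl_opts = cls.acetyl if cls.acetyl is not None else tuple(range(backbone["n_hexn"] + 1))
        if any(a > backbone["n_hexn"] for a in acetyl_opts):
            raise ConfigError(f"acetyl option exceeds backbone in {cls}")
        for ac in acetyl_opts:
            for s in range(cls.min_so3, cls.max_so3 + 1):
                for lab in cls.labeled:
                    c = GlycanComposition(
                        n_acetyl=ac, n_SO3=s, labeled_2AB=bool(lab), **backbone
                    )
                    seen[c.key] = c
    records = []
    for c in sorted(seen.values()):
        iso = tuple(isomers_of(c))
        records.append(
            CompositionRecord(
                id=_record_id(c),
                composition=c,
                isomers=iso,
                gag_class_hint=_class_hint(c, iso),
                nre_flag=c.terminus == "NRE",
            )
        )
    records.sort(key=lambda r: (r.composition.terminus, r.composition.dp,
                                r.composition.n_acetyl, r.composition.n_SO3,
                                not r.composition.labeled_2AB))
    return records


def max_feasible_charge(c: GlycanComposition) -> int:
    """Charge ceiling from ionizable acidic sites (carboxylates + sulfates)."""
    return min(4, c.n_SO3 + c.n_UA + c.n_dUA + 1)


@dataclass(frozen=True)
class CatalogIon:
    composition_id: str
    composition: GlycanComposition
    charge_z: int
    n_dba: int
    n_so3_lost: int
    mz: float

    @property
    def role(self) -> str:
        if self.n_dba > 0:
            return "adduct"
        if self.n_so3_lost > 0:
            return "sulfate_loss"
        return "parent"

    @property
    def key(self) -> tuple:
        return (self.composition_id, self.charge_z, self.n_dba, self.n_so3_lost)


class IonCatalog:
    """Searchable list of theoretical ions with fast m/z lookup arrays."""

    def __init__(self, entries: list, build_config: dict = None):
        keys = [e.key for e in entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise CatalogError(f"duplicate catalog keys: {dupes[:5]}")
        self.entries = sorted(entries, key=lambda e: (e.mz, e.key))
        self.build_config = build_config or {}
        self._mz = np.array([e.mz for e in self.entries])
        self._z = np.array([e.charge_z for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, IonCatalog) and [e.key for e in self.entries] == [
            e.key for e in other.entries
        ]

    @property
    def mz_array(self) -> np.ndarray:
        return self._mz

    @property
    def z_array(self) -> np.ndarray:
        return self._z

    def compositions(self) -> dict:
        out = {}
        for e in self.entries:
            out.setdefault(e.composition_id, e.composition)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            c = e.composition
            rows.append(
                dict(
                    id=e.composition_id, dp=c.dp, n_dUA=c.n_dUA, n_UA=c.n_UA,
                    n_hexN=c.n_hexn, n_acetyl=c.n_acetyl, n_SO3=c.n_SO3,
                    labeled=int(c.labeled_2AB), z=e.charge_z, n_DBA=e.n_dba,
                    n_SO3_lost=e.n_so3_lost, mz_theoretical=e.mz,
                )
            )
        return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def build_ion_catalog(
    records: list,
    z_range: tuple = (1, 4),
    max_dba: int = 1,
    allow_sulfate_loss: bool = True,
) -> IonCatalog:
    """Expand composition records over charge, DBA adducts and sulfate losses.

    Charge is capped by the number of ionizable acidic sites, so neutral-sugar
    dp1 species only appear singly charged.
    """
    z_lo, z_hi = z_range
    entries = []
    for rec in records:
        c = rec.composition
        z_max = min(z_hi, max_feasible_charge(c))
        for z in range(max(1, z_lo), z_max + 1):
            for n_dba in range(max_dba + 1):
                losses = range(c.n_SO3 + 1) if allow_sulfate_loss else (0,)
                for lost in losses:
                    sp = IonSpecies(c, charge_z=z, n_DBA=n_dba, n_SO3_lost=lost)
                    entries.append(
                        CatalogIon(rec.id, c, z, n_dba, lost, ion_mz(sp))
                    )
    return IonCatalog(
        entries,
        build_config=dict(z_range=list(z_range), max_dba=max_dba,
                          allow_sulfate_loss=allow_sulfate_loss,
                          n_compositions=len(records)),
    )


_TSV_COLUMNS = [
    "id", "dp", "n_dUA", "n_UA", "n_hexN", "n_acetyl", "n_SO3", "labeled",
    "z", "n_DBA", "n_SO3_lost", "mz_theoretical",
]


def export_catalog(catalog: IonCatalog, path) -> None:
    """Write the catalog as TSV (header per :data:`_TSV_COLUMNS`)."""
    catalog.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")


def import_catalog(path) -> IonCatalog:
    """Read a catalog TSV; validates keys and recomputes/verifies m/z."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"catalog file {path} missing columns {missing}")
    entries = []
    for i, row in df.iterrows():
        try:
            comp = GlycanComposition(
                int(row.n_dUA), int(row.n_UA), int(row.n_hexN),
                int(row.n_acetyl), int(row.n_SO3), bool(int(row.labeled)),
            )
            sp = IonSpecies(comp, int(row.z), int(row.n_DBA), int(row.n_SO3_lost))
        except Exception as exc:
            raise CatalogError(f"catalog file {path}, line {i + 2}: {exc}") from exc
        mz = ion_mz(sp)
        if abs(mz - float(row.mz_theoretical)) > 1e-4:
            raise CatalogError(
                f"catalog file {path}, line {i + 2}: stored m/z {row.mz_theoretical} "
                f"disagrees with recomputed {mz:.6f}"
            )
        entries.append(CatalogIon(str(row.id), comp, int(row.z), int(row.n_DBA),
                                  int(row.n_SO3_lost), mz))
    return IonCatalog(entries)


def export_catalog_sqlite(catalog: IonCatalog, path) -> None:
    """Mirror the catalog into a single-file relational database."""
    with sqlite3.connect(path) as con:
        catalog.to_dataframe().to_sql("ion_catalog", con, if_exists="replace", index=False)
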