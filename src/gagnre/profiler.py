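"""Rule-based MPS-subtype evidence from an NRE profile.

Each MPS subtype leaves a characteristic set of non-reducing-end structures
because the deficient exo-enzyme defines which terminus can no longer be
degraded: iduronidase deficiency (MPS I) leaves IdoA termini, iduronate-2-
sulfatase deficiency (MPS II) leaves 2-O-sulfated IdoA termini, heparan
alpha-glucosaminide N-acetyltransferase deficiency (MPS IIIc) leaves
free-amine glucosamine (GlcNH2) termini, N-acetylgalactosamine-6-sulfatase
deficiency (MPS IVa) shifts the GalNAc6S/GalNAc4S monosaccharide ratio, and
arylsulfatase-B deficiency (MPS VI) elevates GalNAc4S.

Panels are declarative and auditable: presence rules fire when a marker
exceeds a threshold on the NRE/dp2S1 scale (and, when a control reference is
supplied, is absent/low in the control or sufficiently elevated over it);
the MPS IVa panel is a ratio cutoff.  The verdict is the highest-scoring
subtype with at least ``min_fired`` rules fired, else "no call".

Panels exist only for the subtypes with patient evidence (I, II, IIIc, IVa,
VI); markers for other subtypes would be theoretical and are not called.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .errors import ConfigError
from .quantify import NREProfile
from .structures import REGISTRY

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceRule",
    "RatioRule",
    "BiomarkerPanel",
    "SubtypeCall",
    "MarkerDelta",
    "default_panels",
    "evaluate_panels",
    "compare_followup",
    "panels_to_json",
    "panels_from_json",
]

NO_CALL = "no call"


@dataclass(frozen=True)
class PresenceRule:
    """Marker present above threshold on the NRE/dp2S1 percent scale.

    ``max_control_pct`` demands the marker be essentially absent in the
    control reference ("absent or close to the level of detection");
    ``min_fold_over_control`` instead demands elevation over a control in
    which the marker is normally present (the GalNAc4S case).
    """

    marker: str
    min_pct: float = 1.0
    max_control_pct: float = None
    min_fold_over_control: float = None

    @property
    def rule_id(self) -> str:
        return f"presence:{self.marker}"

    def fires(self, profile: NREProfile, control: NREProfile = None) -> bool:
        value = profile.nre_over_dp2s1.get(self.marker)
        if value is None or value < self.min_pct:
            return False
        if control is not None:
            cval = control.nre_over_dp2s1.get(self.marker, 0.0) or 0.0
            if self.max_control_pct is not None and cval > self.max_control_pct:
                return False
            if self.min_fold_over_control is not None:
                if cval > 0 and value / cval < self.min_fold_over_control:
                    return False
        return True


@dataclass(frozen=True)
class RatioRule:
    """GalNAc6S/GalNAc4S ratio above a cutoff (MPS IVa)."""

    cutoff: float = 0.95  # control mean + 2 SD (0.45 + 2 * 0.25)

    @property
    def rule_id(self) -> str:
        return f"ratio:GalNAc6S/GalNAc4S>{self.cutoff}"

    def fires(self, profile: NREProfile, control: NREProfile = None) -> bool:
        r = profile.galnac6s_4s_ratio
        return r is not None and r > self.cutoff


@dataclass(frozen=True)
class BiomarkerPanel:
    subtype: str
    rules: tuple

    def __post_init__(self) -> None:
        for rule in self.rules:
            marker = getattr(rule, "marker", None)
            if marker is not None and marker not in REGISTRY:
                raise ConfigError(f"panel {self.subtype}: unknown marker {marker!r}")


@dataclass
class SubtypeCall:
    sample_id: str
    scores: dict                      # subtype -> fraction of rules fired
    fired: dict                       # subtype -> list of rule ids
    verdict: str
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "scores": self.scores,
            "fired": self.fired,
            "verdict": self.verdict,
            "notes": self.notes,
        }


def default_panels() -> tuple:
    """The per-subtype marker panels, with default thresholds."""
    return (
        BiomarkerPanel(
            "MPS_I",
            (
                PresenceRule("IdoAGlcNS(6S)", max_control_pct=0.1),
                PresenceRule("IdoAGlcNS", max_control_pct=0.1),
                PresenceRule("IdoAGalNAc4S", max_control_pct=0.1),
            ),
        ),
        BiomarkerPanel(
            "MPS_II",
            (
                PresenceRule("IdoA2SGlcNS(6S)", max_control_pct=0.1),
                PresenceRule("IdoA2SGlcNS", max_control_pct=0.1),
                PresenceRule("IdoA2SGalNAc4S", max_control_pct=0.1),
            ),
        ),
        BiomarkerPanel(
            "MPS_IIIc",
            (
                PresenceRule("GlcNH2UAGlcNAc(6S)", max_control_pct=0.1),
                PresenceRule("GlcNH2UAGlcNS(6S)", max_control_pct=0.1),
                PresenceRule("GlcNH2(6S)UAGlcNS(6S)", max_control_pct=0.1),
            ),
        ),
        BiomarkerPanel("MPS_IVa", (RatioRule(0.95),)),
        BiomarkerPanel(
            "MPS_VI",
            # GalNAc4S occurs in controls too, so the rule demands elevation
            (PresenceRule("GalNAc4S", min_pct=1.0, min_fold_over_control=2.0),),
        ),
    )


def evaluate_panels(
    profile: NREProfile,
    panels: tuple = None,
    control_reference: NREProfile = None,
    min_fired: int = 1,
) -> SubtypeCall:
    """Score every panel against a profile and emit the verdict."""
    panels = panels if panels is not None else default_panels()
    scores, fired = {}, {}
    notes = []
    if control_reference is None:
        notes.append("no control reference supplied; control-dependent guards skipped")
    for panel in panels:
        ids = [r.rule_id for r in panel.rules if r.fires(profile, control_reference)]
        fired[panel.subtype] = ids
        scores[panel.subtype] = len(ids) / len(panel.rules)
    callable_panels = [p.subtype for p in panels if len(fired[p.subtype]) >= min_fired]
    if callable_panels:
        verdict = max(
            callable_panels, key=lambda s: (scores[s], len(fired[s]), s)
        )
    else:
        verdict = NO_CALL
    return SubtypeCall(profile.sample_id, scores, fired, verdict, notes)


@dataclass(frozen=True)
class MarkerDelta:
    marker: str
    before: float
    after: float
    fold_change: float            # after / before on the NRE/dp2S1 scale
    normalized: bool
    detected: bool = True


def compare_followup(
    profile_before: NREProfile,
    profile_after: NREProfile,
    panel: BiomarkerPanel,
    presence_threshold: float = 1.0,
) -> list:
    """Per-marker treatment deltas on the NRE/dp2S1 scale.

    A marker whose post-treatment value falls below the presence threshold is
    flagged ``normalized``; markers undetected in both profiles are reported
    as not detected rather than zero-fold.
    """
    deltas = []
    for rule in panel.rules:
        marker = getattr(rule, "marker", None)
        if marker is None:
            continue
        b = profile_before.nre_over_dp2s1.get(marker)
        a = profile_after.nre_over_dp2s1.get(marker)
        if b is None and a is None:
            deltas.append(MarkerDelta(marker, None, None, None, False, detected=False))
            continue
        b = b or 0.0
        a = a or 0.0
        fold = a / b if b > 0 else None
        deltas.append(
            MarkerDelta(marker, b, a, fold, normalized=a < presence_threshold)
        )
    return deltas


def panels_to_json(panels: tuple) -> str:
    payload = []
    for p in panels:
        rules = []
        for r in p.rules:
            if isinstance(r, PresenceRule):
                rules.append(
                    dict(kind="presence", marker=r.marker, min_pct=r.min_pct,
                         max_control_pct=r.max_control_pct,
                         min_fold_over_control=r.min_fold_over_control)
                )
            else:
                rules.append(dict(kind="ratio", cutoff=r.cutoff))
        payload.append(dict(subtype=p.subtype, rules=rules))
    return json.dumps(payload, indent=2)


def panels_from_json(text: str) -> tuple:
    panels = []
    for entry in json.loads(text):
        rules = []
        for r in entry["rules"]:
            kind = r.pop("kind")
            if kind == "presence":
                rules.append(PresenceRule(**r))
            elif kind == "ratio":
                rules.append(RatioRule(**r))
            else:
                raise ConfigError(f"unknown rule kind {kind!r}")
        panels.append(BiomarkerPanel(entry["subtype"], tuple(rules)))
    return tuple(panels)
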