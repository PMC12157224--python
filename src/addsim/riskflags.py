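"""Environmental-risk decision rules over LogP and TPSA.

Additive screening uses two physicochemical axes: lipophilicity (LogP,
bioaccumulation potential) and topological polar surface area (TPSA,
membrane permeability).  Each axis is partitioned into ordered classes,
and a joint flag combines them: a compound that is strongly lipophilic
(LogP > 5) yet membrane-permeable (TPSA < 75 Å²) is flagged as a
potential hazard; intermediate combinations warrant further
investigation; everything else is low risk.  Very high TPSA (> 140 Å²)
indicates a molecule too polar to cross lipid membranes, which overrides
the lipophilicity hazard in the joint flag.

Boundary values (1, 3, 5, 60, 75, 140) are assigned to classes with the
closed/half-open intervals documented on each function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RiskAssessment",
    "classify_logp",
    "classify_tpsa",
    "joint_flag",
    "assess",
]

LOGP_CLASSES = ("high_bioaccumulation", "borderline", "mild",
                "low_lipophilicity")
TPSA_CLASSES = ("reduced_systemic", "higher_safety", "borderline", "concern")
JOINT_FLAGS = ("hazard", "investigate", "low_risk")


@dataclass
class RiskAssessment:
    cid: int | None
    logp: float
    tpsa: float
    logp_class: str
    tpsa_class: str
    joint_flag: str


def classify_logp(logp: float) -> str:
    """Lipophilicity class.

    > 5 → high_bioaccumulation; (3, 5] → borderline; [1, 3] → mild;
    < 1 → low_lipophilicity.
    """
    if not math.isfinite(logp):
        raise ValueError("LogP must be finite")
    if logp > 5:
        return "high_bioaccumulation"
    if logp > 3:
        return "borderline"
    if logp >= 1:
        return "mild"
    return "low_lipophilicity"


def classify_tpsa(tpsa: float) -> str:
    """Polar-surface-area class.

    > 140 → reduced_systemic; (75, 140] → higher_safety;
    [60, 75] → borderline; < 60 → concern.
    """
    if not math.isfinite(tpsa) or tpsa < 0:
        raise ValueError("TPSA must be finite and non-negative")
    if tpsa > 140:
        return "reduced_systemic"
    if tpsa > 75:
        return "higher_safety"
    if tpsa >= 60:
        return "borderline"
    return "concern"


def joint_flag(logp: float, tpsa: float) -> str:
    """Joint environmental flag.

    hazard iff LogP > 5 and TPSA < 75 Å².  investigate for LogP > 5 with
    TPSA in [75, 83] Å², and for 3 < LogP < 5 with TPSA < 60 Å².
    Everything else — including very polar molecules (TPSA > 140 Å²)
    regardless of LogP — is low_risk.
    """
    if not (math.isfinite(logp) and math.isfinite(tpsa)):
        raise ValueError("inputs must be finite")
    if tpsa < 0:
        raise ValueError("TPSA must be non-negative")
    if tpsa > 140:
        return "low_risk"
    if logp > 5 and tpsa < 75:
        return "hazard"
    if logp > 5 and 75 <= tpsa <= 83:
        return "investigate"
    if 3 < logp < 5 and tpsa < 60:
        return "investigate"
    return "low_risk"


def assess(cid: int | None, logp: float, tpsa: float) -> RiskAssessment:
    """Full per-compound risk assessment record."""
    return RiskAssessment(
        cid=cid, logp=logp, tpsa=tpsa,
        logp_class=classify_logp(logp),
        tpsa_class=classify_tpsa(tpsa),
        joint_flag=joint_flag(logp, tpsa),
    )
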