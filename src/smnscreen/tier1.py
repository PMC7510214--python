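"""First-tier screening decisions with plate-level quality control.

Decision logic per well, applied to the called peak set:

1. if the Q-fragment peak is the strict maximum of the three, too little
   DNA reached the reaction — the well is retested;
2. else a clear SMN2 peak with no SMN1 peak marks a putative homozygous
   SMN1 deletion — referred to the second-tier MLPA test;
3. else a clear SMN2 peak with an SMN1 peak at or below the SD074 threshold
   control (SMN1:SMN2 = 1:5) is also referred: an SMN2:SMN1 copy ratio of
   five or more qualifies for confirmation;
4. otherwise the well is normal.

A plate is only interpretable when its control reactions behave: both blanks
show a dominant Q peak and no SMN peaks, both SD075 wells lack SMN1 while
showing SMN2, and both SD074 wells show SMN1 clearly but lower than SMN2.
"""

from __future__ import annotations

import enum
from collections.abc import Callable, Sequence
from dataclasses import dataclass

import pandas as pd

from .melt import PeakSet, PeakWindow
from .synth import Role

__all__ = [
    "Call",
    "Reason",
    "FirstTierCall",
    "PlateQc",
    "MissingControlError",
    "qc_plate",
    "sd074_reference_height",
    "classify_well",
    "resolve_retests",
    "calls_to_frame",
]


class Call(str, enum.Enum):
    NORMAL = "NORMAL"
    SECOND_TIER = "SECOND_TIER"
    RETEST = "RETEST"


class Reason(str, enum.Enum):
    SMN1_ABSENT = "SMN1_ABSENT"
    SMN1_BELOW_SD074 = "SMN1_BELOW_SD074"
    Q_DOMINANT = "Q_DOMINANT"
    ASSAY_FAILURE = "ASSAY_FAILURE"       # no peak in any window
    RETESTS_EXHAUSTED = "RETESTS_EXHAUSTED"  # fail-safe escalation
    OK = "OK"


_SECOND_TIER_REASONS = frozenset({Reason.SMN1_ABSENT, Reason.SMN1_BELOW_SD074,
                                  Reason.RETESTS_EXHAUSTED})
_RETEST_REASONS = frozenset({Reason.Q_DOMINANT, Reason.ASSAY_FAILURE})


@dataclass(frozen=True)
class FirstTierCall:
    sample_id: str
    call: Call
    reason: Reason
    sd074_smn1_height_used: float

    def __post_init__(self) -> None:
        if (self.call is Call.SECOND_TIER) != (self.reason in _SECOND_TIER_REASONS):
            raise ValueError("SECOND_TIER iff reason is an SMN1 referral reason")
        if (self.call is Call.RETEST) != (self.reason in _RETEST_REASONS):
            raise ValueError("RETEST iff reason is Q_DOMINANT or ASSAY_FAILURE")


@dataclass(frozen=True)
class PlateQc:
    plate_id: str
    blanks_ok: bool
    sd074_ok: bool
    sd075_ok: bool

    @property
    def valid(self) -> bool:
        return self.blanks_ok and self.sd074_ok and self.sd075_ok


class MissingControlError(ValueError):
    """A control role is missing or duplicated beyond its two wells."""


def _group_controls(control_peaksets: Sequence[tuple[Role, PeakSet]]
                    ) -> dict[Role, list[PeakSet]]:
    groups: dict[Role, list[PeakSet]] = {Role.BLANK: [], Role.SD074: [],
                                         Role.SD075: []}
    for role, ps in control_peaksets:
        if role not in groups:
            raise ValueError(f"{role} is not a control role")
        groups[role].append(ps)
    for role, sets in groups.items():
        if len(sets) != 2:
            raise MissingControlError(
                f"plate needs exactly 2 {role.value} control wells, "
                f"got {len(sets)}")
    return groups


def qc_plate(plate_id: str,
             control_peaksets: Sequence[tuple[Role, PeakSet]]) -> PlateQc:
    """Validate a plate's blank / SD074 / SD075 control reactions."""
    groups = _group_controls(control_peaksets)
    blanks_ok = all(
        ps.present(PeakWindow.Q)
        and not ps.present(PeakWindow.SMN1) and not ps.present(PeakWindow.SMN2)
        and ps.height(PeakWindow.Q) > max(ps.height(PeakWindow.SMN1),
                                          ps.height(PeakWindow.SMN2))
        for ps in groups[Role.BLANK])
    sd075_ok = all(
        not ps.present(PeakWindow.SMN1) and ps.present(PeakWindow.SMN2)
        for ps in groups[Role.SD075])
    sd074_ok = all(
        ps.present(PeakWindow.SMN1) and ps.present(PeakWindow.SMN2)
        and ps.height(PeakWindow.SMN1) < ps.height(PeakWindow.SMN2)
        for ps in groups[Role.SD074])
    return PlateQc(plate_id, blanks_ok, sd074_ok, sd075_ok)


def sd074_reference_height(sd074_peaksets: Sequence[PeakSet]) -> float:
    """Plate referral threshold: mean SMN1 peak height of the SD074 wells."""
    if not sd074_peaksets:
        raise ValueError("need at least one SD074 peak set")
    heights = [ps.height(PeakWindow.SMN1) for ps in sd074_peaksets]
    return float(sum(heights) / len(heights))


def classify_well(peaks: PeakSet, sd074_smn1_height: float) -> FirstTierCall:
    """Apply the first-tier decision rules to one specimen well.

    ``sd074_smn1_height`` is the plate's SD074 reference (see
    :func:`sd074_reference_height`).  The SMN1-vs-SD074 comparison is
    inclusive: a specimen whose SMN1 peak equals the threshold control's
    carries an SMN2:SMN1 ratio of at least five and is referred.
    """
    h1 = peaks.height(PeakWindow.SMN1)
    h2 = peaks.height(PeakWindow.SMN2)
    hq = peaks.height(PeakWindow.Q)
    if not any(peaks.present(w) for w in PeakWindow):
        return FirstTierCall(peaks.sample_id, Call.RETEST,
                             Reason.ASSAY_FAILURE, sd074_smn1_height)
    if hq > h1 and hq > h2:
        return FirstTierCall(peaks.sample_id, Call.RETEST, Reason.Q_DOMINANT,
                             sd074_smn1_height)
    if peaks.present(PeakWindow.SMN2) and not peaks.present(PeakWindow.SMN1):
        return FirstTierCall(peaks.sample_id, Call.SECOND_TIER,
                             Reason.SMN1_ABSENT, sd074_smn1_height)
    if peaks.present(PeakWindow.SMN2) and h1 <= sd074_smn1_height:
        return FirstTierCall(peaks.sample_id, Call.SECOND_TIER,
                             Reason.SMN1_BELOW_SD074, sd074_smn1_height)
    return FirstTierCall(peaks.sample_id, Call.NORMAL, Reason.OK,
                         sd074_smn1_height)


def resolve_retests(calls: Sequence[FirstTierCall],
                    reanalysis: Callable[[FirstTierCall], FirstTierCall],
                    max_rounds: int = 2) -> list[FirstTierCall]:
    """Re-run RETEST wells up to ``max_rounds``; escalate survivors.

    ``reanalysis`` stands for a fresh punch and reaction: it maps a RETEST
    call to a new call for the same sample.  A well that fails every round
    is escalated to SECOND_TIER rather than NORMAL — in a screening setting
    an uninterpretable well must err toward confirmation, never dismissal.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    resolved: list[FirstTierCall] = []
    for call in calls:
        rounds = 0
        while call.call is Call.RETEST and rounds < max_rounds:
            call = reanalysis(call)
            rounds += 1
        if call.call is Call.RETEST:
            call = FirstTierCall(call.sample_id, Call.SECOND_TIER,
                                 Reason.RETESTS_EXHAUSTED,
                                 call.sd074_smn1_height_used)
        resolved.append(call)
    return resolved


def calls_to_frame(calls: Sequence[FirstTierCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": c.sample_id, "call": c.call.value,
        "reason": c.reason.value,
        "sd074_ref_height": c.sd074_smn1_height_used,
    } for c in calls])
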