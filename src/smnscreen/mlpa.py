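"""Second-tier MLPA analysis: probe-ratio normalization and copy-number calls.

MLPA probe signal is proportional to target copy number times nuisance
factors (sample DNA quantity, per-probe efficiency).  Normalization is a
deterministic two-stage median scheme:

1. *intra-sample*: each probe height is divided by the median height of the
   sample's reference probes, cancelling the per-sample scale;
2. *inter-sample*: each probe's intra-sample ratio is divided by the median
   of the same statistic over a batch of reference samples of known diploid
   genotype (two copies of each SMN gene), cancelling per-probe efficiency.

A perfectly diploid sample then shows ratio 1.0 at every probe, a probe on
a 3-copy target shows 1.5, on a deleted target 0.0.  Integer copy numbers
are ``round(2 * ratio)`` of the per-target-class median ratio, with a
banding guard: a class median further than 0.2 (ratio scale) from every
half-integer band centre is flagged ambiguous for retest rather than forced
into a band.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from statistics import median

import pandas as pd

from .synth import MlpaProfile, ProbeAnnotation, ProbeTarget

__all__ = [
    "FailedReactionError",
    "CopyNumberCall",
    "BAND_HALF_WIDTH",
    "MIN_REFERENCE_PROFILES",
    "normalize",
    "call_copy_number",
    "call_sample",
    "calls_to_frame",
]

#: Maximum |ratio - band centre| accepted when snapping to an integer copy.
BAND_HALF_WIDTH = 0.2
#: Each batch must carry at least this many diploid reference samples.
MIN_REFERENCE_PROFILES = 3


class FailedReactionError(ValueError):
    """Reference-probe signal collapsed; the reaction cannot be normalized."""


@dataclass(frozen=True)
class CopyNumberCall:
    """Integer SMN1/SMN2 exon-7 copy calls (``None`` when ambiguous)."""

    sample_id: str
    smn1_copies_called: int | None
    smn2_copies_called: int | None
    probe_ratios: dict[str, float]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.probe_ratios.values()):
            raise ValueError("probe ratios must be non-negative")

    @property
    def confirmed_positive(self) -> bool:
        """True iff the sample is confirmed to carry zero SMN1 exon-7 copies."""
        return self.smn1_copies_called == 0

    @property
    def needs_retest(self) -> bool:
        return self.smn1_copies_called is None or self.smn2_copies_called is None


def _intra_sample_ratios(profile: MlpaProfile) -> dict[str, float]:
    ref_heights = [h for p, h in profile.probe_heights.items()
                   if profile.probe_annotations[p].target is ProbeTarget.REFERENCE]
    med = median(ref_heights)
    if med <= 0:
        raise FailedReactionError(
            f"{profile.sample_id}: median reference-probe height is zero")
    return {p: h / med for p, h in profile.probe_heights.items()}


def normalize(profile: MlpaProfile,
              reference_profiles: Sequence[MlpaProfile]) -> dict[str, float]:
    """Two-stage median normalization of one profile against a batch.

    ``reference_profiles`` must be at least :data:`MIN_REFERENCE_PROFILES`
    samples of known diploid (2, 2) genotype.  The output is invariant to
    any global rescaling of the profile's heights.
    """
    if len(reference_profiles) < MIN_REFERENCE_PROFILES:
        raise ValueError(f"need >= {MIN_REFERENCE_PROFILES} reference profiles, "
                         f"got {len(reference_profiles)}")
    sample = _intra_sample_ratios(profile)
    ref_ratios = [_intra_sample_ratios(r) for r in reference_profiles]
    out: dict[str, float] = {}
    for probe, r in sample.items():
        denom = median(rr[probe] for rr in ref_ratios)
        if denom <= 0:
            raise FailedReactionError(
                f"reference batch has no signal for probe {probe}")
        out[probe] = r / denom
    return out


def _band(ratio: float) -> int | None:
    copies = round(2 * ratio)
    if abs(2 * ratio - copies) <= 2 * BAND_HALF_WIDTH:
        return int(copies)
    return None


def call_copy_number(sample_id: str,
                     ratios: Mapping[str, float],
                     annotations: Mapping[str, ProbeAnnotation] | None = None
                     ) -> CopyNumberCall:
    """Integer copy numbers from normalized ratios.

    The call per SMN gene uses the exon-7 probe class (the disease-defining
    locus); exon-8 classes are evaluated too and any disagreement with the
    exon-7 call is flagged (partial-gene events, probe failures).
    """
    if annotations is None:
        from .synth import MLPA_PANEL
        annotations = MLPA_PANEL
    by_class: dict[ProbeTarget, list[float]] = {}
    for probe, ratio in ratios.items():
        by_class.setdefault(annotations[probe].target, []).append(ratio)
    calls: dict[ProbeTarget, int | None] = {}
    flags: list[str] = []
    for target in (ProbeTarget.SMN1_EX7, ProbeTarget.SMN2_EX7,
                   ProbeTarget.SMN1_EX8, ProbeTarget.SMN2_EX8):
        combined = median(by_class[target])
        calls[target] = _band(combined)
        if calls[target] is None:
            flags.append(f"{target.value}_AMBIGUOUS")
    for ex7, ex8 in ((ProbeTarget.SMN1_EX7, ProbeTarget.SMN1_EX8),
                     (ProbeTarget.SMN2_EX7, ProbeTarget.SMN2_EX8)):
        if (calls[ex7] is not None and calls[ex8] is not None
                and calls[ex7] != calls[ex8]):
            flags.append(f"{ex7.value.split('_')[0]}_EXON_DISCORDANT")
    return CopyNumberCall(sample_id, calls[ProbeTarget.SMN1_EX7],
                          calls[ProbeTarget.SMN2_EX7], dict(ratios),
                          tuple(flags))


def call_sample(profile: MlpaProfile,
                reference_profiles: Sequence[MlpaProfile]) -> CopyNumberCall:
    """Normalize one profile against a batch and call copy numbers."""
    ratios = normalize(profile, reference_profiles)
    return call_copy_number(profile.sample_id, ratios,
                            profile.probe_annotations)


def calls_to_frame(calls: Sequence[CopyNumberCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": c.sample_id,
        "smn1_cn": "" if c.smn1_copies_called is None else c.smn1_copies_called,
        "smn2_cn": "" if c.smn2_copies_called is None else c.smn2_copies_called,
        "confirmed_positive": c.confirmed_positive,
        "flags": ";".join(c.flags),
    } for c in calls])
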