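"""Synthetic dried-blood-spot cohorts, melt curves, plates and MLPA profiles.

This module generates everything the two-tiered SMA screening pipeline
consumes: genotype cohorts with configurable DNA-yield and blood-saturation
distributions, per-well probe-dissociation (melt) curves, 96-well plate
layouts with the assay's control reactions, and MLPA probe-height tables.

The melt-curve model
--------------------
A single fluorescent probe hybridises to asymmetrically amplified SMN1 and
SMN2 exon-7 amplicons and to a mismatched quantity ("Q") competitor
oligonucleotide.  Each duplex species dissociates around its own melting
temperature, producing a sigmoidal drop in fluorescence; the negative first
derivative therefore shows up to three peaks (SMN1 ~63 degC, SMN2 ~56 degC,
Q ~49 degC).  Fluorescence is modelled as

    F(T) = quench(blood_load) * [ baseline
                                  + A_smn1 * sigma((Tm1' - T) / w)
                                  + A_smn2 * sigma((Tm2  - T) / w)
                                  + A_q    * sigma((TmQ  - T) / w) ] + noise

with ``sigma`` the standard logistic function and ``Tm1' = Tm1 + shift`` for
probe-region sequence variants (shifts are never positive: any mismatch under
the probe lowers the duplex melting temperature).

Because the asymmetric PCR is driven to plateau, the SMN amplitudes split a
fixed total by copy *ratio*, not absolute copy number: genotypes (1,1) and
(2,2) produce identical curves, which is what makes the assay blind to
carriers.  The Q competitor takes the remaining amplitude through a
Michaelis-like competition term, so its peak only dominates when very little
input DNA is present.  Oversaturated blood spots quench the Cy5 signal
multiplicatively.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import string
import zlib
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "ProbeTarget",
    "Genotype",
    "SampleSpec",
    "MeltCurve",
    "PlateLayout",
    "ProbeAnnotation",
    "MlpaProfile",
    "SimulationConfig",
    "VALIDATION_COHORT_COMPOSITION",
    "MLPA_PANEL",
    "generate_cohort",
    "simulate_melt_curve",
    "simulate_mlpa_profile",
    "make_probe_efficiencies",
    "build_plates",
    "amplitudes",
    "temperature_grid",
    "melt_curves_to_frame",
    "cohort_to_frame",
    "plates_to_frame",
    "mlpa_profiles_to_frame",
]


class Role(str, enum.Enum):
    """What a well contains: a screening specimen or one of the controls."""

    SPECIMEN = "SPECIMEN"
    BLANK = "BLANK"      # blank DBS card, no DNA
    SD074 = "SD074"      # threshold control, SMN1:SMN2 = 1:5
    SD075 = "SD075"      # positive control, no SMN1


class ProbeTarget(str, enum.Enum):
    SMN1_EX7 = "SMN1_EX7"
    SMN2_EX7 = "SMN2_EX7"
    SMN1_EX8 = "SMN1_EX8"
    SMN2_EX8 = "SMN2_EX8"
    REFERENCE = "REFERENCE"


@dataclass(frozen=True, order=True)
class Genotype:
    """SMN1/SMN2 exon-7 copy numbers.

    Complete absence of both genes is embryonically lethal, so every
    generated individual carries at least one copy of one gene.
    """

    smn1_copies: int
    smn2_copies: int

    def __post_init__(self) -> None:
        for name in ("smn1_copies", "smn2_copies"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if not 0 <= v <= 6:
                raise ValueError(f"{name} must be in [0, 6], got {v}")
        if self.smn1_copies + self.smn2_copies < 1:
            raise ValueError("genotype (0, 0) is disallowed: complete absence "
                             "of both SMN genes is lethal")

    @property
    def total_copies(self) -> int:
        return self.smn1_copies + self.smn2_copies


@dataclass(frozen=True)
class SampleSpec:
    """Everything needed to simulate one well.

    ``blood_load`` is the relative spot saturation (1.0 = saturated card,
    > 1 oversaturated, quenching the Cy5 signal).  ``probe_region_tm_shift_c``
    models a sequence variant under the probe; it can only lower the SMN1
    melting temperature, never raise it.  ``smn1_nonfunctional`` marks the
    rare SMA case caused by an intragenic point mutation rather than exon-7
    deletion — such samples are, by design, invisible to the screen.
    """

    sample_id: str
    genotype: Genotype | None
    input_dna_ng: float
    blood_load: float = 1.0
    probe_region_tm_shift_c: float = 0.0
    role: Role = Role.SPECIMEN
    smn1_nonfunctional: bool = False

    def __post_init__(self) -> None:
        if self.input_dna_ng < 0:
            raise ValueError("input_dna_ng must be >= 0")
        if self.blood_load < 0:
            raise ValueError("blood_load must be >= 0")
        if self.probe_region_tm_shift_c > 0:
            raise ValueError("probe_region_tm_shift_c must be <= 0: probe "
                             "mismatches only ever lower the melting temperature")
        if self.role is Role.BLANK:
            if self.input_dna_ng != 0:
                raise ValueError("BLANK wells carry no DNA")
        else:
            if self.role is Role.SPECIMEN and self.input_dna_ng <= 0:
                raise ValueError("SPECIMEN wells need input_dna_ng > 0")
            if self.genotype is None:
                raise ValueError(f"{self.role.value} wells need a genotype")
        if self.role is Role.SD074:
            g = self.genotype
            assert g is not None
            if g.smn1_copies < 1 or g.smn2_copies != 5 * g.smn1_copies:
                raise ValueError("SD074 must have SMN1:SMN2 = 1:5")
        if self.role is Role.SD075:
            assert self.genotype is not None
            if self.genotype.smn1_copies != 0:
                raise ValueError("SD075 must lack SMN1 entirely")


@dataclass(frozen=True)
class MeltCurve:
    """Fluorescence sampled on a rising temperature grid for one well."""

    sample_id: str
    temperatures_c: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_c, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures_c", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("temperature grid must be a 1-D array of >= 2 points")
        if f.shape != t.shape:
            raise ValueError("fluorescence and temperature grids differ in length")
        steps = np.diff(t)
        if not (steps > 0).all():
            raise ValueError("temperature grid must be strictly increasing")
        if steps.max() > 0.5 + 1e-9:
            raise ValueError("temperature grid step must be <= 0.5 degC")
        if t[0] > 45.0 + 1e-9 or t[-1] < 72.0 - 1e-9:
            raise ValueError("temperature grid must cover at least [45, 72] degC")
        if not np.isfinite(f).all():
            raise ValueError("fluorescence must be finite")
        if (f < 0).any():
            raise ValueError("fluorescence must be non-negative")

    @property
    def step_c(self) -> float:
        return float(np.median(np.diff(self.temperatures_c)))


#: 96-well coordinates in row-major order, A1 .. H12.
WELL_POSITIONS: tuple[str, ...] = tuple(
    f"{row}{col}" for row in string.ascii_uppercase[:8] for col in range(1, 13)
)

#: Control wells per plate: 2 blanks, 2 SD074, 2 SD075.
CONTROL_WELL_COUNT = 6
SPECIMENS_PER_PLATE = 90


@dataclass(frozen=True)
class PlateLayout:
    """One 96-well plate: 2 blanks + 2 SD074 + 2 SD075 + up to 90 specimens."""

    plate_id: str
    wells: dict[str, SampleSpec]

    def __post_init__(self) -> None:
        if len(self.wells) > 96:
            raise ValueError("a plate has at most 96 wells")
        unknown = set(self.wells) - set(WELL_POSITIONS)
        if unknown:
            raise ValueError(f"invalid well positions: {sorted(unknown)}")
        counts = {role: 0 for role in Role}
        for spec in self.wells.values():
            counts[spec.role] += 1
        for role, want in ((Role.BLANK, 2), (Role.SD074, 2), (Role.SD075, 2)):
            if counts[role] != 2:
                raise ValueError(f"plate needs exactly 2 {role.value} wells, "
                                 f"got {counts[role]}")
        if counts[Role.SPECIMEN] > SPECIMENS_PER_PLATE:
            raise ValueError(f"at most {SPECIMENS_PER_PLATE} specimens per plate")

    def specimens(self) -> list[tuple[str, SampleSpec]]:
        return [(w, s) for w, s in self.wells.items() if s.role is Role.SPECIMEN]

    def controls(self) -> list[tuple[str, SampleSpec]]:
        return [(w, s) for w, s in self.wells.items() if s.role is not Role.SPECIMEN]


@dataclass(frozen=True)
class ProbeAnnotation:
    target: ProbeTarget
    expected_reference_copies: int = 2


def _default_panel() -> dict[str, ProbeAnnotation]:
    # Synthetic stand-in for a diagnostic SMA MLPA panel: 2 probes per
    # SMN exon class (4 SMN1-specific + 4 SMN2-specific) and 10 autosomal
    # reference probes at diploid loci.
    panel: dict[str, ProbeAnnotation] = {}
    for target in (ProbeTarget.SMN1_EX7, ProbeTarget.SMN2_EX7,
                   ProbeTarget.SMN1_EX8, ProbeTarget.SMN2_EX8):
        for i in (1, 2):
            panel[f"{target.value}_p{i}"] = ProbeAnnotation(target)
    for i in range(1, 11):
        panel[f"REF_{i:02d}"] = ProbeAnnotation(ProbeTarget.REFERENCE)
    return panel


#: Fixed synthetic MLPA probe panel used by the generator and the caller.
MLPA_PANEL: dict[str, ProbeAnnotation] = _default_panel()


@dataclass(frozen=True)
class MlpaProfile:
    """Raw MLPA probe heights plus the panel annotation for one sample."""

    sample_id: str
    probe_heights: dict[str, float]
    probe_annotations: dict[str, ProbeAnnotation] = field(
        default_factory=lambda: dict(MLPA_PANEL))

    def __post_init__(self) -> None:
        if set(self.probe_heights) != set(self.probe_annotations):
            raise ValueError("probe_heights and probe_annotations must cover "
                             "the same probe ids")
        if any(h < 0 for h in self.probe_heights.values()):
            raise ValueError("probe heights must be non-negative")
        by_target: dict[ProbeTarget, int] = {t: 0 for t in ProbeTarget}
        for ann in self.probe_annotations.values():
            by_target[ann.target] += 1
        if by_target[ProbeTarget.REFERENCE] < 8:
            raise ValueError("panel needs >= 8 reference probes")
        for t in ProbeTarget:
            if t is not ProbeTarget.REFERENCE and by_target[t] < 2:
                raise ValueError(f"panel needs >= 2 {t.value} probes")


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and statistical parameters of the simulated assay.

    Melting temperatures are the assay's three designed transitions; the
    SMN1 transition is deliberately the hottest so that any probe-region
    variant (which can only lower Tm) moves a peak *out* of the SMN1 window,
    failing safe toward referral.  ``q_competition_k`` (ng) sets where the Q
    competitor wins: its peak dominates only when the input DNA falls below
    roughly ``2 * q_competition_k``, about 10% of a saturated-spot yield.
    ``curve_noise_sd`` is additive fluorescence noise in absolute units
    (default 0.3% of ``amplitude_total``); ``mlpa_cv`` is the multiplicative
    per-probe coefficient of variation of the MLPA reaction.
    """

    rng_seed: int = 0
    tm_smn1_c: float = 63.0
    tm_smn2_c: float = 56.0
    tm_q_c: float = 49.0
    transition_width_c: float = 1.0
    amplitude_total: float = 10.0
    q_competition_k: float = 0.5
    quench_coefficient: float = 0.7
    curve_noise_sd: float = 0.03
    mlpa_cv: float = 0.05
    baseline_level: float = 0.5
    temp_min_c: float = 45.0
    temp_max_c: float = 75.0
    temp_step_c: float = 0.2
    # DBS extraction yield (ng per 1.5 mm punch), lognormal; spot saturation.
    dna_ng_median: float = 5.0
    dna_ng_log_sd: float = 0.25
    blood_load_mean: float = 1.0
    blood_load_sd: float = 0.1
    control_dna_ng: float = 5.0
    # MLPA nuisance scales (per-sample lognormal scale, per-probe efficiency).
    mlpa_sample_scale_log_sd: float = 0.2
    mlpa_probe_efficiency_log_sd: float = 0.15

    def __post_init__(self) -> None:
        if not (self.tm_q_c < self.tm_smn2_c < self.tm_smn1_c):
            raise ValueError("melting temperatures must satisfy Q < SMN2 < SMN1")
        for name in ("transition_width_c", "amplitude_total", "q_competition_k",
                     "quench_coefficient", "temp_step_c", "dna_ng_median",
                     "control_dna_ng"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("curve_noise_sd", "mlpa_cv", "baseline_level",
                     "dna_ng_log_sd", "blood_load_sd",
                     "mlpa_sample_scale_log_sd", "mlpa_probe_efficiency_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.temp_min_c > 45 or self.temp_max_c < 72:
            raise ValueError("temperature range must cover [45, 72] degC")


#: SMN1 x SMN2 exon-7 copy-number cross-tabulation of the published Dutch
#: 422-sample validation cohort (47 SMA patients with 0 SMN1 copies, 375
#: newborn-screening controls), as determined by second-tier MLPA.
VALIDATION_COHORT_COMPOSITION: dict[Genotype, int] = {
    Genotype(0, 1): 1, Genotype(0, 2): 13, Genotype(0, 3): 27, Genotype(0, 4): 6,
    Genotype(1, 1): 3, Genotype(1, 2): 2, Genotype(1, 3): 4,
    Genotype(2, 0): 24, Genotype(2, 1): 135, Genotype(2, 2): 165,
    Genotype(2, 3): 7, Genotype(2, 4): 1,
    Genotype(3, 0): 3, Genotype(3, 1): 14, Genotype(3, 2): 12, Genotype(3, 3): 1,
    Genotype(4, 0): 2, Genotype(4, 1): 1, Genotype(4, 2): 1,
}


def _sample_rng(config: SimulationConfig, sample_id: str, *,
                stream: str = "") -> np.random.Generator:
    """Deterministic per-sample generator derived from the config seed."""
    key = zlib.crc32(f"{stream}:{sample_id}".encode())
    return np.random.default_rng(np.random.SeedSequence([config.rng_seed, key]))


def temperature_grid(config: SimulationConfig) -> np.ndarray:
    n = int(round((config.temp_max_c - config.temp_min_c) / config.temp_step_c))
    return config.temp_min_c + config.temp_step_c * np.arange(n + 1)


def amplitudes(spec: SampleSpec,
               config: SimulationConfig) -> tuple[float, float, float]:
    """Plateau amplitudes (A_smn1, A_smn2, A_q) for one well.

    The probe-bound amplitude available to the SMN amplicons saturates with
    input DNA, ``S = A_tot * D / (D + k)``, and is split between SMN1 and
    SMN2 in proportion to their copy numbers; the Q competitor takes the
    complement ``A_tot * k / (D + k)``.  Only the copy *ratio* is visible.
    """
    d = spec.input_dna_ng
    total = config.amplitude_total
    smn_share = total * d / (d + config.q_competition_k)
    a_q = total * config.q_competition_k / (d + config.q_competition_k)
    g = spec.genotype
    if g is None or g.total_copies == 0 or smn_share == 0:
        return 0.0, 0.0, a_q
    a1 = smn_share * g.smn1_copies / g.total_copies
    a2 = smn_share * g.smn2_copies / g.total_copies
    return a1, a2, a_q


def _quench(blood_load: float, config: SimulationConfig) -> float:
    return math.exp(-config.quench_coefficient * max(0.0, blood_load - 1.0))


def simulate_melt_curve(spec: SampleSpec, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> MeltCurve:
    """Simulate the fluorescence-vs-temperature curve for one well.

    ``rng`` defaults to a generator derived deterministically from
    ``config.rng_seed`` and ``spec.sample_id``, so repeated calls for the
    same sample reproduce the same noise realisation.
    """
    if rng is None:
        rng = _sample_rng(config, spec.sample_id, stream="melt")
    t = temperature_grid(config)
    a1, a2, a_q = amplitudes(spec, config)
    w = config.transition_width_c

    def sigma(tm: float) -> np.ndarray:
        # logistic dissociation: fully bound well below Tm, released above
        return 1.0 / (1.0 + np.exp(-(tm - t) / w))

    tm1 = config.tm_smn1_c + spec.probe_region_tm_shift_c
    f = config.baseline_level + a1 * sigma(tm1) + a2 * sigma(config.tm_smn2_c) \
        + a_q * sigma(config.tm_q_c)
    f *= _quench(spec.blood_load, config)
    if config.curve_noise_sd > 0:
        f = f + rng.normal(0.0, config.curve_noise_sd, size=t.size)
    return MeltCurve(spec.sample_id, t, np.clip(f, 0.0, None))


def generate_cohort(composition: Mapping[Genotype | tuple[int, int], int],
                    seed: int,
                    config: SimulationConfig | None = None) -> list[SampleSpec]:
    """Generate a randomized cohort of SPECIMEN wells.

    ``composition`` maps genotypes (or ``(smn1, smn2)`` tuples) to counts.
    Input-DNA yield is lognormal and spot saturation truncated-normal, both
    parameterised by ``config``.  The returned order is a seeded permutation
    (the validation study analysed anonymized, randomized cards).
    """
    config = config or SimulationConfig()
    genotypes: list[Genotype] = []
    for g, count in composition.items():
        if not isinstance(g, Genotype):
            g = Genotype(*g)
        if count < 0:
            raise ValueError("composition counts must be >= 0")
        genotypes.extend([g] * int(count))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genotypes))
    specs = []
    for i, idx in enumerate(order):
        dna = float(rng.lognormal(math.log(config.dna_ng_median),
                                  config.dna_ng_log_sd))
        load = float(np.clip(rng.normal(config.blood_load_mean,
                                        config.blood_load_sd), 0.2, None))
        specs.append(SampleSpec(sample_id=f"S{i + 1:04d}",
                                genotype=genotypes[idx],
                                input_dna_ng=dna, blood_load=load))
    return specs


def _control_specs(plate_id: str, config: SimulationConfig) -> list[SampleSpec]:
    d = config.control_dna_ng
    return [
        SampleSpec(f"{plate_id}_BLANK1", None, 0.0, 0.0, role=Role.BLANK),
        SampleSpec(f"{plate_id}_BLANK2", None, 0.0, 0.0, role=Role.BLANK),
        SampleSpec(f"{plate_id}_SD074a", Genotype(1, 5), d, 0.0, role=Role.SD074),
        SampleSpec(f"{plate_id}_SD074b", Genotype(1, 5), d, 0.0, role=Role.SD074),
        SampleSpec(f"{plate_id}_SD075a", Genotype(0, 2), d, 0.0, role=Role.SD075),
        SampleSpec(f"{plate_id}_SD075b", Genotype(0, 2), d, 0.0, role=Role.SD075),
    ]


def build_plates(specimens: list[SampleSpec], seed: int,
                 config: SimulationConfig | None = None) -> list[PlateLayout]:
    """Partition specimens onto 96-well plates with the 6 control wells.

    Controls occupy A1–A6 on every plate; specimens fill the remaining wells
    in a seeded shuffle of positions (plate layout randomization).
    """
    if not specimens:
        raise ValueError("specimen list must be non-empty")
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    plates = []
    for p, start in enumerate(range(0, len(specimens), SPECIMENS_PER_PLATE)):
        plate_id = f"P{p + 1:02d}"
        chunk = specimens[start:start + SPECIMENS_PER_PLATE]
        wells: dict[str, SampleSpec] = dict(
            zip(WELL_POSITIONS[:CONTROL_WELL_COUNT],
                _control_specs(plate_id, config)))
        open_positions = list(WELL_POSITIONS[CONTROL_WELL_COUNT:])
        positions = rng.permutation(open_positions)[:len(chunk)]
        wells.update(zip(positions.tolist(), chunk))
        plates.append(PlateLayout(plate_id, wells))
    return plates


def make_probe_efficiencies(config: SimulationConfig,
                            rng: np.random.Generator | None = None
                            ) -> dict[str, float]:
    """Per-probe ligation/amplification efficiencies, fixed for one run."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.rng_seed, zlib.crc32(b"mlpa-eff")]))
    sd = config.mlpa_probe_efficiency_log_sd
    return {p: float(rng.lognormal(0.0, sd)) for p in MLPA_PANEL}


def simulate_mlpa_profile(spec: SampleSpec, config: SimulationConfig,
                          rng: np.random.Generator | None = None,
                          efficiencies: Mapping[str, float] | None = None
                          ) -> MlpaProfile:
    """Simulate an MLPA probe-height table: h_p = s * k_p * c_p * (1 + eps).

    ``s`` is a per-sample lognormal scale (DNA quantity / overall reaction
    strength), ``k_p`` the run-fixed probe efficiency, ``c_p`` the copy
    number of the probe's target (reference probes: 2), and ``eps`` has
    coefficient of variation ``config.mlpa_cv``.  Exon-8 copies are assumed
    equal to exon-7 copies (whole-gene deletions/duplications).
    """
    if spec.genotype is None:
        raise ValueError("MLPA simulation needs a genotyped sample")
    if rng is None:
        rng = _sample_rng(config, spec.sample_id, stream="mlpa")
    if efficiencies is None:
        efficiencies = make_probe_efficiencies(config)
    g = spec.genotype
    copies = {
        ProbeTarget.SMN1_EX7: g.smn1_copies, ProbeTarget.SMN1_EX8: g.smn1_copies,
        ProbeTarget.SMN2_EX7: g.smn2_copies, ProbeTarget.SMN2_EX8: g.smn2_copies,
        ProbeTarget.REFERENCE: 2,
    }
    s = float(rng.lognormal(0.0, config.mlpa_sample_scale_log_sd))
    heights = {}
    for probe, ann in MLPA_PANEL.items():
        c = copies[ann.target]
        eps = rng.normal(0.0, config.mlpa_cv) if config.mlpa_cv > 0 else 0.0
        heights[probe] = max(0.0, s * efficiencies[probe] * c * (1.0 + eps))
    return MlpaProfile(spec.sample_id, heights)


# ---------------------------------------------------------------------------
# tabular export (long-format CSV conventions shared with the CLI)

def melt_curves_to_frame(curves: Iterable[MeltCurve],
                         wells: Mapping[str, str] | None = None) -> pd.DataFrame:
    wells = wells or {}
    parts = []
    for c in curves:
        parts.append(pd.DataFrame({
            "sample_id": c.sample_id,
            "well": wells.get(c.sample_id, ""),
            "temperature_c": c.temperatures_c,
            "fluorescence": c.fluorescence,
        }))
    return pd.concat(parts, ignore_index=True)


def cohort_to_frame(specs: Iterable[SampleSpec]) -> pd.DataFrame:
    rows = []
    for s in specs:
        rows.append({
            "sample_id": s.sample_id,
            "role": s.role.value,
            "smn1_copies": "" if s.genotype is None else s.genotype.smn1_copies,
            "smn2_copies": "" if s.genotype is None else s.genotype.smn2_copies,
            "input_dna_ng": s.input_dna_ng,
            "blood_load": s.blood_load,
            "probe_region_tm_shift_c": s.probe_region_tm_shift_c,
            "smn1_nonfunctional": s.smn1_nonfunctional,
        })
    return pd.DataFrame(rows)


def plates_to_frame(plates: Iterable[PlateLayout]) -> pd.DataFrame:
    rows = [{"plate_id": p.plate_id, "well": w, "sample_id": s.sample_id,
             "role": s.role.value}
            for p in plates for w, s in sorted(p.wells.items())]
    return pd.DataFrame(rows)


def mlpa_profiles_to_frame(profiles: Iterable[MlpaProfile]) -> pd.DataFrame:
    rows = [{"sample_id": p.sample_id, "probe_id": probe,
             "target_class": p.probe_annotations[probe].target.value,
             "height": h}
            for p in profiles for probe, h in p.probe_heights.items()]
    return pd.DataFrame(rows)
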