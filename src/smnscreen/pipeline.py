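"""End-to-end orchestration: simulate -> melt -> tier1 -> mlpa -> metrics.

:func:`run_validation` reproduces the structure of a retrospective screening
validation: a genotype-composed cohort is distributed over 96-well plates
with control reactions, every well's melt curve is analysed and classified,
uninterpretable wells are retested with a fresh punch, every sample also
receives a second-tier MLPA copy-number call, and sensitivity / specificity /
tier-concordance are computed against the generator's ground truth.

All randomness flows from the single ``seed`` argument through spawned
NumPy bit-generator streams, so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import melt, mlpa, synth, tier1
from .melt import PeakWindow
from .synth import Genotype, Role, SampleSpec, SimulationConfig

__all__ = ["CohortResult", "run_validation", "input_range_experiment"]


@dataclass(frozen=True)
class CohortResult:
    """Cohort-level outcome of a full two-tiered validation run."""

    n_total: int
    n_screen_positive: int
    n_second_tier_controls: int
    n_retested: int
    sensitivity: float
    specificity: float
    concordance: float
    cn_table: dict[tuple[int | None, int | None], int]
    designed_miss_ids: tuple[str, ...] = ()
    excluded_plates: tuple[str, ...] = ()
    plate_qc: tuple[tier1.PlateQc, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.cn_table.values()) != self.n_total:
            raise ValueError("copy-number table must account for every sample")
        for v in (self.sensitivity, self.specificity, self.concordance):
            if not 0.0 <= v <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def to_report(self) -> dict:
        """Machine-readable report (JSON-serializable, deterministic order)."""
        return {
            "n_total": self.n_total,
            "n_screen_positive": self.n_screen_positive,
            "n_second_tier_controls": self.n_second_tier_controls,
            "n_retested": self.n_retested,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "concordance": self.concordance,
            "cn_table": {f"{k[0]},{k[1]}": v
                         for k, v in sorted(self.cn_table.items(),
                                            key=lambda kv: str(kv[0]))},
            "designed_miss_ids": list(self.designed_miss_ids),
            "excluded_plates": list(self.excluded_plates),
            "plate_qc": [{"plate_id": qc.plate_id, "blanks_ok": qc.blanks_ok,
                          "sd074_ok": qc.sd074_ok, "sd075_ok": qc.sd075_ok,
                          "valid": qc.valid} for qc in self.plate_qc],
            "provenance": self.provenance,
        }

    def summary_text(self) -> str:
        lines = [
            "Two-tiered SMA screening — cohort summary",
            f"  samples analysed        : {self.n_total}",
            f"  screen positive (tier 1): {self.n_screen_positive}",
            f"  controls referred       : {self.n_second_tier_controls}",
            f"  wells retested          : {self.n_retested}",
            f"  sensitivity             : {100 * self.sensitivity:.1f}%",
            f"  specificity             : {100 * self.specificity:.1f}%",
            f"  tier concordance        : {100 * self.concordance:.1f}%",
            "  MLPA copy-number table (SMN1, SMN2) -> count:",
        ]
        for (c1, c2), n in sorted(self.cn_table.items(),
                                  key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
            lines.append(f"    ({c1}, {c2}): {n}")
        if self.designed_miss_ids:
            lines.append("  designed misses (point-mutation SMA, not detectable "
                         "by this screen): " + ", ".join(self.designed_miss_ids))
        return "\n".join(lines)


def _analyse_well(spec: SampleSpec, config: SimulationConfig,
                  rng: np.random.Generator) -> melt.PeakSet:
    curve = synth.simulate_melt_curve(spec, config, rng=rng)
    return melt.call_peaks(melt.derivative(curve))


def run_validation(composition: Mapping[Genotype | tuple[int, int], int],
                   config: SimulationConfig | None = None,
                   seed: int = 0,
                   point_mutation_cases: int = 0,
                   max_retest_rounds: int = 2) -> CohortResult:
    """Run the complete two-tiered screen on a synthetic cohort.

    ``point_mutation_cases`` appends SMA cases caused by an intragenic point
    mutation (one non-functional SMN1 copy present): the screen cannot see
    them and the result reports them as designed misses rather than hiding
    them in the metrics.  Plates whose control reactions fail QC are excluded
    from the metrics and listed in ``excluded_plates``.
    """
    if config is None:
        config = SimulationConfig(rng_seed=seed)
    master = np.random.SeedSequence(seed)
    (cohort_ss, plate_ss, melt_ss, retest_ss, mlpa_ss) = master.spawn(5)

    specimens = synth.generate_cohort(
        composition, int(cohort_ss.generate_state(1)[0] % 2**31), config)
    pm_rng = np.random.default_rng(retest_ss.spawn(1)[0])
    for i in range(point_mutation_cases):
        specimens.append(SampleSpec(
            sample_id=f"PM{i + 1:03d}", genotype=Genotype(1, 2),
            input_dna_ng=float(pm_rng.lognormal(np.log(config.dna_ng_median),
                                                config.dna_ng_log_sd)),
            smn1_nonfunctional=True))
    plates = synth.build_plates(
        specimens, int(plate_ss.generate_state(1)[0] % 2**31), config)

    melt_streams = iter(melt_ss.spawn(96 * len(plates)))
    retest_streams = iter(retest_ss.spawn(
        2 * max_retest_rounds * len(specimens) + 4))

    by_id: dict[str, SampleSpec] = {s.sample_id: s for s in specimens}
    final_calls: dict[str, tier1.FirstTierCall] = {}
    retested: set[str] = set()
    qcs: list[tier1.PlateQc] = []
    excluded: list[str] = []
    analysed: list[SampleSpec] = []

    for plate in plates:
        control_sets = [(s.role, _analyse_well(
            s, config, np.random.default_rng(next(melt_streams))))
            for _, s in plate.controls()]
        qc = tier1.qc_plate(plate.plate_id, control_sets)
        qcs.append(qc)
        if not qc.valid:
            excluded.append(plate.plate_id)
            continue
        ref = tier1.sd074_reference_height(
            [ps for role, ps in control_sets if role is Role.SD074])
        plate_calls = []
        for _, spec in plate.specimens():
            ps = _analyse_well(spec, config,
                               np.random.default_rng(next(melt_streams)))
            plate_calls.append(tier1.classify_well(ps, ref))
            analysed.append(spec)

        def reanalyse(call: tier1.FirstTierCall,
                      _ref: float = ref) -> tier1.FirstTierCall:
            # fresh punch: new DNA yield and saturation, new noise draw
            retested.add(call.sample_id)
            rng = np.random.default_rng(next(retest_streams))
            old = by_id[call.sample_id]
            fresh = dataclasses.replace(
                old,
                input_dna_ng=float(rng.lognormal(np.log(config.dna_ng_median),
                                                 config.dna_ng_log_sd)),
                blood_load=float(np.clip(rng.normal(config.blood_load_mean,
                                                    config.blood_load_sd),
                                         0.2, None)))
            return tier1.classify_well(_analyse_well(fresh, config, rng), _ref)

        for call in tier1.resolve_retests(plate_calls, reanalyse,
                                          max_retest_rounds):
            final_calls[call.sample_id] = call

    # Second tier: every analysed sample gets an MLPA copy-number call,
    # normalized against a batch of diploid reference reactions.
    mlpa_rng = np.random.default_rng(mlpa_ss)
    efficiencies = synth.make_probe_efficiencies(config, rng=mlpa_rng)
    references = [synth.simulate_mlpa_profile(
        SampleSpec(f"REF{i}", Genotype(2, 2), config.control_dna_ng),
        config, rng=mlpa_rng, efficiencies=efficiencies) for i in range(1, 4)]
    cn_calls: dict[str, mlpa.CopyNumberCall] = {}
    for spec in analysed:
        # an ambiguous copy-number call triggers one MLPA retest
        for _attempt in range(2):
            profile = synth.simulate_mlpa_profile(spec, config, rng=mlpa_rng,
                                                  efficiencies=efficiencies)
            cn_calls[spec.sample_id] = mlpa.call_sample(profile, references)
            if not cn_calls[spec.sample_id].needs_retest:
                break

    tp = fn = tn = fp = agree = 0
    designed_misses: list[str] = []
    cn_table: dict[tuple[int | None, int | None], int] = {}
    for spec in analysed:
        call = final_calls[spec.sample_id]
        cn = cn_calls[spec.sample_id]
        truth_positive = spec.genotype.smn1_copies == 0
        tier1_positive = call.reason is tier1.Reason.SMN1_ABSENT
        predicted = (call.call is tier1.Call.SECOND_TIER
                     and cn.confirmed_positive)
        if truth_positive:
            tp += predicted
            fn += not predicted
        else:
            fp += predicted
            tn += not predicted
        agree += tier1_positive == cn.confirmed_positive
        if spec.smn1_nonfunctional and call.call is tier1.Call.NORMAL:
            designed_misses.append(spec.sample_id)
        key = (cn.smn1_copies_called, cn.smn2_copies_called)
        cn_table[key] = cn_table.get(key, 0) + 1

    n = len(analysed)
    referred_controls = sum(
        1 for s in analysed
        if final_calls[s.sample_id].call is tier1.Call.SECOND_TIER
        and s.genotype.smn1_copies >= 1)
    return CohortResult(
        n_total=n,
        n_screen_positive=sum(
            final_calls[s.sample_id].reason is tier1.Reason.SMN1_ABSENT
            for s in analysed),
        n_second_tier_controls=referred_controls,
        n_retested=len(retested),
        sensitivity=tp / (tp + fn) if tp + fn else 1.0,
        specificity=tn / (tn + fp) if tn + fp else 1.0,
        concordance=agree / n if n else 1.0,
        cn_table=cn_table,
        designed_miss_ids=tuple(designed_misses),
        excluded_plates=tuple(excluded),
        plate_qc=tuple(qcs),
        provenance={
            "seed": seed,
            "config": dataclasses.asdict(config),
            "composition": {f"{g.smn1_copies},{g.smn2_copies}": c
                            for g, c in sorted(
                                (g if isinstance(g, Genotype) else Genotype(*g), c)
                                for g, c in composition.items())},
            "point_mutation_cases": point_mutation_cases,
            "max_retest_rounds": max_retest_rounds,
        },
    )


def input_range_experiment(dilutions: list[float], replicates: int,
                           config: SimulationConfig | None = None,
                           seed: int = 0,
                           saturated_dna_ng: float = 10.0,
                           include_oversaturated: bool = True) -> pd.DataFrame:
    """Titration experiment: Q-peak height and total signal vs input blood.

    Each dilution ``d`` spots a diploid sample at ``saturated_dna_ng / d``;
    the optional oversaturated condition doubles both the DNA and the spot
    saturation, so the Cy5 quench *lowers* the total signal despite more
    DNA being present.  Returns one row per condition with the mean Q-peak
    height and mean integrated fluorescence over ``replicates`` wells.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if any(d <= 0 for d in dilutions):
        raise ValueError("dilutions must be positive")
    config = config or SimulationConfig()
    streams = iter(np.random.SeedSequence(seed).spawn(
        (len(dilutions) + 1) * replicates))
    conditions: list[tuple[str, float, float, float]] = [
        (f"{d:g}x diluted" if d != 1 else "saturated",
         float(d), saturated_dna_ng / d, 1.0) for d in dilutions]
    if include_oversaturated:
        conditions.append(("oversaturated", 1.0, 2 * saturated_dna_ng, 2.0))
    rows = []
    for label, dilution, dna, load in conditions:
        q_heights, totals = [], []
        for r in range(replicates):
            spec = SampleSpec(f"{label}_r{r + 1}", Genotype(2, 2), dna, load)
            curve = synth.simulate_melt_curve(
                spec, config, rng=np.random.default_rng(next(streams)))
            ps = melt.call_peaks(melt.derivative(curve))
            q_heights.append(ps.height(PeakWindow.Q))
            totals.append(float(np.trapezoid(curve.fluorescence,
                                             curve.temperatures_c)))
        rows.append({"condition": label, "dilution": dilution,
                     "blood_load": load, "input_dna_ng": dna,
                     "mean_q_height": float(np.mean(q_heights)),
                     "mean_total_signal": float(np.mean(totals))})
    return pd.DataFrame(rows)


def report_to_json(result: CohortResult) -> str:
    """Canonical JSON serialization (stable key order, fixed float repr)."""
    return json.dumps(result.to_report(), indent=2, sort_keys=False)
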